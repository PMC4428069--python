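"""Alignment of multi-distance holograms onto a common reference grid.

In a zoom scan every distance has its own magnification, so the holograms
of one projection sample the object at different effective pixels and are
shifted by runout of the positioning stages.  Before a multi-distance CTF
inversion each image is (i) rescaled about its centre by the magnification
ratio onto the grid of the reference (first) distance and (ii) registered
to the reference by subpixel phase correlation on gradient-filtered images.
Both operations and their quality scores are recorded per distance in an
:class:`AlignmentRecord` that serializes to JSON for audit.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from zoomtomo.propagation import Hologram

__all__ = [
    "ShiftEstimate",
    "AlignmentRecord",
    "resample_to_reference",
    "estimate_shift",
    "align_stack",
]

#: Rescale factors beyond this are refused by default: the finer image
#: cannot faithfully represent the coarser grid (or vice versa).
MAX_SCALE = 4.0
#: Normalized-correlation score below which a shift estimate is flagged.
LOW_CONFIDENCE_SCORE = 0.2


def resample_to_reference(
    image: np.ndarray,
    magnification: float,
    reference_magnification: float,
    *,
    order: int = 3,
    max_scale: float = MAX_SCALE,
) -> np.ndarray:
    """Rescale an image by ``M_ref/M_d`` about its centre.

    Output grid equals the input (= reference) grid; cubic-spline
    interpolation by default.  Scale factors outside
    ``[1/max_scale, max_scale]`` are refused.
    """
    if magnification <= 0 or reference_magnification <= 0:
        raise ValueError("magnifications must be positive")
    scale = reference_magnification / magnification
    if scale > max_scale or scale < 1.0 / max_scale:
        raise ValueError(
            f"rescale factor {scale:.3g} outside [{1/max_scale:.3g}, {max_scale}]: "
            "resolution mismatch too large"
        )
    if scale == 1.0:
        return np.asarray(image, dtype=np.float64).copy()
    image = np.asarray(image, dtype=np.float64)
    center = (np.asarray(image.shape) - 1) / 2.0
    # output coord y maps to input coord center + (y - center)/scale
    matrix = np.eye(2) / scale
    offset = center - matrix @ center
    return ndimage.affine_transform(
        image, matrix, offset=offset, order=order, mode="nearest"
    )


@dataclass
class ShiftEstimate:
    """Subpixel shift of a moving image relative to a reference."""

    shift: tuple[float, float]  # (dy, dx), pixels to apply to the moving image
    score: float  # normalized cross-correlation after shifting
    low_confidence: bool


def _grad(image: np.ndarray) -> np.ndarray:
    return ndimage.gaussian_gradient_magnitude(image, sigma=1.0)


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return 0.0
    return float(np.dot(a.ravel(), b.ravel()) / denom)


def _hann2d(shape: tuple[int, int]) -> np.ndarray:
    wy = np.hanning(shape[0])[:, None]
    wx = np.hanning(shape[1])[None, :]
    return wy * wx


def estimate_shift(
    reference: np.ndarray,
    moving: np.ndarray,
    *,
    upsample_factor: int = 20,
    gradient_filter: bool = True,
    max_shift: float | None = None,
    window: bool = False,
) -> ShiftEstimate:
    """Subpixel shift registering ``moving`` to ``reference``.

    Phase correlation (Fourier-upsampled to 1/``upsample_factor`` px) on
    gradient-magnitude images.  ``max_shift`` (pixels) optionally bounds
    the search: a dominant peak outside the bound is rejected in favour of
    the best correlation peak inside it, with parabolic subpixel
    refinement.  ``window`` applies a Hann window first — useful when the
    object is compact in the frame, harmful when it fills it.  The
    returned score is the normalized cross-correlation of the filtered
    images after applying the shift; estimates scoring below 0.2 carry a
    low-confidence flag.
    """
    reference = np.asarray(reference, dtype=np.float64)
    moving = np.asarray(moving, dtype=np.float64)
    if reference.shape != moving.shape:
        raise ValueError("reference and moving images must share a shape")
    ref_f = _grad(reference) if gradient_filter else reference
    mov_f = _grad(moving) if gradient_filter else moving
    ref_w = ref_f - ref_f.mean()
    mov_w = mov_f - mov_f.mean()
    if window:
        win = _hann2d(reference.shape)
        ref_w = ref_w * win
        mov_w = mov_w * win

    shift, _, _ = phase_cross_correlation(
        ref_w, mov_w, upsample_factor=upsample_factor, normalization=None
    )
    if max_shift is not None and np.any(np.abs(shift) > max_shift):
        # bounded search: cross-correlation restricted to small lags, with
        # parabolic subpixel refinement
        from scipy import fft as sp_fft

        xc = sp_fft.ifft2(
            sp_fft.fft2(ref_w) * np.conj(sp_fft.fft2(mov_w))
        ).real
        xc = sp_fft.fftshift(xc)
        cy, cx = np.asarray(xc.shape) // 2
        r = int(np.ceil(max_shift))
        window = xc[cy - r : cy + r + 1, cx - r : cx + r + 1]
        iy, ix = np.unravel_index(np.argmax(window), window.shape)
        peak = np.array([iy - r, ix - r], dtype=float)
        # parabolic refinement along each axis
        for axis in range(2):
            idx = [iy, ix]
            if 0 < idx[axis] < window.shape[axis] - 1:
                lo = list(idx)
                hi = list(idx)
                lo[axis] -= 1
                hi[axis] += 1
                ym, y0, yp = window[tuple(lo)], window[tuple(idx)], window[tuple(hi)]
                denom = ym - 2 * y0 + yp
                if denom != 0:
                    peak[axis] += 0.5 * (ym - yp) / denom
        shift = peak  # correlation peak sits at the registering shift

    shifted = ndimage.shift(mov_f, shift, order=1, mode="nearest")
    score = _ncc(ref_f, shifted)
    return ShiftEstimate(
        shift=(float(shift[0]), float(shift[1])),
        score=score,
        low_confidence=score < LOW_CONFIDENCE_SCORE,
    )


@dataclass
class AlignmentRecord:
    """Per-distance audit trail of one aligned projection."""

    scales: list[float] = field(default_factory=list)
    shifts: list[tuple[float, float]] = field(default_factory=list)
    scores: list[float] = field(default_factory=list)
    low_confidence: list[bool] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "AlignmentRecord":
        d = json.loads(text)
        d["shifts"] = [tuple(s) for s in d["shifts"]]
        return cls(**d)


def _preliminary_phase(intensity: np.ndarray, holo: Hologram,
                       effective_pixel: float) -> np.ndarray:
    """Quick single-distance CTF inversion used only as alignment target.

    Holograms recorded at different Fresnel numbers carry different fringe
    systems, so correlating them directly biases the shift estimate; their
    (approximate) phase maps all resemble the same object and register
    reliably.
    """
    from zoomtomo.phase_retrieval import ctf_factors, ctf_retrieve

    model = ctf_factors([holo.geometry], intensity.shape,
                        effective_pixel=effective_pixel)
    return ctf_retrieve([intensity], model).values


def align_stack(
    holograms: list[Hologram],
    *,
    reference_index: int = 0,
    order: int = 3,
    align_on: str = "phase",
    max_shift: float | None = 10.0,
) -> tuple[list[Hologram], AlignmentRecord]:
    """Rescale and register the holograms of one projection.

    All images end up on the grid of the reference distance (default: the
    first).  Rescaling precedes shift estimation.  ``align_on`` selects
    the registration target: ``"phase"`` (default) correlates preliminary
    single-distance phase maps, which is robust across Fresnel numbers;
    ``"holograms"`` correlates the raw corrected intensities.
    Deterministic.
    """
    if not holograms:
        raise ValueError("empty hologram list")
    if align_on not in ("phase", "holograms"):
        raise ValueError(f"unknown alignment target {align_on!r}")
    ref = holograms[reference_index]
    if ref.geometry is None:
        raise ValueError("holograms must carry geometry for alignment")
    m_ref = ref.geometry.magnification
    ref_px = ref.geometry.effective_pixel
    ref_target = None
    if align_on == "phase" and len(holograms) > 1:
        ref_target = _preliminary_phase(ref.intensity, ref, ref_px)
    record = AlignmentRecord()
    aligned: list[Hologram] = []
    for i, holo in enumerate(holograms):
        scale = m_ref / holo.geometry.magnification
        if i == reference_index:
            record.scales.append(1.0)
            record.shifts.append((0.0, 0.0))
            record.scores.append(1.0)
            record.low_confidence.append(False)
            aligned.append(holo)
            continue
        resampled = resample_to_reference(
            holo.intensity, holo.geometry.magnification, m_ref, order=order
        )
        if align_on == "phase":
            moving = _preliminary_phase(resampled, holo, ref_px)
            est = estimate_shift(ref_target, moving, max_shift=max_shift)
        else:
            est = estimate_shift(ref.intensity, resampled, max_shift=max_shift)
        moved = ndimage.shift(resampled, est.shift, order=order, mode="nearest")
        record.scales.append(scale)
        record.shifts.append(est.shift)
        record.scores.append(est.score)
        record.low_confidence.append(est.low_confidence)
        aligned.append(replace(holo, intensity=np.clip(moved, 0.0, None)))
    return aligned, record
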