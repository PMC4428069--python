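"""Density-based labelling of contrast-agent clusters in reconstructions.

Barium sulphate is several times denser (in refractive decrement) than any
soft-tissue component, so clusters separate from tissue as the upper mode
of the reconstructed-delta histogram.  Voxels above a threshold are grouped
into 26-connected components, small components are discarded, and each
cluster is summarized by centroid, volume, mean delta and bounding box.
Cluster positions can then be referred to an anatomical compartment mask
(e.g. the phantom's ground-truth anatomy, or a user segmentation).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu

from zoomtomo.tomo import ReconVolume

__all__ = [
    "default_threshold",
    "label_high_density",
    "locate_clusters",
]

#: 26-connectivity structuring element.
_CONNECTIVITY = np.ones((3, 3, 3), dtype=bool)


def default_threshold(values: np.ndarray, tail_fraction: float = 0.10) -> float:
    """Otsu two-class split restricted to the upper tail of the histogram.

    The bulk of a reconstruction is background/soft tissue; restricting the
    Otsu split to the top ``tail_fraction`` of voxel values isolates the
    tissue/contrast-agent boundary instead of the background/tissue one.
    """
    flat = np.asarray(values).ravel()
    tail = flat[flat >= np.quantile(flat, 1.0 - tail_fraction)]
    if np.ptp(tail) == 0:
        return float(tail[0])
    return float(threshold_otsu(tail))


def label_high_density(
    volume: ReconVolume | np.ndarray,
    *,
    threshold: float | None = None,
    min_size: int = 8,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Label 26-connected components above a density threshold.

    Returns ``(table, label_volume)``; the table has one row per cluster,
    sorted by volume descending with labels renumbered contiguously from 1
    (matching the label volume).  An out-of-range threshold yields an empty
    result with a warning rather than an error.
    """
    if isinstance(volume, ReconVolume):
        data = volume.delta
        voxel_size = volume.voxel_size
    else:
        data = np.asarray(volume)
        voxel_size = None
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    if threshold is None:
        threshold = default_threshold(data)
    columns = [
        "label", "centroid_z", "centroid_y", "centroid_x",
        "n_voxels", "volume_m3", "mean_delta",
        "bbox_zmin", "bbox_ymin", "bbox_xmin",
        "bbox_zmax", "bbox_ymax", "bbox_xmax",
    ]
    empty = pd.DataFrame(columns=columns)
    if threshold > data.max() or threshold < data.min():
        warnings.warn(
            f"threshold {threshold:.3g} outside the data range "
            f"[{data.min():.3g}, {data.max():.3g}]; no clusters labelled",
            RuntimeWarning,
            stacklevel=2,
        )
        return empty, np.zeros(data.shape, dtype=np.int32)

    raw_labels, n_raw = ndimage.label(data > threshold, structure=_CONNECTIVITY)
    if n_raw == 0:
        return empty, raw_labels.astype(np.int32)

    sizes = ndimage.sum_labels(
        np.ones_like(raw_labels), raw_labels, index=np.arange(1, n_raw + 1)
    )
    keep = np.where(sizes >= min_size)[0] + 1
    order = keep[np.argsort(sizes[keep - 1])[::-1]]

    out_labels = np.zeros(data.shape, dtype=np.int32)
    rows = []
    objects = ndimage.find_objects(raw_labels)
    for new_label, old_label in enumerate(order, start=1):
        sl = objects[old_label - 1]
        mask = raw_labels[sl] == old_label
        out_labels[sl][mask] = new_label
        # intensity-weighted centroid: the excess density above threshold
        # localizes a blurred cluster better than the binary footprint
        weights = np.where(mask, np.clip(data[sl] - threshold, 0, None), 0.0)
        if weights.sum() > 0:
            local_com = ndimage.center_of_mass(weights)
        else:
            local_com = ndimage.center_of_mass(mask)
        com = tuple(s.start + c for s, c in zip(sl, local_com))
        n_vox = int(mask.sum())
        rows.append({
            "label": new_label,
            "centroid_z": com[0], "centroid_y": com[1], "centroid_x": com[2],
            "n_voxels": n_vox,
            "volume_m3": np.nan if voxel_size is None else n_vox * voxel_size**3,
            "mean_delta": float(data[sl][mask].mean()),
            "bbox_zmin": sl[0].start, "bbox_ymin": sl[1].start,
            "bbox_xmin": sl[2].start,
            "bbox_zmax": sl[0].stop, "bbox_ymax": sl[1].stop,
            "bbox_xmax": sl[2].stop,
        })
    table = pd.DataFrame(rows, columns=columns) if rows else empty
    return table, out_labels


def locate_clusters(
    table: pd.DataFrame,
    label_volume: np.ndarray,
    mask: np.ndarray,
    *,
    compartment_names: dict[int, str] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Assign each cluster to a compartment of an anatomical mask.

    The primary assignment is the mask value at the cluster centroid; the
    per-compartment voxel fractions of each cluster are reported as well
    (they sum to 1 for clusters straddling boundaries).  Returns the
    augmented per-cluster table and summary counts per compartment.
    """
    mask = np.asarray(mask)
    if mask.shape != label_volume.shape:
        raise ValueError(
            f"mask shape {mask.shape} != label volume shape {label_volume.shape}"
        )

    def name_of(value: int) -> str:
        if compartment_names and value in compartment_names:
            return compartment_names[value]
        return str(value)

    records = []
    counts: dict[str, int] = {}
    for row in table.itertuples():
        centroid_idx = tuple(
            int(round(v)) for v in (row.centroid_z, row.centroid_y, row.centroid_x)
        )
        centroid_idx = tuple(
            min(max(i, 0), s - 1) for i, s in zip(centroid_idx, mask.shape)
        )
        comp = name_of(int(mask[centroid_idx]))
        counts[comp] = counts.get(comp, 0) + 1
        in_cluster = label_volume == row.label
        vals, n = np.unique(mask[in_cluster], return_counts=True)
        fractions = {name_of(int(v)): float(c) / n.sum() for v, c in zip(vals, n)}
        records.append({
            "label": row.label,
            "compartment": comp,
            "fractions": fractions,
        })
    return pd.DataFrame(records), counts
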