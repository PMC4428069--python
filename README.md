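# zoomtomo

Propagation-based phase-contrast **zoom tomography** of soft tissue, end to
end and in silico: simulate in-line holograms of a barium-labelled lung-tissue
phantom in a divergent (cone) beam, retrieve the projection phase with
multi-distance CTF or single-distance TIE inversion, reconstruct the 3D
refractive-decrement map by filtered back-projection, quantify resolution
(Fourier shell correlation with the half-bit criterion, Gaussian FWHM) and
radiation dose, and automatically segment the contrast-agent clusters.

The package is aimed at people developing or teaching near-field x-ray phase
imaging: it gives a fully controlled, seeded digital twin of a synchrotron
holo-tomography experiment in which every stage of the real analysis chain
can be exercised and scored against ground truth.

## The physics in brief

For hard x-rays the refractive index is `n = 1 − δ + iβ` with the decrement
δ exceeding the absorption index β by 2–3 orders of magnitude for soft
matter, so free-space propagation of the phase-shifted exit wave — not
absorption — carries the contrast.  A point source at distance `z1` before
the sample and a detector at `z2` behind it magnify the image by
`M = (z1+z2)/z1`; by the Fresnel scaling theorem the recorded hologram equals
a plane-wave hologram at the effective distance `z_eff = z1·z2/(z1+z2)`
sampled with the effective pixel `p/M`.  Moving the sample toward the source
therefore *zooms in* — the basis of zoom tomography.

The contrast regime is set by the Fresnel number `F = a²/(λ·z_eff)` of a
feature of size `a` (by convention ten effective pixels): `F ≳ 1` gives
edge-enhanced direct contrast, `F ≪ 1` holographic fringes.  For a weak
object the hologram spectrum obeys the contrast-transfer-function (CTF)
relation

    FT(I − 1)(f) = 2·[sin χ + (β/δ)·cos χ]·FT(φ)(f),   χ = π λ z_eff |f|²,

which is inverted by a regularized least-squares combination of several
propagation distances (the zeros of one distance are covered by the others):

    φ̂(f) = Σ_d s_d·FT(I_d − 1) / (2 Σ_d s_d² + α(f)).

The transport-of-intensity (TIE) inversion implemented alongside is the
small-χ limit of the same expression, valid only at low spatial frequency.
Retrieved phases are line integrals `φ = −k ∫ δ ds`, so slice-wise filtered
back-projection of `−φ/k` yields the 3D δ map, in which the dense barium
sulphate clusters separate from tissue by simple density thresholding.

## Worked example

```python
from zoomtomo.pipeline import default_zoom_config, run_full_pipeline

config = default_zoom_config(seed=0)   # 4-distance zoom scan, 64³ phantom,
                                       # photon noise and stage jitter on
result = run_full_pipeline(config)
print(result.metadata["n_clusters_found"], "/",
      result.metadata["n_clusters_truth"])
print(result.location_counts)
print(round(result.dose_report.dose))
```

prints

```
25 / 25
{'alveolar': 21, '1': 2, 'bronchial_wall': 1, '255': 1}
98577
```

All 25 seeded barium clusters are recovered from the noisy, jittered
four-distance scan; the compartment assignment places most in the alveolar
lumina and the bronchial wall (a few centroids land on neighbouring labels at
this noise level — the noiseless scan recovers the exact 20/5 split), and the
scan's 2.1·10⁸ photons/µm² at 13.8 keV correspond to a dose of ≈ 9.9·10⁴ Gy.
The same pipeline is scriptable from the shell:

```bash
zoomtomo demo-zoom --out runs/zoom --seed 0
zoomtomo dose --fluence 6.9e6 --energy 13.8
```

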