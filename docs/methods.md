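# Methods

This note records the models, numerical choices and known limits of the
package, in the order of the processing chain.

## Imaging geometry

A cone beam from an ideal point source is described by the focus–sample
distance `z1`, sample–detector distance `z2`, photon energy `E` and detector
pixel `p` (all SI internally; `z1 = inf` denotes plane waves).  Derived
quantities: magnification `M = (z1+z2)/z1`, effective propagation distance
`z_eff = z1 z2/(z1+z2)`, effective pixel `p/M`, wavelength `λ = hc/E` with
`hc = 1.239842 keV·nm`.  The Fresnel scaling theorem is the *only* cone-beam
mechanism in the package: every simulation and inversion works on the
parallel-equivalent problem (`z_eff`, `p/M`).  This is exact for an ideal
point source; source-size blur is off by default (a Gaussian blur hook
exists) because a ~16 nm waveguide exit is negligible at the ≥ 50 nm
resolutions targeted here.

A Fresnel number `F = a²/(λ z_eff)` with the feature-size convention
`a = 10` effective pixels classifies the regime; the label boundary is
`F ≥ 0.5` → `direct_contrast`, else `holographic`.  The physical transition
is gradual; 0.5 is a documented package convention.

## Materials

δ is computed from electron densities via `δ = r_e λ² ρ_e/(2π)`; β from
compiled mass-attenuation support points at 10/15/20/30 keV (log-log
interpolated) via `β = (μ/ρ)ρλ/(4π)`.  Water, generic soft tissue, lipid and
barium sulphate are packaged.  Different published compilations differ at
the few-percent level, and the BaSO₄/lipid entries are element-weighted
estimates of similar accuracy; dose accounting uses only the water table.

## Synthetic phantom

The phantom is a stylized hydrated lung-tissue slice: a buffer-filled
cylindrical plug (diameter 84 % of the field, axially clipped to leave
object-free margins), a parenchyma block carved by buffer-filled alveoli,
one hollow bronchial tube and one blood vessel, a few lipid droplets, and
barium-sulphate clusters grouped into macrophage-like cells of 2–4 clusters,
seeded 20 into alveolar lumina and 5 into the bronchial wall.  Cluster
centers are kept ≥ 1–2 voxels inside their compartment and cluster surfaces
≥ 4 voxels apart so that compartment assignment and component counts remain
well-defined after imaging blur — a deliberate resolution-test design.
Structure radii are specified in voxels, so the phantom is a topologically
faithful miniature at any grid size; at the 64³ desk default the physical
dimensions are far below real lung anatomy (a real alveolus would span
hundreds of 52 nm voxels), which the tests must keep in mind: they validate
the *chain*, not anatomical realism.  Generation is deterministic in
(spec, seed); ground truth (centroids, radii, compartments, pre-barium
anatomy labels) is recorded.

Projection is parallel-ray (object thickness ≪ z1): rotate the grids about
the tomographic axis (linear interpolation — bounded smoothing, fast; the
order is exposed) and sum, giving `φ = −k∫δ ds` and `B = k∫β ds`, so the
exit wave is `exp(−B + iφ)` with φ negative for matter.

## Forward holography

Propagation is spectral with kernel `exp(−iπλz|f|²)`; without padding the
operator is exactly unitary and a one-parameter group, which the tests
assert to 1e-10; simulations reflect-pad to twice the linear size to
suppress wrap-around.  When the kernel phase step at the grid edge exceeds π
per sample a warning is emitted (error in strict mode): the discrete model
then no longer represents the continuous field, though forward-and-invert
round trips on one grid remain self-consistent.  Illumination modes: flat;
`waveguide` (smooth low-order envelope); `kb_artifacts` (same envelope plus
high-frequency stripes from mirror figure errors), power-matched.
Empty-beam correction is the pixelwise ratio against the *propagated* empty
image, floored at 1e-6 of its peak.  Photon noise is Poisson at
`fluence/n_projections × (effective pixel area)` counts per pixel — the
total-scan fluence convention used in the experimental metadata.

## Phase retrieval

The CTF model and inversion are as in the README.  Numerical choices:

- Two-level regularization: `α_low` below the first zero of sin χ of the
  shortest distance, `α_high = 0.1` above.  Defaults `α_low = 1e-4`
  (noiseless) and `1e-2` in the noisy demo configurations: a 64² grid has
  ~1000× fewer pixels than the real 2048² detector, so low-frequency photon
  noise is averaged far less and needs stronger damping at the same fluence.
- Homogeneous-object coupling `β/δ` (water's ratio ≈ 1/800 at 13.8 keV in
  the demos) anchors the lowest frequencies with the absorption signal;
  `inf` gives the pure-phase variant.
- DC convention: the median phase over an object-free border (3 px default,
  or an explicit mask) is set to zero; the absolute offset is unobservable.
- Padding mirrors the propagation rule so forward and inverse grids match.
- The weak-object linearization is exact only to first order; at the
  ~0.3 rad projection phases of the desk phantom its second-order error
  appears as a smooth low-frequency bowl of a few 0.01 rad.  No iterative
  refinement is attempted (out of scope); a one-step residual correction was
  evaluated and rejected — the low-frequency residual inversion is
  ill-conditioned and degraded the result.

TIE retrieval divides the contrast spectrum by `2χ + 2β/δ + α`; it is the
small-distance limit, warned against below `F = 0.5`, and the tests show it
losing to CTF by ≥ 2× RMSE in the holographic regime while matching it in
the direct-contrast regime.

## Registration

Multi-distance holograms are rescaled about the image center by the
magnification ratio (cubic splines; factors beyond 4× refused) and then
registered by upsampled phase correlation.  Two departures from the obvious
approach, both forced by cross-Fresnel-number data: correlation is computed
on *preliminary single-distance phase maps* rather than raw holograms
(fringe systems differ between distances and bias raw-intensity
correlation), and the correlation search is bounded (default 10 px) with
parabolic refinement, since periodic FFT correlation of ring-artifact-laden
maps occasionally locks onto distant spurious peaks.  Scores are normalized
cross-correlations after shifting; < 0.2 flags low confidence.  On the
packaged constant-magnification series, injected shifts are recovered to
≲ 0.1 px; across magnifications residuals are a few tenths of a pixel.

## Tomography

Slice-wise parallel-beam FBP (ram-lak default; shepp-logan/hann options)
over the detector rows; the few-mrad cone angle after magnification
correction does not warrant cone-beam weighting.  The rotation axis is
estimated by correlating opposed (θ, θ+π) projections, mirrored; the
back-projector's axis convention (index `n//2`) is reconciled with arbitrary
sub-pixel axis positions by shifting the sinogram in and the slice back out.
Angles are radians, counter-clockwise, angle 0 projecting along +y of the
(z, y, x) volume.

## Metrology

Dose: `D[Gy] = Φ·1e12 · E[J] · (μ/ρ)`, thin-sample limit, water
coefficients.  Both total-attenuation (default) and energy-absorption
conventions are shipped; they differ by how much scattered/fluoresced energy
is assumed to escape, and bracket the published dose figures.

FSC uses unit-width spherical shells, the half-bit threshold
`T(n) = (0.2071 + 1.9102/√n)/(1.2071 + 0.9102/√n)` with n the Fourier
samples per shell, and linear interpolation of the first crossing.
`split_scan_fsc` reconstructs interleaved (even/odd) angle subsets; a
half-vs-half split is available.  FWHM fitting is a four-parameter
least-squares Gaussian (offset, amplitude, center, width), `FWHM = 2.3548σ`,
working on peaks and dips.

## Segmentation

26-connected components above a threshold, minimum size 8 voxels, labels
sorted by volume.  The default threshold is an Otsu split restricted to the
top decile of voxel values (the bulk of the histogram is
background/soft-tissue and would dominate a global Otsu).  Centroids are
intensity-weighted (excess density above threshold), which localizes blurred
clusters better than the binary footprint.  Compartment assignment is by the
anatomy label at the rounded centroid (primary) plus per-compartment voxel
fractions (auxiliary).

## Desk-scale demonstrations and problem sizes

The packaged demos run 64³ phantoms with 90–180 projections; the defaults
keep the experimental detector pixel, energies and total fluences of the two
scan designs (large FOV: 6.9·10⁶ photons/µm² at 245 nm effective pixel;
zoom: 2.1·10⁸ photons/µm² at ~52 nm, four distances) but shorten the
propagation distances so the fringes stay resolvable on the small grid — a
desk grid cannot Nyquist-sample the deeply holographic fringes the real
2048² detector records, so the demos operate at feature-scale Fresnel
numbers of ~1.3–2 rather than ~0.08.  The deeply holographic regime is still
exercised (retrieval tests at F = 0.01) on single grids where forward model
and inversion share the discrete kernel.  A `constant_magnification` variant
of the zoom scan moves the detector with the sample so all distances share
one effective pixel; the drift-free version of that series is the cleanest
end-to-end benchmark (voxel correlation ≈ 0.96 with ground truth, all 25
clusters with the exact 20/5 compartment split).

## Known limitations

- Quantitative δ values at low spatial frequency carry a few-percent bias
  from the weak-object linearization; recovering quantitative electron
  density would require iterative refinement, deliberately out of scope.
- The simulator is monochromatic, point-source, noise-limited by photon
  statistics only: no partial coherence, detector PSF, or scintillator
  physics.
- ROI (interior) tomography truncation is not corrected; zoom scans are
  reconstructed as-is.
- Passing tests on the miniature phantom demonstrate the correctness of the
  chain under its stated models, not performance on real beamline data with
  drifts, ring artifacts and anatomically scaled structures.
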