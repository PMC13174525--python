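# Methods

This note documents the models, parameter choices and numerical conventions
behind `rifiber`, and states what the synthetic validation does and does not
demonstrate about real data.

## Coordinate and unit conventions

Volumes are indexed `(z, y, x)`, 0-based, with physical voxel size
`(dz, dy, dx)` in micrometres. Voxel `k` sits at physical coordinate
`k · d` along each axis. In-plane angles are measured from the +x image
axis, counterclockwise in image coordinates (y pointing down), and folded
into [0°, 180°). All refractive indices are dimensionless; a plausibility
gate of [1.0, 1.7] is enforced at container boundaries (hydrated biological
specimens cannot leave this range; values outside it indicate corrupt data
or metadata).

## Dry-mass calibration

The Barer relation `n = n_m + αC` links local refractive index to the
concentration `C` of non-aqueous material. Defaults are `n_m = 1.3370`
(PBS / culture medium) and `α = 0.18 mL/g`, the standard value for
protein-dominated material; both are parameters of `DryMassParams`. One
global `α` is used — no per-collagen-type increment is available, and the
measurement is not collagen-specific: it reports total dry mass inside
fiber masks.

**Clipping convention.** Negative contrast produced by reconstruction noise
is suppressed by zeroing the *contrast*, pixelwise, before any averaging:
`Δn := max(n − n_m, 0)`. The alternative reading — setting the RI value
itself to zero — would produce contrasts of `−n_m`, amplifying exactly the
non-physical contribution the rule exists to suppress, and is rejected. A
dedicated test pins the order of operations (clip, then mean), which is
observable whenever a fragment contains sub-`n_m` pixels.

**Voxel-equivalent volume.** For 2D-section analysis the default
`V_vox = dy·dx·dz` uses the parent tomogram's slice thickness — the most
literal reading of a "voxel-equivalent volume", and the right one when the
quantity of interest is mass *within the imaged slab*. `analyze_fragments`
additionally offers `thickness_mode="cylinder"`, which replaces the slab
depth `dz` by the mean chord depth of a circular fiber cross-section of
the traced effective width `w`, namely `πw/4` (area `π(w/2)²` divided by
diameter `w`). This converts a mid-fiber section measurement into an
estimate of the *full tube* mass and is what the ground-truth validation
uses, since the phantom oracle is the analytic tube mass `C·πr²L`. The
choice is recorded in the pipeline's config echo.

## Synthetic phantoms

The generator emulates holotomographic acquisitions of reconstituted
collagen gels; it is the package's ground-truth instrument, not a physics
simulation. Its model, in generation order:

1. **Centerlines** are persistent random walks with a fixed step of one
   voxel; the in-plane heading diffuses with variance `step/ℓ_p` per step
   (persistence length `ℓ_p`, default 200 µm — nearly straight fibrils at
   the tens-of-µm scale of a field of view), the axial heading at half that
   rate. Walks are clipped at the volume bounds. Starting points are
   uniform, headings von Mises (concentration 0 = isotropic by default).
2. **Tubes** of radius `r` (diameter lognormal, default median 0.8 µm,
   σ_log 0.3) are rasterised as open cylinders: a voxel belongs to a fiber
   when its center lies within `r` of a centerline segment with the
   projection inside the segment — no end caps, so the discretised volume
   matches the analytic `πr²L` that the mass oracle uses. Interiors take
   `n_m + Δn` with `Δn` uniform in [0.01, 0.03] by default; the range is
   user-adjustable since no canonical fibril contrast value exists, and
   the plausibility gate bounds what is reasonable (≈0.005–0.05).
   Overlapping tubes take the **maximum** contrast, not the sum — the RI of
   fused fibrils is not additive. Mass-conservation tests therefore use
   non-overlapping configurations (`min_separation_um`, enforced by
   rejection sampling; an infeasibly crowded request raises rather than
   silently under-filling).
3. **Optics**: a separable anisotropic Gaussian PSF, default
   σ = (0.5, 0.25, 0.25) µm — the 2:1 axial elongation characteristic of
   optical tomography — followed by additive Gaussian RI noise (default
   sd 0.002).

The default volume is 64×256×256 voxels at (0.5, 0.2, 0.2) µm: a 32 µm
axial extent, matching the ~30 µm fields typical of collagen-gel
holotomography, at desk-scale cost. Validation suites use smaller, flatter
volumes (9–13 slices, `planar=True`, which confines centerlines to the
mid-z plane) so that a single axial section sees every fiber at full
diameter; the problem sizes quoted in the test docstrings (20 seeds ×
5 fibers, 256² sections) were chosen as the smallest configurations at
which the estimators' statistics are stable.

**Subtype presets** encode the organisational contrast between collagen
types — type I thicker and more bundled (diameter median 0.9 µm at
0.8 mg/mL, σ_log 0.35, brighter), type III finer (0.55 µm, σ_log 0.25) —
with fiber count scaling linearly in concentration and width median
sub-linearly (`∝ c^0.25` and `c^0.15`). These exponents are a modelling
choice that reproduces the *direction* of concentration-dependent shifts
(widths and masses rising, more strongly in type I); no quantitative
claim about real gels attaches to them.

**Polymerization series** realise a saturating mean-contrast target
`Δn(t) = Δn_max(1 − e^{−t/τ})` over a fixed fiber geometry, either by
scaling all contrasts (`growth_mode="contrast"`, fibrils densify in place)
or by revealing fibers progressively with a final exact rescale
(`"fibers"`, nucleation over time). Noiseless frames hit the target to
machine precision; with noise the clipped mean acquires an upward bias of
about `noise_sd/√(2π)` from background voxels, which is documented rather
than corrected.

**What passing on phantoms does not show.** The phantoms have piecewise
constant interiors, Gaussian blur and i.i.d. Gaussian noise. Real
tomograms add reconstruction artifacts (missing-cone elongation beyond a
Gaussian, multiple scattering in dense samples), non-fibrillar high-RI
material, and fiber bundles that a 2D tracer splits or merges. Recovery
numbers quoted by the validation are upper bounds on what to expect from
real acquisitions.

## Fiber extraction

The tracer is functionally equivalent to curvelet-plus-FIRE tools:
it produces per-fiber centerlines, widths and fragment masks with testable
recovery guarantees, without reproducing any particular implementation's
internals.

- **Enhancement**: the slowly varying background is estimated by greyscale
  opening with a disk (default radius 20 px, larger than any fiber width)
  and subtracted; because opening sits below a noisy signal everywhere, the
  residual's median is re-zeroed so the background lands at `n_m`. Gaussian
  denoising (σ = 1.5 px) follows; σ = 0 gives the flattening-only path.
  A curvelet front end was considered and rejected: the pipeline's
  contracts are recovery guarantees on the tracer output, which the
  flattening + Gaussian stage meets at a fraction of the complexity, and
  the stage is pluggable behind `enhance_section`.
- **Binarisation**: the default automatic threshold is a robust noise
  floor — 4 × (1.4826 · MAD of the section about its median; fibers are
  sparse so the median estimates the background) with a floor of 1e-4 RI
  units. Otsu's method is available (`threshold_mode="otsu"`) but is not
  the default: with fibers of heterogeneous brightness in one field, Otsu
  places its threshold *between* faint and bright fibers and deletes the
  faint ones entirely — observed on phantoms with contrast ranges as
  modest as 2×. Fixed contrast thresholds are also accepted. Components
  smaller than `min_width_px²` are removed.
- **Tracing** follows the FIRE recipe on the Euclidean distance transform
  (EDT) of the mask: nucleation at EDT ridge maxima (minimum separation
  5 px), bidirectional extension in 2 px steps along the ridge tangent
  (the Hessian eigenvector of the smoothed EDT with eigenvalue closest to
  zero), sub-pixel recentering by a parabolic fit across the ridge, turn
  rejection above 40°, and a claimed-corridor rule so secondary maxima
  along an already-traced fiber do not nucleate duplicates. At junctions
  extension continues along the direction minimising the turn; loops are
  cut at the nucleation point. Co-linear fragments with facing endpoints
  within 4 px are linked; traces shorter than 15 px are pruned. Fiber ids
  are assigned by decreasing length, ties by starting position, making
  outputs deterministic.
- **Width**: the local width is the chord length of the bilinearly
  interpolated mask along the ridge normal (0.5-crossing, sub-sample
  interpolated), capped at `2·EDT + 3` px so a normal running along a
  crossing fiber cannot inflate it. The doubled EDT value itself is
  pixel-quantised and biased by the half-pixel offset of background pixel
  centers (±0.5–1 px depending on parity and orientation); the chord
  estimator is unbiased on binarised tubes, which is what the 1 px width
  recovery guarantee rests on.
- **Fragment masks** dilate each centerline by a disk of the local
  half-width; contested pixels go to the nearest centerline, exact ties to
  the smaller fiber id, so crossing fibers partition their union without
  double counting.

Effective width aggregates per-point widths by the arithmetic mean
(median selectable) — the fragment-level statistic CT-FIRE-style tools
report. No deconvolution correction for the enhancement blur is applied;
on PSF-blurred data traced widths include the optical blur.

## Kinetics

`mean_delta_n` is a pure voxel statistic (clipped mean over an optional
ROI; the ROI used is recorded in outputs since mean contrast over a full
volume and over a sub-volume differ). Monotonicity of a trajectory is
*reported* as the fraction of non-decreasing steps, never asserted: on
ideal noiseless series it equals 1.0 by construction, while real data may
dip. The saturating fit uses bounded Levenberg-Marquardt
(`scipy.optimize.curve_fit`) with documented initialisation: amplitude
from the last trajectory value, τ from the interpolated time-to-half-
amplitude. An all-zero trajectory returns amplitude 0 with τ flagged
unidentifiable rather than an arbitrary number. Temporal composites tint
each frame's projection with a perceptually ordered colormap (`turbo`)
mapped linearly over the series time span and keep, per pixel, the tint of
the brightest frame — so a structure appearing only at the end carries the
end-of-scale hue exactly.

## Registration

Raw RI and second-modality intensities (e.g. SHG) are not comparable, so
the similarity objective is mutual information between gradient-magnitude
images (Gaussian-derivative magnitude, σ = 1.5 px by default);
raw-intensity MI is available behind a flag for ablation. MI is computed
from a joint histogram over each image's observed range, on the overlap
region only (out-of-field pixels after warping are excluded). Binning is
plain (no partial-volume interpolation): the bilinear interpolation of
the warped image already smooths the objective enough for sub-pixel
optimisation, and plain binning preserves the exact identity
MI(a, a) = H(a), which the suite pins with the standalone
`mutual_information` default of 64 bins. The registration *objective*
defaults to 32 bins: on small noisy fields, 64 bins leave only a handful
of pixels per joint-histogram cell and the MI surface becomes rough
enough for local refinement to stall on ridges 1–2 px from the optimum.
The rigid stage is a deterministic coarse grid (rotation ±15° step 1°,
translation ±20 px step 4 px, on 4× downsampled images) followed by
Powell refinement at full resolution with one restart (Powell's
direction set degrades on correlated rotation/translation errors; a
restart from the first solution recovers it), optionally multi-started
from the top-k grid candidates; no stochastic search, so results
reproduce without seeds. The reported MI is never below the MI at
identity, and an optimum with under 25% field overlap is flagged
non-converged. Affine refinement perturbs the six parameters about the
rigid solution (decoupled about the image center) and falls back to the
rigid transform, flagged, if it cannot improve MI.

## Axial section choice

How a "representative" section is chosen is not canonical; both a fixed
index and an automatic rule are provided. The automatic rule picks the
slice maximising the summed clipped contrast, ties toward smaller z, and
the pipeline records which rule produced each report.

## Degenerate inputs and tie-breaks

Empty masks are legal everywhere downstream of binarisation (empty trace
lists, empty tables); an empty *fiber region* is an error only where the
computation is undefined (RI densities). Depth-colored projections break
argmax ties toward smaller z. Histogram binning for RI densities is
Freedman-Diaconis on the pooled fiber + background sample, shared between
the two densities so they are directly comparable; near-constant samples
fall back to 10 uniform bins.

## Known limitations

- Tracing is 2D on axial sections; fibers crossing the section plane
  obliquely are foreshortened and their chord widths overestimate the
  perpendicular diameter. Full 3D tracing is out of scope.
- Dry mass in fiber masks is total dry mass, not collagen-specific.
- The `cylinder` thickness mode assumes circular cross-sections and
  mid-fiber sectioning; for the slab reading use the default `voxel` mode.
- The polymerization generator varies contrast/fiber count over a static
  geometry; it does not model cell-driven remodeling.
- Registration assumes a dominant rigid + mild affine relation within the
  coarse-search range; it is not a deformable method.
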