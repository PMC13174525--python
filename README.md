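# rifiber

Label-free quantification of collagen fiber architecture and dry mass from
3D refractive-index (RI) tomograms.

Holotomography reconstructs the volumetric refractive index *n* of a
specimen. Because RI rises linearly with the concentration of non-aqueous
material (the Barer relation), an RI tomogram of a collagen gel is a
physically calibrated map: every fiber's morphology *and* dry mass can be
read from a single label-free acquisition. `rifiber` implements the full
analysis chain for such data, aimed at matrix-biology and biophotonics labs
working with reconstituted collagen networks:

- **I/O** — RI tomogram stacks (TIFF + JSON sidecar metadata), time-lapse
  series, maximum-intensity and depth-colored projections, axial section
  selection (`rifiber.tomo`);
- **fiber extraction** — a FIRE-style tracer (distance-transform nucleation,
  ridge following, gap linking) producing sub-pixel centerlines, local
  widths, and effective-width-weighted fragment masks (`rifiber.extraction`);
- **morphometry** — per-fiber length, orientation angle, straightness and
  effective width with pooled summaries (`rifiber.metrics`);
- **dry mass** — RI contrast to mass density `C = Δn/α` with
  `α = 0.18 mL/g` and `n_m = 1.3370`, per-fragment mass `m = C·V_vox·N`,
  and fiber/background RI probability densities (`rifiber.drymass`);
- **kinetics** — mean-Δn trajectories during polymerization, saturating
  fits `Δn(t) = Δn_max(1 − e^{−t/τ})`, temporally encoded RGB composites
  (`rifiber.kinetics`);
- **registration** — mutual-information rigid + affine alignment on
  gradient-magnitude images for HT↔SHG-style multimodal overlays and line
  profiles (`rifiber.registration`);
- **phantoms** — a synthetic generator producing RI tomograms of simulated
  collagen networks with exact per-fiber ground truth (geometry and
  analytic mass), used throughout the test suite (`rifiber.phantom`).

## The physics in one paragraph

A fiber's voxels carry contrast `Δn = max(n − n_m, 0)` above the medium
index `n_m` (1.3370 for PBS/culture medium; negative contrast from
reconstruction noise is clipped per pixel before any averaging). The
specific refractive increment `α` links contrast to dry mass density,
`C = Δn/α` in g/mL. For each traced fiber fragment the mask pixel count
`N` and voxel-equivalent volume `V_vox` give the fragment dry mass
`m = C · V_vox · N`, reported in picograms (1 µm³ = 10⁻¹² mL and
1 pg = 10⁻¹² g cancel, so `m[pg] = C · volume[µm³]` numerically).

## Worked example

```python
import numpy as np
from rifiber import (
    PhantomConfig, generate_phantom, extract_axial_section,
    ExtractionParams, binarize_foreground, trace_fibers,
    build_width_weighted_mask, analyze_fragments, describe_fiber,
    true_fiber_mass,
)

cfg = PhantomConfig(
    shape_vox=(13, 256, 256), voxel_size=(0.4, 0.2, 0.2),
    n_fibers=5, planar=True, min_separation_um=1.5,
    psf_sigma_um=(0, 0, 0), noise_sd=0.0,
    persistence_length_um=1e6, seed=9,
)
tomo, truth = generate_phantom(cfg)
section = extract_axial_section(tomo, "max_contrast")
mask = binarize_foreground(section)
traces = trace_fibers(section, mask)
fmask = build_width_weighted_mask(traces, section.shape)
fragments = analyze_fragments(section, fmask, traces=traces,
                              thickness_mode="cylinder")

for frag, trace in zip(fragments, traces):
    d = describe_fiber(trace, section.pixel_size)
    print(f"fiber {frag.fiber_id}: width {d.effective_width_um:.2f} um, "
          f"length {d.length_um:.1f} um, mass {frag.mass_pg:.3f} pg")
print("true masses:", np.round([true_fiber_mass(f) for f in truth.fibers], 3))
```

Output:

```
fiber 1: width 0.81 um, length 18.4 um, mass 0.671 pg
fiber 2: width 0.63 um, length 18.3 um, mass 0.511 pg
fiber 3: width 0.86 um, length 12.4 um, mass 0.428 pg
fiber 4: width 0.63 um, length 12.0 um, mass 0.511 pg
fiber 5: width 0.81 um, length 10.7 um, mass 0.634 pg
true masses: [0.516 0.43  0.672 0.65  0.525]
```

Each traced fiber's effective width is the mean of its local widths along
the centerline; its mass comes from the measured contrast over its
width-weighted mask. The recovered masses match the generator's analytic
tube masses (`C · πr²L`) fiber for fiber to within a few percent —
the ids differ because traces are numbered by decreasing length.

The same stages run from the command line via a single YAML config:

```bash
rifiber run --config pipeline.yaml --seed 9 --out results/
```

which writes `descriptors.csv`, `fragment_mass.csv`, `ri_density.csv`,
`trajectory.csv` (for time-lapse inputs) and a `run_report.json` manifest
echoing every defaulted parameter.

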