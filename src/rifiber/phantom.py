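"""Synthetic RI phantoms of collagen fiber networks with exact ground truth.

The generator emulates holotomographic acquisitions of reconstituted
collagen gels: curvilinear tubes of elevated refractive index embedded in
a medium of ``n_m = 1.3370``, blurred by an anisotropic point-spread
function (elongated along z, as in optical tomography) and corrupted by
additive Gaussian noise.  Centerlines follow a persistent random walk
with a fixed step of one voxel; tube interiors take
``medium_ri + ri_contrast`` and overlapping tubes take the maximum
contrast (RI of fused fibrils is not additive).  Ground truth — true
centerline, diameter, length, in-plane orientation and analytic dry
mass — is recorded before blur and noise and serves as the oracle for
the downstream extraction and mass pipeline.

Subtype presets reflect the organisational contrast between collagen
types: type I networks are thicker and more bundled, type III finer.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .errors import RifiberError, ValidationError
from .tomo import RITomogram, TimeLapseSeries

#: Specific refractive increment for protein-dominated material (mL/g).
ALPHA_ML_PER_G = 0.18
#: Medium refractive index of PBS / culture medium.
MEDIUM_RI = 1.3370


class GenerationError(RifiberError):
    """Requested phantom is infeasible (e.g. fiber count cannot be placed)."""


@dataclass
class FiberSpec:
    """Analytic description of one simulated fiber.

    ``control_points`` is the ordered centerline in micrometres, indexed
    ``(z, y, x)``; ``radius_um`` the tube radius; ``ri_contrast`` the RI
    elevation of the tube interior above the medium.
    """

    control_points: np.ndarray
    radius_um: float
    ri_contrast: float

    def __post_init__(self) -> None:
        self.control_points = np.asarray(self.control_points, dtype=float)
        if self.control_points.ndim != 2 or self.control_points.shape[1] != 3:
            raise ValidationError("control_points must be (M, 3) in (z, y, x) um")
        if len(self.control_points) < 2:
            raise ValidationError("a fiber needs at least 2 control points")
        if self.radius_um <= 0:
            raise ValidationError("radius_um must be positive")
        if self.ri_contrast < 0:
            raise ValidationError("ri_contrast must be non-negative")

    @property
    def length_um(self) -> float:
        """Arc length of the centerline polyline."""
        seg = np.diff(self.control_points, axis=0)
        return float(np.sqrt((seg**2).sum(axis=1)).sum())

    @property
    def diameter_um(self) -> float:
        return 2.0 * self.radius_um

    @property
    def orientation_deg(self) -> float:
        """In-plane (x-y) end-to-end orientation vs +x, folded into [0, 180)."""
        d = self.control_points[-1] - self.control_points[0]
        ang = math.degrees(math.atan2(d[1], d[2]))  # (dy, dx)
        return ang % 180.0


def true_fiber_mass(fiber: FiberSpec, alpha: float = ALPHA_ML_PER_G) -> float:
    """Analytic dry mass of a fiber in picograms.

    Mass density ``C = ri_contrast / alpha`` (g/mL) times the tube volume
    ``pi r^2 L`` (um^3), converted at 1 um^3 = 1e-12 mL and reported in pg
    (1e-12 g); the two factors of 1e12 cancel, so numerically
    ``mass_pg = C * V_um3``.
    """
    if alpha <= 0:
        raise ValidationError("alpha must be positive")
    volume_um3 = math.pi * fiber.radius_um**2 * fiber.length_um
    concentration = fiber.ri_contrast / alpha  # g/mL
    return concentration * volume_um3  # pg (unit factors cancel)


@dataclass
class PhantomGroundTruth:
    """Per-fiber truth emitted alongside a phantom volume."""

    fibers: list[FiberSpec]
    alpha: float = ALPHA_ML_PER_G

    def table(self) -> pd.DataFrame:
        rows = []
        for k, f in enumerate(self.fibers, start=1):
            rows.append(
                {
                    "fiber_id": k,
                    "diameter_um": f.diameter_um,
                    "length_um": f.length_um,
                    "orientation_deg": f.orientation_deg,
                    "ri_contrast": f.ri_contrast,
                    "mass_pg": true_fiber_mass(f, self.alpha),
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "fiber_id",
                "diameter_um",
                "length_um",
                "orientation_deg",
                "ri_contrast",
                "mass_pg",
            ],
        )

    def total_mass_pg(self) -> float:
        return float(sum(true_fiber_mass(f, self.alpha) for f in self.fibers))


@dataclass
class PhantomConfig:
    """Parameters of one simulated acquisition.

    Defaults give a 64 x 256 x 256 voxel volume at (0.5, 0.2, 0.2) um —
    a 32 um axial extent, matching the ~30 um fields typical of
    holotomography of collagen gels.  ``width_lognormal`` is
    ``(median_diameter_um, sigma_of_log)``; ``ri_contrast_range`` a
    uniform range of tube contrasts; ``orientation_kappa`` the von Mises
    concentration of in-plane fiber angles (0 = isotropic);
    ``persistence_length_um`` controls centerline curvature (larger =
    straighter).  ``planar=True`` confines centerlines to the mid-z
    slice plane, which makes a single axial section see every fiber at
    full diameter.  ``min_separation_um`` enforces non-overlapping
    fibers by rejection sampling.
    """

    shape_vox: tuple[int, int, int] = (64, 256, 256)
    voxel_size: tuple[float, float, float] = (0.5, 0.2, 0.2)
    medium_ri: float = MEDIUM_RI
    n_fibers: int = 24
    width_lognormal: tuple[float, float] = (0.8, 0.3)
    ri_contrast_range: tuple[float, float] = (0.01, 0.03)
    orientation_kappa: float = 0.0
    persistence_length_um: float = 200.0
    fiber_length_um: tuple[float, float] = (10.0, 25.0)
    psf_sigma_um: tuple[float, float, float] = (0.5, 0.25, 0.25)
    noise_sd: float = 0.002
    seed: int = 0
    planar: bool = False
    min_separation_um: Optional[float] = None
    margin_um: float = 1.5
    label: str = "phantom"

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.shape_vox) or any(v <= 0 for v in self.voxel_size):
            raise ValidationError("shape_vox and voxel_size must be positive")
        if self.n_fibers < 0:
            raise ValidationError("n_fibers must be >= 0")
        if self.width_lognormal[0] <= 0 or self.width_lognormal[1] < 0:
            raise ValidationError("width_lognormal needs positive median and sigma >= 0")
        if self.ri_contrast_range[0] <= 0 or self.ri_contrast_range[1] < self.ri_contrast_range[0]:
            raise ValidationError("ri_contrast_range must be positive and ordered")
        if self.persistence_length_um <= 0:
            raise ValidationError("persistence_length_um must be positive")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


# ---------------------------------------------------------------------------
# centerline sampling

def _sample_direction(rng: np.random.Generator, kappa: float, planar: bool) -> np.ndarray:
    if kappa > 0:
        theta = rng.vonmises(0.0, kappa)
    else:
        theta = rng.uniform(0.0, 2.0 * math.pi)
    d = np.array([0.0, math.sin(theta), math.cos(theta)])
    if not planar:
        tilt = rng.uniform(-0.15, 0.15)  # modest axial tilt keeps fibers near-planar
        d[0] = tilt
        d /= np.linalg.norm(d)
    return d


def _walk_centerline(
    rng: np.random.Generator,
    start: np.ndarray,
    direction: np.ndarray,
    length_um: float,
    step_um: float,
    persistence_um: float,
    bounds_lo: np.ndarray,
    bounds_hi: np.ndarray,
    planar: bool,
) -> np.ndarray:
    """Persistent random walk with fixed step, clipped at the volume bounds."""
    n_steps = max(int(round(length_um / step_um)), 1)
    sigma = math.sqrt(step_um / persistence_um)
    pts = [start.copy()]
    p, d = start.copy(), direction.copy()
    for _ in range(n_steps):
        # in-plane angular diffusion; axial component diffuses at half rate
        dtheta = rng.normal(0.0, sigma)
        cy, cx = d[1], d[2]
        c, s = math.cos(dtheta), math.sin(dtheta)
        d[1], d[2] = cy * c + cx * s, -cy * s + cx * c
        if not planar:
            d[0] += rng.normal(0.0, sigma / 2)
        d /= np.linalg.norm(d)
        nxt = p + step_um * d
        if np.any(nxt < bounds_lo) or np.any(nxt > bounds_hi):
            break
        p = nxt
        pts.append(p.copy())
    return np.asarray(pts)


def _min_clearance(points_a: np.ndarray, points_b: np.ndarray) -> float:
    from scipy.spatial import cKDTree

    return float(cKDTree(points_b).query(points_a)[0].min())


# ---------------------------------------------------------------------------
# rasterisation

def rasterize_fiber(
    canvas: np.ndarray, fiber: FiberSpec, voxel_size: tuple[float, float, float]
) -> None:
    """Mark tube-interior voxels on ``canvas`` with ``max(existing, contrast)``.

    A voxel belongs to the tube when its center lies within ``radius_um``
    of some centerline segment, with the projection falling inside the
    segment (open cylinder without end caps, matching the analytic
    ``pi r^2 L`` volume).
    """
    vox = np.asarray(voxel_size)
    shape = np.asarray(canvas.shape)
    r = fiber.radius_um
    pts = fiber.control_points
    for p0, p1 in zip(pts[:-1], pts[1:]):
        seg = p1 - p0
        seg_len2 = float((seg**2).sum())
        if seg_len2 == 0:
            continue
        lo_um = np.minimum(p0, p1) - r
        hi_um = np.maximum(p0, p1) + r
        lo = np.maximum(np.floor(lo_um / vox).astype(int), 0)
        hi = np.minimum(np.ceil(hi_um / vox).astype(int) + 1, shape)
        if np.any(lo >= hi):
            continue
        zz, yy, xx = np.meshgrid(
            np.arange(lo[0], hi[0]) * vox[0],
            np.arange(lo[1], hi[1]) * vox[1],
            np.arange(lo[2], hi[2]) * vox[2],
            indexing="ij",
        )
        rel = np.stack([zz - p0[0], yy - p0[1], xx - p0[2]], axis=-1)
        t = rel @ seg / seg_len2
        perp = rel - t[..., None] * seg
        inside = (t >= 0.0) & (t <= 1.0) & ((perp**2).sum(axis=-1) <= r**2)
        view = canvas[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
        np.maximum(view, np.where(inside, fiber.ri_contrast, 0.0), out=view)


# ---------------------------------------------------------------------------
# generation

def generate_phantom(config: PhantomConfig) -> tuple[RITomogram, PhantomGroundTruth]:
    """Generate one phantom tomogram plus its per-fiber ground truth.

    The full generation stream is a pure function of ``config`` (including
    ``config.seed``): identical configs give bit-identical volumes.
    """
    rng = np.random.default_rng(config.seed)
    nz, ny, nx = config.shape_vox
    dz, dy, dx = config.voxel_size
    step_um = min(config.voxel_size)
    margin = config.margin_um
    bounds_lo = np.array([margin if not config.planar else 0.0, margin, margin])
    bounds_hi = np.array([(nz - 1) * dz, (ny - 1) * dy, (nx - 1) * dx]) - np.array(
        [margin if not config.planar else 0.0, margin, margin]
    )
    if config.n_fibers > 0 and np.any(bounds_hi <= bounds_lo):
        raise GenerationError("volume too small for the requested margin")
    mid_z = (nz // 2) * dz

    fibers: list[FiberSpec] = []
    placed_points: list[tuple[np.ndarray, float]] = []
    max_tries = 200
    for _ in range(config.n_fibers):
        for attempt in range(max_tries):
            median, sigma = config.width_lognormal
            diameter = median * math.exp(rng.normal(0.0, sigma))
            radius = diameter / 2.0
            contrast = rng.uniform(*config.ri_contrast_range)
            length = rng.uniform(*config.fiber_length_um)
            direction = _sample_direction(rng, config.orientation_kappa, config.planar)
            start = np.array(
                [
                    mid_z if config.planar else rng.uniform(bounds_lo[0], bounds_hi[0]),
                    rng.uniform(bounds_lo[1], bounds_hi[1]),
                    rng.uniform(bounds_lo[2], bounds_hi[2]),
                ]
            )
            pts = _walk_centerline(
                rng,
                start,
                direction,
                length,
                step_um,
                config.persistence_length_um,
                np.array([mid_z, bounds_lo[1], bounds_lo[2]]) if config.planar else bounds_lo,
                np.array([mid_z, bounds_hi[1], bounds_hi[2]]) if config.planar else bounds_hi,
                config.planar,
            )
            if len(pts) < 2 or _polyline_length(pts) < 0.5 * length:
                continue
            if config.min_separation_um is not None and placed_points:
                ok = all(
                    _min_clearance(pts, other_pts)
                    >= radius + other_r + config.min_separation_um
                    for other_pts, other_r in placed_points
                )
                if not ok:
                    continue
            fiber = FiberSpec(control_points=pts, radius_um=radius, ri_contrast=contrast)
            if fiber.radius_um < max(config.voxel_size) / 2:
                warnings.warn(
                    f"fiber radius {fiber.radius_um:.3f} um is sub-voxel "
                    f"(max voxel dim {max(config.voxel_size)} um)",
                    stacklevel=2,
                )
            fibers.append(fiber)
            placed_points.append((pts, radius))
            break
        else:
            raise GenerationError(
                f"could not place fiber {len(fibers) + 1}/{config.n_fibers} "
                f"after {max_tries} attempts; volume too crowded"
            )

    contrast_field = np.zeros(config.shape_vox, dtype=np.float64)
    for fiber in fibers:
        rasterize_fiber(contrast_field, fiber, config.voxel_size)

    psf_vox = [s / v for s, v in zip(config.psf_sigma_um, config.voxel_size)]
    if any(s > 0 for s in psf_vox):
        contrast_field = gaussian_filter(contrast_field, sigma=psf_vox)
    values = config.medium_ri + contrast_field
    if config.noise_sd > 0:
        values = values + rng.normal(0.0, config.noise_sd, size=values.shape)
    values = np.clip(values, 1.0, 1.7)  # plausibility gate

    tomo = RITomogram(
        values=values,
        voxel_size=config.voxel_size,
        medium_ri=config.medium_ri,
        label=config.label,
    )
    return tomo, PhantomGroundTruth(fibers=fibers)


def _polyline_length(pts: np.ndarray) -> float:
    seg = np.diff(pts, axis=0)
    return float(np.sqrt((seg**2).sum(axis=1)).sum())


# ---------------------------------------------------------------------------
# subtype / concentration presets

def phantom_preset(
    subtype: str,
    concentration_mg_ml: float = 0.8,
    seed: int = 0,
    **overrides,
) -> PhantomConfig:
    """Preset configs for the two collagen subtypes.

    Type I gels form thicker, more bundled fibrils; type III forms a
    finer network of thinner fibrils.  Fiber number density scales
    linearly with concentration and the width-distribution median rises
    sub-linearly with it, reproducing the direction of the
    concentration-dependent width and mass shifts seen in reconstituted
    gels.
    """
    if concentration_mg_ml <= 0:
        raise ValidationError("concentration_mg_ml must be positive")
    rel = concentration_mg_ml / 0.8
    if subtype in ("type_I", "I"):
        base = dict(
            n_fibers=max(int(round(20 * rel)), 1),
            width_lognormal=(0.9 * rel**0.25, 0.35),
            ri_contrast_range=(0.012, 0.035),
        )
    elif subtype in ("type_III", "III"):
        base = dict(
            n_fibers=max(int(round(26 * rel)), 1),
            width_lognormal=(0.55 * rel**0.15, 0.25),
            ri_contrast_range=(0.008, 0.022),
        )
    else:
        raise ValidationError(f"unknown subtype {subtype!r}; use 'type_I' or 'type_III'")
    base.update(overrides)
    return PhantomConfig(seed=seed, label=f"{subtype}_{concentration_mg_ml:g}mgml", **base)


# ---------------------------------------------------------------------------
# polymerization time series

@dataclass
class PolymerizationConfig:
    """Saturating-growth time series: ``dn(t) = dn_max (1 - exp(-t/tau))``.

    ``growth_mode`` selects how the target mean contrast is realised:
    ``"contrast"`` scales all tube contrasts uniformly (fibrils densify in
    place), ``"fibers"`` reveals fibers progressively then rescales to hit
    the target exactly (new fibrils nucleate over time).
    """

    time_points_min: tuple[float, ...]
    dn_max: float = 0.01
    tau_min: float = 30.0
    base: PhantomConfig = field(default_factory=PhantomConfig)
    growth_mode: str = "contrast"
    seed: int = 0

    def __post_init__(self) -> None:
        t = list(self.time_points_min)
        if not t:
            raise ValidationError("need at least one time point")
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValidationError(f"time points must be strictly increasing; got {t}")
        if any(tp < 0 for tp in t):
            raise ValidationError("time points must be >= 0")
        if self.dn_max < 0 or self.tau_min <= 0:
            raise ValidationError("dn_max must be >= 0 and tau_min > 0")
        if self.growth_mode not in ("contrast", "fibers"):
            raise ValidationError("growth_mode must be 'contrast' or 'fibers'")


def target_delta_n(t_min: np.ndarray, dn_max: float, tau_min: float) -> np.ndarray:
    """The saturating mean-contrast curve ``dn_max (1 - exp(-t/tau))``."""
    return dn_max * (1.0 - np.exp(-np.asarray(t_min, dtype=float) / tau_min))


def generate_polymerization_series(
    config: PolymerizationConfig,
) -> tuple[TimeLapseSeries, np.ndarray]:
    """Generate a time-lapse series whose clipped-mean contrast follows the target curve.

    Noiseless frames hit the target exactly (machine precision); with
    noise the clipped mean is biased upward by roughly
    ``noise_sd / sqrt(2 pi)`` per background voxel, which is documented
    rather than corrected.  All frames share the fiber geometry of the
    base phantom.  Returns the series and the true target trajectory.
    """
    base_cfg = replace(config.base, seed=config.seed, noise_sd=0.0)
    tomo, truth = generate_phantom(base_cfg)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    times = np.asarray(config.time_points_min, dtype=float)
    targets = target_delta_n(times, config.dn_max, config.tau_min)

    dn_full = np.clip(tomo.values - base_cfg.medium_ri, 0.0, None).astype(np.float64)
    mean_full = float(dn_full.mean())
    if mean_full <= 0 and config.dn_max > 0:
        raise GenerationError("base phantom has no contrast; cannot reach a positive dn_max")

    per_fiber_fields: list[np.ndarray] = []
    order: list[int] = []
    if config.growth_mode == "fibers" and truth.fibers:
        order = list(rng.permutation(len(truth.fibers)))
        psf_vox = [s / v for s, v in zip(base_cfg.psf_sigma_um, base_cfg.voxel_size)]
        for k in order:
            canvas = np.zeros(base_cfg.shape_vox, dtype=np.float64)
            rasterize_fiber(canvas, truth.fibers[k], base_cfg.voxel_size)
            if any(s > 0 for s in psf_vox):
                canvas = gaussian_filter(canvas, sigma=psf_vox)
            per_fiber_fields.append(canvas)

    frames = []
    for t, tgt in zip(times, targets):
        if config.growth_mode == "fibers" and per_fiber_fields:
            frac = tgt / config.dn_max if config.dn_max > 0 else 0.0
            n_show = int(round(frac * len(per_fiber_fields)))
            fld = np.zeros(base_cfg.shape_vox, dtype=np.float64)
            for canvas in per_fiber_fields[:n_show]:
                np.maximum(fld, canvas, out=fld)
            m = float(fld.mean())
            fld = fld * (tgt / m) if m > 0 else dn_full * (tgt / mean_full)
        else:
            fld = dn_full * (tgt / mean_full) if mean_full > 0 else dn_full
        vals = base_cfg.medium_ri + fld
        if config.base.noise_sd > 0:
            vals = vals + rng.normal(0.0, config.base.noise_sd, size=vals.shape)
        vals = np.clip(vals, 1.0, 1.7)
        frames.append(
            RITomogram(
                values=vals,
                voxel_size=base_cfg.voxel_size,
                medium_ri=base_cfg.medium_ri,
                time_min=float(t),
                label=f"{base_cfg.label}_t{t:g}min",
            )
        )
    interval = float(times[1] - times[0]) if len(times) > 1 else None
    return TimeLapseSeries(frames=frames, interval_min=interval), targets


# ---------------------------------------------------------------------------
# bookkeeping helpers

def cell_density_from_seeding(
    cells: float, gel_volume_ul: float, sig_figs: Optional[int] = None
) -> float:
    """Cell seeding density in cells/mL from a count and gel volume in uL.

    With ``sig_figs`` set, the result is rounded to that many significant
    figures (e.g. 8000 cells in 60 uL -> 1.3e5 cells/mL at 2 s.f.).
    """
    if gel_volume_ul <= 0:
        raise ValidationError("gel_volume_ul must be positive")
    if cells < 0:
        raise ValidationError("cells must be >= 0")
    density = cells / (gel_volume_ul * 1e-3)
    if sig_figs is not None and density != 0:
        exponent = math.floor(math.log10(abs(density)))
        density = round(density, -exponent + sig_figs - 1)
    return density
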