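"""RI-calibrated dry mass of fiber fragments and fiber/background RI densities.

The Barer relation links refractive index to the concentration of
non-aqueous material: ``n = n_m + alpha * C`` with specific refractive
increment ``alpha`` (0.18 mL/g for protein-dominated material), so the
clipped contrast ``delta_n = max(n - n_m, 0)`` converts to a dry mass
density ``C = delta_n / alpha`` in g/mL.  Per-fragment dry mass is
``m = C * V_vox * N`` with ``N`` the pixel count of the
effective-width-weighted fragment mask and ``V_vox`` the
voxel-equivalent volume; unit bookkeeping (1 um^3 = 1e-12 mL, 1 pg =
1e-12 g) cancels, so masses in pg equal ``C * volume_um3`` numerically.

Clipping is applied pixelwise *before* averaging: negative contrast from
reconstruction noise is zeroed per pixel, not after the mean.  The
alternative reading — setting RI itself to zero — would produce a
contrast of ``-n_m`` and is rejected as non-physical.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from .errors import ValidationError
from .extraction import FiberMask, FiberTrace
from .tomo import RI_MAX_DEFAULT, RI_MIN_DEFAULT, Section2D

#: defaults matching PBS / culture medium and protein-dominated material
DEFAULT_MEDIUM_RI = 1.3370
DEFAULT_ALPHA_ML_PER_G = 0.18

UM3_PER_ML = 1e12  # 1 mL = 1e12 um^3
PG_PER_G = 1e12


@dataclass
class DryMassParams:
    """Calibration constants of the RI-to-mass conversion.

    ``voxel_equiv_volume_um3`` left as ``None`` derives ``V_vox`` from
    the analysed section (``dy * dx * dz`` of the parent tomogram); an
    explicit value overrides it.
    """

    medium_ri: float = DEFAULT_MEDIUM_RI
    alpha_ml_per_g: float = DEFAULT_ALPHA_ML_PER_G
    voxel_equiv_volume_um3: Optional[float] = None

    def __post_init__(self) -> None:
        if self.alpha_ml_per_g <= 0:
            raise ValidationError("alpha must be positive")
        if self.voxel_equiv_volume_um3 is not None and self.voxel_equiv_volume_um3 <= 0:
            raise ValidationError("voxel_equiv_volume_um3 must be positive")
        if not (RI_MIN_DEFAULT <= self.medium_ri <= RI_MAX_DEFAULT):
            raise ValidationError("medium_ri outside plausibility gate")

    def voxel_volume(self, section: Section2D) -> float:
        if self.voxel_equiv_volume_um3 is not None:
            return self.voxel_equiv_volume_um3
        dy, dx = section.pixel_size
        return dy * dx * section.slice_thickness


@dataclass
class FragmentMass:
    """Physical readout for one fiber fragment."""

    fiber_id: int
    mean_delta_n: float
    mass_density_g_per_ml: float
    pixel_count: int
    volume_um3: float
    mass_pg: float

    def __post_init__(self) -> None:
        if self.mean_delta_n < 0 or self.mass_pg < 0:
            raise ValidationError("mean_delta_n and mass_pg must be non-negative")
        expected = self.mass_density_g_per_ml * self.volume_um3 / UM3_PER_ML * PG_PER_G
        if abs(self.mass_pg - expected) > 1e-9 * max(abs(expected), 1e-30):
            raise ValidationError("mass_pg inconsistent with density * volume")


@dataclass
class RIDensity:
    """Normalised RI probability densities of fiber and background regions."""

    bin_edges: np.ndarray
    fiber_density: np.ndarray
    background_density: np.ndarray

    def __post_init__(self) -> None:
        widths = np.diff(self.bin_edges)
        for name, dens in (("fiber", self.fiber_density), ("background", self.background_density)):
            if np.any(dens < 0):
                raise ValidationError(f"{name} density has negative entries")
            total = float((dens * widths).sum())
            if abs(total - 1.0) > 1e-6:
                raise ValidationError(f"{name} density integrates to {total}, not 1")

    def fiber_mean_ri(self) -> float:
        centers = 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])
        w = np.diff(self.bin_edges)
        return float((centers * self.fiber_density * w).sum())

    def background_mean_ri(self) -> float:
        centers = 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])
        w = np.diff(self.bin_edges)
        return float((centers * self.background_density * w).sum())


# ---------------------------------------------------------------------------

def fragment_mean_delta_n(
    section: Section2D, mask: FiberMask, fiber_id: int, params: Optional[DryMassParams] = None
) -> float:
    """Mean clipped contrast over one fiber's labeled pixels.

    Per-pixel ``delta_n = max(n - n_m, 0)`` — clipping precedes the mean.
    """
    params = params or DryMassParams()
    sel = mask.label_image == fiber_id
    if not sel.any():
        raise ValidationError(f"fiber_id {fiber_id} absent from mask")
    dn = np.clip(section.values[sel] - params.medium_ri, 0.0, None)
    return float(dn.mean())


def dry_mass_density(mean_delta_n: float, params: Optional[DryMassParams] = None) -> float:
    """Dry mass density ``C = delta_n / alpha`` in g/mL."""
    params = params or DryMassParams()
    if mean_delta_n < 0:
        raise ValidationError("mean_delta_n must be >= 0")
    return mean_delta_n / params.alpha_ml_per_g


def fragment_dry_mass(
    mass_density_g_per_ml: float,
    pixel_count: int,
    params: Optional[DryMassParams] = None,
    voxel_volume_um3: Optional[float] = None,
) -> float:
    """Fragment dry mass ``m = C * V_vox * N`` in picograms."""
    params = params or DryMassParams()
    if pixel_count < 0:
        raise ValidationError("pixel_count must be >= 0")
    v_vox = voxel_volume_um3 if voxel_volume_um3 is not None else params.voxel_equiv_volume_um3
    if v_vox is None:
        raise ValidationError("voxel volume required (set params.voxel_equiv_volume_um3)")
    volume_ml = pixel_count * v_vox / UM3_PER_ML
    return mass_density_g_per_ml * volume_ml * PG_PER_G


def analyze_fragments(
    section: Section2D,
    mask: FiberMask,
    params: Optional[DryMassParams] = None,
    traces: Optional[list[FiberTrace]] = None,
    thickness_mode: str = "voxel",
) -> list[FragmentMass]:
    """Per-fragment dry mass for every fiber in a mask.

    ``thickness_mode`` picks the voxel-equivalent volume: ``"voxel"``
    uses the section's physical voxel (``dy*dx*dz``, the literal
    reading); ``"cylinder"`` replaces the slab depth ``dz`` by the mean
    chord depth of a circular cross-section of the fiber's effective
    width (``pi*w/4``), which turns a mid-fiber section measurement into
    an estimate of the full tube mass and requires ``traces``.
    """
    params = params or DryMassParams()
    if thickness_mode not in ("voxel", "cylinder"):
        raise ValidationError("thickness_mode must be 'voxel' or 'cylinder'")
    width_um: dict[int, float] = {}
    if thickness_mode == "cylinder":
        if traces is None:
            raise ValidationError("cylinder mode needs traces for per-fiber widths")
        dy, dx = section.pixel_size
        scale = float(np.sqrt(dy * dx))
        width_um = {t.fiber_id: float(np.mean(t.widths_px)) * scale for t in traces}

    out = []
    for fiber_id in mask.fiber_ids:
        n_px = mask.count(fiber_id)
        mean_dn = fragment_mean_delta_n(section, mask, fiber_id, params)
        c = dry_mass_density(mean_dn, params)
        if thickness_mode == "cylinder":
            dy, dx = section.pixel_size
            v_vox = dy * dx * (np.pi / 4.0) * width_um[fiber_id]
        else:
            v_vox = params.voxel_volume(section)
        mass = fragment_dry_mass(c, n_px, params, voxel_volume_um3=v_vox)
        out.append(
            FragmentMass(
                fiber_id=fiber_id,
                mean_delta_n=mean_dn,
                mass_density_g_per_ml=c,
                pixel_count=n_px,
                volume_um3=n_px * v_vox,
                mass_pg=mass,
            )
        )
    return out


def fragment_table(fragments: list[FragmentMass]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "fiber_id": f.fiber_id,
                "mean_delta_n": f.mean_delta_n,
                "mass_density_g_per_ml": f.mass_density_g_per_ml,
                "pixel_count": f.pixel_count,
                "volume_um3": f.volume_um3,
                "mass_pg": f.mass_pg,
            }
            for f in fragments
        ],
        columns=[
            "fiber_id",
            "mean_delta_n",
            "mass_density_g_per_ml",
            "pixel_count",
            "volume_um3",
            "mass_pg",
        ],
    )


# ---------------------------------------------------------------------------

def ri_probability_density(
    section: Section2D, mask: FiberMask, guard_px: int = 2
) -> RIDensity:
    """Fiber-associated vs background RI probability densities.

    Background pixels are those outside the fiber mask dilated by
    ``guard_px`` (a guard band excluding the partial-volume halo around
    fibers).  Both histograms share Freedman-Diaconis bins computed on
    the pooled sample so the densities are directly comparable.
    """
    fiber_sel = mask.label_image > 0
    if not fiber_sel.any():
        raise ValidationError("empty fiber region")
    if guard_px > 0:
        yy, xx = np.mgrid[-guard_px : guard_px + 1, -guard_px : guard_px + 1]
        disk = yy**2 + xx**2 <= guard_px**2
        halo = ndimage.binary_dilation(fiber_sel, structure=disk)
    else:
        halo = fiber_sel
    bg_sel = ~halo
    if not bg_sel.any():
        raise ValidationError("empty background: guard_px too large")

    fiber_vals = section.values[fiber_sel].astype(np.float64)
    bg_vals = section.values[bg_sel].astype(np.float64)
    pooled = np.concatenate([fiber_vals, bg_vals])
    edges = np.histogram_bin_edges(pooled, bins="fd")
    if len(edges) < 3:  # degenerate (near-constant) sample
        edges = np.histogram_bin_edges(pooled, bins=10)
    fiber_d, _ = np.histogram(fiber_vals, bins=edges, density=True)
    bg_d, _ = np.histogram(bg_vals, bins=edges, density=True)
    return RIDensity(bin_edges=edges, fiber_density=fiber_d, background_density=bg_d)
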