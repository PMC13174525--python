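"""Refractive-index tomogram containers and I/O.

A tomogram is a 3D scalar field of refractive index (RI), indexed
``(z, y, x)`` with physical voxel size in micrometres and the medium RI
``n_m`` carried as first-class metadata.  Stacks are stored as multi-page
32-bit float TIFF with a JSON sidecar holding the physical metadata
(``voxel_size_um``, ``medium_ri``, ``time_min``); integer stacks are
accepted on read only when the sidecar supplies an explicit affine
``scale``/``offset`` decode, because RI contrasts of order 1e-3 must not
be left to guessed scaling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import tifffile

from .errors import FormatError, MetadataError, ValidationError

#: Physical plausibility gate for refractive indices of hydrated specimens.
RI_MIN_DEFAULT = 1.0
RI_MAX_DEFAULT = 1.7


@dataclass
class RITomogram:
    """3D refractive-index field with physical metadata.

    Parameters
    ----------
    values : ndarray, shape (nz, ny, nx)
        Refractive index per voxel (dimensionless).
    voxel_size : (dz, dy, dx)
        Voxel dimensions in micrometres.
    medium_ri : float
        Background (immersion medium) refractive index ``n_m``.
    time_min : float, optional
        Acquisition time in minutes for time-lapse frames.
    label : str
        Free-text identifier.
    """

    values: np.ndarray
    voxel_size: tuple[float, float, float]
    medium_ri: float
    time_min: Optional[float] = None
    label: str = ""
    ri_gate: tuple[float, float] = (RI_MIN_DEFAULT, RI_MAX_DEFAULT)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 3:
            raise ValidationError(f"values must be 3D (z, y, x); got ndim={self.values.ndim}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValidationError(f"voxel_size must be 3 positive lengths; got {self.voxel_size}")
        self.medium_ri = float(self.medium_ri)
        self.validate()

    def validate(self) -> None:
        lo, hi = self.ri_gate
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("tomogram contains non-finite values")
        vmin, vmax = float(self.values.min(initial=lo)), float(self.values.max(initial=lo))
        if vmin < lo or vmax > hi:
            raise ValidationError(
                f"RI values [{vmin:.4f}, {vmax:.4f}] outside plausibility gate [{lo}, {hi}]"
            )
        if not (lo <= self.medium_ri <= hi):
            raise ValidationError(f"medium_ri {self.medium_ri} outside gate [{lo}, {hi}]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_um3(self) -> float:
        """Voxel-equivalent volume ``V_vox = dz*dy*dx`` in um^3."""
        dz, dy, dx = self.voxel_size
        return dz * dy * dx

    def delta_n(self) -> np.ndarray:
        """Clipped RI contrast ``max(n - n_m, 0)`` per voxel."""
        return np.clip(self.values - self.medium_ri, 0.0, None)


@dataclass
class TimeLapseSeries:
    """Ordered sequence of tomogram frames sharing geometry."""

    frames: list[RITomogram]
    interval_min: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValidationError("a time-lapse series needs at least one frame")
        times = [f.time_min for f in self.frames]
        if any(t is None for t in times):
            raise ValidationError("every frame needs time_min")
        if any(b <= a for a, b in zip(times, times[1:])):  # type: ignore[operator]
            raise ValidationError(f"frame times must be strictly increasing; got {times}")
        shape0, vox0 = self.frames[0].shape, self.frames[0].voxel_size
        for f in self.frames[1:]:
            if f.shape != shape0 or f.voxel_size != vox0:
                raise ValidationError("all frames must share shape and voxel_size")

    @property
    def times_min(self) -> list[float]:
        return [float(f.time_min) for f in self.frames]  # type: ignore[arg-type]

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class Section2D:
    """A single axial (x-y) section of a tomogram, with provenance."""

    values: np.ndarray
    pixel_size: tuple[float, float]  # (dy, dx) um
    slice_thickness: float  # dz um
    z_index: int
    medium_ri: float
    ri_gate: tuple[float, float] = (RI_MIN_DEFAULT, RI_MAX_DEFAULT)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 2:
            raise ValidationError("section values must be 2D (y, x)")
        if any(v <= 0 for v in self.pixel_size) or self.slice_thickness <= 0:
            raise ValidationError("pixel_size and slice_thickness must be positive")
        lo, hi = self.ri_gate
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("section contains non-finite values")
        if self.values.size and (self.values.min() < lo or self.values.max() > hi):
            raise ValidationError("section RI outside plausibility gate")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    def delta_n(self) -> np.ndarray:
        return np.clip(self.values - self.medium_ri, 0.0, None)


# ---------------------------------------------------------------------------
# I/O

def _sidecar_path(path: Union[str, Path]) -> Path:
    return Path(path).with_suffix(Path(path).suffix + ".json")


def write_tomogram(tomo: RITomogram, path: Union[str, Path]) -> Path:
    """Write a tomogram as multi-page float32 TIFF plus JSON sidecar.

    The sidecar carries ``voxel_size_um``, ``medium_ri``, ``time_min`` and
    ``label``; the pair round-trips losslessly through :func:`read_tomogram`.
    Encoding is deterministic: identical tomograms produce byte-identical
    files.
    """
    tomo.validate()
    path = Path(path)
    tifffile.imwrite(path, tomo.values.astype(np.float32), photometric="minisblack")
    meta = {
        "voxel_size_um": list(tomo.voxel_size),
        "medium_ri": tomo.medium_ri,
        "time_min": tomo.time_min,
        "label": tomo.label,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return path


def read_tomogram(
    path: Union[str, Path],
    meta: Union[None, str, Path, dict] = None,
) -> RITomogram:
    """Read a multi-page grayscale stack into an :class:`RITomogram`.

    ``meta`` may be an inline dict, a path to a JSON sidecar, or ``None``
    (the default sidecar location next to ``path``).  The function fails
    rather than guessing missing metadata.  Integer stacks require
    ``scale`` and ``offset`` in the metadata and are decoded as
    ``offset + scale * integer``.
    """
    path = Path(path)
    if isinstance(meta, dict):
        metadata = dict(meta)
    else:
        sidecar = Path(meta) if meta is not None else _sidecar_path(path)
        if not sidecar.exists():
            raise MetadataError(f"no metadata sidecar at {sidecar}")
        try:
            metadata = json.loads(sidecar.read_text())
        except json.JSONDecodeError as exc:
            raise MetadataError(f"unparseable sidecar {sidecar}: {exc}") from exc

    with tifffile.TiffFile(path) as tif:
        dtypes = {page.dtype for page in tif.pages}
        if len(dtypes) > 1:
            raise FormatError(f"mixed page dtypes in {path}: {sorted(map(str, dtypes))}")
        arr = tif.asarray()
        # accept OME physical sizes as a fallback voxel size
        if "voxel_size_um" not in metadata and tif.ome_metadata:
            ome = _ome_voxel_size(tif.ome_metadata)
            if ome is not None:
                metadata["voxel_size_um"] = ome
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise FormatError(f"expected a grayscale stack; got array of ndim {arr.ndim}")

    if "voxel_size_um" not in metadata:
        raise MetadataError("metadata missing voxel_size_um")
    if "medium_ri" not in metadata:
        raise MetadataError("metadata missing medium_ri")

    if np.issubdtype(arr.dtype, np.integer):
        if "scale" not in metadata or "offset" not in metadata:
            raise MetadataError("integer stack requires explicit scale and offset metadata")
        arr = float(metadata["offset"]) + float(metadata["scale"]) * arr.astype(np.float64)

    return RITomogram(
        values=arr,
        voxel_size=tuple(metadata["voxel_size_um"]),
        medium_ri=float(metadata["medium_ri"]),
        time_min=metadata.get("time_min"),
        label=metadata.get("label", ""),
    )


def _ome_voxel_size(ome_xml: str) -> Optional[list[float]]:
    import re

    m = {}
    for axis in ("Z", "Y", "X"):
        hit = re.search(rf'PhysicalSize{axis}="([0-9.eE+-]+)"', ome_xml)
        if hit:
            m[axis] = float(hit.group(1))
    if len(m) == 3:
        return [m["Z"], m["Y"], m["X"]]
    return None


def read_series(
    paths: Sequence[Union[str, Path]], interval_min: Optional[float] = None
) -> TimeLapseSeries:
    """Read an ordered list of stacks as a time-lapse series."""
    return TimeLapseSeries([read_tomogram(p) for p in paths], interval_min=interval_min)


# ---------------------------------------------------------------------------
# Projections and sections

def max_intensity_projection(tomo: RITomogram, depth_colored: bool = False, cmap: str = "viridis"):
    """Maximum-intensity projection along z.

    Plain mode returns the 2D array of per-column maxima.  Depth-colored
    mode returns an RGB float image where hue encodes the argmax z (via
    the named matplotlib colormap over ``[0, nz-1]``, ties broken toward
    smaller z — the convention of ``argmax``) and brightness encodes the
    clipped contrast of the MIP normalised to its maximum.
    """
    if tomo.values.size == 0:
        raise ValidationError("empty volume")
    mip = tomo.values.max(axis=0)
    if not depth_colored:
        return mip
    import matplotlib

    zarg = tomo.values.argmax(axis=0)  # first occurrence = smallest z
    nz = tomo.values.shape[0]
    znorm = zarg / max(nz - 1, 1)
    colors = matplotlib.colormaps[cmap](znorm)[..., :3]
    contrast = np.clip(mip - tomo.medium_ri, 0.0, None)
    peak = contrast.max()
    intensity = contrast / peak if peak > 0 else np.zeros_like(contrast)
    return colors * intensity[..., None]


def extract_axial_section(tomo: RITomogram, rule: Union[int, str] = "max_contrast") -> Section2D:
    """Extract one axial (x-y) section.

    ``rule`` is either a fixed z index or ``"max_contrast"``, which picks
    the z maximising the slice sum of clipped contrast
    ``sum(max(n - n_m, 0))``; ties go to the smallest z.
    """
    nz = tomo.values.shape[0]
    if isinstance(rule, str):
        if rule != "max_contrast":
            raise ValidationError(f"unknown section rule {rule!r}")
        energy = np.clip(tomo.values - tomo.medium_ri, 0.0, None).sum(axis=(1, 2))
        z = int(np.argmax(energy))  # argmax takes the first (smallest z) maximiser
    else:
        z = int(rule)
        if not (0 <= z < nz):
            raise ValidationError(f"z index {z} out of bounds for {nz} slices")
    dz, dy, dx = tomo.voxel_size
    return Section2D(
        values=tomo.values[z],
        pixel_size=(dy, dx),
        slice_thickness=dz,
        z_index=z,
        medium_ri=tomo.medium_ri,
    )
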