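"""Time-resolved mean RI contrast during polymerization, and temporal composites.

During collagen gelation the volume-mean clipped contrast
``delta_n(t)`` rises as monomers assemble into fibrils; on ideal
(noiseless) data the rise is monotone and well described by the
saturating-growth model ``dn_max * (1 - exp(-t/tau))``.  Real
trajectories may dip, so monotonicity is reported as a score (fraction
of non-decreasing steps), never asserted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import curve_fit

from .errors import FitError, ValidationError
from .tomo import RITomogram, TimeLapseSeries


@dataclass
class DeltaNTrajectory:
    """Time-ordered mean clipped-contrast values."""

    times_min: np.ndarray
    mean_delta_n: np.ndarray
    roi: Optional[tuple[slice, slice, slice]] = None

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.mean_delta_n = np.asarray(self.mean_delta_n, dtype=float)
        if self.times_min.shape != self.mean_delta_n.shape:
            raise ValidationError("times and values must have the same length")
        if np.any(np.diff(self.times_min) <= 0):
            raise ValidationError("times must be strictly increasing")

    def monotonicity_score(self) -> float:
        """Fraction of consecutive steps that are non-decreasing, in [0, 1]."""
        if len(self.times_min) < 2:
            return 1.0
        steps = np.diff(self.mean_delta_n)
        return float(np.mean(steps >= -1e-15))


@dataclass
class KineticsFit:
    """Recovered parameters of the saturating-growth model."""

    dn_max_hat: float
    tau_hat_min: float
    residual_rms: float
    tau_identifiable: bool = True

    def __post_init__(self) -> None:
        if self.dn_max_hat < 0:
            raise ValidationError("dn_max_hat must be >= 0")
        if self.tau_identifiable and not self.tau_hat_min > 0:
            raise ValidationError("tau_hat_min must be positive when identifiable")


def mean_delta_n(
    tomo: RITomogram,
    n_m: Optional[float] = None,
    roi: Optional[tuple[slice, slice, slice]] = None,
) -> float:
    """Mean over (ROI-restricted) voxels of ``max(n - n_m, 0)``."""
    n_m = tomo.medium_ri if n_m is None else float(n_m)
    values = tomo.values[roi] if roi is not None else tomo.values
    if values.size == 0:
        raise ValidationError("empty ROI")
    return float(np.clip(values - n_m, 0.0, None).mean())


def trajectory(
    series: TimeLapseSeries,
    n_m: Optional[float] = None,
    roi: Optional[tuple[slice, slice, slice]] = None,
) -> DeltaNTrajectory:
    """Per-frame mean clipped contrast in time order."""
    times = np.asarray(series.times_min, dtype=float)
    values = np.array([mean_delta_n(f, n_m=n_m, roi=roi) for f in series.frames])
    return DeltaNTrajectory(times_min=times, mean_delta_n=values, roi=roi)


def saturating_model(t: np.ndarray, dn_max: float, tau: float) -> np.ndarray:
    return dn_max * (1.0 - np.exp(-np.asarray(t, dtype=float) / tau))


def fit_saturating_kinetics(traj: DeltaNTrajectory) -> KineticsFit:
    """Least-squares fit of ``dn_max * (1 - exp(-t/tau))``.

    Initialisation: ``dn_max0`` = last trajectory value; ``tau0`` = time
    at which the trajectory first reaches half of ``dn_max0``
    (interpolated), falling back to the mid-span.  The search is bounded
    to non-negative ``dn_max`` and positive ``tau``.  An all-zero
    trajectory returns ``dn_max_hat = 0`` with ``tau`` flagged
    unidentifiable.
    """
    t = traj.times_min
    y = traj.mean_delta_n
    if len(t) < 4:
        raise ValidationError("need at least 4 time points to fit")
    if np.all(y <= 0):
        return KineticsFit(
            dn_max_hat=0.0, tau_hat_min=float("nan"), residual_rms=float(np.sqrt((y**2).mean())),
            tau_identifiable=False,
        )
    dn0 = max(float(y[-1]), float(y.max()) * 0.5, 1e-12)
    half = dn0 / 2.0
    above = np.nonzero(y >= half)[0]
    if len(above) and above[0] > 0:
        i = above[0]
        frac = (half - y[i - 1]) / (y[i] - y[i - 1]) if y[i] != y[i - 1] else 0.5
        tau0 = t[i - 1] + frac * (t[i] - t[i - 1])
    elif len(above):
        tau0 = max(t[1] - t[0], 1e-6)
    else:
        tau0 = 0.5 * (t[0] + t[-1])
    tau0 = max(float(tau0), 1e-6)
    span = max(float(t[-1] - t[0]), 1e-6)
    try:
        popt, _ = curve_fit(
            saturating_model,
            t,
            y,
            p0=[dn0, tau0],
            bounds=([0.0, 1e-9], [np.inf, 1e4 * span]),
            maxfev=10000,
        )
    except RuntimeError as exc:
        raise FitError(f"saturating-kinetics fit failed: {exc}", {"p0": [dn0, tau0]}) from exc
    resid = y - saturating_model(t, *popt)
    return KineticsFit(
        dn_max_hat=float(popt[0]),
        tau_hat_min=float(popt[1]),
        residual_rms=float(np.sqrt((resid**2).mean())),
    )


def time_color_composite(
    series: TimeLapseSeries,
    mode: str | int = "mip",
    cmap: str = "turbo",
) -> np.ndarray:
    """Temporally encoded RGB composite of a time-lapse series.

    Each frame is reduced to a 2D clipped-contrast image (MIP over z, or
    a fixed z slice), tinted with the colormap hue mapped linearly from
    its time over the series span, and the composite takes, per pixel,
    the tint of the frame with the maximum intensity there.  Output
    values lie in [0, 1]; deterministic for a fixed colormap.
    """
    import matplotlib

    times = np.asarray(series.times_min, dtype=float)
    span = times[-1] - times[0]
    projections = []
    for frame in series.frames:
        dn = np.clip(frame.values - frame.medium_ri, 0.0, None)
        if mode == "mip":
            proj = dn.max(axis=0)
        else:
            z = int(mode)
            if not (0 <= z < frame.values.shape[0]):
                raise ValidationError(f"z index {z} out of bounds")
            proj = dn[z]
        projections.append(proj)
    stack = np.stack(projections)  # (T, ny, nx)
    peak = stack.max()
    intensity = stack / peak if peak > 0 else stack
    colors = matplotlib.colormaps[cmap](
        (times - times[0]) / span if span > 0 else np.zeros_like(times)
    )[:, :3]
    winner = intensity.argmax(axis=0)  # ties -> earliest frame
    amp = np.take_along_axis(intensity, winner[None], axis=0)[0]
    rgb = colors[winner] * amp[..., None]
    return np.clip(rgb, 0.0, 1.0)
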