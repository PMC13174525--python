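"""Multimodal 2D co-registration by mutual information on gradient magnitudes.

Cross-modality image pairs (e.g. an RI section and a second-harmonic
image of the same field) have incomparable raw intensities, so the
similarity objective is mutual information (MI) between
gradient-magnitude images: rigid alignment by a deterministic coarse
grid search plus derivative-free local refinement, followed by affine
refinement that is guaranteed never to report a lower MI than its rigid
initialisation.  No stochastic search is used, so results reproduce
without seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage, optimize

from .errors import ValidationError


@dataclass
class RigidTransform2D:
    """Rotation (degrees, counterclockwise in (y, x) with y down) about
    ``center`` followed by translation ``(ty, tx)`` in pixels; maps moving
    coordinates to fixed coordinates."""

    rotation_deg: float = 0.0
    translation: tuple[float, float] = (0.0, 0.0)
    center: Optional[tuple[float, float]] = None  # defaults to image center at use

    def matrix(self, shape: tuple[int, int]) -> np.ndarray:
        """2x3 affine (fixed <- moving) for an image of ``shape``."""
        cy, cx = self.center if self.center is not None else ((shape[0] - 1) / 2, (shape[1] - 1) / 2)
        th = math.radians(self.rotation_deg)
        c, s = math.cos(th), math.sin(th)
        R = np.array([[c, -s], [s, c]])
        offset = np.array([cy, cx]) - R @ np.array([cy, cx]) + np.asarray(self.translation)
        return np.hstack([R, offset[:, None]])

    def inverse(self) -> "RigidTransform2D":
        inv = RigidTransform2D(
            rotation_deg=-self.rotation_deg, translation=(0.0, 0.0), center=self.center
        )
        # translation of the inverse: solve R^-1 (p - t - c) + c
        th = math.radians(-self.rotation_deg)
        c, s = math.cos(th), math.sin(th)
        Rinv = np.array([[c, -s], [s, c]])
        t = np.asarray(self.translation)
        inv.translation = tuple(-(Rinv @ t))
        return inv


@dataclass
class AffineTransform2D:
    """2x3 matrix mapping moving -> fixed pixel coordinates (y, x)."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (2, 3):
            raise ValidationError("affine matrix must be 2x3")
        if abs(np.linalg.det(self.matrix[:, :2])) < 1e-12:
            raise ValidationError("singular linear part")

    @classmethod
    def from_rigid(cls, rigid: RigidTransform2D, shape: tuple[int, int]) -> "AffineTransform2D":
        return cls(matrix=rigid.matrix(shape))


@dataclass
class RegistrationResult:
    rigid: RigidTransform2D
    affine: Optional[AffineTransform2D]
    final_mi_bits: float
    converged: bool
    mi_at_identity: float = 0.0


# ---------------------------------------------------------------------------
# building blocks

def gradient_magnitude(image: np.ndarray, sigma: float = 1.0) -> np.ndarray:
    """Isotropic first-derivative magnitude via Gaussian-smoothed central differences."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or min(image.shape) < 3:
        raise ValidationError("image must be 2D and at least 3x3")
    return ndimage.gaussian_gradient_magnitude(image, sigma=sigma)


def mutual_information(
    a: np.ndarray,
    b: np.ndarray,
    bins: int = 64,
    valid: Optional[np.ndarray] = None,
) -> float:
    """Mutual information of the joint intensity histogram, in bits.

    Each image is binned over its own observed range; with ``a is b``
    the joint histogram is diagonal and MI equals the histogram entropy
    H(a) exactly.  ``valid`` masks pixels (e.g. excluding out-of-field
    samples after warping).
    """
    a, b = np.asarray(a, dtype=np.float64), np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValidationError(f"shape mismatch {a.shape} vs {b.shape}")
    if bins < 2:
        raise ValidationError("bins must be >= 2")
    if valid is not None:
        a, b = a[valid], b[valid]
    if a.size == 0:
        return 0.0
    joint, _, _ = np.histogram2d(a.ravel(), b.ravel(), bins=bins)
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float((p[nz] * np.log2(p[nz] / (px @ py)[nz])).sum())


def entropy_bits(a: np.ndarray, bins: int = 64) -> float:
    """Shannon entropy of the binned intensity histogram, in bits."""
    hist, _ = np.histogram(np.asarray(a).ravel(), bins=bins)
    p = hist / hist.sum()
    nz = p > 0
    return float(-(p[nz] * np.log2(p[nz])).sum())


def warp_affine(moving: np.ndarray, matrix: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Resample ``moving`` into the fixed frame; out-of-field pixels become NaN."""
    A = np.asarray(matrix, dtype=float)
    R, t = A[:, :2], A[:, 2]
    Rinv = np.linalg.inv(R)
    out = ndimage.affine_transform(
        np.asarray(moving, dtype=np.float64),
        Rinv,
        offset=-Rinv @ t,
        output_shape=shape,
        order=1,
        mode="constant",
        cval=np.nan,
    )
    return out


def _mi_of_matrix(fixed: np.ndarray, moving: np.ndarray, matrix: np.ndarray, bins: int) -> tuple[float, float]:
    warped = warp_affine(moving, matrix, fixed.shape)
    valid = ~np.isnan(warped)
    overlap = float(valid.mean())
    if overlap == 0:
        return 0.0, 0.0
    return mutual_information(fixed, np.nan_to_num(warped), bins=bins, valid=valid), overlap


# ---------------------------------------------------------------------------
# rigid registration

@dataclass
class RigidSearchSettings:
    """Deterministic coarse-to-fine search for the rigid stage."""

    rotation_range_deg: float = 15.0
    rotation_step_deg: float = 1.0
    translation_range_px: float = 20.0
    translation_step_px: float = 4.0
    downsample: int = 4
    bins: int = 32  # coarser than the standalone MI default: smoother objective on noisy images
    use_gradient: bool = True
    gradient_sigma: float = 1.5
    min_overlap: float = 0.25
    refine: bool = True
    refine_starts: int = 1  # top-k grid candidates to refine
    refine_restarts: int = 2  # Powell restarts per candidate (escapes ridge stalls)


def register_rigid(
    fixed: np.ndarray,
    moving: np.ndarray,
    settings: Optional[RigidSearchSettings] = None,
) -> RegistrationResult:
    """Recover the rigid transform maximising MI of gradient magnitudes.

    Coarse grid search over (rotation, ty, tx) on ``downsample``-reduced
    gradient images, then Powell refinement at full resolution.  The
    reported MI is never below the MI at the identity initialisation,
    and a result whose optimum overlaps less than ``min_overlap`` of the
    field is flagged non-converged.
    """
    s = settings or RigidSearchSettings()
    if s.use_gradient:
        f_img = gradient_magnitude(fixed, sigma=s.gradient_sigma)
        m_img = gradient_magnitude(moving, sigma=s.gradient_sigma)
    else:
        f_img = np.asarray(fixed, dtype=np.float64)
        m_img = np.asarray(moving, dtype=np.float64)

    d = max(int(s.downsample), 1)
    f_small = ndimage.zoom(f_img, 1.0 / d, order=1) if d > 1 else f_img
    m_small = ndimage.zoom(m_img, 1.0 / d, order=1) if d > 1 else m_img

    rotations = np.arange(-s.rotation_range_deg, s.rotation_range_deg + 1e-9, s.rotation_step_deg)
    trans = np.arange(-s.translation_range_px, s.translation_range_px + 1e-9, s.translation_step_px)
    candidates: list[tuple[float, float, float, float]] = []
    for rot in rotations:
        for ty in trans:
            for tx in trans:
                rt = RigidTransform2D(rotation_deg=rot, translation=(ty / d, tx / d))
                mi, overlap = _mi_of_matrix(f_small, m_small, rt.matrix(f_small.shape), s.bins)
                if overlap >= s.min_overlap:
                    candidates.append((mi, rot, ty, tx))
    candidates.sort(reverse=True)
    if not candidates:
        candidates = [(0.0, 0.0, 0.0, 0.0)]

    def neg_mi(p):
        rt = RigidTransform2D(rotation_deg=p[0], translation=(p[1], p[2]))
        mi, overlap = _mi_of_matrix(f_img, m_img, rt.matrix(f_img.shape), s.bins)
        if overlap < s.min_overlap:
            return 1e3
        return -mi

    if s.refine:
        best_fun, x = np.inf, np.array(candidates[0][1:])
        for _, rot0, ty0, tx0 in candidates[: max(s.refine_starts, 1)]:
            xk = np.array([rot0, ty0, tx0])
            res = None
            for _ in range(max(s.refine_restarts, 1)):
                res = optimize.minimize(
                    neg_mi, xk, method="Powell",
                    options={"xtol": 1e-3, "ftol": 1e-7, "maxfev": 3000},
                )
                xk = res.x
            if res.fun < best_fun:
                best_fun, x = res.fun, res.x
    else:
        x = np.array(candidates[0][1:])
    rigid = RigidTransform2D(rotation_deg=float(x[0]), translation=(float(x[1]), float(x[2])))
    mi_final, overlap = _mi_of_matrix(f_img, m_img, rigid.matrix(f_img.shape), s.bins)
    identity = RigidTransform2D()
    mi_id, _ = _mi_of_matrix(f_img, m_img, identity.matrix(f_img.shape), s.bins)
    converged = overlap >= s.min_overlap
    if mi_final < mi_id:
        rigid, mi_final = identity, mi_id
        converged = False
    return RegistrationResult(
        rigid=rigid, affine=None, final_mi_bits=mi_final, converged=converged,
        mi_at_identity=mi_id,
    )


def refine_affine(
    fixed: np.ndarray,
    moving: np.ndarray,
    init: RigidTransform2D,
    settings: Optional[RigidSearchSettings] = None,
) -> tuple[AffineTransform2D, RegistrationResult]:
    """Local MI maximisation over the 6 affine parameters from the rigid solution.

    If the optimiser cannot improve on the initialisation the rigid
    transform is returned promoted to affine, flagged ``converged=False``.
    """
    s = settings or RigidSearchSettings()
    if s.use_gradient:
        f_img = gradient_magnitude(fixed, sigma=s.gradient_sigma)
        m_img = gradient_magnitude(moving, sigma=s.gradient_sigma)
    else:
        f_img = np.asarray(fixed, dtype=np.float64)
        m_img = np.asarray(moving, dtype=np.float64)

    A0 = init.matrix(f_img.shape)
    mi_init, _ = _mi_of_matrix(f_img, m_img, A0, s.bins)
    cy, cx = (f_img.shape[0] - 1) / 2, (f_img.shape[1] - 1) / 2
    center = np.array([cy, cx])

    def build(p):
        # perturbation about the center so translation and linear parts decouple
        L = A0[:, :2] @ (np.eye(2) + p[:4].reshape(2, 2))
        t = A0[:, :2] @ center + A0[:, 2] + p[4:] - L @ center
        return np.hstack([L, t[:, None]])

    def neg_mi(p):
        mi, overlap = _mi_of_matrix(f_img, m_img, build(p), s.bins)
        if overlap < s.min_overlap:
            return 1e3
        return -mi

    res = optimize.minimize(
        neg_mi, np.zeros(6), method="Powell",
        options={"xtol": 1e-4, "ftol": 1e-7, "maxfev": 4000},
    )
    A = build(res.x)
    mi_final, overlap = _mi_of_matrix(f_img, m_img, A, s.bins)
    if mi_final < mi_init or overlap < s.min_overlap:
        affine = AffineTransform2D.from_rigid(init, f_img.shape)
        return affine, RegistrationResult(
            rigid=init, affine=affine, final_mi_bits=mi_init, converged=False,
            mi_at_identity=mi_init,
        )
    affine = AffineTransform2D(matrix=A)
    return affine, RegistrationResult(
        rigid=init, affine=affine, final_mi_bits=mi_final, converged=True,
        mi_at_identity=mi_init,
    )


# ---------------------------------------------------------------------------

def line_profile(
    image: np.ndarray,
    p0: tuple[float, float],
    p1: tuple[float, float],
    n_samples: Optional[int] = None,
) -> np.ndarray:
    """Bilinear samples along the segment p0 -> p1 (points as (y, x) px).

    Default ``n_samples`` is ``ceil(length_px) + 1`` so a 10-px segment
    yields 11 evenly spaced samples including both endpoints.
    """
    image = np.asarray(image, dtype=np.float64)
    p0, p1 = np.asarray(p0, dtype=float), np.asarray(p1, dtype=float)
    for p in (p0, p1):
        if not (0 <= p[0] <= image.shape[0] - 1 and 0 <= p[1] <= image.shape[1] - 1):
            raise ValidationError(f"point {tuple(p)} outside image {image.shape}")
    length = float(np.linalg.norm(p1 - p0))
    if n_samples is None:
        n_samples = int(math.ceil(length)) + 1
    if n_samples < 2:
        n_samples = 2 if length > 0 else 1
    ts = np.linspace(0.0, 1.0, n_samples)
    pts = p0[None, :] + ts[:, None] * (p1 - p0)[None, :]
    return ndimage.map_coordinates(image, [pts[:, 0], pts[:, 1]], order=1, mode="nearest")
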