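"""Shared helpers for the test suite: phantom recipes and trace <-> truth matching."""

from __future__ import annotations

import math

import numpy as np

from rifiber.extraction import (
    ExtractionParams,
    binarize_foreground,
    build_width_weighted_mask,
    enhance_section,
    trace_fibers,
)
from rifiber.phantom import PhantomConfig
from rifiber.tomo import extract_axial_section

PLANAR_VOXEL = (0.4, 0.2, 0.2)


def straight_planar_config(seed: int, n_fibers: int = 5, **overrides) -> PhantomConfig:
    """Non-overlapping straight fibers in the mid-z plane; the workhorse
    configuration for recovery tests (diameters ~3-10 px at 0.2 um/px)."""
    kw = dict(
        shape_vox=(13, 256, 256),
        voxel_size=PLANAR_VOXEL,
        n_fibers=n_fibers,
        noise_sd=0.0,
        psf_sigma_um=(0.0, 0.0, 0.0),
        planar=True,
        min_separation_um=1.5,
        width_lognormal=(1.1, 0.28),
        persistence_length_um=1e6,
        fiber_length_um=(12.0, 22.0),
        seed=seed,
    )
    kw.update(overrides)
    return PhantomConfig(**kw)


def extract_all(section, params: ExtractionParams | None = None, enhance: bool = False):
    """Run binarise -> trace -> mask on a section; returns (traces, fiber_mask)."""
    params = params or ExtractionParams()
    work = enhance_section(section, params) if enhance else section
    mask = binarize_foreground(work, params)
    traces = trace_fibers(section, mask, params)
    fmask = build_width_weighted_mask(traces, section.shape)
    return traces, fmask


def trace_angle_deg(trace) -> float:
    d = trace.centerline[-1] - trace.centerline[0]
    return math.degrees(math.atan2(d[0], d[1])) % 180.0


def match_to_truth(traces, ground_truth, pixel_size_xy: float):
    """Match each trace to the nearest true fiber by centerline midpoint.

    Returns a list of (trace, FiberSpec) pairs; greedy nearest matching is
    adequate for the well-separated phantoms used in tests.
    """
    pairs = []
    for t in traces:
        mid = t.centerline.mean(axis=0)
        best = min(
            ground_truth.fibers,
            key=lambda f: np.linalg.norm(
                f.control_points[:, 1:].mean(axis=0) / pixel_size_xy - mid
            ),
        )
        pairs.append((t, best))
    return pairs


def angle_diff_deg(a: float, b: float, period: float = 180.0) -> float:
    d = abs(a - b) % period
    return min(d, period - d)


def phantom_section(config: PhantomConfig):
    from rifiber.phantom import generate_phantom

    tomo, truth = generate_phantom(config)
    return extract_axial_section(tomo, "max_contrast"), truth, tomo
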