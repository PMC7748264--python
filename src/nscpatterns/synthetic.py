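"""Synthetic hemispheres and division patterns with known ground truth.

Every pipeline stage is testable without experimental data: hemispheres
are quasi-regular point clouds (perturbed hexagonal packing, matching the
single-layer tiling of NSC somata and the observed ~200 cells within a
100 um radius), and Time-2 division events are drawn from the same
categorical placement model the interaction fit assumes — weight ``g``
within radius ``r`` of a Time-1 event and 1 elsewhere — so that
round-trip parameter recovery is exact in expectation.  ``g = 1`` yields
the discrete-random null, ``g > 1`` aggregated, ``g < 1`` dispersed
patterns.
"""

from __future__ import annotations

import numpy as np

from .division import CellCycleParams, LABELING_INTERVALS, cohort_fractions
from .geometry import Hemisphere, build_hemisphere
from .spatial import LabeledPattern

__all__ = [
    "generate_hemisphere",
    "generate_pattern",
    "generate_observed_fractions",
    "HEX_SPACING",
]

#: hexagonal spacing (um) giving ~202 cells within a 100-um radius
HEX_SPACING = float(np.sqrt(2.0 * (np.pi * 100.0**2 / 202.0) / np.sqrt(3.0)))


def generate_hemisphere(
    n_cells: int = 2400,
    geometry: str = "flat-disc",
    spacing: float = HEX_SPACING,
    jitter: float = 1.5,
    cap_radius: float = 300.0,
    seed=None,
    hemisphere_id: str = "synthetic",
) -> Hemisphere:
    """Quasi-regular NSC point cloud on a flat disc or a spherical cap.

    ``jitter`` (um) perturbs the hexagonal lattice positions; values at or
    above half the spacing risk coincident points and trigger a warning.
    The spherical cap maps the flat colony onto a sphere of radius
    ``cap_radius`` via the area-preserving azimuthal projection, so the
    surface density matches the flat calibration.
    """
    if n_cells < 3:
        raise ValueError("need at least 3 cells")
    if jitter >= spacing / 2:
        import warnings

        warnings.warn("jitter >= spacing/2; points may nearly coincide", stacklevel=2)
    rng = np.random.default_rng(seed)
    m = int(np.ceil(np.sqrt(n_cells))) + 6
    i, j = np.meshgrid(np.arange(-m, m + 1), np.arange(-m, m + 1))
    x = spacing * (i + 0.5 * (j % 2))
    y = spacing * (np.sqrt(3) / 2) * j
    pts = np.column_stack([x.ravel(), y.ravel()])
    order = np.argsort((pts**2).sum(axis=1))
    pts = pts[order[:n_cells]] + rng.normal(0, jitter, size=(n_cells, 2))

    if geometry == "flat-disc":
        coords = np.column_stack([pts, np.zeros(n_cells)])
    elif geometry == "spherical-cap":
        # Lambert azimuthal equal-area: planar radius rho -> polar angle theta
        rho = np.linalg.norm(pts, axis=1)
        theta = 2 * np.arcsin(np.clip(rho / (2 * cap_radius), 0, 1))
        phi = np.arctan2(pts[:, 1], pts[:, 0])
        coords = cap_radius * np.column_stack(
            [
                np.sin(theta) * np.cos(phi),
                np.sin(theta) * np.sin(phi),
                np.cos(theta),
            ]
        )
    else:
        raise ValueError(f"unknown geometry {geometry!r}")
    return build_hemisphere(coords, hemisphere_id=hemisphere_id)


def generate_pattern(
    h: Hemisphere,
    d,
    n1: int = 40,
    n2: int = 40,
    g: float = 1.0,
    r: float = 100.0,
    delta_t: float | None = None,
    seed=None,
) -> LabeledPattern:
    """Draw a labeled division pattern from the placement model.

    Time-1 events are uniform without replacement over all NSCs; Time-2
    events are drawn sequentially without replacement from the remaining
    (non-Time-1) cells with probability proportional to ``g`` for cells
    within geodesic distance ``r`` of any Time-1 event and 1 otherwise.
    The generating (g, r) is stored as the pattern's ground truth.
    """
    if g <= 0 or r <= 0:
        raise ValueError("g and r must be positive")
    n = h.n_cells
    if n1 + n2 > n:
        raise ValueError("fewer cells than requested events")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    s1 = rng.choice(n, size=n1, replace=False)
    candidates = np.setdiff1d(np.arange(n), s1)
    dmin = d.entries[np.ix_(s1, candidates)].min(axis=0)
    weights = np.where(dmin <= r, g, 1.0)
    s2 = np.empty(n2, dtype=int)
    avail = np.ones(len(candidates), dtype=bool)
    for k in range(n2):
        w = weights * avail
        pick = rng.choice(len(candidates), p=w / w.sum())
        s2[k] = candidates[pick]
        avail[pick] = False
    return LabeledPattern(
        hemisphere=h,
        s1_indices=np.sort(s1),
        s2_indices=np.sort(s2),
        delta_t=delta_t,
        ground_truth={"g": float(g), "r": float(r)},
    )


def generate_observed_fractions(
    kinetics: CellCycleParams,
    hemispheres_per_interval: int = 6,
    intervals=LABELING_INTERVALS,
    n_cells: int = 10000,
    seed=None,
) -> dict:
    """Per-interval redivision/DLS fraction table from known kinetics.

    Shaped exactly like the transcribed per-hemisphere count summaries:
    interval -> {"rediv": [...], "dls": [...]} with one entry per
    simulated hemisphere replicate.  Feeds ``abc_fit`` for round-trip
    parameter recovery.
    """
    rng = np.random.default_rng(seed)
    table = {float(dt): {"rediv": [], "dls": []} for dt in intervals}
    for _ in range(hemispheres_per_interval):
        fr = cohort_fractions(kinetics, intervals, n_cells=n_cells, seed=rng)
        for dt in intervals:
            table[float(dt)]["rediv"].append(fr[float(dt)]["rediv"])
            table[float(dt)]["dls"].append(fr[float(dt)]["dls"])
    return table
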