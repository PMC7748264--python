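"""Discrete Ripley's K statistics for NSC division patterns.

Division events (cells in S-phase) can only occur where NSCs already sit, so
the null model is not a spatial Poisson process but uniform resampling from
the discrete NSC locations.  The spatial statistic

    K_S(r) = (S/A)^-1 * sum_i w(i,r) * [ sum_{j != i} 1{dist(i,j) <= r} ] / S

counts S-phase NSCs within radius r of each S-phase NSC i, normalized by the
event density S/A; w(i,r) is the edge-correction weight (fraction of the
disc inside the hemisphere).  The spatiotemporal variant counts Time-2
events around Time-1 events,

    K_ST(r) = (S1/A)^-1 * sum_{i in S1} w(i,r) * [ sum_{j in S2} 1{...} ] / S2,

where the inner sum runs over all S2 cells (a cell carrying both labels is
counted; the formula does not exclude j = i).

Observed curves are compared against envelopes built by resampling the
event set from all NSC locations (20 draws by default), standardized so
that the 95% envelope quantile maps to +1 and the 5% quantile to -1, and a
pattern is classified from the mean standardized value over 30-150 um:
above +1 aggregated, below -1 dispersed, random in between.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import DistanceMatrix, Hemisphere, edge_correction_table

__all__ = [
    "LabeledPattern",
    "RipleyCurve",
    "default_radii",
    "ripley_spatial",
    "ripley_spatiotemporal",
    "sampling_envelope",
    "standardize_k",
    "classify_pattern",
    "analyze_pattern",
]

#: default radius grid (um): spans the 30-150 um classification window with margin
DEFAULT_RADII = np.arange(10.0, 301.0, 10.0)

CLASSIFICATION_WINDOW = (30.0, 150.0)


def default_radii() -> np.ndarray:
    return DEFAULT_RADII.copy()


@dataclass
class LabeledPattern:
    """S-phase event sets on a hemisphere at one or two label times.

    ``s1_indices`` / ``s2_indices`` index into the hemisphere's cells; for
    single-time analyses only ``s1_indices`` is used.  ``dls_indices`` are
    double-labeled S-phases (one S-phase long enough to catch both labels);
    they carry the Time-1 label by construction and are a subset of s1.
    ``delta_t`` is the labeling interval in hours.
    """

    hemisphere: Hemisphere
    s1_indices: np.ndarray
    s2_indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    delta_t: float | None = None
    dls_indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    doublet_groups: dict | None = None
    ground_truth: dict | None = None

    def __post_init__(self) -> None:
        self.s1_indices = np.asarray(self.s1_indices, dtype=int)
        self.s2_indices = np.asarray(self.s2_indices, dtype=int)
        self.dls_indices = np.asarray(self.dls_indices, dtype=int)
        n = self.hemisphere.n_cells
        for name in ("s1_indices", "s2_indices", "dls_indices"):
            idx = getattr(self, name)
            if idx.size and (idx.min() < 0 or idx.max() >= n):
                raise ValueError(f"{name} out of range for hemisphere with {n} cells")
        if len(np.unique(self.s1_indices)) != len(self.s1_indices):
            raise ValueError("s1_indices contain duplicates")
        if len(np.unique(self.s2_indices)) != len(self.s2_indices):
            raise ValueError("s2_indices contain duplicates")
        if not np.isin(self.dls_indices, self.s1_indices).all():
            raise ValueError("dls_indices must be a subset of s1_indices")


@dataclass
class RipleyCurve:
    """K(r) with its resampling envelope, z-scores and classification."""

    radii: np.ndarray
    k_values: np.ndarray
    envelope_q05: np.ndarray | None = None
    envelope_q95: np.ndarray | None = None
    z_scores: np.ndarray | None = None
    classification: str | None = None


def _edge_weights(
    h: Hemisphere, indices: np.ndarray, radii: np.ndarray, edge_mode: str
) -> np.ndarray:
    if edge_mode == "none":
        return np.ones((len(indices), len(radii)))
    if edge_mode == "fraction":
        return edge_correction_table(h, indices, radii)
    raise ValueError(f"unknown edge correction mode {edge_mode!r}")


def ripley_spatial(
    pattern: LabeledPattern,
    d: DistanceMatrix,
    radii=None,
    edge_mode: str = "fraction",
) -> np.ndarray:
    """Discrete spatial Ripley's K of a single event set."""
    radii = DEFAULT_RADII if radii is None else np.asarray(radii, dtype=float)
    if np.any(radii <= 0) or np.any(np.diff(radii) <= 0):
        raise ValueError("radii must be positive and strictly increasing")
    events = pattern.s1_indices
    s = len(events)
    if s == 0:
        raise ValueError("no events to analyze")
    h = pattern.hemisphere
    w = _edge_weights(h, events, radii, edge_mode)
    dsub = d.entries[np.ix_(events, events)]
    # counts[i, b] = number of other events within radii[b] of event i
    counts = (dsub[:, :, None] <= radii[None, None, :]).sum(axis=1) - 1
    return (h.area / s) * (w * counts).sum(axis=0) / s


def ripley_spatiotemporal(
    pattern: LabeledPattern,
    d: DistanceMatrix,
    radii=None,
    edge_mode: str = "fraction",
    s2_indices=None,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Discrete spatiotemporal Ripley's K: Time-2 events around Time-1 events.

    ``s2_indices`` overrides the pattern's Time-2 set (used by the envelope
    resampler, which holds Time-1 positions fixed).  ``weights`` may supply
    precomputed edge-correction weights for the Time-1 cells (s1 x radii).
    """
    radii = DEFAULT_RADII if radii is None else np.asarray(radii, dtype=float)
    s1 = pattern.s1_indices
    s2 = pattern.s2_indices if s2_indices is None else np.asarray(s2_indices, dtype=int)
    if len(s1) == 0 or len(s2) == 0:
        raise ValueError("both Time-1 and Time-2 event sets must be non-empty")
    h = pattern.hemisphere
    w = _edge_weights(h, s1, radii, edge_mode) if weights is None else weights
    dsub = d.entries[np.ix_(s1, s2)]
    counts = (dsub[:, :, None] <= radii[None, None, :]).sum(axis=1)
    return (h.area / len(s1)) * (w * counts).sum(axis=0) / len(s2)


def sampling_envelope(
    pattern: LabeledPattern,
    d: DistanceMatrix,
    radii=None,
    mode: str = "spatiotemporal",
    n_samples: int = 20,
    seed=None,
    edge_mode: str = "fraction",
):
    """Random-resampling envelope of the discrete K statistic.

    The observed number of events is redrawn uniformly without replacement
    from all NSC locations ``n_samples`` times (Time-1 locations stay fixed
    in spatiotemporal mode; only Time-2 events are resampled) and the 5%
    and 95% per-radius quantiles across the samples are returned.
    """
    if n_samples < 2:
        raise ValueError("need at least 2 samples for an envelope")
    radii = DEFAULT_RADII if radii is None else np.asarray(radii, dtype=float)
    rng = np.random.default_rng(seed)
    n = pattern.hemisphere.n_cells
    ks = np.empty((n_samples, len(radii)))
    if mode == "spatial":
        s = len(pattern.s1_indices)
        if s > n:
            raise ValueError("more events than NSCs")
        for m in range(n_samples):
            draw = rng.choice(n, size=s, replace=False)
            ks[m] = ripley_spatial(
                LabeledPattern(pattern.hemisphere, draw), d, radii, edge_mode
            )
    elif mode == "spatiotemporal":
        s2 = len(pattern.s2_indices)
        if s2 > n:
            raise ValueError("more events than NSCs")
        w1 = _edge_weights(pattern.hemisphere, pattern.s1_indices, radii, edge_mode)
        for m in range(n_samples):
            draw = rng.choice(n, size=s2, replace=False)
            ks[m] = ripley_spatiotemporal(
                pattern, d, radii, edge_mode, s2_indices=draw, weights=w1
            )
    else:
        raise ValueError(f"unknown mode {mode!r}")
    q05 = np.quantile(ks, 0.05, axis=0)
    q95 = np.quantile(ks, 0.95, axis=0)
    return q05, q95


def standardize_k(k_values, q05, q95) -> np.ndarray:
    """Standardize K against its envelope: +1 at the 95% quantile, -1 at 5%.

    Degenerate radii where the envelope collapses (q95 == q05) map to 0,
    i.e. "not distinguishable from random".
    """
    k_values = np.asarray(k_values, dtype=float)
    q05 = np.asarray(q05, dtype=float)
    q95 = np.asarray(q95, dtype=float)
    if not (k_values.shape == q05.shape == q95.shape):
        raise ValueError("k_values and envelope quantiles must have equal length")
    if np.any(q95 < q05):
        raise ValueError("q95 must be >= q05 at every radius")
    mid = 0.5 * (q95 + q05)
    half = 0.5 * (q95 - q05)
    z = np.zeros_like(k_values)
    ok = half > 0
    z[ok] = (k_values[ok] - mid[ok]) / half[ok]
    return z


def classify_pattern(z_scores, radii, window=CLASSIFICATION_WINDOW) -> str:
    """Classify a standardized K curve as aggregated, random or dispersed.

    The mean z-score over grid radii within ``window`` (inclusive, default
    30-150 um) is thresholded: above +1 aggregated, below -1 dispersed,
    random otherwise.
    """
    z_scores = np.asarray(z_scores, dtype=float)
    radii = np.asarray(radii, dtype=float)
    sel = (radii >= window[0]) & (radii <= window[1])
    if not sel.any():
        raise ValueError("no radii fall inside the classification window")
    mean_z = float(z_scores[sel].mean())
    if mean_z > 1:
        return "aggregated"
    if mean_z < -1:
        return "dispersed"
    return "random"


def analyze_pattern(
    pattern: LabeledPattern,
    d: DistanceMatrix,
    radii=None,
    mode: str = "spatiotemporal",
    n_samples: int = 20,
    seed=None,
    edge_mode: str = "fraction",
) -> RipleyCurve:
    """Full per-hemisphere chain: K, envelope, z-scores, classification."""
    radii = DEFAULT_RADII if radii is None else np.asarray(radii, dtype=float)
    if mode == "spatial":
        k = ripley_spatial(pattern, d, radii, edge_mode)
    else:
        k = ripley_spatiotemporal(pattern, d, radii, edge_mode)
    q05, q95 = sampling_envelope(pattern, d, radii, mode, n_samples, seed, edge_mode)
    z = standardize_k(k, q05, q95)
    return RipleyCurve(
        radii=radii,
        k_values=k,
        envelope_q05=q05,
        envelope_q95=q95,
        z_scores=z,
        classification=classify_pattern(z, radii),
    )
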