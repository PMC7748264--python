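"""Agent-based spatiotemporal simulation of a growing NSC sheet.

Cells are soft discs on a flat 2D sheet (all downstream statistics consume
centroids only, so a centroid-based mechanical model replaces the original
lattice description).  Each cell waits at least one cell-cycle duration
after its birth before it becomes available for spontaneous cycle entry at
the base rate ``p_div`` (per hour); a cycling cell completes its cycle after
a lag-exponentially distributed duration and splits into two daughters, one
of which keeps the mother's record.  With probability ``p_rediv`` one
daughter immediately begins a new cycle (a redivision, independent of the
base rate); with probability ``differentiation_fraction`` one daughter is
gfap-negative, never divides, and is removed one cell-cycle duration after
its creation, mimicking differentiating progeny leaving the stem-cell pool.

The simulation starts from a quasi-hexagonal colony of ``n_init`` cells and
runs until the population reaches ``n_target`` (drawn per hemisphere from
the observed colony-size distribution).  Mechanical relaxation pushes
overlapping neighbours apart; the equilibrium spacing is calibrated so the
interior packing matches the observed ~200 NSCs within a 100 um radius.

Virtual double-labeling measurements mirror the experimental protocol:
Time 2 is the end of the run, Time 1 is ``delta_t`` earlier, and each
cycle's S-phase window is drawn post hoc from the lag-exponential S-phase
distribution, placed at the end of the cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .division import CellCycleParams, FITTED_KINETICS, lagexp_sample
from .geometry import build_hemisphere, distance_matrix
from .interaction import InteractionDataset, fit_interaction, strength_significance
from .spatial import LabeledPattern, analyze_pattern

__all__ = [
    "SimConfig",
    "PopulationTrajectory",
    "simulate_population",
    "virtual_measurement",
    "run_insilico_experiment",
    "CONTROL_CONFIG",
    "REDIVISION_CONFIG",
]

#: packing target: ~202 NSCs within a 100-um radius => ~155.5 um^2 per cell
_AREA_PER_CELL = np.pi * 100.0**2 / 202.0
_HEX_SPACING = float(np.sqrt(2.0 * _AREA_PER_CELL / np.sqrt(3.0)))  # ~13.4 um


@dataclass
class SimConfig:
    """Parameters of the agent-based sheet simulation.

    ``p_div`` is the spontaneous cycle-entry rate per hour (1e-3 for the
    control variant, 9e-4 when redivisions add extra divisions), ``p_rediv``
    the redivision probability (0.38 fitted / 0 control),
    ``differentiation_fraction`` the chance that a division yields one
    gfap-negative daughter (~10% observed).  ``n_target_mean/sd`` give the
    stopping colony size (observed 2,356 +/- 460 cells).
    """

    p_div: float = 9e-4
    p_rediv: float = 0.38
    differentiation_fraction: float = 0.10
    n_init: int = 500
    n_target_mean: float = 2356.0
    n_target_sd: float = 460.0
    n_target_min: float = 1000.0
    timestep: float = 0.5
    cell_radius_min: float = 3.5
    cell_radius_max: float = 5.0
    growth_time: float = 24.0
    spacing_factor: float = _HEX_SPACING / 10.0  # rest length / sum of adult radii
    relax_every: int = 2
    max_steps: int = 40000

    def __post_init__(self) -> None:
        if self.p_div < 0 or self.p_rediv < 0:
            raise ValueError("rates must be >= 0")
        if self.n_init >= self.n_target_mean:
            raise ValueError("n_init must be below the target colony size")
        if self.timestep <= 0:
            raise ValueError("timestep must be > 0")


CONTROL_CONFIG = SimConfig(p_div=1e-3, p_rediv=0.0)
REDIVISION_CONFIG = SimConfig(p_div=9e-4, p_rediv=0.38)


@dataclass
class PopulationTrajectory:
    """Final-state cell records plus the full division-event log.

    Record arrays are indexed by cell record id; a record persists through
    divisions (one daughter keeps it), so a record's position is the current
    position of that lineage branch.  ``events`` hold one row per completed
    or ongoing cell cycle: the record running the cycle, its start and
    (scheduled) division time, the event that created the cell, and whether
    the cycle was a redivision.
    """

    config: SimConfig
    kinetics: CellCycleParams
    t_final: float
    positions: np.ndarray
    alive: np.ndarray
    gfap_pos: np.ndarray
    birth: np.ndarray
    parent_record: np.ndarray
    # event (cycle) log
    ev_record: np.ndarray
    ev_start: np.ndarray
    ev_div: np.ndarray
    ev_parent_event: np.ndarray
    ev_is_rediv: np.ndarray
    ev_completed: np.ndarray
    n_completed_divisions: int = 0
    n_rediv_divisions: int = 0
    n_rediv_triggered: int = 0
    n_gfap_neg_daughters: int = 0

    @property
    def n_alive(self) -> int:
        return int(self.alive.sum())

    def redivision_fraction(self) -> float:
        """Fraction of completed divisions followed by an immediate daughter
        re-entry (the per-division redivision draw); estimates p_rediv."""
        if self.n_completed_divisions == 0:
            return float("nan")
        return self.n_rediv_triggered / self.n_completed_divisions

    def redivision_division_fraction(self) -> float:
        """Fraction of completed divisions that were themselves redivision
        cycles; lags :meth:`redivision_fraction` in a growing colony because
        a triggered re-entry only completes one cell cycle later."""
        done = self.ev_completed
        if not done.any():
            return float("nan")
        return float(self.ev_is_rediv[done].mean())


def _hex_colony(n: int, spacing: float, rng) -> np.ndarray:
    """Centred quasi-hexagonal colony of n cells with small positional jitter."""
    m = int(np.ceil(np.sqrt(n / 0.9))) + 4
    i, j = np.meshgrid(np.arange(-m, m + 1), np.arange(-m, m + 1))
    x = spacing * (i + 0.5 * (j % 2))
    y = spacing * (np.sqrt(3) / 2) * j
    pts = np.column_stack([x.ravel(), y.ravel()])
    order = np.argsort((pts**2).sum(axis=1))
    pts = pts[order[:n]]
    return pts + rng.normal(0, 0.08 * spacing, size=pts.shape)


class _Population:
    """Growable struct-of-arrays state for the simulation loop."""

    def __init__(self, n0: int, cap: int):
        self.pos = np.zeros((cap, 2))
        self.birth = np.zeros(cap)
        self.eligible = np.zeros(cap)
        self.alive = np.zeros(cap, dtype=bool)
        self.gfap = np.zeros(cap, dtype=bool)
        self.cycling = np.zeros(cap, dtype=bool)
        self.div_time = np.full(cap, np.inf)
        self.cycle_event = np.full(cap, -1, dtype=np.int64)
        self.creation_event = np.full(cap, -1, dtype=np.int64)
        self.removal_time = np.full(cap, np.inf)
        self.parent_record = np.full(cap, -1, dtype=np.int64)
        self.n = n0

    def grow(self) -> None:
        def ext(a, fill=0):
            extra = np.full((len(a),) + a.shape[1:], fill, dtype=a.dtype)
            return np.concatenate([a, extra])

        self.pos = ext(self.pos)
        self.birth = ext(self.birth)
        self.eligible = ext(self.eligible)
        self.alive = ext(self.alive, False)
        self.gfap = ext(self.gfap, False)
        self.cycling = ext(self.cycling, False)
        self.div_time = ext(self.div_time, np.inf)
        self.cycle_event = ext(self.cycle_event, -1)
        self.creation_event = ext(self.creation_event, -1)
        self.removal_time = ext(self.removal_time, np.inf)
        self.parent_record = ext(self.parent_record, -1)


def _radii(cfg: SimConfig, age: np.ndarray) -> np.ndarray:
    """Sigmoidal growth from newborn to adult radius over ``growth_time``."""
    x = np.clip(age / cfg.growth_time, 0.0, 1.0)
    s = x * x * (3.0 - 2.0 * x)  # smoothstep
    return cfg.cell_radius_min + (cfg.cell_radius_max - cfg.cell_radius_min) * s


def _relax(pop: _Population, cfg: SimConfig, t: float, iterations: int = 1) -> None:
    idx = np.nonzero(pop.alive[: pop.n])[0]
    if idx.size < 2:
        return
    for _ in range(iterations):
        p = pop.pos[idx]
        r = _radii(cfg, t - pop.birth[idx])
        rest_max = cfg.spacing_factor * 2.0 * r.max()
        tree = cKDTree(p)
        pairs = tree.query_pairs(rest_max, output_type="ndarray")
        if len(pairs) == 0:
            return
        a, b = pairs[:, 0], pairs[:, 1]
        delta = p[b] - p[a]
        dist = np.linalg.norm(delta, axis=1)
        rest = cfg.spacing_factor * (r[a] + r[b])
        over = dist < rest
        if not over.any():
            return
        a, b, delta, dist, rest = a[over], b[over], delta[over], dist[over], rest[over]
        dist = np.maximum(dist, 1e-6)
        push = 0.5 * (rest - dist) / dist
        disp = delta * push[:, None]
        np.subtract.at(pop.pos, idx[a], 0.5 * disp)
        np.add.at(pop.pos, idx[b], 0.5 * disp)


def simulate_population(
    config: SimConfig | None = None,
    kinetics: CellCycleParams = FITTED_KINETICS,
    seed=None,
) -> PopulationTrajectory:
    """Grow an NSC colony from ``n_init`` cells to its target size.

    Returns the final population state and the complete cycle/event log
    needed for virtual double-labeling measurements.
    """
    cfg = SimConfig() if config is None else config
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_target = int(
        max(cfg.n_target_min, rng.normal(cfg.n_target_mean, cfg.n_target_sd))
    )

    cap = max(2 * n_target, 4 * cfg.n_init)
    pop = _Population(cfg.n_init, cap)
    pop.pos[: cfg.n_init] = _hex_colony(cfg.n_init, _HEX_SPACING, rng)
    pop.alive[: cfg.n_init] = True
    pop.gfap[: cfg.n_init] = True
    pop.birth[: cfg.n_init] = 0.0
    pop.eligible[: cfg.n_init] = lagexp_sample(
        kinetics.beta_cc, kinetics.d_cc, cfg.n_init, rng
    )

    ev_record, ev_start, ev_div = [], [], []
    ev_parent_event, ev_is_rediv = [], []
    n_completed = 0
    n_rediv_done = 0
    n_rediv_trig = 0
    n_gfap_neg = 0

    def start_cycle(rec: int, t0: float, is_rediv: bool) -> None:
        nonlocal pop
        length = float(lagexp_sample(kinetics.beta_cc, kinetics.d_cc, 1, rng)[0])
        eid = len(ev_record)
        ev_record.append(rec)
        ev_start.append(t0)
        ev_div.append(t0 + length)
        ev_parent_event.append(int(pop.creation_event[rec]))
        ev_is_rediv.append(is_rediv)
        pop.cycling[rec] = True
        pop.div_time[rec] = t0 + length
        pop.cycle_event[rec] = eid

    t = 0.0
    step = 0
    while pop.alive[: pop.n].sum() < n_target:
        step += 1
        if step > cfg.max_steps:
            raise RuntimeError(
                f"colony did not reach {n_target} cells within {cfg.max_steps} steps "
                f"(currently {int(pop.alive[:pop.n].sum())} cells at t = {t:.0f} h)"
            )
        t += cfg.timestep

        # spontaneous cycle entries among eligible resting gfap+ cells
        sl = slice(0, pop.n)
        can = (
            pop.alive[sl]
            & pop.gfap[sl]
            & ~pop.cycling[sl]
            & (pop.eligible[sl] <= t)
        )
        ids = np.nonzero(can)[0]
        if ids.size:
            enter = ids[rng.random(ids.size) < cfg.p_div * cfg.timestep]
            for rec in enter:
                start_cycle(int(rec), t, is_rediv=False)

        # completed divisions
        dividing = np.nonzero(pop.cycling[sl] & (pop.div_time[sl] <= t))[0]
        for rec in dividing:
            rec = int(rec)
            eid = int(pop.cycle_event[rec])
            ev_div[eid] = float(pop.div_time[rec])
            n_completed += 1
            if ev_is_rediv[eid]:
                n_rediv_done += 1

            # daughter B: a fresh record placed next to the mother
            if pop.n >= len(pop.alive):
                pop.grow()
            nb = pop.n
            pop.n += 1
            ang = rng.uniform(0, 2 * np.pi)
            offset = 1.2 * cfg.cell_radius_min
            pop.pos[nb] = pop.pos[rec] + offset * np.array([np.cos(ang), np.sin(ang)])
            pop.alive[nb] = True
            pop.birth[nb] = t
            pop.parent_record[nb] = rec
            pop.creation_event[nb] = eid
            # daughters are immediately available for spontaneous entry; the
            # one-cycle wait is an initialization device for the founders
            # only (it removes the artificial synchrony of the seed colony)
            pop.eligible[nb] = t

            # daughter A: the mother's record continues, reborn
            pop.cycling[rec] = False
            pop.div_time[rec] = np.inf
            pop.cycle_event[rec] = -1
            pop.birth[rec] = t
            pop.creation_event[rec] = eid
            pop.eligible[rec] = t

            rediv = rng.random() < cfg.p_rediv
            if rediv:
                n_rediv_trig += 1
            differentiate = rng.random() < cfg.differentiation_fraction
            if differentiate:
                n_gfap_neg += 1
                if rediv:
                    # gfap- goes to daughter B, the redivision to daughter A
                    pop.gfap[nb] = False
                    pop.removal_time[nb] = t + float(
                        lagexp_sample(kinetics.beta_cc, kinetics.d_cc, 1, rng)[0]
                    )
                    start_cycle(rec, t, is_rediv=True)
                else:
                    pop.gfap[nb] = False
                    pop.removal_time[nb] = t + float(
                        lagexp_sample(kinetics.beta_cc, kinetics.d_cc, 1, rng)[0]
                    )
            else:
                pop.gfap[nb] = True
                if rediv:
                    start_cycle(nb, t, is_rediv=True)

        # gfap- removals after one further cycle duration (pop.n may have grown)
        gone = pop.alive[: pop.n] & (pop.removal_time[: pop.n] <= t)
        if gone.any():
            pop.alive[: pop.n][gone] = False

        if dividing.size or step % cfg.relax_every == 0:
            _relax(pop, cfg, t, iterations=2 if dividing.size else 1)

    _relax(pop, cfg, t, iterations=4)

    n = pop.n
    return PopulationTrajectory(
        config=cfg,
        kinetics=kinetics,
        t_final=t,
        positions=pop.pos[:n].copy(),
        alive=pop.alive[:n].copy(),
        gfap_pos=pop.gfap[:n].copy(),
        birth=pop.birth[:n].copy(),
        parent_record=pop.parent_record[:n].copy(),
        ev_record=np.array(ev_record, dtype=np.int64),
        ev_start=np.array(ev_start),
        ev_div=np.array(ev_div),
        ev_parent_event=np.array(ev_parent_event, dtype=np.int64),
        ev_is_rediv=np.array(ev_is_rediv, dtype=bool),
        ev_completed=np.array(ev_div) <= t,
        n_completed_divisions=n_completed,
        n_rediv_divisions=n_rediv_done,
        n_rediv_triggered=n_rediv_trig,
        n_gfap_neg_daughters=n_gfap_neg,
    )


def virtual_measurement(
    traj: PopulationTrajectory,
    delta_t: float,
    kinetics: CellCycleParams | None = None,
    seed=None,
) -> LabeledPattern:
    """Double-labeling snapshot measurement on a simulated colony.

    Time 2 is the end of the run, Time 1 is ``delta_t`` hours earlier.
    Each cycle's S-phase window is drawn post hoc (lag-exponential length,
    truncated at the cycle length, ending at division); a cycle whose
    window covers Time 1 (resp. Time 2) labels its record into s1 (resp.
    s2).  Double-labeled S-phases (one window covering both times) appear
    in both sets and are annotated in ``dls_indices``; downstream consumers
    that assign DLS to Time 1 only (the interaction fit) strip the overlap
    themselves.  Events are reported on the final positions of alive gfap+
    cells.
    """
    kin = traj.kinetics if kinetics is None else kinetics
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t2 = traj.t_final
    t1 = t2 - delta_t
    if t1 <= 0:
        raise ValueError("delta_t exceeds the simulated span")

    n_ev = len(traj.ev_record)
    cyc_len = traj.ev_div - traj.ev_start
    sp = lagexp_sample(kin.beta_sp, kin.d_sp, n_ev, rng)
    for _ in range(100):
        bad = sp > cyc_len
        if not bad.any():
            break
        sp[bad] = lagexp_sample(kin.beta_sp, kin.d_sp, int(bad.sum()), rng)
    sp = np.minimum(sp, cyc_len)
    s_start = traj.ev_div - sp
    s_end = traj.ev_div

    covers_t1 = (s_start <= t1) & (t1 <= s_end)
    covers_t2 = (s_start <= t2) & (t2 <= s_end)
    dls_ev = covers_t1 & covers_t2

    # NSC grid: alive gfap+ records at their final positions
    nsc_records = np.nonzero(traj.alive & traj.gfap_pos)[0]
    rec_to_idx = {int(r): i for i, r in enumerate(nsc_records)}

    def records_of(mask: np.ndarray) -> np.ndarray:
        recs = np.unique(traj.ev_record[mask])
        return np.array(
            [rec_to_idx[int(r)] for r in recs if int(r) in rec_to_idx], dtype=int
        )

    s1 = records_of(covers_t1)
    # DLS cells carry both labels: they stay in s2 for the Ripley statistic
    # (the spatiotemporal K counts j = i pairs); the interaction fit assigns
    # them to Time 1 only by stripping the s1/s2 overlap itself.
    s2 = records_of(covers_t2)
    dls = records_of(dls_ev)

    hemi = build_hemisphere(traj.positions[nsc_records], hemisphere_id="simulated")
    return LabeledPattern(
        hemisphere=hemi,
        s1_indices=s1,
        s2_indices=s2,
        delta_t=float(delta_t),
        dls_indices=np.intersect1d(dls, s1),
        ground_truth={
            "p_rediv": traj.config.p_rediv,
            "p_div": traj.config.p_div,
            "variant": "redivision" if traj.config.p_rediv > 0 else "control",
        },
    )


def measurement_readout(
    traj: PopulationTrajectory,
    delta_t: float,
    kinetics: CellCycleParams | None = None,
    seed=None,
):
    """Nonspatial double-labeling counts from an agent simulation.

    Mirrors :func:`nscpatterns.division.virtual_double_label` on the agent
    event log (S-phase windows drawn post hoc): counts Time-1-labeled
    cycles, DLS, and Time-1 cycles with a descendant cycle in S-phase at
    Time 2; used for cross-checking the spatial and nonspatial models at
    identical kinetics.
    """
    from .division import LabelingReadout

    kin = traj.kinetics if kinetics is None else kinetics
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t2 = traj.t_final
    t1 = t2 - delta_t
    cyc_len = traj.ev_div - traj.ev_start
    sp = lagexp_sample(kin.beta_sp, kin.d_sp, len(cyc_len), rng)
    sp = np.minimum(sp, cyc_len)
    s_start = traj.ev_div - sp
    covers_t1 = (s_start <= t1) & (t1 <= traj.ev_div)
    covers_t2 = (s_start <= t2) & (t2 <= traj.ev_div)
    dls = covers_t1 & covers_t2

    has_desc_in_s = np.zeros(len(cyc_len), dtype=bool)
    idx = traj.ev_parent_event[covers_t2]
    idx = idx[idx >= 0]
    while idx.size:
        has_desc_in_s[idx] = True
        idx = traj.ev_parent_event[idx]
        idx = idx[idx >= 0]
    rediv = covers_t1 & has_desc_in_s
    return LabelingReadout(
        delta_t=float(delta_t),
        n_labeled_t1=int(covers_t1.sum()),
        n_dls=int(dls.sum()),
        n_rediv=int(rediv.sum()),
    )


def run_insilico_experiment(
    n_hemispheres: int = 36,
    delta_ts=(9.0, 18.0, 24.0, 32.0, 48.0, 72.0),
    config: SimConfig | None = None,
    kinetics: CellCycleParams = FITTED_KINETICS,
    seed=None,
    n_envelope_samples: int = 20,
    fit_posterior_samples: int = 4000,
    fit_per_interval: bool = True,
) -> dict:
    """Full in-silico chain: simulate, measure, classify, fit interactions.

    Each simulated hemisphere is assigned one labeling interval (cycling
    through ``delta_ts``), measured, run through the discrete Ripley
    pipeline (20-sample envelopes, 30-150 um classification) and pooled
    into per-interval interaction-model fits.

    Returns a dict with the patterns, Ripley curves, per-hemisphere
    classifications, aggregated fraction, per-interval fits and the
    constant-model significance test on the fitted strengths.
    """
    cfg = SimConfig() if config is None else config
    rng = np.random.default_rng(seed)
    patterns, curves, classifications, intervals, dmats = [], [], [], [], []
    for i in range(n_hemispheres):
        dt = float(delta_ts[i % len(delta_ts)])
        traj = simulate_population(cfg, kinetics, seed=rng)
        pattern = virtual_measurement(traj, dt, kinetics, seed=rng)
        patterns.append(pattern)
        intervals.append(dt)
        if len(pattern.s1_indices) == 0 or len(pattern.s2_indices) == 0:
            curves.append(None)
            classifications.append("empty")
            dmats.append(None)
            continue
        d = distance_matrix(pattern.hemisphere)
        dmats.append(d)
        curve = analyze_pattern(
            pattern,
            d,
            mode="spatiotemporal",
            n_samples=n_envelope_samples,
            seed=rng.integers(2**31),
        )
        curves.append(curve)
        classifications.append(curve.classification)

    result = {
        "patterns": patterns,
        "curves": curves,
        "classifications": classifications,
        "delta_ts": intervals,
        "aggregated_fraction": float(
            np.mean([c == "aggregated" for c in classifications if c != "empty"])
        ),
    }

    if fit_per_interval:
        fits = {}
        for dt in sorted(set(intervals)):
            datasets = []
            for pat, dti, d in zip(patterns, intervals, dmats):
                if dti != dt or d is None or len(pat.s2_indices) == 0:
                    continue
                datasets.append(
                    InteractionDataset.from_pattern(
                        pat.hemisphere, pat.s1_indices, pat.s2_indices, d
                    )
                )
            if datasets:
                fits[dt] = fit_interaction(
                    datasets, n_samples=fit_posterior_samples, seed=rng.integers(2**31)
                )
        result["fits"] = fits
        strengths = [f.ml_params.g for f in fits.values()]
        result["strengths"] = strengths
        if len(strengths) >= 2:
            result["strength_test"] = strength_significance(strengths)
    return result
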