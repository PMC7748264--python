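"""Readers, writers and the end-to-end analysis pipeline.

The coordinate-table schema is one row per NSC:

    hemisphere_id,cell_id,x_um,y_um,z_um,gfap,label_t1,label_t2,doublet_id

with ``gfap`` in {pos, neg}, label columns in {0, 1} and ``doublet_id``
empty or a shared integer per sibling group.  Cells labeled at both times
are double-labeled S-phases (DLS) and are assigned to Time 1 only.

The per-hemisphere count summary table (one row per hemisphere: NSC count,
S-phases and NSC S-phases at both label times, redivisions and DLS counts)
ships as a packaged fixture; the raw experimental coordinates were never
deposited, so the packaged table is a synthetic stand-in generated from
reported summary statistics (see ``data/s1_table_synthetic.csv``
and ``scripts/make_s1_table.py``).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import Hemisphere, build_hemisphere, distance_matrix
from .spatial import LabeledPattern

__all__ = [
    "read_pattern_csv",
    "write_pattern_csv",
    "read_s1_counts",
    "observed_fraction_table",
    "redraw_null",
    "RunConfig",
    "run_pipeline",
]

PATTERN_COLUMNS = [
    "hemisphere_id",
    "cell_id",
    "x_um",
    "y_um",
    "z_um",
    "gfap",
    "label_t1",
    "label_t2",
    "doublet_id",
]


def read_pattern_csv(path, delta_t: float | None = None):
    """Read a coordinate table into a (Hemisphere, LabeledPattern) pair.

    DLS membership is inferred from label_t1 = label_t2 = 1; Time-2 events
    that are DLS keep only their Time-1 assignment.
    """
    df = pd.read_csv(path, dtype={"doublet_id": "string"})
    missing = [c for c in PATTERN_COLUMNS if c not in df.columns and c != "doublet_id"]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    dup = df["cell_id"][df["cell_id"].duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicated cell_id values {sorted(set(dup))[:5]}")
    for col in ("x_um", "y_um", "z_um"):
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()].tolist()
            raise ValueError(f"{path}: non-numeric {col} in rows {bad[:5]}")
    bad_gfap = ~df["gfap"].isin(["pos", "neg"])
    if bad_gfap.any():
        rows = df.index[bad_gfap].tolist()
        raise ValueError(f"{path}: unknown gfap value in rows {rows[:5]}")

    coords = df[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
    hemi = build_hemisphere(coords, hemisphere_id=str(df["hemisphere_id"].iloc[0]))
    t1 = df["label_t1"].to_numpy(dtype=int)
    t2 = df["label_t2"].to_numpy(dtype=int)
    dls = np.nonzero((t1 == 1) & (t2 == 1))[0]
    s1 = np.nonzero(t1 == 1)[0]
    s2 = np.nonzero((t2 == 1) & (t1 == 0))[0]
    groups = None
    if "doublet_id" in df.columns:
        with_group = df["doublet_id"].notna() & (df["doublet_id"].astype(str) != "")
        if with_group.any():
            groups = {
                str(k): v.tolist()
                for k, v in df.index[with_group]
                .to_series()
                .groupby(df.loc[with_group, "doublet_id"])
                .groups.items()
            }
    pattern = LabeledPattern(
        hemisphere=hemi,
        s1_indices=s1,
        s2_indices=s2,
        delta_t=delta_t,
        dls_indices=dls,
        doublet_groups=groups,
    )
    return hemi, pattern


def write_pattern_csv(path, pattern: LabeledPattern, gfap=None) -> None:
    """Write a LabeledPattern back to the coordinate-table schema."""
    h = pattern.hemisphere
    n = h.n_cells
    t1 = np.zeros(n, dtype=int)
    t1[pattern.s1_indices] = 1
    t2 = np.zeros(n, dtype=int)
    t2[pattern.s2_indices] = 1
    t2[pattern.dls_indices] = 1
    doublet = [""] * n
    if pattern.doublet_groups:
        for gid, members in pattern.doublet_groups.items():
            for m in members:
                doublet[m] = str(gid)
    df = pd.DataFrame(
        {
            "hemisphere_id": h.hemisphere_id,
            "cell_id": np.arange(n),
            "x_um": h.coords[:, 0],
            "y_um": h.coords[:, 1],
            "z_um": h.coords[:, 2],
            "gfap": gfap if gfap is not None else ["pos"] * n,
            "label_t1": t1,
            "label_t2": t2,
            "doublet_id": doublet,
        }
    )
    df.to_csv(path, index=False)


S1_COLUMNS = [
    "hemisphere",
    "delta_t",
    "n_nsc",
    "s_t1",
    "s_t2",
    "nsc_s_t1",
    "nsc_s_t2",
    "redivisions",
    "nsc_redivisions",
    "dls",
    "nsc_dls",
]


def _default_s1_path():
    return resources.files("nscpatterns").joinpath("data/s1_table_synthetic.csv")


def read_s1_counts(path=None) -> pd.DataFrame:
    """Per-hemisphere count summaries with derived fractions.

    Adds ``rediv_fraction`` (NSC redivisions / NSC S-phases at T1) and
    ``dls_fraction`` (NSC DLS / NSC S-phases at T1); hemispheres with zero
    NSC S-phases at T1 get NaN fractions and drop out of means.
    """
    src = _default_s1_path() if path is None else path
    with resources.as_file(src) if path is None else _noop(src) as p:
        df = pd.read_csv(p)
    missing = [c for c in S1_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"count table missing columns {missing}")
    denom = df["nsc_s_t1"].astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        df["rediv_fraction"] = np.where(denom > 0, df["nsc_redivisions"] / denom, np.nan)
        df["dls_fraction"] = np.where(denom > 0, df["nsc_dls"] / denom, np.nan)
    return df


class _noop:
    def __init__(self, value):
        self.value = value

    def __enter__(self):
        return self.value

    def __exit__(self, *exc):
        return False


def observed_fraction_table(df: pd.DataFrame) -> dict:
    """Reshape a count summary into the ABC observed-fraction structure."""
    out = {}
    for dt, grp in df.groupby("delta_t"):
        out[float(dt)] = {
            "rediv": grp["rediv_fraction"].dropna().tolist(),
            "dls": grp["dls_fraction"].dropna().tolist(),
        }
    return out


def redraw_null(df: pd.DataFrame, n_draws: int = 200, seed=None) -> dict:
    """Random-redraw null for the redivision frequency.

    For each hemisphere, the observed numbers of Time-1 and Time-2 NSC
    divisions are redrawn uniformly from all NSCs and the fraction of
    Time-1 draws that reappear at Time 2 is recorded (the overlap of two
    uniform draws is hypergeometric).  Returns the mean and SD over
    hemispheres of the per-hemisphere mean redraw fraction — the chance
    level against which the observed ~14% redivision frequency is judged.
    """
    rng = np.random.default_rng(seed)
    per_hemisphere = []
    for _, row in df.iterrows():
        n = int(row["n_nsc"])
        n1 = int(row["nsc_s_t1"])
        n2 = int(row["nsc_s_t2"])
        if n1 == 0 or n == 0:
            continue
        overlap = rng.hypergeometric(n1, n - n1, n2, size=n_draws)
        per_hemisphere.append(float((overlap / n1).mean()))
    arr = np.asarray(per_hemisphere)
    return {
        "mean": float(arr.mean()),
        "sd": float(arr.std(ddof=0)),
        "per_hemisphere": per_hemisphere,
    }


@dataclass
class RunConfig:
    """Configuration of an end-to-end pipeline run."""

    stages: tuple = ("synth", "ripley")
    seed: int = 0
    out_dir: str | None = None
    input_paths: tuple = ()
    # stage parameters
    synth: dict = field(default_factory=dict)
    ripley: dict = field(default_factory=dict)
    interaction: dict = field(default_factory=dict)
    division: dict = field(default_factory=dict)
    abc: dict = field(default_factory=dict)
    agents: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the selected stages in dependency order.

    Stage names: ``synth`` (generate hemisphere + pattern), ``ripley``
    (K curves, envelopes, classification), ``fit-interaction``,
    ``simulate-division`` (nonspatial cohort fractions), ``fit-abc``,
    ``simulate-agents`` (in-silico experiment).  Results are returned as a
    dict and, when ``out_dir`` is set, written as CSV/JSON together with a
    reproducibility manifest (config hash, seed, package version).
    """
    from . import __version__
    from . import synthetic
    from .division import FITTED_KINETICS, abc_fit
    from .interaction import fit_interaction
    from .spatial import analyze_pattern

    master = np.random.default_rng(config.seed)
    stage_seeds = {
        s: int(master.integers(2**31))
        for s in ("synth", "ripley", "fit-interaction", "simulate-division", "fit-abc", "simulate-agents")
    }
    results: dict = {"manifest": {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stage_seeds": stage_seeds,
        "version": __version__,
    }}

    patterns = []
    dmats = []
    for stage in config.stages:
        if stage == "synth":
            kw = dict(config.synth)
            pat_kw = {
                k: kw.pop(k) for k in ("n1", "n2", "g", "r") if k in kw
            }
            h = synthetic.generate_hemisphere(seed=stage_seeds["synth"], **kw)
            d = distance_matrix(h)
            pat = synthetic.generate_pattern(
                h, d, seed=stage_seeds["synth"] + 1, **pat_kw
            )
            patterns.append(pat)
            dmats.append(d)
            results["synth"] = {"n_cells": h.n_cells, "area": h.area,
                                "ground_truth": pat.ground_truth}
        elif stage == "load":
            for path in config.input_paths:
                h, pat = read_pattern_csv(path)
                patterns.append(pat)
                dmats.append(distance_matrix(h))
        elif stage == "ripley":
            if not patterns:
                raise RuntimeError("ripley stage requires a synth or load stage first")
            curves = [
                analyze_pattern(p, d, seed=stage_seeds["ripley"], **config.ripley)
                for p, d in zip(patterns, dmats)
            ]
            results["ripley"] = {
                "classifications": [c.classification for c in curves],
                "curves": curves,
            }
        elif stage == "fit-interaction":
            if not patterns:
                raise RuntimeError("fit-interaction requires patterns")
            fit = fit_interaction(
                [
                    (p.hemisphere, p.s1_indices, p.s2_indices, d)
                    for p, d in zip(patterns, dmats)
                ],
                seed=stage_seeds["fit-interaction"],
                **config.interaction,
            )
            results["fit-interaction"] = fit
        elif stage == "simulate-division":
            kin = config.division.get("kinetics", FITTED_KINETICS)
            table = synthetic.generate_observed_fractions(
                kin,
                hemispheres_per_interval=config.division.get("hemispheres_per_interval", 6),
                n_cells=config.division.get("n_cells", 10000),
                seed=stage_seeds["simulate-division"],
            )
            results["simulate-division"] = table
        elif stage == "fit-abc":
            observed = results.get("simulate-division")
            if observed is None:
                observed = observed_fraction_table(read_s1_counts())
            results["fit-abc"] = abc_fit(
                observed, seed=stage_seeds["fit-abc"], **config.abc
            )
        elif stage == "simulate-agents":
            from .agents import run_insilico_experiment

            results["simulate-agents"] = run_insilico_experiment(
                seed=stage_seeds["simulate-agents"], **config.agents
            )
        else:
            raise ValueError(f"unknown pipeline stage {stage!r}")

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "manifest.json", "w") as fh:
            json.dump(results["manifest"], fh, indent=2)
        if "ripley" in results:
            rows = []
            for i, c in enumerate(results["ripley"]["curves"]):
                for r, k, q05, q95, z in zip(
                    c.radii, c.k_values, c.envelope_q05, c.envelope_q95, c.z_scores
                ):
                    rows.append(
                        {"pattern": i, "radius": r, "k": k, "q05": q05, "q95": q95, "z": z}
                    )
            pd.DataFrame(rows).to_csv(out / "ripley.csv", index=False)
            with open(out / "classifications.json", "w") as fh:
                json.dump(results["ripley"]["classifications"], fh)
    return results
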