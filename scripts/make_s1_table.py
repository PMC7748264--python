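"""Regenerate the synthetic per-hemisphere count-summary fixture.

The raw experimental table (one row per hemisphere: NSC counts, S-phases
at both label times, redivision and DLS counts) was never deposited, so
the packaged fixture ``src/nscpatterns/data/s1_table_synthetic.csv`` is a
synthetic stand-in generated here.  It honours the reported population
constraints — 36 hemispheres, 6 per labeling interval (9, 18, 24, 32, 48,
72 h), a grand total of exactly 87,807 NSCs, and a ~1.9% snapshot S-phase
fraction — while the per-interval redivision and DLS counts are drawn from
the package's cell-division model at the reference fitted kinetics
(minimal cycle 22.2 h, mean cycle 107.5 h, minimal S-phase 16.6 h, mean
S-phase 18.2 h, redivision probability 0.38).

Run from the repository root:

    python scripts/make_s1_table.py [--seed 20]
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from nscpatterns.division import FITTED_KINETICS, LABELING_INTERVALS, cohort_fractions

TOTAL_NSCS = 87_807
N_PER_INTERVAL = 6
S_PHASE_FRACTION = 0.019
PROGENITOR_FACTOR = (1.5, 2.2)  # non-NSC S-phases relative to NSC S-phases


def main(seed: int, out: Path) -> None:
    rng = np.random.default_rng(seed)
    n_hemi = N_PER_INTERVAL * len(LABELING_INTERVALS)

    # hemisphere sizes: normal around the observed colony size, adjusted to
    # sum exactly to the reported total NSC count
    sizes = rng.normal(TOTAL_NSCS / n_hemi, 460.0, size=n_hemi)
    sizes = np.maximum(sizes, 1200.0)
    sizes = np.round(sizes * TOTAL_NSCS / sizes.sum()).astype(int)
    sizes[-1] += TOTAL_NSCS - sizes.sum()

    rows = []
    i = 0
    for dt in LABELING_INTERVALS:
        for rep in range(N_PER_INTERVAL):
            n = int(sizes[i])
            nsc_s1 = rng.binomial(n, S_PHASE_FRACTION)
            nsc_s2 = rng.binomial(n, S_PHASE_FRACTION)
            # per-hemisphere model fractions (each hemisphere is its own cohort)
            fr = cohort_fractions(FITTED_KINETICS, intervals=(dt,), n_cells=20000, seed=rng)
            f_re, f_dls = fr[float(dt)]["rediv"], fr[float(dt)]["dls"]
            nsc_re = rng.binomial(nsc_s1, min(max(f_re, 0.0), 1.0))
            nsc_dls = rng.binomial(nsc_s1, min(max(f_dls, 0.0), 1.0))
            prog = rng.uniform(*PROGENITOR_FACTOR)
            s1 = int(round(nsc_s1 * prog))
            s2 = int(round(nsc_s2 * prog))
            re_all = nsc_re + rng.binomial(max(s1 - nsc_s1, 0), min(max(f_re, 0.0), 1.0))
            dls_all = nsc_dls + rng.binomial(max(s1 - nsc_s1, 0), min(max(f_dls, 0.0), 1.0))
            rows.append(
                dict(
                    hemisphere=f"h{i + 1:02d}",
                    delta_t=float(dt),
                    n_nsc=n,
                    s_t1=s1,
                    s_t2=s2,
                    nsc_s_t1=nsc_s1,
                    nsc_s_t2=nsc_s2,
                    redivisions=int(re_all),
                    nsc_redivisions=int(nsc_re),
                    dls=int(dls_all),
                    nsc_dls=int(nsc_dls),
                )
            )
            i += 1

    df = pd.DataFrame(rows)
    assert df["n_nsc"].sum() == TOTAL_NSCS
    out.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(out, index=False)
    print(f"wrote {out} ({len(df)} hemispheres, {df['n_nsc'].sum()} NSCs)")


if __name__ == "__main__":
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=20)
    ap.add_argument(
        "--out",
        type=Path,
        default=Path(__file__).resolve().parents[1]
        / "src/nscpatterns/data/s1_table_synthetic.csv",
    )
    args = ap.parse_args()
    main(args.seed, args.out)
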