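#!/usr/bin/env python
"""Which variables drive the cluster separation?  Contribution statistics
on a synthetic dataset with known structure.

Reuses the seed-11 dataset of 02_synthetic_pipeline and reports, per theme
and variable: the robust (MM-regression) R^2 of the one-way cluster-means
model, the Kruskal-Wallis H and p, and the Shapiro-Wilk normality flag,
sorted by robust R^2 within theme.  A Benjamini-Hochberg adjusted-p column
is included.

Finding: with a common planted separation of 6 SDs every variable is a
strong separator (robust R^2 ~ 0.9-0.97, p << 1e-10), and normality is
rejected for most columns — the planted three-tier mixture is trimodal,
which is precisely why the pipeline pairs rank-based tests with robust
regression instead of ANOVA.

Writes results/contributions_synthetic.csv.
"""

from pathlib import Path

import pandas as pd

from themeclust.inference import contribution_table
from themeclust.pipeline import run_full
from themeclust.synthetic import SyntheticConfig, generate

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 11


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    ds = generate(SyntheticConfig(n_countries=200, tier_separation=6.0,
                                  discordance=0.1, seed=SEED))
    bundle = run_full(ds.table, ds.directions, k=3, seed=SEED, restarts=50)
    rows = contribution_table(ds.table, bundle["assignments"], bh=True)
    df = pd.DataFrame([r.__dict__ for r in rows])
    df.to_csv(RESULTS / "contributions_synthetic.csv", index=False, float_format="%.4g")
    with pd.option_context("display.width", 120):
        print(df.groupby("theme").head(3).to_string(index=False))
    frac_nonnormal = 1 - df.normal_flag.mean()
    print(f"\nfraction of variables failing the normality gate: {frac_nonnormal:.2f}")
    print(f"wrote {RESULTS/'contributions_synthetic.csv'}")


if __name__ == "__main__":
    main()
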