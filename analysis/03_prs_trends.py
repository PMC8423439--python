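#!/usr/bin/env python
"""Polygenic scores and their temporal trends for both cohorts.

For each cohort: harmonize summary statistics to the panel, select QTLs at
p < 1e-5, clump in 250-kb windows, score every sample with mean-dosage
imputation, min-max scale, then fit the pre/post-Neolithic piecewise trends,
the LOESS curve, and the adjacent-period t-tests. Writes
results/trends.tsv, results/group_tests.tsv, results/loess_<cohort>.tsv and
per-sample scores under scratch/.
"""

import sys, os
sys.path.insert(0, os.path.dirname(__file__))
from common import RESULTS, cohort_dir, ensure_dirs

import pandas as pd

from paleoprs import panels, prs, sumstats as ss, trends

P_THRESHOLD = 1e-5
WINDOW_KB = 250.0


def load(name):
    d = cohort_dir(name)
    ancient = panels.read_eigenstrat(os.path.join(d, "ancient"))
    modern = panels.read_eigenstrat(os.path.join(d, "modern"))
    meta = panels.assign_periods(panels.read_sample_meta(os.path.join(d, "samples.tsv")))
    panel = panels.intersect_variants(ancient, modern)
    panel = panels.assign_ploidy(panel, meta, {"EUP", "LUP", "Mesolithic",
                                               "Neolithic", "PostNeolithic"})
    table = ss.read_sumstats(os.path.join(d, "sumstats_trait.tsv"))
    return panel, meta, table


def main() -> None:
    ensure_dirs()
    trend_rows, group_rows = [], []
    for name in ("selected", "neutral"):
        panel, meta, table = load(name)
        table = ss.align_effect_alleles(ss.drop_ambiguous(ss.filter_biallelic(table)), panel)
        leads = prs.clump_window(ss.select_by_pvalue(table, P_THRESHOLD), WINDOW_KB)
        scored = prs.scale_scores(prs.score_samples(panel, leads))
        scored.to_csv(os.path.join(cohort_dir(name), "scores.tsv"), sep="\t", index=False)

        scaled = scored["scaled_score"].to_numpy()
        ages = meta["age_bp"].to_numpy(float)
        periods = meta["period"].to_numpy()
        fit = trends.piecewise_fit(scaled, ages, periods)
        print(f"[{name}] {len(leads)} lead QTLs at p < {P_THRESHOLD:g}")
        for side, res in fit.items():
            print(f"    {side:<4} n={res.n:<4} r={res.r:+.3f} "
                  f"signed -log10 p = {res.signed_neglog10_p:+.2f}")
            trend_rows.append({"cohort": name, "side": side, "n": res.n, "r": res.r,
                               "p": res.p, "signed_neglog10_p": res.signed_neglog10_p,
                               "slope": res.slope, "intercept": res.intercept})
        grid, fitted = trends.loess_curve(scaled, ages)
        pd.DataFrame({"age_bp": grid, "loess_fit": fitted}).to_csv(
            os.path.join(RESULTS, f"loess_{name}.tsv"), sep="\t", index=False,
            float_format="%.6g")
        comps, anova = trends.adjacent_period_tests(scaled, periods)
        for c in comps:
            group_rows.append({"cohort": name, "period_a": c.period_a,
                               "period_b": c.period_b, "t": c.t, "p": c.p,
                               "mean_a": c.mean_a, "mean_b": c.mean_b,
                               "anova_F": anova[0], "anova_p": anova[1]})
    pd.DataFrame(trend_rows).to_csv(os.path.join(RESULTS, "trends.tsv"),
                                    sep="\t", index=False, float_format="%.6g")
    pd.DataFrame(group_rows).to_csv(os.path.join(RESULTS, "group_tests.tsv"),
                                    sep="\t", index=False, float_format="%.6g")


if __name__ == "__main__":
    main()
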