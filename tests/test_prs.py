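"""PRS engine: clumping vs exhaustive references, scoring vs a dense oracle,
mean-dosage imputation, scaling, and the robustness grid."""

import numpy as np
import pandas as pd
import pytest

from paleoprs.prs import (
    clump_ld,
    clump_window,
    mean_dosage,
    scale_scores,
    score_samples,
    threshold_grid,
)

from .conftest import make_panel

# ---------------------------------------------------------------------------
# independent reference implementations (kept deliberately naive)
# ---------------------------------------------------------------------------

def brute_force_window_clump(table: pd.DataFrame, window_kb: float) -> list[str]:
    remaining = table.sort_values(["pvalue", "chrom", "pos"]).to_dict("records")
    leads = []
    while remaining:
        lead = remaining.pop(0)
        leads.append(lead["variant_id"])
        remaining = [r for r in remaining
                     if r["chrom"] != lead["chrom"]
                     or abs(r["pos"] - lead["pos"]) > window_kb * 1000]
    return leads


def pairwise_r2_pandas(panel, i: int, j: int) -> float:
    dip = np.asarray(panel.ploidy) == "diploid"
    frame = pd.DataFrame({"a": panel.dosage[dip, i], "b": panel.dosage[dip, j]})
    r = frame["a"].corr(frame["b"], min_periods=2)
    return np.nan if pd.isna(r) else r * r


def brute_force_ld_clump(table, panel, window_kb, r2_max) -> list[str]:
    remaining = table.sort_values(["pvalue", "chrom", "pos"]).to_dict("records")
    leads = []
    while remaining:
        lead = remaining.pop(0)
        leads.append(lead["variant_id"])
        kept = []
        for r in remaining:
            in_window = (r["chrom"] == lead["chrom"]
                         and abs(r["pos"] - lead["pos"]) <= window_kb * 1000)
            if in_window:
                r2 = pairwise_r2_pandas(panel, int(lead["panel_index"]), int(r["panel_index"]))
                if not np.isnan(r2) and r2 > r2_max:
                    continue
            kept.append(r)
        remaining = kept
    return leads


def dense_score_oracle(panel, idx, beta) -> np.ndarray:
    means = [np.nanmean(panel.dosage[:, j]) for j in idx]
    out = np.zeros(panel.n_samples)
    for i in range(panel.n_samples):
        for k, j in enumerate(idx):
            x = panel.dosage[i, j]
            out[i] += (means[k] if np.isnan(x) else x) * beta[k]
    return out


def random_instance(rng, n_var=40, n_chrom=3, span=2_000_000):
    chrom = rng.integers(1, n_chrom + 1, n_var).astype(str)
    pos = rng.choice(span, size=n_var, replace=False) + 1
    return pd.DataFrame({
        "variant_id": [f"v{i}" for i in range(n_var)],
        "chrom": chrom, "pos": pos,
        "effect_allele": "A", "other_allele": "G",
        "beta": rng.normal(size=n_var),
        "pvalue": rng.uniform(1e-12, 1, n_var),
        "panel_index": np.arange(n_var),
    })


# ---------------------------------------------------------------------------

class TestClumpWindow:
    def test_single_variant_is_its_own_lead(self):
        t = random_instance(np.random.default_rng(0), n_var=1)
        assert len(clump_window(t, 250)) == 1

    def test_three_variant_hand_example(self):
        t = pd.DataFrame({
            "variant_id": ["a", "b", "c"], "chrom": ["1"] * 3,
            "pos": [100_000, 200_000, 600_000],
            "effect_allele": "A", "other_allele": "G",
            "beta": 0.1, "pvalue": [1e-8, 1e-7, 1e-6],
        })
        leads = clump_window(t, 250).leads
        assert leads["variant_id"].tolist() == ["a", "c"]

    def test_same_position_different_chromosomes_both_kept(self):
        t = pd.DataFrame({
            "variant_id": ["a", "b"], "chrom": ["1", "2"], "pos": [100, 100],
            "effect_allele": "A", "other_allele": "G", "beta": 0.1,
            "pvalue": [1e-8, 1e-7],
        })
        assert len(clump_window(t, 250)) == 2

    def test_row_order_invariance(self, rng):
        t = random_instance(rng)
        shuffled = t.sample(frac=1, random_state=7).reset_index(drop=True)
        a = clump_window(t, 100).leads["variant_id"].tolist()
        b = clump_window(shuffled, 100).leads["variant_id"].tolist()
        assert a == b

    def test_leads_respect_pairwise_distance(self, rng):
        t = random_instance(rng, n_var=60)
        leads = clump_window(t, 150).leads
        for c, grp in leads.groupby("chrom"):
            p = np.sort(grp["pos"].to_numpy())
            assert (np.diff(p) > 150_000).all()


class TestClumpLd:
    def _ld_panel(self, rng, n_var):
        # block-correlated diploid dosages: pairs of adjacent variants share
        # an underlying haplotype with high probability
        n = 40
        base = rng.binomial(2, 0.5, size=(n, n_var)).astype(float)
        for j in range(1, n_var, 2):
            copy = rng.random(n) < 0.9
            base[copy, j] = base[copy, j - 1]
        base[rng.random(base.shape) < 0.05] = np.nan
        return make_panel(base, ploidy=["diploid"] * n,
                          chrom=[str(1 + j // 10) for j in range(n_var)],
                          pos=[(j % 10) * 50_000 + 1 for j in range(n_var)])

    def test_perfectly_correlated_pair_drops_weaker(self):
        d = np.array([[0., 0.], [1., 1.], [2., 2.], [1., 1.], [0., 0.], [2., 2.]])
        panel = make_panel(d, ploidy=["diploid"] * 6, pos=[1000, 2000])
        t = pd.DataFrame({"variant_id": ["a", "b"], "chrom": ["1"] * 2,
                          "pos": [1000, 2000], "effect_allele": "A",
                          "other_allele": "G", "beta": 0.1,
                          "pvalue": [1e-8, 1e-7], "panel_index": [0, 1]})
        assert clump_ld(t, panel, 250, 0.2).leads["variant_id"].tolist() == ["a"]

    def test_independent_in_window_pair_kept(self, rng):
        d = np.column_stack([rng.binomial(2, 0.5, 60), rng.binomial(2, 0.5, 60)]).astype(float)
        panel = make_panel(d, ploidy=["diploid"] * 60, pos=[1000, 2000])
        t = pd.DataFrame({"variant_id": ["a", "b"], "chrom": ["1"] * 2,
                          "pos": [1000, 2000], "effect_allele": "A",
                          "other_allele": "G", "beta": 0.1,
                          "pvalue": [1e-8, 1e-7], "panel_index": [0, 1]})
        assert len(clump_ld(t, panel, 250, 0.2)) == 2

    def test_matches_exhaustive_reference(self, rng):
        for _ in range(10):
            n_var = 30
            panel = self._ld_panel(rng, n_var)
            t = pd.DataFrame({
                "variant_id": [f"v{i}" for i in range(n_var)],
                "chrom": panel.variants["chrom"], "pos": panel.variants["pos"],
                "effect_allele": "A", "other_allele": "G",
                "beta": 0.1, "pvalue": rng.uniform(size=n_var),
                "panel_index": np.arange(n_var),
            })
            got = clump_ld(t, panel, 200, 0.2).leads["variant_id"].tolist()
            want = brute_force_ld_clump(t, panel, 200, 0.2)
            assert got == want


class TestMeanDosage:
    def test_cases(self):
        panel = make_panel(np.array([[0.0, 2.0, 1.0],
                                     [2.0, 2.0, 0.0],
                                     [np.nan, 2.0, 2.0]]))
        means = mean_dosage(panel)
        assert means[0] == pytest.approx(1.0)   # {0, 2, missing}
        assert means[1] == pytest.approx(2.0)   # all 2
        assert means[2] == pytest.approx(1.0)   # mixed ploidy {1, 0, 2}

    def test_all_missing_variant_is_nan(self):
        panel = make_panel(np.array([[np.nan], [np.nan]]))
        assert np.isnan(mean_dosage(panel))[0]


class TestScoreSamples:
    def _leads(self, beta, m):
        return pd.DataFrame({
            "variant_id": [f"v{j}" for j in range(m)], "chrom": ["1"] * m,
            "pos": (np.arange(m) + 1) * 1000, "effect_allele": "A",
            "other_allele": "G", "beta": beta,
            "pvalue": np.full(m, 1e-8), "panel_index": np.arange(m),
        })

    def test_hand_example(self):
        panel = make_panel(np.array([[2.0, 0.0], [0.0, 1.0]]))
        scored = score_samples(panel, self._leads([0.5, -1.0], 2))
        assert np.allclose(scored["raw_score"], [1.0, -1.0])

    def test_zero_betas_give_zero_scores(self):
        panel = make_panel(np.array([[2.0, 0.0], [0.0, 1.0]]))
        assert np.allclose(score_samples(panel, self._leads([0.0, 0.0], 2))["raw_score"], 0)

    def test_fully_missing_sample_gets_population_average_score(self):
        dosage = np.array([[2.0, 0.0], [0.0, 2.0], [np.nan, np.nan]])
        panel = make_panel(dosage)
        beta = [0.5, -1.0]
        scored = score_samples(panel, self._leads(beta, 2))
        expected = 1.0 * 0.5 + 1.0 * -1.0  # mean dosages are 1.0 and 1.0
        assert scored["raw_score"][2] == pytest.approx(expected)
        assert scored["n_imputed"][2] == 2

    def test_adding_fully_missing_sample_leaves_others_invariant(self, rng):
        dosage = rng.choice([0.0, 1.0, 2.0], size=(5, 8))
        beta = rng.normal(size=8)
        base = score_samples(make_panel(dosage), self._leads(beta, 8))
        grown = np.vstack([dosage, np.full((1, 8), np.nan)])
        extended = score_samples(make_panel(grown), self._leads(beta, 8))
        assert np.allclose(extended["raw_score"][:5], base["raw_score"])

    def test_matches_dense_oracle_on_random_panels(self, rng):
        # sparse pseudo-haploid panels vs a quadruple-loop reference
        for _ in range(50):
            n = rng.integers(2, 20)
            m = rng.integers(1, 100)
            dosage = rng.choice([0.0, 1.0, 2.0, np.nan], size=(n, m),
                                p=[0.25, 0.1, 0.25, 0.4])
            dosage[0] = rng.choice([0.0, 2.0], size=m)  # keep every variant scorable
            panel = make_panel(dosage)
            beta = rng.normal(size=m)
            got = score_samples(panel, self._leads(beta, m))["raw_score"].to_numpy()
            assert np.allclose(got, dense_score_oracle(panel, np.arange(m), beta),
                               atol=1e-12, rtol=0)

    def test_beta_doubling_doubles_raw_and_fixes_scaled(self, rng):
        dosage = rng.choice([0.0, 2.0, np.nan], size=(6, 10))
        dosage[0] = 2.0
        panel = make_panel(dosage)
        beta = rng.normal(size=10)
        a = score_samples(panel, self._leads(beta, 10))
        b = score_samples(panel, self._leads(2 * np.asarray(beta), 10))
        assert np.allclose(b["raw_score"], 2 * a["raw_score"])
        assert np.allclose(scale_scores(a)["scaled_score"], scale_scores(b)["scaled_score"])


class TestScaleScores:
    def _frame(self, raw):
        return pd.DataFrame({"sample_id": [f"s{i}" for i in range(len(raw))],
                             "raw_score": raw, "n_variants": 1, "n_imputed": 0})

    def test_endpoints_map_to_plus_minus_one(self):
        assert scale_scores(self._frame([1.0, -1.0]))["scaled_score"].tolist() == [1.0, -1.0]

    def test_affine_map_example(self):
        assert scale_scores(self._frame([0.0, 5.0, 10.0]))["scaled_score"].tolist() == [-1.0, 0.0, 1.0]

    def test_constant_scores_map_to_zero(self):
        assert scale_scores(self._frame([3.0, 3.0, 3.0]))["scaled_score"].tolist() == [0.0, 0.0, 0.0]

    def test_range_bounds_on_random_input(self, rng):
        scaled = scale_scores(self._frame(rng.normal(size=50)))["scaled_score"]
        assert scaled.min() == -1.0 and scaled.max() == 1.0
        assert scaled.between(-1, 1).all()


class TestThresholdGrid:
    def test_single_cell_equals_direct_pipeline(self, sim_neutral):
        from paleoprs.panels import filter_samples_missingness, restrict_to_meta
        from paleoprs.sumstats import align_effect_alleles, drop_ambiguous, filter_biallelic, select_by_pvalue
        from paleoprs.trends import piecewise_fit

        panel, meta = sim_neutral.panel, sim_neutral.meta
        table = align_effect_alleles(drop_ambiguous(filter_biallelic(sim_neutral.sumstats)), panel)
        grid = threshold_grid(panel, meta, {"t": table}, [1e-4], [0.96], [250.0])
        assert len(grid) == 2  # one row per epoch side

        sub = filter_samples_missingness(panel, 0.96)
        sub, sub_meta = restrict_to_meta(sub, meta)
        leads = clump_window(select_by_pvalue(table, 1e-4), 250.0)
        scored = scale_scores(score_samples(sub, leads))
        direct = piecewise_fit(scored["scaled_score"].to_numpy(),
                               sub_meta["age_bp"].to_numpy(float),
                               sub_meta["period"].to_numpy())
        post_row = grid[grid["epoch_side"] == "post"].iloc[0]
        assert post_row["r"] == pytest.approx(direct["post"].r)
        assert post_row["signed_neglog10_p"] == pytest.approx(direct["post"].signed_neglog10_p)

    def test_empty_selection_marks_na(self, sim_neutral):
        panel, meta = sim_neutral.panel, sim_neutral.meta
        from paleoprs.sumstats import align_effect_alleles, drop_ambiguous, filter_biallelic

        table = align_effect_alleles(drop_ambiguous(filter_biallelic(sim_neutral.sumstats)), panel)
        # reported p-values are floored at the smallest positive normal float,
        # so a threshold at that floor selects nothing
        grid = threshold_grid(panel, meta, {"t": table}, [np.finfo(float).tiny], [0.96], [250.0])
        assert grid["r"].isna().all()

    def test_planted_trend_is_sign_consistent_across_cells(self, sim_selected):
        from paleoprs.sumstats import align_effect_alleles, drop_ambiguous, filter_biallelic

        panel, meta = sim_selected.panel, sim_selected.meta
        table = align_effect_alleles(drop_ambiguous(filter_biallelic(sim_selected.sumstats)), panel)
        grid = threshold_grid(panel, meta, {"t": table},
                              [1e-4, 1e-5, 1e-6], [0.96, 0.80], [250.0, 500.0])
        post = grid[(grid["epoch_side"] == "post") & grid["r"].notna()]
        assert len(post) == 12
        # selection raises the trait toward the present: r < 0 against age BP
        assert (post["r"] < 0).all()
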