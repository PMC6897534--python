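"""sgRNA phenotypes, gene scores, control genes and cross-resistance calls."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from combokill.screens import (
    build_control_genes,
    call_cross_resistance,
    score_control_genes,
    score_genes,
    select_cutoff,
    sgrna_phenotypes,
)
from combokill.simulate import ScreenUniverse, simulate_crispr_screen


def small_table(treated, reference, nt_counts=((1000, 1000), (2000, 2000),
                                               (4000, 4000))):
    """One targeting guide plus non-targeting guides with identical counts
    in both columns (their shared LFC is the depth factor, so the centered
    rho of the targeting guide is exactly log2(t/r)/doublings)."""
    rows = [("sg_target", "GENE", "P1", True, treated[0], reference[0])]
    for i, (a, b) in enumerate(nt_counts):
        rows.append((f"nt_{i}", "negative_control", "none", False, a, b))
    df = pd.DataFrame(rows, columns=["sgrna_id", "gene", "tss", "targeting",
                                     "treated", "vehicle"])
    return df.set_index("sgrna_id")


class TestSgrnaPhenotypes:
    def test_direct_rho_evaluation(self):
        # counts 490 vs 90, pseudocount 10 -> log2(500/100)/7.6
        table = small_table((490,), (90,))
        res = sgrna_phenotypes(table, "treated", "vehicle", 7.6)
        assert res.table.loc["sg_target", "rho"] == pytest.approx(
            math.log2(5.0) / 7.6, abs=1e-12)

    def test_rho_zero_at_nontargeting_median(self):
        table = small_table((300,), (300,))
        res = sgrna_phenotypes(table, "treated", "vehicle", 7.6)
        assert res.table.loc["sg_target", "rho"] == pytest.approx(0.0)

    def test_low_count_guides_excluded(self):
        table = small_table((5,), (3,))
        res = sgrna_phenotypes(table, "treated", "vehicle", 7.6)
        assert not res.table.loc["sg_target", "passed"]
        assert np.isnan(res.table.loc["sg_target", "rho"])

    def test_depth_invariance(self):
        table = small_table((490,), (90,))
        res1 = sgrna_phenotypes(table, "treated", "vehicle", 7.6)
        scaled = table.copy()
        scaled["treated"] = scaled["treated"] * 7
        res2 = sgrna_phenotypes(scaled, "treated", "vehicle", 7.6,
                                pseudocount=0, min_count=1)
        res1b = sgrna_phenotypes(table, "treated", "vehicle", 7.6,
                                 pseudocount=0, min_count=1)
        assert res2.table.loc["sg_target", "rho"] == pytest.approx(
            res1b.table.loc["sg_target", "rho"], abs=1e-12)

    def test_nontargeting_median_anchor_is_exact_zero(self, rng):
        n = 500
        df = pd.DataFrame({
            "gene": ["negative_control"] * n,
            "tss": "none",
            "targeting": False,
            "treated": rng.integers(50, 5000, n),
            "vehicle": rng.integers(50, 5000, n),
        }, index=[f"nt_{i}" for i in range(n)])
        res = sgrna_phenotypes(df, "treated", "vehicle", 7.6)
        # exact zero up to the rounding of the even-count median average
        assert np.median(res.nontargeting) == pytest.approx(0.0, abs=1e-15)
        # with an odd count the anchor is exactly zero
        res_odd = sgrna_phenotypes(df.iloc[:499], "treated", "vehicle", 7.6)
        assert np.median(res_odd.nontargeting) == 0.0

    def test_zero_pseudocount_mode_for_half_library(self):
        table = small_table((0,), (90,))
        res = sgrna_phenotypes(table, "treated", "vehicle", 4.38,
                               pseudocount=1, pseudocount_mode="zeros")
        # only the zero cell is lifted to 1; the non-targeting guides cancel
        # the depth factor, leaving rho = log2(1/90) / doublings
        expected = math.log2(1 / 90) / 4.38
        assert res.table.loc["sg_target", "rho"] == pytest.approx(expected)

    def test_requires_positive_doubling_difference(self):
        with pytest.raises(ValueError):
            sgrna_phenotypes(small_table((10,), (10,)), "treated",
                             "vehicle", 0.0)

    def test_requires_nontargeting(self):
        table = small_table((490,), (90,), nt_counts=())
        with pytest.raises(ValueError, match="non-targeting"):
            sgrna_phenotypes(table, "treated", "vehicle", 7.6)


def exact_rank_sum_p(x, y):
    """Two-sided exact Mann-Whitney p by dynamic programming over the
    rank-sum distribution (no ties assumed)."""
    n, m = len(x), len(y)
    ranks = pd.Series(np.concatenate([x, y])).rank().to_numpy()
    u_obs = ranks[:n].sum() - n * (n + 1) / 2
    # dp[k][u] = number of ways to pick k of the N items with U statistic u
    big_n = n + m
    max_u = n * m
    dp = np.zeros((n + 1, max_u + 1))
    dp[0, 0] = 1.0
    for i in range(1, big_n + 1):
        for k in range(min(i, n), 0, -1):
            u = i - k  # item i contributes (i - k) to U when chosen as kth
            if u <= max_u:
                dp[k, u:] += dp[k - 1, :max_u + 1 - u]
    dist = dp[n]
    dist /= dist.sum()
    u_obs = round(u_obs)
    mu = n * m / 2
    lo = min(u_obs, int(2 * mu) - u_obs)
    hi = max(u_obs, int(2 * mu) - u_obs)
    p = dist[:lo + 1].sum() + dist[hi:].sum()
    return min(1.0, float(p))


class TestGeneScores:
    def make_phenotypes(self, gene_rhos, controls, tss=None):
        genes = []
        for g, rhos in gene_rhos.items():
            for i, r in enumerate(rhos):
                genes.append((f"{g}_sg{i}", g,
                              tss.get(g, "P1") if tss else "P1", True, r))
        for i, r in enumerate(controls):
            genes.append((f"nt_{i}", "negative_control", "none", False, r))
        tab = pd.DataFrame(genes, columns=["sgrna_id", "gene", "tss",
                                           "targeting", "rho"])
        tab["passed"] = np.isfinite(tab["rho"])
        from combokill.screens import PhenotypeResult

        return PhenotypeResult(tab, np.asarray(controls, float), "X", 7.6)

    def test_top_five_mean_selects_strongest(self, rng):
        controls = rng.normal(0, 0.05, 200)
        ph = self.make_phenotypes(
            {"G1": [1.0] * 5 + [0.0] * 5}, controls)
        scores = score_genes(ph)
        assert scores.loc["G1", "mean_top_rho"] == pytest.approx(1.0)

    def test_null_gene_scores_near_zero(self, rng):
        controls = rng.normal(0, 0.1, 500)
        ph = self.make_phenotypes({"G1": rng.normal(0, 0.1, 10)}, controls)
        scores = score_genes(ph)
        assert abs(scores.loc["G1", "resistance_score"]) < 1.0

    def test_min_observed_filter_drops_gene(self, rng):
        controls = rng.normal(0, 0.1, 100)
        rhos = [0.5] * 7 + [np.nan] * 3  # only 7 observed phenotypes
        ph = self.make_phenotypes({"G1": rhos}, controls)
        assert "G1" not in score_genes(ph, min_observed=8).index
        assert "G1" in score_genes(ph, min_observed=7).index

    def test_tss_with_lowest_p_represents_gene(self, rng):
        controls = list(rng.normal(0, 0.05, 300))
        rows = []
        for i in range(10):
            rows.append((f"a{i}", "G1", "P1", True, 0.02 * (i % 3)))
        for i in range(10):
            rows.append((f"b{i}", "G1", "P2", True, 1.0 + 0.01 * i))
        for i, r in enumerate(controls):
            rows.append((f"nt_{i}", "negative_control", "none", False, r))
        tab = pd.DataFrame(rows, columns=["sgrna_id", "gene", "tss",
                                          "targeting", "rho"])
        tab["passed"] = True
        from combokill.screens import PhenotypeResult

        scores = score_genes(PhenotypeResult(
            tab, np.asarray(controls), "X", 7.6))
        assert scores.loc["G1", "tss"] == "P2"
        assert scores.loc["G1", "mean_top_rho"] > 0.9

    def test_asymptotic_p_agrees_with_exact_enumeration(self, rng):
        """The normal-approximation Mann-Whitney used for scoring matches an
        exact rank-sum enumeration on a 10-vs-50 downsample."""
        for shift in (0.0, 0.1, 0.3):
            x = rng.normal(shift, 0.1, 10)
            y = rng.normal(0, 0.1, 50)
            ph = self.make_phenotypes({"G1": list(x)}, list(y))
            p_impl = score_genes(ph).loc["G1", "mw_p"]
            p_exact = exact_rank_sum_p(x, y)
            assert p_impl == pytest.approx(p_exact,
                                           rel=0.2, abs=0.005)

    def test_hypersensitivity_is_negated_score(self, rng):
        controls = rng.normal(0, 0.05, 300)
        ph = self.make_phenotypes({"G1": [-0.8] * 10}, controls)
        scores = score_genes(ph)
        assert scores.loc["G1", "resistance_score"] < 0
        assert scores.loc["G1", "hypersensitivity_score"] == pytest.approx(
            -scores.loc["G1", "resistance_score"])


class TestControlGenes:
    def make_screen(self, seed=0, n_genes=80, n_nt=400):
        genes = [f"G{i:03d}" for i in range(n_genes)]
        rho = pd.DataFrame(0.0, index=genes, columns=["C"])
        uni = ScreenUniverse(rho, n_nontargeting=n_nt, seed=seed)
        table, _, _ = simulate_crispr_screen(uni, ["C"], depth=1_000_000,
                                             seed=seed)
        return table, uni

    def test_reproducible_given_seed(self):
        table, _ = self.make_screen()
        s1 = build_control_genes(table, n_genes=50, n_sets=2, seed=4)
        s2 = build_control_genes(table, n_genes=50, n_sets=2, seed=4)
        assert s1 == s2

    def test_group_size_exceeding_pool_rejected(self):
        table, _ = self.make_screen(n_nt=5)
        with pytest.raises(ValueError, match="fewer non-targeting"):
            build_control_genes(table, n_genes=10, group_size=10, seed=1)

    def test_null_calibration_on_all_null_screen(self):
        """With no true effects anywhere, pseudo-gene scores center on zero
        and their Mann-Whitney p-values are roughly uniform."""
        table, uni = self.make_screen(seed=6)
        ph = sgrna_phenotypes(table, "C", "vehicle", 9.34, arm="C")
        csets = build_control_genes(table, n_genes=300, n_sets=2, seed=7)
        scored = score_control_genes(ph, csets)
        pooled = pd.concat(scored)
        assert abs(pooled["mean_top_rho"].median()) < 0.02
        frac = (pooled["mw_p"] < 0.05).mean()
        assert frac == pytest.approx(0.05, abs=0.03)
        # real (null) genes score like controls at a fixed cutoff
        real = score_genes(ph)
        n_real = (real["resistance_score"] >= 1.0).sum()
        n_ctrl = np.mean([(s["resistance_score"] >= 1.0).sum()
                          for s in scored])
        assert n_real <= n_ctrl * (len(real) / len(scored[0])) + 2


class TestCutoffSelection:
    def brute_force_cutoff(self, control_scores_by_drug, target=1.0,
                           step=0.001):
        drugs = list(control_scores_by_drug)
        n_sets = len(control_scores_by_drug[drugs[0]])
        c = step
        while True:
            total = 0
            for s in range(n_sets):
                merged = pd.DataFrame(
                    {d: control_scores_by_drug[d][s]["resistance_score"]
                     for d in drugs})
                total += ((merged >= c).sum(axis=1) >= 2).sum()
            if total / n_sets <= target:
                return c
            c = round(c + step, 10)

    def make_control_scores(self, rng, n=400, n_sets=3, scale=0.3):
        out = {}
        for d in ("C", "O"):
            sets = []
            for _ in range(n_sets):
                sets.append(pd.DataFrame(
                    {"resistance_score": rng.standard_t(3, n) * scale},
                    index=[f"control_{i:05d}" for i in range(n)]))
            out[d] = sets
        return out

    def test_matches_finer_grid_brute_force(self, rng):
        controls = self.make_control_scores(rng)
        fast = select_cutoff(controls, step=0.01)
        brute = self.brute_force_cutoff(controls, step=0.001)
        assert abs(fast - brute) <= 0.01  # grid resolution

    def test_zero_controls_give_smallest_cutoff(self):
        zeros = {"C": [pd.DataFrame({"resistance_score": [0.0] * 10})],
                 "O": [pd.DataFrame({"resistance_score": [0.0] * 10})]}
        assert select_cutoff(zeros) == pytest.approx(0.01)

    def test_false_count_monotone_in_cutoff(self, rng):
        controls = self.make_control_scores(rng)
        drugs = list(controls)
        counts = []
        for c in np.arange(0.01, 2.0, 0.1):
            total = 0
            for s in range(len(controls[drugs[0]])):
                merged = pd.DataFrame(
                    {d: controls[d][s]["resistance_score"] for d in drugs})
                total += ((merged >= c).sum(axis=1) >= 2).sum()
            counts.append(total)
        assert (np.diff(counts) <= 0).all()


class TestCrossResistanceCalls:
    def test_disjoint_planted_genes_do_not_overlap(self):
        idx = ["G1", "G2", "G3"]
        scores = {
            "C": pd.DataFrame({"resistance_score": [5.0, 0.0, 0.0],
                               "hypersensitivity_score": [-5.0, 0.0, 0.0]},
                              index=idx),
            "O": pd.DataFrame({"resistance_score": [0.0, 5.0, 0.0],
                               "hypersensitivity_score": [0.0, -5.0, 0.0]},
                              index=idx),
        }
        calls = call_cross_resistance(scores, cutoff=1.0)
        assert calls["resistance"]["exact"][("C", "O")] == 0
        assert calls["resistance"]["multiplicity"][1] == 2

    def test_collateral_sensitivity_pair_detected(self):
        idx = ["G1"]
        scores = {
            "C": pd.DataFrame({"resistance_score": [5.0],
                               "hypersensitivity_score": [-5.0]}, index=idx),
            "O": pd.DataFrame({"resistance_score": [-4.0],
                               "hypersensitivity_score": [4.0]}, index=idx),
        }
        calls = call_cross_resistance(scores, cutoff=1.0)
        assert calls["collateral_pairs"] == [("G1", "C", "O")]
        assert calls["collateral_fraction"] == 1.0

    def test_planted_dual_resistance_recovered(self):
        """Strong planted dual-resistance genes are all recovered at the
        control-calibrated cutoff with no pseudo-gene called, across seeds."""
        genes = [f"G{i:03d}" for i in range(150)]
        for seed in range(3):
            rho = pd.DataFrame(0.0, index=genes, columns=["C", "O"])
            dual = genes[:5]
            rho.loc[dual, :] = 1.0
            uni = ScreenUniverse(rho, n_nontargeting=400, seed=seed)
            table, _, _ = simulate_crispr_screen(uni, ["C", "O"],
                                                 depth=1_500_000, seed=seed)
            phen = {d: sgrna_phenotypes(table, d, "vehicle",
                                        uni.doublings[d], arm=d)
                    for d in ("C", "O")}
            csets = build_control_genes(table, n_genes=150, n_sets=2,
                                        seed=seed)
            cscores = {d: score_control_genes(phen[d], csets)
                       for d in ("C", "O")}
            cutoff = select_cutoff(cscores)
            real = {d: score_genes(phen[d]) for d in ("C", "O")}
            calls = call_cross_resistance(real, cutoff)
            double = calls["resistance"]["sets"]["C"] & \
                calls["resistance"]["sets"]["O"]
            assert set(dual) <= double
            n_ctrl_double = np.mean([
                ((pd.DataFrame({d: cscores[d][s]["resistance_score"]
                                for d in ("C", "O")}) >= cutoff)
                 .sum(axis=1) >= 2).sum()
                for s in range(2)])
            assert n_ctrl_double <= 1.0
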