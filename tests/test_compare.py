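"""Responder classification, contingency tables, exact tests, FDR."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import panss_traj as pt
from panss_traj.errors import (
    AlignmentError,
    ConfigurationError,
    DegenerateTableError,
)

from _oracles import bh_fdr_oracle, fisher_exact_enum, pearson_chi2_oracle


class TestClassifyThreshold:
    @pytest.mark.parametrize(
        "pct,expected", [(73.58, True), (50.0, True), (31.99, False), (49.99, False)]
    )
    def test_inclusive_boundary(self, pct, expected):
        assert pt.classify_threshold(pct) is expected

    def test_strict_boundary_option(self):
        assert not pt.classify_threshold(50.0, strict=True)
        assert pt.classify_threshold(50.001, strict=True)

    def test_vectorised(self):
        out = pt.classify_threshold(np.array([10.0, 50.0, 90.0]))
        assert out.tolist() == [False, True, True]


class TestPairedCrosstab:
    def test_all_high_responders(self):
        ct = pt.paired_crosstab(["high"] * 4, [True] * 4)
        assert ct.counts.tolist() == [[4, 0], [0, 0]]

    def test_published_discordance_pattern(self):
        """Off-diagonal cells 47 (high/non-responder) and 302 (low/responder)
        must book-keep to 349 discordant patients."""
        labels = np.array(["high"] * (1424 + 47) + ["low"] * (302 + 1237))
        flags = np.array([True] * 1424 + [False] * 47 + [True] * 302 + [False] * 1237)
        ct = pt.paired_crosstab(labels, flags)
        assert ct.counts.tolist() == [[1424, 47], [302, 1237]]
        assert pt.discordant_count(ct) == 349
        assert ct.grand_total == 3010

    def test_length_mismatch_rejected(self):
        with pytest.raises(AlignmentError):
            pt.paired_crosstab(["high", "low"], [True])


class TestCompositionTable:
    def test_identical_partitions_give_zero_chi2(self):
        labels = np.array(["high"] * 30 + ["low"] * 20)
        flags = np.array([True] * 30 + [False] * 20)
        ct = pt.composition_table(labels, flags)
        assert (ct.counts[0] == ct.counts[1]).all()
        assert pt.pearson_chi2(ct).statistic == pytest.approx(0.0, abs=1e-12)

    def test_published_counts_layout(self):
        labels = np.array(["high"] * 1471 + ["low"] * 1539)
        flags = np.array([True] * 1726 + [False] * 1284)
        ct = pt.composition_table(labels, flags)
        assert ct.counts.tolist() == [[1471, 1539], [1726, 1284]]
        assert (ct.row_totals == 3010).all()
        assert ct.grand_total == 2 * 3010


class TestPearsonChi2:
    def test_published_composition_statistic(self):
        ct = pt.CrossTab(("t", "d"), ("good", "poor"), [[1471, 1539], [1726, 1284]])
        res = pt.pearson_chi2(ct)
        assert round(res.statistic, 2) == 43.37
        assert res.df == 1
        assert res.p_value < 0.001

    def test_proportional_rows_give_zero(self):
        ct = pt.CrossTab(("a", "b"), ("x", "y"), [[10, 10], [10, 10]])
        assert pt.pearson_chi2(ct).statistic == pytest.approx(0.0, abs=1e-12)

    def test_diagonal_table(self):
        ct = pt.CrossTab(("a", "b"), ("x", "y"), [[5, 0], [0, 5]])
        assert pt.pearson_chi2(ct).statistic == pytest.approx(10.0)

    def test_matches_scatter_formula_oracle(self, rng):
        for _ in range(200):
            shape = (int(rng.integers(2, 5)), int(rng.integers(2, 5)))
            counts = rng.integers(1, 40, size=shape)
            ct = pt.CrossTab(
                tuple(f"r{i}" for i in range(shape[0])),
                tuple(f"c{j}" for j in range(shape[1])),
                counts,
            )
            assert pt.pearson_chi2(ct).statistic == pytest.approx(
                pearson_chi2_oracle(counts), abs=1e-9
            )

    def test_zero_margin_rejected(self):
        ct = pt.CrossTab(("a", "b"), ("x", "y"), [[0, 5], [0, 5]])
        with pytest.raises(DegenerateTableError):
            pt.pearson_chi2(ct)


class TestFisherExact:
    def test_hand_enumerated_example(self):
        ct = pt.CrossTab(("a", "b"), ("x", "y"), [[1, 9], [11, 3]])
        res = pt.fisher_exact_2x2(ct)
        assert res.p_value == pytest.approx(0.00276, abs=5e-6)
        assert res.p_value == pytest.approx(fisher_exact_enum(1, 9, 11, 3), rel=1e-9)

    def test_zero_margin_gives_p_one(self):
        ct = pt.CrossTab(("a", "b"), ("x", "y"), [[0, 9], [0, 3]])
        assert pt.fisher_exact_2x2(ct).p_value == 1.0

    def test_symmetric_table_gives_p_one(self):
        ct = pt.CrossTab(("a", "b"), ("x", "y"), [[5, 5], [5, 5]])
        assert pt.fisher_exact_2x2(ct).p_value == pytest.approx(1.0)

    def test_matches_enumeration_on_random_tables(self, rng):
        for _ in range(200):
            a, b, c, d = (int(v) for v in rng.integers(0, 16, size=4))
            if a + b + c + d == 0:
                continue
            ct = pt.CrossTab(("r1", "r2"), ("c1", "c2"), [[a, b], [c, d]])
            assert pt.fisher_exact_2x2(ct).p_value == pytest.approx(
                fisher_exact_enum(a, b, c, d), rel=1e-7, abs=1e-12
            )


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert pt.bh_fdr([0.04])[0] == pytest.approx(0.04)

    def test_step_up_arithmetic(self):
        assert pt.bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_idempotent_on_tied_adjusted_block(self):
        # (0.01, 0.02, 0.03) adjusts to a tied block (0.03, 0.03, 0.03),
        # which is a fixed point of the adjustment
        once = pt.bh_fdr([0.01, 0.02, 0.03])
        assert pt.bh_fdr(once) == pytest.approx(once)

    def test_out_of_range_rejected(self):
        with pytest.raises(ConfigurationError):
            pt.bh_fdr([0.5, 1.2])

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=12))
    def test_matches_oracle_dominates_raw_and_order_invariant(self, pvals):
        adj = pt.bh_fdr(pvals)
        assert adj == pytest.approx(bh_fdr_oracle(pvals), rel=1e-12, abs=1e-12)
        assert (adj >= np.asarray(pvals) - 1e-15).all()
        perm = np.argsort(pvals)
        assert pt.bh_fdr(np.asarray(pvals)[perm]) == pytest.approx(adj[perm])


class TestMcNemar:
    def test_balanced_discordance_gives_zero(self):
        ct = pt.CrossTab(("high", "low"), ("r", "n"), [[10, 7], [7, 10]])
        res = pt.mcnemar_paired(ct)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_statistic_formula(self):
        ct = pt.CrossTab(("high", "low"), ("r", "n"), [[100, 47], [302, 100]])
        res = pt.mcnemar_paired(ct)
        assert res.statistic == pytest.approx((302 - 47) ** 2 / 349)


def _simulate_arm_cohort(rng, probs, n_per=400):
    arms = np.repeat(pt.ARMS, n_per)
    p = np.repeat(probs, n_per)
    resp = rng.random(len(arms)) < p
    # trajectory labels loosely tied to response
    traj = np.where(rng.random(len(arms)) < 0.85, resp, ~resp)
    labels = np.where(traj, "high", "low").astype(object)
    return labels, arms, resp


class TestPerArmBreakdown:
    def test_identical_distributions_give_null_results(self):
        labels, arms, resp = [], [], []
        for arm in pt.ARMS:
            labels += ["high"] * 10 + ["low"] * 10
            arms += [arm] * 20
            resp += [True] * 10 + [False] * 10
        out = pt.per_arm_breakdown(labels, arms, resp)
        assert out.omnibus_trajectory.statistic == pytest.approx(0.0, abs=1e-12)
        assert out.omnibus_threshold.statistic == pytest.approx(0.0, abs=1e-12)
        assert (out.pairwise["p_adjusted"] == 1.0).all()
        assert len(out.pairwise) == 21

    def test_elevated_arms_dominate_smallest_adjusted_p(self):
        """Two arms with responder probability 0.7 against five at 0.5: the
        most significant pairwise contrasts must involve an elevated arm."""
        probs = np.array([0.7, 0.7, 0.5, 0.5, 0.5, 0.5, 0.5])
        elevated = {pt.ARMS[0], pt.ARMS[1]}
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(4000 + seed)
            labels, arms, resp = _simulate_arm_cohort(rng, probs)
            out = pt.per_arm_breakdown(labels, arms, resp)
            top = out.pairwise.nsmallest(3, "p_adjusted")
            hits += all(
                {row.arm_a, row.arm_b} & elevated for row in top.itertuples()
            )
        assert hits >= 9

    def test_invariant_under_patient_permutation(self, rng):
        probs = np.array([0.6, 0.5, 0.5, 0.55, 0.5, 0.5, 0.45])
        labels, arms, resp = _simulate_arm_cohort(rng, probs, n_per=50)
        out1 = pt.per_arm_breakdown(labels, arms, resp)
        perm = rng.permutation(len(labels))
        out2 = pt.per_arm_breakdown(labels[perm], arms[perm], resp[perm])
        assert out1.omnibus_threshold.statistic == pytest.approx(
            out2.omnibus_threshold.statistic
        )
        assert out1.threshold_table.counts.tolist() == out2.threshold_table.counts.tolist()

    def test_empty_arm_dropped_with_warning(self):
        labels = ["high", "low"] * 20
        arms = [pt.ARMS[0]] * 20 + [pt.ARMS[1]] * 20
        resp = [True, False] * 20
        with pytest.warns(UserWarning, match="empty arm"):
            out = pt.per_arm_breakdown(labels, arms, resp)
        assert out.threshold_table.row_labels == (pt.ARMS[0], pt.ARMS[1])


class TestOmnibusFallbacks:
    def test_small_2x2_falls_back_to_fisher(self):
        ct = pt.CrossTab(("a", "b"), ("x", "y"), [[2, 8], [7, 3]])
        res = pt.omnibus_test(ct)
        assert res.method == "fisher_exact"

    def test_sparse_rxc_uses_seeded_permutation(self):
        counts = [[1, 5], [4, 2], [0, 6]]
        ct = pt.CrossTab(("a", "b", "c"), ("x", "y"), counts)
        r1 = pt.omnibus_test(ct, seed=1, n_mc=2000)
        r2 = pt.omnibus_test(ct, seed=1, n_mc=2000)
        assert r1.method == "mc_permutation_chi2"
        assert r1.p_value == r2.p_value  # seeded determinism
        # sanity: agrees with the chi2 approximation to first order
        approx = stats.chi2_contingency(np.array(counts), correction=False)[1]
        assert abs(r1.p_value - approx) < 0.1

    def test_large_counts_use_pearson(self):
        ct = pt.CrossTab(("a", "b"), ("x", "y"), [[40, 60], [55, 45]])
        assert pt.omnibus_test(ct).method == "pearson_chi2"


class TestEpisodeSplit:
    def test_identical_rates_give_zero_statistic(self):
        labels = (["high"] * 10 + ["low"] * 10) * 2
        arms = ["haloperidol"] * 20 + ["risperidone"] * 20
        fe = ([True] * 5 + [False] * 5) * 4
        out = pt.episode_split(labels, arms, fe)
        for name in ("typical", "atypical"):
            assert out[name][1].statistic == pytest.approx(0.0, abs=1e-12)

    def test_power_to_detect_episode_effect_in_typical_stratum(self):
        """First-episode high-trajectory rate 0.6 vs relapse 0.45 at
        n = 140/350 is detected at alpha = 0.05 in most replicates."""
        sig = 0
        for seed in range(100):
            rng = np.random.default_rng(5000 + seed)
            n_fe, n_rel = 140, 350
            fe = np.array([True] * n_fe + [False] * n_rel)
            p = np.where(fe, 0.6, 0.45)
            labels = np.where(rng.random(len(fe)) < p, "high", "low").astype(object)
            arms = np.array(["haloperidol"] * len(fe), dtype=object)
            with pytest.warns(UserWarning, match="empty stratum"):
                out = pt.episode_split(labels, arms, fe)
            sig += out["typical"][1].p_value < 0.05
        assert sig >= 80

    def test_swapping_stratum_definition_swaps_tables(self, rng):
        n = 200
        arms = rng.choice(np.asarray(pt.ARMS, dtype=object), size=n)
        labels = rng.choice(np.array(["high", "low"], dtype=object), size=n)
        fe = rng.random(n) < 0.5
        out1 = pt.episode_split(labels, arms, fe)
        out2 = pt.episode_split(labels, arms, fe, typical_arm_set=pt.ATYPICAL_ARMS)
        assert out1["typical"][0].counts.tolist() == out2["atypical"][0].counts.tolist()
        assert out1["atypical"][0].counts.tolist() == out2["typical"][0].counts.tolist()

    def test_unknown_typical_arm_rejected(self):
        with pytest.raises(ConfigurationError):
            pt.episode_split(["high"], ["haloperidol"], [True],
                             typical_arm_set=("clozapine",))
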