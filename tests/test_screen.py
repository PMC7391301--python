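"""Dropout-screen scoring: normalisation, robust-Z masking, Z calls, Fisher."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rbscreen as rb
from rbscreen.screen import (
    check_gaussian,
    dropout_z,
    fisher_exact_2x2,
    gene_hits_screen1,
    gene_hits_screen2,
    log_transform,
    normalize_counts,
    robust_z_exclude,
    score_screen1,
    score_screen2,
    tier_of,
)

from conftest import make_screen


def simple_screen(tumor, t0=None, n_genes=None, log_scale=False):
    tumor = np.asarray(tumor, dtype=float)
    n = tumor.shape[0]
    if t0 is None:
        t0 = np.full(n, 100.0)
    shrnas = [f"sh{i}" for i in range(n)]
    genes = [f"g{i // 2}" for i in range(n)] if n_genes is None else n_genes
    return make_screen(tumor, np.asarray(t0, dtype=float), shrnas, genes,
                       log_scale=log_scale)


class TestNormalizeCounts:
    def test_column_already_at_target_unchanged(self):
        sc = simple_screen(np.full((4, 6), 25.0), t0=np.array([40, 30, 20, 10.0]))
        out = normalize_counts(sc, target_total=100.0)
        pd.testing.assert_series_equal(out.counts["L1_T0"], sc.counts["L1_T0"])

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        tumor = rng.integers(1, 100, size=(5, 4)).astype(float)
        a = normalize_counts(simple_screen(tumor))
        b = normalize_counts(simple_screen(2 * tumor))
        pd.testing.assert_frame_equal(a.counts, b.counts)

    def test_proportional_scaling(self):
        sc = simple_screen(np.array([[1.0], [2.0], [7.0]]),
                           t0=np.array([1, 2, 7.0]))
        out = normalize_counts(sc, target_total=100.0)
        np.testing.assert_allclose(out.counts["L1_T0"], [10, 20, 70])

    def test_zero_total_sample_named(self):
        sc = simple_screen(np.array([[0.0, 5.0], [0.0, 5.0]]))
        with pytest.raises(ValueError, match="L1_tumor_1"):
            normalize_counts(sc)

    def test_rank_order_preserved(self):
        rng = np.random.default_rng(1)
        tumor = rng.integers(0, 1000, size=(20, 3)).astype(float)
        out = normalize_counts(simple_screen(tumor))
        for col in out.counts.columns:
            assert (out.counts[col].rank() == simple_screen(tumor).counts[col].rank()).all()


class TestLogTransform:
    @pytest.mark.parametrize("x,expected", [(0.0, -1.0), (9.9, 1.0)])
    def test_pseudocount_examples(self, x, expected):
        sc = simple_screen(np.full((2, 4), x), t0=np.array([x, x]))
        out = log_transform(sc, pseudocount=0.1)
        assert out.counts.iloc[0, 0] == pytest.approx(expected)

    def test_monotone(self):
        sc = simple_screen(np.array([[1.0], [5.0], [500.0]]),
                           t0=np.array([1, 2, 3.0]))
        out = log_transform(sc)
        assert out.counts["L1_tumor_1"].is_monotonic_increasing


class TestRobustZExclude:
    def test_identical_replicates_no_exclusion(self):
        sc = simple_screen(np.full((2, 6), 5.0))
        out = robust_z_exclude(sc)["L1"]
        assert not out["excluded"].any()
        assert (out["robust_z"] == 0).all()

    def test_hand_oracle_single_outlier(self):
        # replicates (4,5,5,5,6,50): median 5, MAD 0.5, Z(50) = 45/0.7413
        sc = simple_screen(np.array([[4, 5, 5, 5, 6, 50.0]]))
        out = robust_z_exclude(sc)["L1"]
        z50 = out.loc[out["sample"] == "L1_tumor_6", "robust_z"].iloc[0]
        assert z50 == pytest.approx(45 / (1.4826 * 0.5), rel=1e-9)
        assert out["excluded"].sum() == 1
        assert out.loc[out["sample"] == "L1_tumor_6", "excluded"].iloc[0]

    def test_cap_when_three_replicates_flagged(self):
        # tight inlier cluster plus three wild values: all three exceed the
        # threshold but only the two largest |Z| may be excluded
        sc = simple_screen(np.array([[4.9, 5.0, 5.0, 5.05, 5.1,
                                      1000.0, 2000.0, 3000.0]]))
        out = robust_z_exclude(sc)["L1"]
        flagged = (out["robust_z"].abs() > 5).sum()
        assert flagged == 3
        assert out["excluded"].sum() == 2
        excluded = set(out.loc[out["excluded"], "sample"])
        assert excluded == {"L1_tumor_7", "L1_tumor_8"}

    def test_never_leaves_fewer_than_four(self):
        sc = simple_screen(np.array([[1, 2, 3, 1000.0, 2000.0]]))
        out = robust_z_exclude(sc, max_excluded=2)["L1"]
        assert 5 - out["excluded"].sum() >= 4

    def test_fewer_than_four_replicates_rejected(self):
        sc = simple_screen(np.array([[5, 6, 7.0]]))
        with pytest.raises(ValueError, match=">= 4"):
            robust_z_exclude(sc)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_exclusion_cap_property(self, seed):
        rng = np.random.default_rng(seed)
        tumor = rng.lognormal(3, 2, size=(8, 6))
        out = robust_z_exclude(log_transform(simple_screen(tumor)))["L1"]
        per_shrna = out.groupby("shrna")["excluded"].sum()
        assert (per_shrna <= 2).all()


class TestCheckGaussian:
    def test_normal_sample_passes(self):
        x = np.random.default_rng(0).normal(size=1000)
        _, p, ok = check_gaussian(x)
        assert ok and p >= 0.01

    def test_exponential_sample_fails(self):
        x = np.random.default_rng(0).exponential(size=1000)
        with pytest.warns(UserWarning, match="Gaussian"):
            _, p, ok = check_gaussian(x)
        assert not ok and p < 0.01

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            check_gaussian(np.full(50, 3.0))

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match=">= 20"):
            check_gaussian(np.arange(10.0))


class TestDropoutZ:
    def test_degenerate_sd_rejected(self):
        with pytest.raises(ValueError, match="SD"):
            dropout_z(pd.Series([0.5] * 10))

    def test_threshold_boundary(self):
        # craft ratios whose z-scores straddle -1.96 exactly
        x = pd.Series(np.r_[np.zeros(98), -1.0, 1.0])
        out = dropout_z(x)
        z = out["z"]
        assert not out.loc[z >= -1.96, "dropout"].any()
        assert out.loc[z < -1.96, "dropout"].all()

    def test_hand_standardization_oracle(self):
        ratios = pd.Series(np.r_[np.full(9, 0.0), -2.0],
                           index=[f"sh{i}" for i in range(10)])
        out = dropout_z(ratios)
        expected_z = (ratios - ratios.mean()) / ratios.std(ddof=0)
        np.testing.assert_allclose(out["z"], expected_z)
        assert list(out.index[out["dropout"]]) == ["sh9"]

    def test_z_standardisation_invariant(self):
        rng = np.random.default_rng(3)
        out = dropout_z(pd.Series(rng.normal(size=500)))
        assert out["z"].mean() == pytest.approx(0.0, abs=1e-12)
        assert out["z"].std(ddof=0) == pytest.approx(1.0, rel=1e-12)


class TestGeneHits:
    def _dropouts(self, flags_by_line, shrnas):
        return {
            line: pd.DataFrame({"dropout": flags}, index=shrnas)
            for line, flags in flags_by_line.items()
        }

    def test_single_dropout_shrna_not_a_hit(self):
        gene_of = pd.Series(["gA", "gA", "gB", "gB"],
                            index=["s1", "s2", "s3", "s4"])
        d = self._dropouts({"Y79": [True, False, False, False]}, gene_of.index)
        hits = gene_hits_screen1(d, gene_of)
        assert not hits.loc["gA", "any_line"]

    def test_two_dropouts_in_one_line_hit_there_only(self):
        gene_of = pd.Series(["gA"] * 3, index=["s1", "s2", "s3"])
        d = self._dropouts({"Y79": [True, True, False],
                            "WERI": [False, True, False]}, gene_of.index)
        hits = gene_hits_screen1(d, gene_of)
        assert hits.loc["gA", "Y79"] and not hits.loc["gA", "WERI"]
        assert hits.loc["gA", "any_line"] and not hits.loc["gA", "all_lines"]

    def test_screen2_tiers(self):
        shrnas = ["s1", "s2"]
        gene_of = pd.Series(["gA", "gA"], index=shrnas)
        # two shRNAs at -0.70 in 3 of 4 lines -> high tier
        lr = pd.DataFrame({"L1": [-0.70, -0.70], "L2": [-0.70, -0.70],
                           "L3": [-0.70, -0.70], "L4": [0.0, 0.0]},
                          index=shrnas)
        hits = gene_hits_screen2(lr, gene_of)
        assert hits.loc["gA", "tier"] == "high"
        # boundary: -0.68 does not score
        lr2 = lr.copy()
        lr2.loc[:, ["L2", "L3"]] = -0.68
        assert gene_hits_screen2(lr2, gene_of).loc["gA", "tier"] == "low"

    def test_two_line_gene_is_medium(self):
        shrnas = ["s1", "s2"]
        gene_of = pd.Series(["gA", "gA"], index=shrnas)
        lr = pd.DataFrame({"L1": [-1.0, -1.0], "L2": [-1.0, -1.0],
                           "L3": [0.0, 0.0], "L4": [0.0, 0.0]}, index=shrnas)
        assert gene_hits_screen2(lr, gene_of).loc["gA", "tier"] == "medium"

    @pytest.mark.parametrize("n,tier", [(4, "high"), (3, "high"), (2, "medium"),
                                        (1, "low"), (0, "none")])
    def test_tier_map(self, n, tier):
        assert tier_of(n) == tier


# ---------------------------------------------------------------------------
# Fisher exact


def fisher_oracle(a, b, c, d):
    """Brute-force hypergeometric enumeration (probability-mass two-sided)."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x):
        return (math.comb(r1, x) * math.comb(r2, c1 - x)) / math.comb(n, c1)

    p_obs = prob(a)
    return sum(prob(x) for x in range(max(0, c1 - r2), min(r1, c1) + 1)
               if prob(x) <= p_obs * (1 + 1e-12))


class TestFisherExact:
    def test_validation_table_matches_printed_p(self):
        p = fisher_exact_2x2(15, 3, 3, 15)
        assert round(p, 4) == 0.0002

    def test_symmetric_table_p_one(self):
        assert fisher_exact_2x2(5, 5, 5, 5) == pytest.approx(1.0)

    def test_diagonal_table_enumeration(self):
        assert fisher_exact_2x2(3, 0, 0, 3) == pytest.approx(0.1, rel=1e-9)

    def test_zero_margin_convention(self):
        with pytest.warns(UserWarning, match="margin"):
            assert fisher_exact_2x2(0, 0, 3, 4) == 1.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.tuples(st.integers(0, 10), st.integers(0, 10),
                     st.integers(0, 10), st.integers(0, 10)))
    def test_matches_enumeration_oracle(self, table):
        a, b, c, d = table
        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
            return
        assert fisher_exact_2x2(a, b, c, d) == pytest.approx(
            fisher_oracle(a, b, c, d), rel=1e-7)


# ---------------------------------------------------------------------------
# end-to-end scoring


class TestEndToEnd:
    def test_screen1_recovers_depleted_genes(self):
        depleted = frozenset(range(5))
        spec = rb.SimScreenSpec(n_genes=100, shrnas_per_gene=2,
                                depleted_gene_ids=depleted,
                                depletion_factor=0.2, n_tumor_reps=6, seed=0)
        counts, truth, _ = rb.gen_screen(spec)
        scores = score_screen1(counts)
        called = set(scores.gene_hits.index[scores.gene_hits["any_line"]])
        assert called == truth

    def test_null_calibration_two_sided(self, null_screen):
        scores = score_screen1(null_screen)
        z = scores.per_shrna["LINE1"]["z"]
        frac = (z.abs() > 1.96).mean()
        half_band = 2.5758 * np.sqrt(0.05 * 0.95 / len(z))
        assert abs(frac - 0.05) <= half_band

    def test_screen2_four_lines_tiering(self):
        depleted = frozenset(range(3))
        lines = []
        for i, name in enumerate(["Y79", "WERI", "RB3535S", "RB3823"]):
            spec = rb.SimScreenSpec(n_genes=40, shrnas_per_gene=3,
                                    depleted_gene_ids=depleted,
                                    depletion_factor=0.1, seed=20 + i)
            lines.append(rb.gen_screen(spec, cell_line=name)[0])
        combined = rb.combine_screens(lines)
        ratios, hits = score_screen2(combined)
        assert list(ratios.columns) == sorted(["Y79", "WERI", "RB3535S", "RB3823"])
        for g in sorted(depleted):
            assert hits.loc[f"gene_{g:04d}", "tier"] == "high"
        assert (hits.loc[~hits.index.isin({f"gene_{g:04d}" for g in depleted}),
                         "tier"] == "none").all()
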