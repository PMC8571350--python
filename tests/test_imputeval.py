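"""Aggregate R² pooling, discordance/NRD, and completeness by allele count."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import panelqc as pq
from panelqc.containers import MISSING
from panelqc.imputeval import hard_call, pearson_r2

from conftest import toy_genotypes


def naive_pearson_r2(x, y):
    """Independent two-pass Pearson implementation (oracle)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    denom = np.sqrt((xm**2).sum() * (ym**2).sum())
    if denom == 0:
        return float("nan")
    return float(((xm * ym).sum() / denom) ** 2)


def dosage_matrix(values, variants=None, samples=None):
    arr = np.asarray(values, dtype=np.float64).T
    n, m = arr.shape
    samples = samples or [f"s{i}" for i in range(n)]
    variants = variants or [pq.VariantKey("1", 100 + 10 * j, "A", "G") for j in range(m)]
    return pq.DosageMatrix(samples, variants, arr)


ONE_BIN = pq.BinSpec((0.0, 1.0))


class TestAggregateR2:
    def test_perfect_imputation(self):
        truth = toy_genotypes([[0, 1, 2, 1], [0, 0, 1, 2]])
        ds = dosage_matrix([[0, 1, 2, 1], [0, 0, 1, 2]], variants=truth.variants)
        af = pq.AFTrack.from_genotypes(truth)
        rep = pq.aggregate_r2(ds, truth, af, ONE_BIN)
        assert rep.r2_table["aggregate_r2"].iloc[0] == pytest.approx(1.0)

    def test_toy_matches_pooled_pearson_oracle(self):
        truth = toy_genotypes([[0, 1, 2, 1], [0, 0, 1, 2]])
        ds_vals = [[0.1, 0.9, 1.8, 1.2], [0.0, 0.2, 0.8, 1.9]]
        ds = dosage_matrix(ds_vals, variants=truth.variants)
        af = pq.AFTrack.from_genotypes(truth)
        rep = pq.aggregate_r2(ds, truth, af, ONE_BIN)
        x = [0, 1, 2, 1, 0, 0, 1, 2]
        y = [0.1, 0.9, 1.8, 1.2, 0.0, 0.2, 0.8, 1.9]
        assert rep.r2_table["aggregate_r2"].iloc[0] == pytest.approx(
            naive_pearson_r2(x, y), abs=1e-12
        )
        assert rep.r2_table["n_pairs"].iloc[0] == 8

    def test_penalize_below_intersect_with_truth_only_variant(self):
        truth = toy_genotypes([[0, 1, 2, 1], [0, 0, 1, 2], [0, 0, 1, 2]])
        ds = dosage_matrix(
            [[0.1, 0.9, 1.8, 1.2], [0.0, 0.2, 0.8, 1.9]],
            variants=truth.variants[:2],
        )
        af = pq.AFTrack.from_genotypes(truth)
        pen = pq.aggregate_r2(ds, truth, af, ONE_BIN, mode="penalize")
        inter = pq.aggregate_r2(ds, truth, af, ONE_BIN, mode="intersect")
        assert (
            pen.r2_table["aggregate_r2"].iloc[0]
            < inter.r2_table["aggregate_r2"].iloc[0]
        )
        assert pen.r2_table["n_variants"].iloc[0] == 3
        assert inter.r2_table["n_variants"].iloc[0] == 2

    def test_invariant_to_ordering(self, small_sim):
        truth = small_sim.panel.genotypes()
        ds = pq.corrupt_dosages(truth, 0.8, ONE_BIN, seed=9)
        af = pq.AFTrack.from_genotypes(truth)
        base = pq.aggregate_r2(ds, truth, af, ONE_BIN)
        rng = np.random.default_rng(0)
        perm_s = rng.permutation(truth.n_samples)
        perm_v = rng.permutation(truth.n_variants)
        truth_p = pq.GenotypeMatrix(
            [truth.samples[i] for i in perm_s],
            [truth.variants[j] for j in perm_v],
            truth.gt[np.ix_(perm_s, perm_v)],
        )
        shuffled = pq.aggregate_r2(ds, truth_p, af, ONE_BIN)
        assert base.r2_table["aggregate_r2"].iloc[0] == pytest.approx(
            shuffled.r2_table["aggregate_r2"].iloc[0], abs=1e-12
        )

    def test_zero_variance_bin_undefined(self):
        truth = toy_genotypes([[1, 1, 1, 1]])
        ds = dosage_matrix([[1, 1, 1, 1]], variants=truth.variants)
        af = pq.AFTrack.from_genotypes(truth)
        rep = pq.aggregate_r2(ds, truth, af, ONE_BIN)
        assert np.isnan(rep.r2_table["aggregate_r2"].iloc[0])

    def test_disjoint_samples_raise(self):
        truth = toy_genotypes([[0, 1]], samples=["a", "b"])
        ds = dosage_matrix([[0, 1]], variants=truth.variants, samples=["c", "d"])
        with pytest.raises(ValueError, match="disjoint"):
            pq.aggregate_r2(ds, truth, pq.AFTrack.from_genotypes(truth), ONE_BIN)

    @given(
        st.lists(st.floats(0, 2), min_size=3, max_size=30),
        st.integers(0, 2**31 - 1),
    )
    def test_pearson_matches_naive_oracle(self, ys, seed):
        xs = np.random.default_rng(seed).integers(0, 3, size=len(ys))
        got = pearson_r2(xs, np.asarray(ys))
        want = naive_pearson_r2(xs, ys)
        if np.isnan(want):
            assert np.isnan(got)
        else:
            assert got == pytest.approx(want, abs=1e-10)


class TestHardCall:
    def test_ties_round_down(self):
        assert hard_call(np.array([0.5, 1.5, 0.49, 1.51])).tolist() == [0, 1, 0, 2]


class TestDiscordance:
    def test_identity(self):
        truth = toy_genotypes([[0, 1, 2, 1]])
        ds = dosage_matrix([[0, 1, 2, 1]], variants=truth.variants)
        assert pq.discordance(ds, truth) == (0.0, 0.0)

    def test_toy_hand_count(self):
        # 10 pairs: 6 concordant hom-ref, 4 non-ref-involved with 2 errors
        truth_g = [0, 0, 0, 0, 0, 0, 1, 2, 1, 0]
        call_g = [0, 0, 0, 0, 0, 0, 1, 2, 2, 1]
        truth = toy_genotypes([[g] for g in truth_g], samples=["s"],
                              variants=None)
        ds = dosage_matrix([[g] for g in call_g], variants=truth.variants,
                           samples=["s"])
        overall, nrd = pq.discordance(ds, truth)
        assert overall == pytest.approx(0.2)
        assert nrd == pytest.approx(0.5)

    def test_single_false_positive_het(self):
        truth_g = [0] * 10
        call_g = [0] * 9 + [1]
        truth = toy_genotypes([[g] for g in truth_g], samples=["s"])
        ds = dosage_matrix([[g] for g in call_g], variants=truth.variants,
                           samples=["s"])
        overall, nrd = pq.discordance(ds, truth)
        assert overall == pytest.approx(0.1)
        assert nrd == pytest.approx(1.0)

    def test_nrd_at_least_overall(self, small_sim):
        truth = small_sim.panel.genotypes()
        ds = pq.corrupt_dosages(truth, 0.9, ONE_BIN, seed=10)
        overall, nrd = pq.discordance(ds, truth)
        assert nrd >= overall

    def test_no_comparable_pairs(self):
        truth = toy_genotypes([[MISSING, MISSING]])
        ds = dosage_matrix([[0, 0]], variants=truth.variants)
        with pytest.raises(ValueError):
            pq.discordance(ds, truth)


class TestCompleteness:
    def make_truth(self):
        # 4 samples; ACs: three singletons, two doubletons, two common; mix types
        variants = [
            pq.VariantKey("1", 10, "A", "G"),
            pq.VariantKey("1", 20, "A", "G"),
            pq.VariantKey("1", 30, "A", "AT"),  # indel singleton
            pq.VariantKey("1", 40, "A", "G"),
            pq.VariantKey("1", 50, "AT", "A"),  # indel doubleton
            pq.VariantKey("1", 60, "A", "G"),
            pq.VariantKey("1", 70, "A", "G"),
        ]
        gt = np.array(
            [
                [1, 0, 0, 0],  # AC=1 SNP
                [0, 1, 0, 0],  # AC=1 SNP
                [0, 0, 1, 0],  # AC=1 indel
                [1, 1, 0, 0],  # AC=2 SNP
                [0, 0, 1, 1],  # AC=2 indel
                [2, 1, 1, 0],  # AC=4 SNP
                [1, 1, 1, 1],  # AC=4 SNP
            ],
            dtype=np.int16,
        ).T
        return pq.GenotypeMatrix(["a", "b", "c", "d"], variants, gt)

    def test_superset_panel_is_complete(self):
        truth = self.make_truth()
        table = pq.completeness_by_ac(truth, set(truth.variants))
        defined = table["fraction"].dropna()
        assert (defined == 1.0).all()

    def test_partial_counts(self):
        truth = self.make_truth()
        panel = {truth.variants[0], truth.variants[3], truth.variants[5]}
        table = pq.completeness_by_ac(truth, panel).set_index(["type", "stratum"])
        assert table.loc[("SNP", "AC=1"), "fraction"] == pytest.approx(0.5)
        assert table.loc[("SNP", "AC=2"), "fraction"] == pytest.approx(1.0)
        assert table.loc[("SNP", "AC>2"), "fraction"] == pytest.approx(0.5)
        assert table.loc[("indel", "AC=1"), "fraction"] == pytest.approx(0.0)

    def test_empty_stratum_is_nan_not_zero(self):
        truth = self.make_truth()
        table = pq.completeness_by_ac(truth, set()).set_index(["type", "stratum"])
        assert np.isnan(table.loc[("indel", "AC>2"), "fraction"])
        assert table.loc[("SNP", "AC=1"), "fraction"] == 0.0
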