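"""Generator properties: admixture structure, Mendelian pedigrees,
coverage-dependent calling error, array emulation, dosage corruption."""

import numpy as np
import pytest

import panelqc as pq
from panelqc.containers import MISSING
from panelqc.synthio import PanelSimulation


class TestSimulatePanel:
    def test_mean_admixture_recovered(self):
        sim = pq.simulate_panel(
            pq.CohortSpec(n_samples=500, n_variants=500, chrom_length=5_000_000, seed=7)
        )
        assert abs(sim.african_fraction.mean() - 0.823) < 0.03

    def test_zero_divergence_limit(self):
        sim = pq.simulate_panel(
            pq.CohortSpec(n_samples=5, n_variants=400, chrom_length=400_000,
                          fst=1e-6, seed=3)
        )
        assert np.abs(sim.ancestral_af[0] - sim.ancestral_af[1]).max() < 0.01

    def test_deterministic_given_seed(self):
        spec = pq.CohortSpec(n_samples=20, n_variants=300, chrom_length=300_000, seed=9)
        a, b = pq.simulate_panel(spec), pq.simulate_panel(spec)
        assert (a.panel.haps == b.panel.haps).all()
        assert a.panel.variants == b.panel.variants

    def test_realized_af_tracks_balding_nichols_draws(self, small_sim):
        # haplotypes of a given ancestry are Bernoulli draws from that
        # ancestry's site frequency: agree within 3 binomial SDs (pooled)
        anc = small_sim.local_ancestry
        haps = small_sim.panel.haps
        for pop in (0, 1):
            n_pop = (anc == pop).sum(axis=0)
            ok = n_pop >= 20
            realized = np.where(anc == pop, haps, 0).sum(axis=0)[ok] / n_pop[ok]
            expected = small_sim.ancestral_af[pop][ok]
            sd = np.sqrt(expected * (1 - expected) / n_pop[ok])
            assert (np.abs(realized - expected) < 3 * sd).mean() > 0.98

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            pq.CohortSpec(n_samples=0, n_variants=10)
        with pytest.raises(ValueError):
            pq.CohortSpec(n_samples=5, n_variants=10, fst=1.5)


class TestSimulatePedigree:
    def test_trio_child_is_mendelian(self, pedigree_sim):
        _, ped = pedigree_sim
        gm = ped.panel.genotypes()
        child = gm.gt[gm.sample_index("trio0_child")]
        for parent in ("S0000", "S0001"):
            pg = gm.gt[gm.sample_index(parent)]
            opposite = ((child == 0) & (pg == 2)) | ((child == 2) & (pg == 0))
            assert not opposite.any()

    def test_sib_ibd0_matches_mendelian_expectation(self):
        # IBD0 = both parental transmissions differ; expectation 1/4
        sim = pq.simulate_panel(
            pq.CohortSpec(n_samples=10, n_variants=20_000, chrom_length=20_000_000, seed=4)
        )
        ped = pq.simulate_pedigree(
            sim.panel, pq.PedigreeSpec(n_trios=0, n_duos=0, n_sib_pairs=50,
                                       n_cousin_pairs=0, seed=5)
        )
        fracs = []
        for s in range(50):
            ma, pa = ped.transmissions[f"sib{s}_a"]
            mb, pb = ped.transmissions[f"sib{s}_b"]
            fracs.append(((ma != mb) & (pa != pb)).mean())
        assert abs(np.mean(fracs) - 0.25) < 0.02

    def test_empty_pedigree_returns_panel_unchanged(self, small_sim):
        ped = pq.simulate_pedigree(
            small_sim.panel,
            pq.PedigreeSpec(n_trios=0, n_duos=0, n_sib_pairs=0, n_cousin_pairs=0),
        )
        assert ped.panel is small_sim.panel
        assert ped.truth.empty

    def test_capacity_error(self, small_sim):
        with pytest.raises(ValueError, match="founders"):
            pq.simulate_pedigree(small_sim.panel, pq.PedigreeSpec(n_trios=40, n_duos=0))


class TestSimulateSequencing:
    def test_high_coverage_error_rate(self, small_sim):
        params = pq.SeqSimParams(mean_coverage=60, base_error=0.001)
        called = pq.simulate_sequencing(small_sim.panel, params, seed=11)
        truth = small_sim.panel.genotypes()
        called_mask = called.gt != MISSING
        err = ((called.gt != truth.gt) & called_mask).sum() / called_mask.sum()
        assert err < 1e-3

    def test_low_coverage_inflates_fn_and_genotype_errors_more_than_fp(self, small_sim):
        truth = small_sim.panel.genotypes()
        out = {}
        for cov in (8, 30):
            called = pq.simulate_sequencing(
                small_sim.panel, pq.SeqSimParams(mean_coverage=cov), seed=13
            )
            nonref = truth.gt > 0
            fn = ((called.gt == 0) | (called.gt == MISSING))[nonref].sum()
            geno_err = ((called.gt != truth.gt) & (called.gt > 0) & nonref).sum()
            fp = ((called.gt > 0) & (truth.gt == 0)).sum()
            out[cov] = (fn + geno_err, max(fp, 1))
        ratio_8 = out[8][0] / out[8][1]
        ratio_30 = out[30][0] / out[30][1]
        assert ratio_8 > ratio_30

    def test_near_zero_coverage_mostly_missing(self, small_sim):
        called = pq.simulate_sequencing(
            small_sim.panel, pq.SeqSimParams(mean_coverage=0.01), seed=17
        )
        assert (called.gt == MISSING).mean() > 0.98

    def test_error_rate_monotone_in_coverage(self, small_sim):
        truth = small_sim.panel.genotypes()
        rates = []
        for cov in (4, 10, 25, 60):
            errs = []
            for seed in range(5):
                called = pq.simulate_sequencing(
                    small_sim.panel, pq.SeqSimParams(mean_coverage=cov), seed=seed
                )
                ok = called.gt != MISSING
                errs.append(((called.gt != truth.gt) & ok).sum() / ok.sum())
            rates.append(np.mean(errs))
        assert all(a >= b for a, b in zip(rates, rates[1:]))


class TestEmulateArray:
    def test_identity_when_no_subset_no_error(self, small_sim):
        truth = small_sim.panel.genotypes()
        out = pq.emulate_array(truth, site_fraction=1.0, call_error=0.0, seed=1)
        assert out.variants == truth.variants
        assert (out.gt == truth.gt).all()

    def test_error_count_in_binomial_ci(self, small_sim):
        truth = small_sim.panel.genotypes()  # 60 x 2000 = 120k calls
        out = pq.emulate_array(truth, site_fraction=1.0, call_error=0.01, seed=2)
        n_calls = truth.gt.size
        observed = (out.gt != truth.gt).sum()
        expected = 0.01 * n_calls
        half_width = 2.576 * np.sqrt(n_calls * 0.01 * 0.99)
        assert abs(observed - expected) < half_width

    def test_subset_size(self, small_sim):
        truth = small_sim.panel.genotypes()
        out = pq.emulate_array(truth, site_fraction=0.1, call_error=0.0, seed=3)
        assert out.n_variants == round(0.1 * truth.n_variants)


class TestCorruptDosages:
    def test_target_one_is_exact(self, small_sim):
        truth = small_sim.panel.genotypes()
        ds = pq.corrupt_dosages(truth, 1.0, pq.BinSpec((0.0, 1.0)), seed=4)
        assert (ds.ds == truth.gt).all()

    def test_deterministic(self, small_sim):
        truth = small_sim.panel.genotypes()
        a = pq.corrupt_dosages(truth, 0.7, pq.BinSpec((0.0, 1.0)), seed=5)
        b = pq.corrupt_dosages(truth, 0.7, pq.BinSpec((0.0, 1.0)), seed=5)
        assert (a.ds == b.ds).all()

    def test_per_bin_targets_recovered(self, small_sim):
        truth = small_sim.panel.genotypes()
        bins = pq.BinSpec((0.0, 0.1, 0.3, 1.0))
        targets = [0.95, 0.8, 0.6]
        ds = pq.corrupt_dosages(truth, targets, bins, seed=6)
        af = pq.AFTrack.from_genotypes(truth)
        rep = pq.aggregate_r2(ds, truth, af, bins, mode="intersect")
        for got, want, n in zip(
            rep.r2_table["aggregate_r2"], targets, rep.r2_table["n_pairs"]
        ):
            if n >= 5000:
                assert abs(got - want) < 0.04

    def test_zero_variance_bin_warns(self, toy_warn_matrix=None):
        gt = np.zeros((4, 3), dtype=np.int16)
        gt[:, 0] = [0, 1, 2, 1]  # only first site varies
        matrix = pq.GenotypeMatrix(
            ["a", "b", "c", "d"],
            [pq.VariantKey("1", p, "A", "G") for p in (10, 20, 30)],
            gt,
        )
        with pytest.warns(UserWarning, match="zero genotype variance"):
            pq.corrupt_dosages(matrix, 0.5, pq.BinSpec((0.0, 0.4, 1.0)), seed=1)
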