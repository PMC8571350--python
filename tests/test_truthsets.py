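"""Consensus WGS truth rules and microarray probe-filter curation."""

import numpy as np
import pytest

import panelqc as pq
from panelqc.containers import MISSING
from panelqc.truthsets import PROBE_LENGTH, ProbeRecord, _exact_matches

from conftest import toy_genotypes


def full_region(chrom="1", end=10_000):
    return [pq.Region(chrom, 0, end)]


class TestConsensusWgsTruth:
    def test_identity_when_callers_agree(self):
        gt = [[0, 1, 2, 1, 0], [1, 1, 0, 0, 2]]
        gq = [[99] * 5, [99] * 5]
        a = toy_genotypes(gt, gq=gq)
        b = toy_genotypes(gt, gq=gq)
        ts = pq.consensus_wgs_truth(a, b, confident=full_region())
        assert ts.genotypes.variants == a.variants
        assert (ts.genotypes.gt == a.gt).all()

    def test_disagreement_blanks_then_drops_site(self):
        # 10 samples; at site 0 two samples disagree -> 20% missing > 10%
        gt_a = [[1] * 10, [0, 1] * 5]
        gt_b = [[1] * 8 + [2, 2], [0, 1] * 5]
        gq = [[99] * 10, [99] * 10]
        a = toy_genotypes(gt_a, gq=gq)
        b = toy_genotypes(gt_b, gq=gq)
        ts = pq.consensus_wgs_truth(a, b, max_missing=0.10, confident=full_region())
        assert len(ts.genotypes.variants) == 1
        assert ts.genotypes.variants[0] == a.variants[1]

    def test_low_gq_blanked(self):
        gt = [[1, 1, 1, 1, 1, 1, 1, 1, 1, 1]]
        gq_a = [[99] * 9 + [5]]
        a = toy_genotypes(gt, gq=gq_a)
        b = toy_genotypes(gt, gq=[[99] * 10])
        ts = pq.consensus_wgs_truth(a, b, gq_min=20, max_missing=0.5,
                                    confident=full_region())
        assert ts.genotypes.gt[9, 0] == MISSING

    def test_excluded_region_masks_site(self):
        gt = [[1, 0, 1], [0, 1, 1]]
        a = toy_genotypes(gt, gq=[[99] * 3, [99] * 3])
        b = toy_genotypes(gt, gq=[[99] * 3, [99] * 3])
        # variants sit at pos 100 and 110; exclude [105, 120)
        ts = pq.consensus_wgs_truth(
            a, b, confident=full_region(), exclude=[pq.Region("1", 105, 120)]
        )
        assert [v.pos for v in ts.genotypes.variants] == [100]

    def test_sample_mismatch_raises(self):
        a = toy_genotypes([[0, 1]], samples=["x", "y"])
        b = toy_genotypes([[0, 1]], samples=["x", "z"])
        with pytest.raises(ValueError, match="different samples"):
            pq.consensus_wgs_truth(a, b)

    def test_missingness_invariant(self):
        rng = np.random.default_rng(3)
        gt = rng.integers(0, 3, size=(5, 20))
        gt_b = gt.copy()
        gt_b[rng.random(gt.shape) < 0.1] = 0  # sprinkle disagreements
        a = toy_genotypes(gt.T.tolist(), gq=np.full((20, 5), 99).tolist())
        b = toy_genotypes(gt_b.T.tolist(), gq=np.full((20, 5), 99).tolist())
        ts = pq.consensus_wgs_truth(a, b, max_missing=0.25, confident=full_region())
        if ts.genotypes.n_variants:
            assert (ts.genotypes.missing_fraction() <= 0.25).all()


def build_probe_fixture(with_defects=True, seed=99):
    """Synthetic reference plus 10 probes; when ``with_defects``: one probe
    duplicated elsewhere in the reference (two exact matches), one probe
    footprint overlapping a 2%-AF common variant, and two probes mutually
    overlapping -> 6 survive."""
    rng = np.random.default_rng(seed)
    ref = rng.choice(list("ACGT"), size=4000).tolist()
    starts = [100, 300, 500, 700, 900, 1100, 1300, 1500, 1700, 1720]
    if not with_defects:
        starts[-1] = 1900  # keep all probes disjoint
    probes = []
    keys = []
    for i, s in enumerate(starts):
        target_pos = s + 25  # 1-based, inside the footprint [s+1, s+50]
        ref_base = ref[target_pos - 1]
        alt = {"A": "G", "C": "T", "G": "A", "T": "C"}[ref_base]
        key = pq.VariantKey("1", target_pos, ref_base, alt)
        keys.append(key)
        seq = "".join(ref[s : s + PROBE_LENGTH])
        probes.append(ProbeRecord(f"p{i}", seq, "1", target_pos, key))
    if with_defects:
        # duplicate probe 0's 50-mer far away (no other footprint nearby)
        ref[2500 : 2500 + PROBE_LENGTH] = list(probes[0].sequence)
    reference = {"1": "".join(ref)}
    # cohort & array genotypes: every target polymorphic
    gt = [[0, 1, 1, 2] for _ in keys]
    cohort = toy_genotypes(gt, variants=keys)
    array = toy_genotypes(gt, variants=keys)
    common = {}
    if with_defects:
        # a 2%-AF variant inside probe 1's footprint, distinct from its target
        pos = starts[1] + 10
        base = reference["1"][pos - 1]
        common[pq.VariantKey("1", pos, base, "A" if base != "A" else "C")] = 0.02
    call_rate = {k: 0.99 for k in keys}
    maf = {k: 0.01 for k in keys}
    return array, probes, reference, common, cohort, call_rate, maf


class TestCurateArrayTruth:
    def test_defect_fixture_six_survive(self):
        array, probes, ref, common, cohort, cr, maf = build_probe_fixture()
        ts = pq.curate_array_truth(array, probes, ref, common, cohort, cr, maf)
        survivors = {v.pos for v in ts.genotypes.variants}
        # p0 (two matches), p1 (common-variant overlap), p8+p9 (overlap) drop
        assert len(survivors) == 6
        dropped_positions = {probes[i].vendor_pos for i in (0, 1, 8, 9)}
        assert survivors.isdisjoint(dropped_positions)

    def test_vacuous_filters_keep_all(self):
        array, probes, ref, common, cohort, cr, maf = build_probe_fixture(
            with_defects=False
        )
        ts = pq.curate_array_truth(
            array, probes, ref, {}, cohort, cr, maf,
            min_call_rate=0.0, min_maf=0.0,
        )
        assert ts.genotypes.n_variants == len(probes)

    def test_mismatched_probe_dropped(self):
        array, probes, ref, common, cohort, cr, maf = build_probe_fixture(
            with_defects=False
        )
        seq = probes[0].sequence
        mutated = ("A" if seq[10] != "A" else "C").join([seq[:10], seq[11:]])
        probes[0] = ProbeRecord("p0", mutated, "1", probes[0].vendor_pos,
                                probes[0].target)
        ts = pq.curate_array_truth(array, probes, ref, {}, cohort, cr, maf)
        assert probes[0].vendor_pos not in {v.pos for v in ts.genotypes.variants}

    def test_db_thresholds_monotone(self):
        array, probes, ref, common, cohort, cr, maf = build_probe_fixture(
            with_defects=False
        )
        loose = pq.curate_array_truth(array, probes, ref, {}, cohort, cr, maf,
                                      min_call_rate=0.5)
        tight = pq.curate_array_truth(array, probes, ref, {}, cohort, cr, maf,
                                      min_call_rate=0.995)
        assert set(tight.genotypes.variants) <= set(loose.genotypes.variants)

    def test_confident_regions_cover_all_truth_sites(self):
        array, probes, ref, common, cohort, cr, maf = build_probe_fixture()
        ts = pq.curate_array_truth(array, probes, ref, common, cohort, cr, maf)
        for key in ts.genotypes.variants:
            assert ts.covers(key)

    def test_exact_match_helper_counts_occurrences(self):
        ref = {"1": "AAACGTACGTAAA"}
        assert _exact_matches("ACGT", ref) == [("1", 2), ("1", 6)]
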