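"""Truth-set curation.

Two recipes are implemented:

* a dual-caller WGS consensus truth — intersect two call sets, blank
  disagreements and low-GQ calls, drop high-missingness sites, and restrict
  to confident regions minus an exclusion (e.g. segmental-duplication) mask;
* a microarray-derived truth with probe-level filters — database call-rate
  and MAF gates, cohort polymorphism, unique exact probe alignment
  consistent with vendor coordinates, no common-variant overlap within the
  50-mer probe footprint, and pairwise non-overlapping probes.

Probe "alignment" is emulated as a unique exact full-length substring match
against the supplied reference: at this scale the MAPQ=60 / NM=0 /
no-clipping alignment conditions collapse to exactly that. A hook accepts
precomputed alignment positions for real data. Indel probes are handled
identically to SNP probes by footprint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .containers import MISSING, GenotypeMatrix, Region, TruthSet, VariantKey
from .vcfio import bed_subtract, merge_regions, regions_contain

logger = logging.getLogger(__name__)

PROBE_LENGTH = 50

AUTOSOMES = {str(c) for c in range(1, 23)} | {f"chr{c}" for c in range(1, 23)}


@dataclass(frozen=True)
class ProbeRecord:
    """One microarray probe: its 50-mer sequence, vendor-declared placement,
    and the variant it targets."""

    probe_id: str
    sequence: str
    vendor_chrom: str
    vendor_pos: int
    target: VariantKey

    def __post_init__(self) -> None:
        if len(self.sequence) != PROBE_LENGTH:
            raise ValueError(
                f"probe {self.probe_id}: sequence must be {PROBE_LENGTH}-mer"
            )
        if not set(self.sequence) <= set("ACGT"):
            raise ValueError(f"probe {self.probe_id}: alphabet must be ACGT")


def consensus_wgs_truth(
    calls_a: GenotypeMatrix,
    calls_b: GenotypeMatrix,
    gq_min: int = 20,
    max_missing: float = 0.10,
    confident: Sequence[Region] = (),
    exclude: Sequence[Region] = (),
) -> TruthSet:
    """Dual-caller consensus truth set.

    Site set = intersection of the two callers' variant keys. Per call, the
    genotype is blanked to missing when the callers disagree or either has
    GQ below ``gq_min``; sites whose resulting missing fraction exceeds
    ``max_missing`` are dropped. Sites are finally restricted to
    ``confident`` minus ``exclude``.
    """
    if set(calls_a.samples) != set(calls_b.samples):
        raise ValueError("call sets cover different samples")
    b = calls_b.take_samples(list(calls_a.samples))
    index_b = {k: j for j, k in enumerate(b.variants)}

    keep_keys: list[VariantKey] = []
    cols: list[np.ndarray] = []
    n = calls_a.n_samples
    allowed = (
        bed_subtract(confident, exclude) if confident else []
    )
    for ja, key in enumerate(calls_a.variants):
        jb = index_b.get(key)
        if jb is None:
            continue
        if confident and not regions_contain(allowed, key.chrom, key.pos):
            continue
        ga = calls_a.gt[:, ja]
        gb = b.gt[:, jb]
        gt = np.where((ga == gb) & (ga != MISSING), ga, MISSING).astype(np.int16)
        for calls, j in ((calls_a, ja), (b, jb)):
            if calls.gq is not None:
                low = (calls.gq[:, j] == MISSING) | (calls.gq[:, j] < gq_min)
                gt = np.where(low, MISSING, gt).astype(np.int16)
        if (gt == MISSING).mean() > max_missing:
            continue
        keep_keys.append(key)
        cols.append(gt)

    gt = np.stack(cols, axis=1) if cols else np.empty((n, 0), dtype=np.int16)
    matrix = GenotypeMatrix(list(calls_a.samples), keep_keys, gt)
    return TruthSet(genotypes=matrix, confident_regions=list(allowed))


def _exact_matches(sequence: str, reference: Mapping[str, str]) -> list[tuple[str, int]]:
    """All (chrom, 0-based start) exact full-length occurrences."""
    hits = []
    for chrom, seq in reference.items():
        start = seq.upper().find(sequence)
        while start != -1:
            hits.append((chrom, start))
            start = seq.upper().find(sequence, start + 1)
    return hits


def curate_array_truth(
    array: GenotypeMatrix,
    probes: Sequence[ProbeRecord],
    reference: Mapping[str, str],
    common_variants: Mapping[VariantKey, float],
    cohort: GenotypeMatrix,
    db_call_rate: Mapping[VariantKey, float],
    db_maf: Mapping[VariantKey, float],
    min_call_rate: float = 0.90,
    min_maf: float = 1e-5,
    common_af_threshold: float = 0.01,
    alignments: Mapping[str, tuple[str, int]] | None = None,
) -> TruthSet:
    """Microarray truth with probe-level filters; see module docstring.

    ``alignments`` optionally supplies precomputed (chrom, 0-based start)
    probe placements in place of the exact-substring emulation. Confident
    regions are derived from every surviving genotyped position (hom-ref
    calls contribute confident region only; the genotype matrix itself
    retains all surviving sites).
    """
    cohort_ac = dict(zip(cohort.variants, cohort.alt_allele_count()))
    cohort_called = dict(
        zip(cohort.variants, (cohort.gt != MISSING).sum(axis=0))
    )

    # per-probe footprints for the chip-level overlap rule
    footprints: dict[str, tuple[str, int, int]] = {}
    unique_match: dict[str, tuple[str, int]] = {}
    for p in probes:
        if alignments is not None and p.probe_id in alignments:
            chrom, start = alignments[p.probe_id]
            hits = [(chrom, start)]
        else:
            hits = _exact_matches(p.sequence, reference)
        if len(hits) == 1:
            unique_match[p.probe_id] = hits[0]
            chrom, start = hits[0]
            footprints[p.probe_id] = (chrom, start, start + PROBE_LENGTH)

    overlapping: set[str] = set()
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for pid, (chrom, s, e) in footprints.items():
        by_chrom.setdefault(chrom, []).append((s, e, pid))
    for ivs in by_chrom.values():
        ivs.sort()
        for (s1, e1, p1), (s2, e2, p2) in zip(ivs, ivs[1:]):
            if s2 < e1:  # both members of an overlapping pair are dropped
                overlapping.update((p1, p2))

    surviving: list[ProbeRecord] = []
    for p in probes:
        key = p.target
        if key.chrom not in AUTOSOMES:
            continue
        if db_call_rate.get(key, 0.0) < min_call_rate:
            continue
        if db_maf.get(key, 0.0) < min_maf:
            continue
        ac = cohort_ac.get(key, 0)
        called = cohort_called.get(key, 0)
        mac = min(ac, 2 * called - ac)
        if mac < 1:
            continue
        if p.probe_id not in unique_match:
            continue  # zero or multiple exact matches
        chrom, start = unique_match[p.probe_id]
        if chrom != p.vendor_chrom or not (start + 1 <= p.vendor_pos <= start + PROBE_LENGTH):
            continue  # alignment inconsistent with vendor coordinates
        lo, hi = start + 1, start + PROBE_LENGTH  # 1-based inclusive footprint
        if any(
            k.chrom == chrom and lo <= k.pos <= hi and k != key and af > common_af_threshold
            for k, af in common_variants.items()
        ):
            continue
        if p.probe_id in overlapping:
            continue
        surviving.append(p)

    target_keys = {p.target for p in surviving}
    keep = [j for j, k in enumerate(array.variants) if k in target_keys]
    matrix = array.take_variants(np.asarray(keep, dtype=int))
    confident = merge_regions(
        Region(k.chrom, k.pos - 1, k.pos - 1 + len(k.ref)) for k in matrix.variants
    ) if matrix.n_variants else []
    logger.info("array truth: %d/%d probes survive", len(surviving), len(probes))
    return TruthSet(genotypes=matrix, confident_regions=confident)
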