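"""Per-sample genotype benchmarking against a curated truth set.

Implements the confusion-count bookkeeping used by hap.py-style
benchmarking, at position/key-level matching (no haplotype-aware
realignment of complex representations — variants are expected left-aligned
and multiallelic-split before comparison):

* TP — query record matches a truth record's key and genotype;
* FP.gt — key matches, genotype differs;
* FP.al — position matches, alleles differ (consumes both records);
* FN — truth record with no query record at its key or position;
* spurious FP — query non-ref record with no truth record;
* FP = FP.gt + FP.al + spurious.

Recall = TP/(TP+FN), precision = TP/(TP+FP), F1 the harmonic mean of the
two. Strata are SNP (both alleles length 1) vs indel.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .containers import GenotypeMatrix, TruthSet
from .vcfio import regions_contain


@dataclass
class BenchReport:
    stratum: str
    tp: int = 0
    fn: int = 0
    fp: int = 0
    fp_gt: int = 0
    fp_al: int = 0

    @property
    def recall(self) -> float | None:
        r, _, _ = prf1(self.tp, self.fn, self.fp)
        return r

    @property
    def precision(self) -> float | None:
        _, p, _ = prf1(self.tp, self.fn, self.fp)
        return p

    @property
    def f1(self) -> float | None:
        _, _, f = prf1(self.tp, self.fn, self.fp)
        return f


def prf1(tp: int, fn: int, fp: int) -> tuple[float | None, float | None, float | None]:
    """(recall, precision, F1); a metric with a zero denominator is None."""
    for v in (tp, fn, fp):
        if v < 0 or int(v) != v:
            raise ValueError("counts must be nonnegative integers")
    recall = tp / (tp + fn) if tp + fn > 0 else None
    precision = tp / (tp + fp) if tp + fp > 0 else None
    f1 = (
        2.0 * precision * recall / (precision + recall)
        if recall is not None and precision is not None and (precision + recall) > 0
        else None
    )
    return recall, precision, f1


def compare_sample(
    query: GenotypeMatrix, truth: TruthSet
) -> dict[str, BenchReport]:
    """Benchmark one sample's calls against a single-sample truth set.

    Both inputs are restricted to the truth's confident regions before
    counting. Only non-reference, non-missing records participate. Returns
    reports for strata ``SNP`` and ``indel``.
    """
    if query.n_samples != 1 or truth.genotypes.n_samples != 1:
        raise ValueError("compare_sample expects single-sample inputs")
    regions = truth.confident_regions

    def confident_nonref(matrix: GenotypeMatrix) -> dict:
        records = {}
        for j, key in enumerate(matrix.variants):
            g = int(matrix.gt[0, j])
            if g not in (1, 2):
                continue
            if regions and not regions_contain(regions, key.chrom, key.pos):
                continue
            if key in records:
                raise ValueError(f"duplicate record at {key}; normalize first")
            records[key] = g
        return records

    t_rec = confident_nonref(truth.genotypes)
    q_rec = confident_nonref(query)

    reports = {"SNP": BenchReport("SNP"), "indel": BenchReport("indel")}

    def stratum(key) -> BenchReport:
        return reports["SNP" if key.is_snp else "indel"]

    matched_q = set()
    unmatched_truth = []
    for key, g in t_rec.items():
        if key in q_rec:
            matched_q.add(key)
            if q_rec[key] == g:
                stratum(key).tp += 1
            else:
                stratum(key).fp_gt += 1
        else:
            unmatched_truth.append(key)

    # allele mismatches: greedy one-to-one position-level pairing
    q_by_pos = {}
    for key in q_rec:
        if key not in matched_q:
            q_by_pos.setdefault((key.chrom, key.pos), []).append(key)
    for key in unmatched_truth:
        candidates = q_by_pos.get((key.chrom, key.pos))
        if candidates:
            qkey = candidates.pop(0)
            matched_q.add(qkey)
            stratum(key).fp_al += 1
        else:
            stratum(key).fn += 1

    for key in q_rec:
        if key not in matched_q:
            stratum(key).fp += 1  # spurious call

    for rep in reports.values():
        rep.fp += rep.fp_gt + rep.fp_al
    return reports


def report_table(reports: dict[str, BenchReport], caller: str = "query") -> pd.DataFrame:
    """Tabulate reports in Table-style columns (one row per stratum)."""
    rows = []
    for rep in reports.values():
        rows.append(
            {
                "Caller": caller,
                "Type": rep.stratum,
                "F1": rep.f1,
                "Recall": rep.recall,
                "Precision": rep.precision,
                "TP": rep.tp,
                "FN": rep.fn,
                "FP": rep.fp,
                "FP.gt": rep.fp_gt,
                "FP.al": rep.fp_al,
            }
        )
    return pd.DataFrame(rows)
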