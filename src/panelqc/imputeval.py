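"""Imputation-accuracy evaluation: allele-frequency-binned aggregate R²,
genotype discordance, non-reference discordance, and panel completeness by
allele count.

"Aggregate R²" is the squared Pearson correlation between *pooled* imputed
dosages and truth hard genotypes across every (sample, variant) pair whose
variant falls in an allele-frequency bin — not a mean of per-variant R²
values. Two modes are supported: ``penalize`` treats truth variants absent
from the imputed set as imputed to homozygous reference (dosage 0.0),
penalizing panels with missing variation; ``intersect`` evaluates only truth
variants present in the imputed set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import MISSING, DosageMatrix, GenotypeMatrix, VariantKey

logger = logging.getLogger(__name__)

#: Default alt-AF bin edges, half-open [lo, hi) with the last bin closed.
DEFAULT_BIN_EDGES = (
    0.0, 1e-4, 2e-4, 5e-4, 1e-3, 2e-3, 5e-3,
    0.01, 0.02, 0.05, 0.1, 0.2, 0.5, 1.0,
)


@dataclass(frozen=True)
class BinSpec:
    """Ascending alt-allele-frequency breakpoints; bins are [lo, hi) except
    the last, which includes its upper edge."""

    edges: tuple = DEFAULT_BIN_EDGES

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=np.float64)
        if e.size < 2 or np.any(np.diff(e) <= 0):
            raise ValueError("edges must be strictly increasing with >= 2 values")
        if e[0] < 0 or e[-1] > 1:
            raise ValueError("edges must lie in [0, 1]")

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    def assign(self, af) -> np.ndarray:
        """Bin index per AF value; -1 for NaN or out-of-range."""
        af = np.asarray(af, dtype=np.float64)
        e = np.asarray(self.edges)
        idx = np.searchsorted(e, af, side="right") - 1
        idx[af == e[-1]] = self.n_bins - 1  # close the last bin
        bad = ~np.isfinite(af) | (af < e[0]) | (af > e[-1])
        idx[bad] = -1
        return idx

    def label(self, b: int) -> str:
        return f"[{self.edges[b]:g},{self.edges[b + 1]:g})"


class AFTrack(dict):
    """Map VariantKey -> alt allele frequency (an external AF annotation)."""

    @classmethod
    def from_genotypes(cls, matrix: GenotypeMatrix) -> "AFTrack":
        af = matrix.alt_allele_frequency()
        return cls(
            {k: float(a) for k, a in zip(matrix.variants, af) if np.isfinite(a)}
        )

    @classmethod
    def read_tsv(cls, path: str | Path) -> "AFTrack":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        return cls(
            {
                VariantKey(r.chrom, int(r.pos), r.ref, r.alt): float(r.af)
                for r in df.itertuples()
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        rows = [
            {"chrom": k.chrom, "pos": k.pos, "ref": k.ref, "alt": k.alt, "af": v}
            for k, v in sorted(self.items())
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass
class EvalReport:
    """Collected evaluation outputs; fields filled by the respective ops."""

    r2_table: pd.DataFrame | None = None
    genotype_discordance: float | None = None
    non_ref_discordance: float | None = None
    completeness: pd.DataFrame | None = None
    n_dropped_no_af: int = 0
    bin_edges: tuple = field(default_factory=tuple)


def _common_samples(truth: GenotypeMatrix, dosages: DosageMatrix) -> list[str]:
    shared = [s for s in truth.samples if s in set(dosages.samples)]
    if not shared:
        raise ValueError("truth and dosage sample sets are disjoint")
    return shared


def aggregate_r2(
    dosages: DosageMatrix,
    truth: GenotypeMatrix,
    af: AFTrack,
    bins: BinSpec | None = None,
    mode: str = "penalize",
) -> EvalReport:
    """Pooled squared Pearson correlation per allele-frequency bin.

    Truth variants without an AF annotation are dropped (count logged and
    reported). Missing truth genotypes are skipped pairwise. Bins where
    either pooled vector has zero variance report NaN.
    """
    if mode not in ("penalize", "intersect"):
        raise ValueError(f"mode must be penalize|intersect, got {mode!r}")
    bins = bins or BinSpec()
    shared = _common_samples(truth, dosages)
    t = truth.take_samples(shared)
    d_index = dosages.key_index()
    d_rows = [dosages.samples.index(s) for s in shared]
    ds = dosages.ds[d_rows, :]

    af_vals = np.array([af.get(k, np.nan) for k in t.variants])
    n_dropped = int(np.sum(~np.isfinite(af_vals)))
    if n_dropped:
        logger.info("dropping %d truth variants with no AF annotation", n_dropped)
    bin_of = bins.assign(af_vals)

    pooled_t: list[list[np.ndarray]] = [[] for _ in range(bins.n_bins)]
    pooled_d: list[list[np.ndarray]] = [[] for _ in range(bins.n_bins)]
    n_var = np.zeros(bins.n_bins, dtype=int)
    for j, key in enumerate(t.variants):
        b = bin_of[j]
        if b < 0:
            continue
        col = d_index.get(key)
        if col is None:
            if mode == "intersect":
                continue
            dose = np.zeros(len(shared))  # absent => imputed hom-ref
        else:
            dose = ds[:, col]
        called = t.gt[:, j] != MISSING
        if not called.any():
            continue
        pooled_t[b].append(t.gt[called, j].astype(np.float64))
        pooled_d[b].append(dose[called])
        n_var[b] += 1

    rows = []
    for b in range(bins.n_bins):
        if pooled_t[b]:
            x = np.concatenate(pooled_t[b])
            y = np.concatenate(pooled_d[b])
            r2 = pearson_r2(x, y)
            n_pairs = x.size
        else:
            r2, n_pairs = np.nan, 0
        rows.append(
            {
                "bin": bins.label(b),
                "af_lo": bins.edges[b],
                "af_hi": bins.edges[b + 1],
                "n_variants": n_var[b],
                "n_pairs": n_pairs,
                "aggregate_r2": r2,
            }
        )
    return EvalReport(
        r2_table=pd.DataFrame(rows),
        n_dropped_no_af=n_dropped,
        bin_edges=tuple(bins.edges),
    )


def pearson_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation; NaN when either vector is constant."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def hard_call(ds: np.ndarray) -> np.ndarray:
    """Round dosages to {0,1,2}; ties at x.5 round toward the smaller genotype."""
    return np.clip(np.ceil(np.asarray(ds) - 0.5), 0, 2).astype(np.int16)


def discordance(
    dosages: DosageMatrix, truth: GenotypeMatrix
) -> tuple[float, float]:
    """(overall genotype discordance, non-reference discordance).

    Dosages are hard-called; comparisons run over the truth/dosage variant
    intersection, skipping missing truth calls. NRD excludes comparisons
    where both truth and call are homozygous reference from numerator and
    denominator.
    """
    shared = _common_samples(truth, dosages)
    t = truth.take_samples(shared)
    d_index = dosages.key_index()
    d_rows = [dosages.samples.index(s) for s in shared]

    cols_t, cols_d = [], []
    for j, key in enumerate(t.variants):
        col = d_index.get(key)
        if col is not None:
            cols_t.append(j)
            cols_d.append(col)
    if not cols_t:
        raise ValueError("no shared variants between truth and dosages")
    g = t.gt[:, cols_t]
    calls = hard_call(dosages.ds[np.ix_(d_rows, cols_d)])
    ok = g != MISSING
    if not ok.any():
        raise ValueError("no comparable genotype pairs")
    mismatch = (g != calls) & ok
    overall = float(mismatch.sum() / ok.sum())
    nonref = ok & ((g > 0) | (calls > 0))
    nrd = float(mismatch[nonref].sum() / nonref.sum()) if nonref.any() else float("nan")
    return overall, nrd


def completeness_by_ac(
    truth: GenotypeMatrix, panel_sites: set[VariantKey]
) -> pd.DataFrame:
    """Fraction of truth variants present in a panel, stratified by truth
    allele count (1, 2, >2) and variant type (SNP vs indel).

    Empty strata report NaN, not zero.
    """
    ac = truth.alt_allele_count()
    rows = []
    for vtype, is_type in (
        ("SNP", lambda k: k.is_snp),
        ("indel", lambda k: not k.is_snp),
    ):
        for label, lo, hi in (("AC=1", 1, 1), ("AC=2", 2, 2), ("AC>2", 3, np.inf)):
            keys = [
                k
                for k, a in zip(truth.variants, ac)
                if is_type(k) and lo <= a <= hi
            ]
            frac = (
                sum(k in panel_sites for k in keys) / len(keys) if keys else np.nan
            )
            rows.append(
                {"type": vtype, "stratum": label, "n_truth": len(keys), "fraction": frac}
            )
    return pd.DataFrame(rows)


def evaluate_imputation(
    dosages: DosageMatrix,
    truth: GenotypeMatrix,
    af: AFTrack,
    bins: BinSpec | None = None,
    mode: str = "penalize",
    panel_sites: set[VariantKey] | None = None,
) -> EvalReport:
    """Run the full evaluation: binned aggregate R², discordance/NRD, and
    (when ``panel_sites`` is given) completeness by allele count."""
    report = aggregate_r2(dosages, truth, af, bins, mode)
    overall, nrd = discordance(dosages, truth)
    report.genotype_discordance = overall
    report.non_ref_discordance = nrd
    if panel_sites is not None:
        report.completeness = completeness_by_ac(truth, panel_sites)
    return report
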