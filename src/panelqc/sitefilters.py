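"""Panel variant-level filters: singleton removal, missingness, the exact
Hardy-Weinberg test, and the GQ-based expected-correct-genotype statistic.

Two presets mirror the two panel recipes this package models: ``dvglx``
(drop singletons; missingness <= 20%; HWE exact p >= 1e-20; expected correct
>= 60%) and ``gatk`` (drop singletons; missingness <= 10%; no HWE or GQ
rule).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .containers import MISSING, GenotypeMatrix


@dataclass(frozen=True)
class FilterThresholds:
    hwe_min_p: float = 1e-20
    max_missing: float = 0.20
    min_expected_correct: float = 0.60
    drop_singletons: bool = True

    def __post_init__(self) -> None:
        for name in ("hwe_min_p", "max_missing", "min_expected_correct"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


PRESETS = {
    "dvglx": FilterThresholds(1e-20, 0.20, 0.60, True),
    "gatk": FilterThresholds(0.0, 0.10, 0.0, True),
}


@lru_cache(maxsize=100_000)
def _hwe_het_distribution(n: int, n_alt: int) -> tuple[np.ndarray, np.ndarray]:
    """Conditional distribution of the heterozygote count given allele counts.

    Returns (feasible het counts, their probabilities) under random pairing
    of n_alt alt and 2n - n_alt ref alleles into n genotypes.
    """
    n_ref = 2 * n - n_alt
    max_het = min(n_alt, n_ref)
    hets = np.arange(n_alt % 2, max_het + 1, 2)  # het count shares n_alt's parity
    n_aa = (n_alt - hets) // 2
    n_AA = (n_ref - hets) // 2
    logp = (
        gammaln(n + 1)
        - gammaln(n_AA + 1)
        - gammaln(hets + 1)
        - gammaln(n_aa + 1)
        + hets * np.log(2.0)
        + gammaln(n_alt + 1)
        + gammaln(n_ref + 1)
        - gammaln(2 * n + 1)
    )
    p = np.exp(logp - logp.max())
    p /= p.sum()
    return hets, p


def hwe_exact_pvalue(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value (probability-ordered,
    two-sided): the summed probability of all heterozygote configurations no
    more probable than the observed one, given the observed allele counts.
    """
    for v in (n_AA, n_Aa, n_aa):
        if v < 0 or int(v) != v:
            raise ValueError("genotype counts must be nonnegative integers")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("at least one genotyped sample required")
    n_alt = n_Aa + 2 * n_aa
    hets, probs = _hwe_het_distribution(int(n), int(n_alt))
    p_obs = probs[np.searchsorted(hets, n_Aa)]
    # relative tolerance guards float ties in the probability ordering
    return float(min(1.0, probs[probs <= p_obs * (1.0 + 1e-9)].sum()))


def expected_correct_fraction(gq_values) -> float:
    """Mean of 1 - 10^(-GQ/10) over the given (non-missing) calls."""
    gq = np.asarray(gq_values, dtype=np.float64)
    if gq.size == 0:
        raise ValueError("no genotype calls with GQ")
    if (gq < 0).any():
        raise ValueError("GQ must be >= 0")
    return float(np.mean(1.0 - 10.0 ** (-gq / 10.0)))


def site_statistics(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Per-site genotype counts, AC/AF, missingness, HWE p and expected-correct."""
    n_AA, n_Aa, n_aa, n_missing = matrix.genotype_counts()
    ac = matrix.alt_allele_count()
    af = matrix.alt_allele_frequency()
    missing_frac = matrix.missing_fraction()
    hwe_p = np.array(
        [
            hwe_exact_pvalue(int(a), int(h), int(b)) if a + h + b > 0 else np.nan
            for a, h, b in zip(n_AA, n_Aa, n_aa)
        ]
    )
    ec = np.full(matrix.n_variants, np.nan)
    if matrix.gq is not None:
        for j in range(matrix.n_variants):
            called = (matrix.gt[:, j] != MISSING) & (matrix.gq[:, j] != MISSING)
            if called.any():
                ec[j] = expected_correct_fraction(matrix.gq[called, j])
    return pd.DataFrame(
        {
            "key": [str(v) for v in matrix.variants],
            "n_AA": n_AA,
            "n_Aa": n_Aa,
            "n_aa": n_aa,
            "n_missing": n_missing,
            "ac": ac,
            "af": af,
            "missing_frac": missing_frac,
            "hwe_p": hwe_p,
            "expected_correct": ec,
        }
    )


def filter_panel_sites(
    matrix: GenotypeMatrix, th: FilterThresholds
) -> tuple[np.ndarray, list[list[str]]]:
    """Apply the panel site filters; returns (pass mask, failing reasons per site).

    A site fails iff any rule fires: singleton (AC == 1, when enabled),
    missingness above ``max_missing``, HWE exact p below ``hwe_min_p``, or
    expected-correct below ``min_expected_correct`` (skipped when the matrix
    carries no GQ). Reasons list every rule that fired.
    """
    stats = site_statistics(matrix)
    reasons: list[list[str]] = []
    for j in range(matrix.n_variants):
        row = stats.iloc[j]
        why = []
        if th.drop_singletons and row["ac"] == 1:
            why.append("singleton")
        if row["missing_frac"] > th.max_missing:
            why.append("missingness")
        if np.isfinite(row["hwe_p"]) and row["hwe_p"] < th.hwe_min_p:
            why.append("hwe")
        if np.isfinite(row["expected_correct"]) and (
            row["expected_correct"] < th.min_expected_correct
        ):
            why.append("expected_correct")
        reasons.append(why)
    mask = np.array([not r for r in reasons], dtype=bool)
    return mask, reasons


def site_report(matrix: GenotypeMatrix, th: FilterThresholds) -> pd.DataFrame:
    """Site statistics joined with pass/fail and reasons, ready for TSV export."""
    stats = site_statistics(matrix)
    mask, reasons = filter_panel_sites(matrix, th)
    stats["pass"] = mask
    stats["reasons"] = [";".join(r) for r in reasons]
    return stats
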