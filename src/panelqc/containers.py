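"""In-memory containers shared by every pipeline stage.

Conventions
-----------
* Genotypes are alt-allele counts ``0/1/2``; ``-1`` marks a missing call.
* VCF positions are 1-based; :class:`Region` is 0-based half-open (BED).
* A :class:`HaplotypePanel` stores two phased haplotype rows per sample,
  rows ``2*i`` and ``2*i + 1`` belonging to sample ``i``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MISSING = -1

_ALLELE_ALPHABET = set("ACGT")


@dataclass(frozen=True, order=True)
class VariantKey:
    """Site identity: chromosome, 1-based position, ref and alt allele."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("alleles must be non-empty")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        for allele in (self.ref, self.alt):
            if not set(allele) <= _ALLELE_ALPHABET:
                raise ValueError(f"allele {allele!r} not uppercase ACGT")

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass(frozen=True, order=True)
class Region:
    """0-based half-open genomic interval ``[start, end)``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains_pos(self, pos: int) -> bool:
        """Membership of a 1-based VCF position."""
        return self.start <= pos - 1 < self.end


def _as_matrix(arr, n_samples: int, n_variants: int, dtype) -> np.ndarray:
    out = np.asarray(arr, dtype=dtype)
    if out.shape != (n_samples, n_variants):
        raise ValueError(
            f"expected shape {(n_samples, n_variants)}, got {out.shape}"
        )
    return out


@dataclass
class GenotypeMatrix:
    """Samples x variants hard genotypes with optional per-call GQ and DP.

    ``gt`` holds alt-allele counts with :data:`MISSING` for no-calls; ``gq``
    and ``dp`` use :data:`MISSING` where the field is absent.
    """

    samples: list[str]
    variants: list[VariantKey]
    gt: np.ndarray
    gq: np.ndarray | None = None
    dp: np.ndarray | None = None

    def __post_init__(self) -> None:
        n, m = len(self.samples), len(self.variants)
        self.gt = _as_matrix(self.gt, n, m, np.int16)
        if self.gq is not None:
            self.gq = _as_matrix(self.gq, n, m, np.int32)
        if self.dp is not None:
            self.dp = _as_matrix(self.dp, n, m, np.int32)
        if len(set(self.samples)) != n:
            raise ValueError("duplicate sample ids")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.samples.index(sample_id)
        except ValueError:
            raise KeyError(f"sample {sample_id!r} not in matrix") from None

    def take_variants(self, mask_or_index) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            samples=list(self.samples),
            variants=[self.variants[i] for i in idx],
            gt=self.gt[:, idx],
            gq=None if self.gq is None else self.gq[:, idx],
            dp=None if self.dp is None else self.dp[:, idx],
        )

    def take_samples(self, sample_ids: list[str]) -> "GenotypeMatrix":
        rows = [self.sample_index(s) for s in sample_ids]
        return GenotypeMatrix(
            samples=list(sample_ids),
            variants=list(self.variants),
            gt=self.gt[rows, :],
            gq=None if self.gq is None else self.gq[rows, :],
            dp=None if self.dp is None else self.dp[rows, :],
        )

    # --- per-site summaries (missing calls excluded throughout) ---

    def genotype_counts(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(n_AA, n_Aa, n_aa, n_missing) per variant."""
        gt = self.gt
        return (
            (gt == 0).sum(axis=0),
            (gt == 1).sum(axis=0),
            (gt == 2).sum(axis=0),
            (gt == MISSING).sum(axis=0),
        )

    def alt_allele_count(self) -> np.ndarray:
        gt = np.where(self.gt == MISSING, 0, self.gt)
        return gt.sum(axis=0)

    def alt_allele_frequency(self) -> np.ndarray:
        """Alt AF over non-missing calls; NaN where every call is missing."""
        called = (self.gt != MISSING).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(called > 0, self.alt_allele_count() / (2.0 * called), np.nan)

    def missing_fraction(self) -> np.ndarray:
        return (self.gt == MISSING).mean(axis=0)


@dataclass
class HaplotypePanel:
    """Phased binary haplotypes, two rows per sample, over ordered variants."""

    samples: list[str]
    variants: list[VariantKey]
    haps: np.ndarray  # (2 * n_samples, n_variants) in {0, 1}

    def __post_init__(self) -> None:
        self.haps = _as_matrix(self.haps, 2 * len(self.samples), len(self.variants), np.int8)
        bad = (self.haps != 0) & (self.haps != 1)
        if bad.any():
            raise ValueError("haplotype alleles must be 0/1")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def positions(self) -> np.ndarray:
        return np.asarray([v.pos for v in self.variants], dtype=np.int64)

    def sample_haps(self, i: int) -> np.ndarray:
        return self.haps[2 * i : 2 * i + 2]

    def genotypes(self) -> GenotypeMatrix:
        gt = (self.haps[0::2] + self.haps[1::2]).astype(np.int16)
        return GenotypeMatrix(list(self.samples), list(self.variants), gt)

    def take_variants(self, mask_or_index) -> "HaplotypePanel":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return HaplotypePanel(
            list(self.samples), [self.variants[i] for i in idx], self.haps[:, idx]
        )


@dataclass
class DosageMatrix:
    """Imputed alt-allele dosages in [0, 2], samples x variants."""

    samples: list[str]
    variants: list[VariantKey]
    ds: np.ndarray

    def __post_init__(self) -> None:
        self.ds = _as_matrix(self.ds, len(self.samples), len(self.variants), np.float64)
        if np.nanmin(self.ds, initial=0.0) < 0 or np.nanmax(self.ds, initial=0.0) > 2:
            raise ValueError("dosages must lie in [0, 2]")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def key_index(self) -> dict[VariantKey, int]:
        return {k: j for j, k in enumerate(self.variants)}


@dataclass
class TruthSet:
    """Benchmark truth: genotypes plus the confident regions they cover."""

    genotypes: GenotypeMatrix
    confident_regions: list[Region] = field(default_factory=list)

    def covers(self, key: VariantKey) -> bool:
        return any(
            r.chrom == key.chrom and r.contains_pos(key.pos)
            for r in self.confident_regions
        )
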