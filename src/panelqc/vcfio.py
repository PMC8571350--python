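"""VCF / BED input-output and interval arithmetic.

Reading goes through :mod:`cyvcf2`; writing emits plain-text VCFv4.2 with the
FORMAT fields the pipeline uses (GT, GQ, DP, DS) and an AF INFO field.
Multiallelic records are split into biallelic keys on read, recoding each
sample genotype as the count of the focal alt allele.

Coordinate conventions: VCF positions are 1-based, all interval math is
0-based half-open (BED).
"""

from __future__ import annotations

import logging
from collections import defaultdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml
from cyvcf2 import VCF

from .containers import (
    MISSING,
    DosageMatrix,
    GenotypeMatrix,
    HaplotypePanel,
    Region,
    VariantKey,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Interval arithmetic (0-based half-open)
# ---------------------------------------------------------------------------

def merge_regions(regions: Iterable[Region]) -> list[Region]:
    """Sort and merge touching/overlapping intervals per chromosome."""
    by_chrom: dict[str, list[Region]] = defaultdict(list)
    for r in regions:
        by_chrom[r.chrom].append(r)
    out: list[Region] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda r: (r.start, r.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for r in ivs[1:]:
            if r.start <= cur_end:
                cur_end = max(cur_end, r.end)
            else:
                out.append(Region(chrom, cur_start, cur_end))
                cur_start, cur_end = r.start, r.end
        out.append(Region(chrom, cur_start, cur_end))
    return out


def bed_subtract(a: Iterable[Region], b: Iterable[Region]) -> list[Region]:
    """Regions of ``a`` not covered by ``b``; output merged and sorted."""
    a = merge_regions(a)
    b_by_chrom: dict[str, list[Region]] = defaultdict(list)
    for r in merge_regions(b):
        b_by_chrom[r.chrom].append(r)
    out: list[Region] = []
    for r in a:
        cursor = r.start
        for cut in b_by_chrom.get(r.chrom, []):
            if cut.end <= cursor or cut.start >= r.end:
                continue
            if cut.start > cursor:
                out.append(Region(r.chrom, cursor, cut.start))
            cursor = max(cursor, cut.end)
            if cursor >= r.end:
                break
        if cursor < r.end:
            out.append(Region(r.chrom, cursor, r.end))
    return out


def bed_intersect(a: Iterable[Region], b: Iterable[Region]) -> list[Region]:
    """Regions covered by both ``a`` and ``b``; output merged and sorted."""
    a = merge_regions(a)
    b_by_chrom: dict[str, list[Region]] = defaultdict(list)
    for r in merge_regions(b):
        b_by_chrom[r.chrom].append(r)
    out: list[Region] = []
    for r in a:
        for other in b_by_chrom.get(r.chrom, []):
            lo, hi = max(r.start, other.start), min(r.end, other.end)
            if lo < hi:
                out.append(Region(r.chrom, lo, hi))
    return merge_regions(out) if out else []


def regions_contain(regions: Sequence[Region], chrom: str, pos: int) -> bool:
    """Membership of a 1-based position in a region list."""
    return any(r.chrom == chrom and r.contains_pos(pos) for r in regions)


# ---------------------------------------------------------------------------
# Variant normalization
# ---------------------------------------------------------------------------

def left_align(key: VariantKey, refseq: str) -> VariantKey:
    """Left-align an indel against a reference sequence for its chromosome.

    ``refseq`` is the full chromosome sequence (1-based addressing via
    ``refseq[pos - 1]``). SNPs and already-minimal alleles pass through after
    shared prefix/suffix trimming.
    """
    pos, ref, alt = key.pos, key.ref.upper(), key.alt.upper()
    while True:
        if len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]  # trim shared suffix
        elif ref[-1] == alt[-1] and pos > 1:
            prev = refseq[pos - 2].upper()  # shift left through the reference
            ref, alt, pos = prev + ref[:-1], prev + alt[:-1], pos - 1
        else:
            break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt, pos = ref[1:], alt[1:], pos + 1  # trim shared prefix
    return VariantKey(key.chrom, pos, ref, alt)


# ---------------------------------------------------------------------------
# VCF reading
# ---------------------------------------------------------------------------

def _split_record(variant, n_alts: int):
    """Yield (alt_index, per-sample alt-count vector) for each alt allele."""
    geno = np.asarray([g[:2] for g in variant.genotypes], dtype=np.int32)
    for k in range(1, n_alts + 1):
        counts = (geno == k).sum(axis=1).astype(np.int16)
        counts[(geno < 0).any(axis=1)] = MISSING
        yield k, counts


def read_genotypes(path: str | Path, samples: Sequence[str] | None = None) -> GenotypeMatrix:
    """Load a VCF into a :class:`GenotypeMatrix` (biallelic keys, split multiallelics)."""
    vcf = VCF(str(path), samples=list(samples) if samples else None)
    if samples:
        absent = set(samples) - set(vcf.samples)
        if absent:
            raise KeyError(f"samples not in VCF: {sorted(absent)}")
    out_samples = list(vcf.samples)
    keys: list[VariantKey] = []
    gt_cols: list[np.ndarray] = []
    gq_cols: list[np.ndarray] = []
    dp_cols: list[np.ndarray] = []
    for variant in vcf:
        gq = _format_int_field(variant, "GQ", len(out_samples))
        dp = _format_int_field(variant, "DP", len(out_samples))
        for k, counts in _split_record(variant, len(variant.ALT)):
            keys.append(VariantKey(variant.CHROM, variant.POS, variant.REF, variant.ALT[k - 1]))
            gt_cols.append(counts)
            gq_cols.append(gq)
            dp_cols.append(dp)
    vcf.close()
    n, m = len(out_samples), len(keys)
    gt = np.stack(gt_cols, axis=1) if m else np.empty((n, 0), dtype=np.int16)
    gq = np.stack(gq_cols, axis=1) if m else np.empty((n, 0), dtype=np.int32)
    dp = np.stack(dp_cols, axis=1) if m else np.empty((n, 0), dtype=np.int32)
    return GenotypeMatrix(out_samples, keys, gt, gq, dp)


def _format_int_field(variant, field: str, n: int) -> np.ndarray:
    try:
        arr = variant.format(field)
    except KeyError:  # field not declared in the header
        arr = None
    if arr is None:
        return np.full(n, MISSING, dtype=np.int32)
    arr = np.asarray(arr).reshape(n, -1)[:, 0]
    out = np.where(np.isfinite(arr.astype(np.float64)) & (arr >= 0), arr, MISSING)
    return out.astype(np.int32)


def read_haplotypes(path: str | Path) -> HaplotypePanel:
    """Load a phased VCF into a :class:`HaplotypePanel` (biallelic records only)."""
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    keys: list[VariantKey] = []
    cols: list[np.ndarray] = []
    for variant in vcf:
        if len(variant.ALT) != 1:
            raise ValueError(f"haplotype VCF must be biallelic at {variant.CHROM}:{variant.POS}")
        geno = np.asarray([g for g in variant.genotypes])
        if not bool(np.all(geno[:, 2])):
            raise ValueError(f"unphased genotype at {variant.CHROM}:{variant.POS}")
        alleles = geno[:, :2].astype(np.int8).reshape(-1)
        if (alleles < 0).any():
            raise ValueError(f"missing allele in phased VCF at {variant.CHROM}:{variant.POS}")
        keys.append(VariantKey(variant.CHROM, variant.POS, variant.REF, variant.ALT[0]))
        cols.append(alleles)
    vcf.close()
    haps = (
        np.stack(cols, axis=1)
        if keys
        else np.empty((2 * len(samples), 0), dtype=np.int8)
    )
    return HaplotypePanel(samples, keys, haps)


def read_dosages(path: str | Path) -> DosageMatrix:
    """Load DS dosages from a VCF; falls back to hard GT where DS is absent."""
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    keys: list[VariantKey] = []
    cols: list[np.ndarray] = []
    for variant in vcf:
        try:
            ds = variant.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            col = np.asarray(ds, dtype=np.float64).reshape(len(samples), -1)[:, 0]
        else:
            geno = np.asarray([g[:2] for g in variant.genotypes], dtype=np.int32)
            col = np.clip(geno, 0, None).sum(axis=1).astype(np.float64)
        for k in range(len(variant.ALT)):
            if k > 0:
                raise ValueError(
                    f"multiallelic dosage record at {variant.CHROM}:{variant.POS}; split first"
                )
            keys.append(VariantKey(variant.CHROM, variant.POS, variant.REF, variant.ALT[k]))
            cols.append(col)
    vcf.close()
    ds = np.stack(cols, axis=1) if keys else np.empty((len(samples), 0))
    return DosageMatrix(samples, keys, ds)


# ---------------------------------------------------------------------------
# VCF writing (plain-text VCFv4.2)
# ---------------------------------------------------------------------------

_HEADER_META = [
    '##INFO=<ID=AF,Number=A,Type=Float,Description="Alternate allele frequency">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality (phred)">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    '##FORMAT=<ID=DS,Number=A,Type=Float,Description="Alt allele dosage">',
]


def _header(samples: Sequence[str], contigs: dict[str, int]) -> str:
    lines = ["##fileformat=VCFv4.2"]
    for chrom, length in contigs.items():
        lines.append(f"##contig=<ID={chrom},length={length}>")
    lines.extend(_HEADER_META)
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    )
    return "\n".join(lines) + "\n"


def _contigs_for(variants: Sequence[VariantKey]) -> dict[str, int]:
    contigs: dict[str, int] = {}
    for v in variants:
        contigs[v.chrom] = max(contigs.get(v.chrom, 0), v.pos + len(v.ref) + 1000)
    return contigs


def _sorted_order(variants: Sequence[VariantKey]) -> list[int]:
    return sorted(range(len(variants)), key=lambda j: variants[j])


def write_genotypes(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write unphased hard genotypes (GT plus GQ/DP when present) as VCF."""
    gt_strings = {MISSING: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
    af = matrix.alt_allele_frequency()
    with open(path, "w") as fh:
        fh.write(_header(matrix.samples, _contigs_for(matrix.variants)))
        for j in _sorted_order(matrix.variants):
            v = matrix.variants[j]
            fmt_keys = ["GT"]
            if matrix.gq is not None:
                fmt_keys.append("GQ")
            if matrix.dp is not None:
                fmt_keys.append("DP")
            cells = []
            for i in range(matrix.n_samples):
                parts = [gt_strings[int(matrix.gt[i, j])]]
                if matrix.gq is not None:
                    q = int(matrix.gq[i, j])
                    parts.append("." if q == MISSING else str(q))
                if matrix.dp is not None:
                    d = int(matrix.dp[i, j])
                    parts.append("." if d == MISSING else str(d))
                cells.append(":".join(parts))
            info = "AF=." if np.isnan(af[j]) else f"AF={af[j]:.6g}"
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t{info}\t"
                + ":".join(fmt_keys)
                + "\t"
                + "\t".join(cells)
                + "\n"
            )


def write_haplotypes(panel: HaplotypePanel, path: str | Path) -> None:
    """Write phased haplotypes (``|``-separated GT) as VCF."""
    af = panel.haps.mean(axis=0)
    with open(path, "w") as fh:
        fh.write(_header(panel.samples, _contigs_for(panel.variants)))
        for j in _sorted_order(panel.variants):
            v = panel.variants[j]
            cells = [
                f"{panel.haps[2 * i, j]}|{panel.haps[2 * i + 1, j]}"
                for i in range(panel.n_samples)
            ]
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\tAF={af[j]:.6g}\tGT\t"
                + "\t".join(cells)
                + "\n"
            )


def write_dosages(dosages: DosageMatrix, path: str | Path) -> None:
    """Write imputed dosages (DS, with a hard-called GT for compatibility)."""
    with open(path, "w") as fh:
        fh.write(_header(dosages.samples, _contigs_for(dosages.variants)))
        for j in _sorted_order(dosages.variants):
            v = dosages.variants[j]
            cells = []
            for i in range(dosages.n_samples):
                d = dosages.ds[i, j]
                hard = int(np.ceil(d - 0.5))  # ties at x.5 round down
                gt = {0: "0/0", 1: "0/1", 2: "1/1"}[hard]
                cells.append(f"{gt}:{float(d)!r}")
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT:DS\t"
                + "\t".join(cells)
                + "\n"
            )


# ---------------------------------------------------------------------------
# BED and tabular IO
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[Region]:
    regions = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{line_no}: expected >= 3 BED columns")
            regions.append(Region(fields[0], int(fields[1]), int(fields[2])))
    return regions


def write_bed(regions: Iterable[Region], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in sorted(regions):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------

def load_config(path: str | Path | None) -> dict:
    """Read a YAML config; every CLI flag may be supplied from it."""
    if path is None:
        return {}
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg


def resolve_options(defaults: dict, config: dict, overrides: dict) -> dict:
    """Defaults < config file < explicit CLI flags; logs the resolved set."""
    resolved = dict(defaults)
    resolved.update({k: v for k, v in config.items() if k in defaults})
    resolved.update({k: v for k, v in overrides.items() if v is not None})
    logger.info("resolved options: %s", resolved)
    return resolved
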