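"""Chunk planning and ligation of independently phased chunks.

Phasing large cohorts is done on overlapping genomic chunks (fixed length,
e.g. ~10 Mbp with 400 kbp overlaps, or fixed marker count for genotype
refinement, ~1.4 Mbp at panel marker density). Each chunk is phased
independently, so its haplotype pair carries an arbitrary global
orientation; ligation resolves consecutive-chunk orientation by majority
vote over heterozygous sites shared in the overlap and splices the chunks
into chromosome-length haplotypes. Phasing itself is out of scope: this
module orchestrates and ligates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .containers import HaplotypePanel, Region

logger = logging.getLogger(__name__)


@dataclass
class ChunkPlan:
    chunks: list[Region]
    overlap_bp: int
    cores: list[Region] = field(default_factory=list)  # marker-based plans only

    def __post_init__(self) -> None:
        if self.chunks != sorted(self.chunks):
            raise ValueError("chunks must be sorted")


@dataclass
class PhasedChunk:
    """Phased haplotypes over the variants inside one chunk region."""

    region: Region
    panel: HaplotypePanel

    def __post_init__(self) -> None:
        for v in self.panel.variants:
            if v.chrom != self.region.chrom or not self.region.contains_pos(v.pos):
                raise ValueError(f"variant {v} outside chunk region {self.region}")


def plan_chunks_by_length(
    interval: Region, target_len: int, overlap_bp: int
) -> ChunkPlan:
    """Fixed-length chunks: chunk k starts at k*(target_len - overlap_bp).

    All chunks have length ``target_len`` except the last, which ends at the
    interval end; a final chunk shorter than ``overlap_bp`` is merged into
    its predecessor.
    """
    if not target_len > overlap_bp > 0:
        raise ValueError("need target_len > overlap_bp > 0")
    step = target_len - overlap_bp
    chunks: list[Region] = []
    start = interval.start
    while True:
        end = start + target_len
        if end >= interval.end:
            if chunks and interval.end - start < overlap_bp:
                last = chunks.pop()  # merge short tail into predecessor
                chunks.append(Region(interval.chrom, last.start, interval.end))
            else:
                chunks.append(Region(interval.chrom, start, interval.end))
            break
        chunks.append(Region(interval.chrom, start, end))
        start += step
    return ChunkPlan(chunks=chunks, overlap_bp=overlap_bp)


def plan_chunks_by_markers(
    positions, markers_per_chunk: int, overlap_bp: int, chrom: str = "1"
) -> ChunkPlan:
    """Fixed-marker-count chunks with base-pair overlaps.

    Consecutive runs of ``markers_per_chunk`` markers form chunk cores whose
    boundaries sit at midpoints between flanking markers; each chunk is then
    extended left by ``overlap_bp`` into the previous core. Core memberships
    partition the markers.
    """
    pos = np.asarray(positions, dtype=np.int64)
    if pos.size == 0:
        raise ValueError("no marker positions given")
    if np.any(np.diff(pos) < 0):
        raise ValueError("positions must be sorted ascending")
    if markers_per_chunk < 1:
        raise ValueError("markers_per_chunk must be >= 1")
    n_cores = max(1, int(np.ceil(pos.size / markers_per_chunk)))

    cores: list[Region] = []
    bounds = [int(pos[0]) - 1]
    for c in range(1, n_cores):
        last_prev = pos[c * markers_per_chunk - 1]
        first_next = pos[c * markers_per_chunk]
        bounds.append(int((last_prev + first_next) // 2))
    bounds.append(int(pos[-1]))
    for c in range(n_cores):
        cores.append(Region(chrom, bounds[c], bounds[c + 1]))

    chunks = [
        Region(chrom, max(core.start - (overlap_bp if c else 0), bounds[0]), core.end)
        for c, core in enumerate(cores)
    ]
    return ChunkPlan(chunks=chunks, overlap_bp=overlap_bp, cores=cores)


def extract_chunks(panel: HaplotypePanel, plan: ChunkPlan) -> list[PhasedChunk]:
    """Slice a phased panel into the planned (overlapping) chunks."""
    pos = panel.positions
    out = []
    for region in plan.chunks:
        mask = np.array(
            [v.chrom == region.chrom and region.contains_pos(v.pos) for v in panel.variants]
        )
        out.append(PhasedChunk(region=region, panel=panel.take_variants(mask)))
    return out


def ligate(chunks: list[PhasedChunk]) -> HaplotypePanel:
    """Ligate independently phased overlapping chunks into one panel.

    For each consecutive chunk pair and each sample, orientation is decided
    by majority vote over heterozygous sites shared in the overlap (flip the
    downstream chunk when flipped orientation agrees at more hets; ties keep
    the same orientation with a warning, as does an overlap with no shared
    het). The downstream chunk takes over after the median shared het.
    Output genotypes equal input genotypes at every site.
    """
    if not chunks:
        raise ValueError("no chunks to ligate")
    chunks = sorted(chunks, key=lambda c: (c.region.chrom, c.region.start))
    samples = chunks[0].panel.samples
    for c in chunks[1:]:
        if c.panel.samples != samples:
            raise ValueError("chunks cover different samples")

    # ordered union of variant keys
    union: list = []
    col_of: dict = {}
    for c in chunks:
        for v in c.panel.variants:
            if v not in col_of:
                col_of[v] = len(union)
                union.append(v)
    order = sorted(range(len(union)), key=lambda j: union[j])
    union = [union[j] for j in order]
    col_of = {v: j for j, v in enumerate(union)}

    n = len(samples)
    m = len(union)
    out = np.zeros((2 * n, m), dtype=np.int8)
    filled = np.zeros(m, dtype=bool)

    # chunk 0 writes everything it covers
    prev = chunks[0].panel
    flip = np.zeros(n, dtype=bool)  # cumulative per-sample orientation
    _write(out, filled, prev, col_of, flip, start_after=None)

    prev_haps = prev.haps
    prev_index = {v: j for j, v in enumerate(prev.variants)}
    for c in chunks[1:]:
        cur = c.panel
        cur_index = {v: j for j, v in enumerate(cur.variants)}
        shared = [v for v in cur.variants if v in prev_index]
        cur_flip = flip.copy()
        start_after = np.full(n, -1, dtype=np.int64)  # global col of splice het
        for i in range(n):
            pj = np.array([prev_index[v] for v in shared], dtype=int)
            cj = np.array([cur_index[v] for v in shared], dtype=int)
            gp = prev_haps[2 * i, pj] + prev_haps[2 * i + 1, pj]
            gc = cur.haps[2 * i, cj] + cur.haps[2 * i + 1, cj]
            if np.any(gp != gc):
                raise ValueError(
                    f"overlap genotypes disagree for sample {samples[i]}"
                )
            het = gp == 1
            if not het.any():
                logger.warning(
                    "no shared het for sample %s in overlap at %s; keeping orientation",
                    samples[i],
                    c.region,
                )
                cur_flip[i] = False
                if shared:
                    start_after[i] = col_of[shared[len(shared) // 2]]
                continue
            prev_allele = prev_haps[2 * i, pj[het]]
            if flip[i]:
                prev_allele = 1 - prev_allele
            cur_allele = cur.haps[2 * i, cj[het]]
            same = int((prev_allele == cur_allele).sum())
            flipped = int(het.sum()) - same
            if flipped == same:
                logger.warning(
                    "orientation vote tie for sample %s at %s; keeping orientation",
                    samples[i],
                    c.region,
                )
            # prev alleles were compared in their final orientation, so the
            # vote outcome is the downstream chunk's absolute flip state
            cur_flip[i] = flipped > same
            het_keys = [v for v, h in zip(shared, het) if h]
            start_after[i] = col_of[het_keys[len(het_keys) // 2]]
        _write(out, filled, cur, col_of, cur_flip, start_after=start_after)
        flip = cur_flip
        prev_haps = cur.haps
        prev_index = cur_index

    if not filled.all():
        raise AssertionError("ligation left unfilled variant columns")
    return HaplotypePanel(list(samples), union, out)


def _write(out, filled, panel: HaplotypePanel, col_of, flip, start_after) -> None:
    """Write a chunk's (possibly flipped) haplotypes into the output.

    ``start_after`` gives, per sample, the global column index after which
    this chunk's phase takes over (None or -1: write everything)."""
    cols = np.array([col_of[v] for v in panel.variants], dtype=np.int64)
    for i in range(len(panel.samples)):
        h1 = panel.haps[2 * i].copy()
        h2 = panel.haps[2 * i + 1].copy()
        if flip[i]:
            h1, h2 = h2, h1
        if start_after is None:
            sel = np.ones(cols.size, dtype=bool)
        else:
            sel = cols > start_after[i]
            # unfilled columns (new territory) are always written
            sel |= ~filled[cols]
        out[2 * i, cols[sel]] = h1[sel]
        out[2 * i + 1, cols[sel]] = h2[sel]
    filled[cols] = True


def apply_random_flips(
    chunks: list[PhasedChunk], seed: int = 0
) -> list[PhasedChunk]:
    """Flip each chunk's haplotype pair per sample with probability 1/2 —
    emulates the arbitrary orientation of independently phased chunks."""
    rng = np.random.default_rng(seed)
    out = []
    for c in chunks:
        haps = c.panel.haps.copy()
        flips = rng.random(len(c.panel.samples)) < 0.5
        for i in np.flatnonzero(flips):
            haps[[2 * i, 2 * i + 1]] = haps[[2 * i + 1, 2 * i]]
        out.append(
            PhasedChunk(
                region=c.region,
                panel=HaplotypePanel(
                    list(c.panel.samples), list(c.panel.variants), haps
                ),
            )
        )
    return out


def count_switch_errors(truth: HaplotypePanel, test: HaplotypePanel) -> np.ndarray:
    """Per-sample switch-error counts of ``test`` phase against truth.

    At consecutive heterozygous sites, a switch error is a change in the
    orientation of the test haplotypes relative to truth; the global
    orientation of each sample is free.
    """
    if truth.variants != test.variants or truth.samples != test.samples:
        raise ValueError("panels must share samples and variants")
    n = truth.n_samples
    errors = np.zeros(n, dtype=int)
    g_truth = truth.haps[0::2] + truth.haps[1::2]
    g_test = test.haps[0::2] + test.haps[1::2]
    if np.any(g_truth != g_test):
        raise ValueError("genotypes differ; switch error undefined")
    for i in range(n):
        het = g_truth[i] == 1
        agree = truth.haps[2 * i, het] == test.haps[2 * i, het]
        if agree.size < 2:
            continue
        errors[i] = int(np.sum(agree[1:] != agree[:-1]))
    return errors
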