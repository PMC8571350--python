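"""Synthetic admixed cohorts for exercising the panel-QC pipeline.

The generator emulates the statistical structure the downstream analyses
assume, not sequence-level realism:

* a two-ancestry admixed cohort — per-site ancestral allele frequencies
  diverged under a Balding-Nichols model, each haplotype a Markov mosaic of
  the two ancestries, individual admixture proportions Beta-distributed
  around a configurable mean (default 0.823 African);
* pedigree structure (trios, duos, sibling pairs, first-cousin pairs) built
  by explicit Mendelian meiosis with crossovers;
* coverage-dependent genotype calling — Poisson depth, binomial allele
  reads, maximum-likelihood hard calls with calibrated phred GQ;
* microarray emulation (site subset plus independent call errors); and
* imputed dosages with controllable per-allele-frequency-bin correlation to
  the truth genotypes.

Every simulator is deterministic given its parameters and seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import MISSING, DosageMatrix, GenotypeMatrix, HaplotypePanel, VariantKey

AFRICAN, EUROPEAN = 0, 1

#: Beta concentration for individual admixture proportions; the cohort the
#: generator emulates reports only the mean African fraction, so the spread
#: is a free shape parameter chosen to give a realistic wide distribution.
ADMIXTURE_CONCENTRATION = 10.0

#: Default crossover rate for pedigree meiosis, events per bp. Deliberately
#: far above the physical ~1e-8/bp: the single simulated chromosome stands in
#: for a whole genome, so crossover density is scaled up until realized IBD
#: sharing between relatives concentrates near its pedigree expectation
#: (a "compressed genome" convention).
RECOMB_RATE_PER_BP = 1e-5


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the simulated admixed cohort."""

    n_samples: int
    n_variants: int
    chrom_length: int = 10_000_000
    chrom: str = "1"
    fst: float = 0.15
    mean_admixture: float = 0.823
    ancestry_switch_rate: float = 1.0  # switches per Mb along a haplotype
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_variants < 1:
            raise ValueError("n_samples and n_variants must be >= 1")
        if not 0 < self.fst < 1:
            raise ValueError(f"fst must be in (0,1), got {self.fst}")
        if not 0 < self.mean_admixture < 1:
            raise ValueError("mean_admixture must be in (0,1)")
        if self.n_variants > self.chrom_length:
            raise ValueError("more variants than base pairs")
        if self.ancestry_switch_rate < 0:
            raise ValueError("ancestry_switch_rate must be >= 0")


@dataclass(frozen=True)
class PedigreeSpec:
    """Relative counts to graft onto a founder panel.

    Defaults mirror the close-relative structure reported for the cohort this
    package models: 15 parent-child pairs (one of them a full trio, the rest
    duos), three sibling pairs, and seven first-cousin pairs.
    """

    n_trios: int = 1
    n_duos: int = 14
    n_sib_pairs: int = 3
    n_cousin_pairs: int = 7
    seed: int = 0
    recomb_rate_per_bp: float = RECOMB_RATE_PER_BP

    def __post_init__(self) -> None:
        for name in ("n_trios", "n_duos", "n_sib_pairs", "n_cousin_pairs"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class SeqSimParams:
    """Sequencing-and-calling emulation parameters.

    ``mean_coverage`` defaults to the intermediate ~15x regime the panel was
    sequenced at; ``base_error`` is the per-read allele error probability.
    """

    mean_coverage: float = 15.0
    base_error: float = 0.005
    gq_cap: int = 99

    def __post_init__(self) -> None:
        if self.mean_coverage <= 0:
            raise ValueError("mean_coverage must be > 0")
        if not 0 < self.base_error < 0.5:
            raise ValueError("base_error must be in (0, 0.5)")
        if self.gq_cap < 1:
            raise ValueError("gq_cap must be >= 1")


@dataclass
class PanelSimulation:
    """Output of :func:`simulate_panel`: the phased panel plus its truth."""

    panel: HaplotypePanel
    ancestral_af: np.ndarray  # (2, n_variants): African, European alt AF
    local_ancestry: np.ndarray  # (2 * n_samples, n_variants) in {AFRICAN, EUROPEAN}
    african_fraction: np.ndarray  # realized per-sample African fraction
    spec: CohortSpec


@dataclass
class PedigreeResult:
    """Panel extended with relatives, plus the relationship truth table."""

    panel: HaplotypePanel
    truth: pd.DataFrame  # sample1, sample2, relationship, expected_kinship, expected_ibd0
    transmissions: dict = field(default_factory=dict)  # child -> (maternal, paternal hap idx)


def _draw_positions(rng: np.random.Generator, m: int, length: int) -> np.ndarray:
    """m distinct sorted 1-based positions on [1, length]."""
    pos: set[int] = set()
    while len(pos) < m:
        need = m - len(pos)
        pos.update((rng.integers(0, length, size=2 * need) + 1).tolist())
    return np.sort(np.fromiter(pos, dtype=np.int64, count=len(pos))[:m])


def _markov_mosaic(
    rng: np.random.Generator,
    n_rows: int,
    positions: np.ndarray,
    p_state0: np.ndarray,
    switch_rate_per_bp: float,
) -> np.ndarray:
    """Two-state ancestry mosaic along positions for each haplotype row.

    Ancestry is resampled from Bernoulli(p_state0) at switch points placed
    with per-gap probability 1 - exp(-rate * gap); the first site always
    draws fresh.
    """
    m = positions.size
    cand = np.where(rng.random((n_rows, m)) < p_state0[:, None], AFRICAN, EUROPEAN)
    switch = np.empty((n_rows, m), dtype=bool)
    switch[:, 0] = True
    if m > 1:
        p_sw = 1.0 - np.exp(-switch_rate_per_bp * np.diff(positions))
        switch[:, 1:] = rng.random((n_rows, m - 1)) < p_sw[None, :]
    cols = np.arange(m)
    last_switch = np.maximum.accumulate(np.where(switch, cols[None, :], -1), axis=1)
    return np.take_along_axis(cand, last_switch, axis=1).astype(np.int8)


def simulate_panel(spec: CohortSpec) -> PanelSimulation:
    """Simulate a phased two-ancestry admixed cohort.

    Ancestral allele frequencies are Uniform(0.05, 0.95); each ancestry's
    frequency diverges by Beta((1-F)/F * p, (1-F)/F * (1-p)) with F = fst
    (Balding-Nichols). Haplotypes are mosaics of the two ancestries with the
    per-sample African proportion Beta-distributed around
    ``spec.mean_admixture``.
    """
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_samples, spec.n_variants
    positions = _draw_positions(rng, m, spec.chrom_length)
    variants = _snp_keys(rng, spec.chrom, positions)

    p_anc = rng.uniform(0.05, 0.95, size=m)
    conc = (1.0 - spec.fst) / spec.fst
    pop_af = np.vstack(
        [rng.beta(conc * p_anc, conc * (1.0 - p_anc)) for _ in range(2)]
    )

    c = ADMIXTURE_CONCENTRATION
    alpha = rng.beta(spec.mean_admixture * c, (1.0 - spec.mean_admixture) * c, size=n)
    ancestry = _markov_mosaic(
        rng, 2 * n, positions, np.repeat(alpha, 2), spec.ancestry_switch_rate / 1e6
    )
    p_site = np.where(ancestry == AFRICAN, pop_af[AFRICAN][None, :], pop_af[EUROPEAN][None, :])
    haps = (rng.random((2 * n, m)) < p_site).astype(np.int8)

    samples = [f"S{i:04d}" for i in range(n)]
    african_fraction = (ancestry == AFRICAN).reshape(n, 2, m).mean(axis=(1, 2))
    return PanelSimulation(
        panel=HaplotypePanel(samples, variants, haps),
        ancestral_af=pop_af,
        local_ancestry=ancestry,
        african_fraction=african_fraction,
        spec=spec,
    )


def _snp_keys(rng: np.random.Generator, chrom: str, positions: np.ndarray) -> list[VariantKey]:
    bases = np.array(list("ACGT"))
    refs = bases[rng.integers(0, 4, size=positions.size)]
    alts = np.array([rng.choice([b for b in "ACGT" if b != r]) for r in refs])
    return [
        VariantKey(chrom, int(p), str(r), str(a))
        for p, r, a in zip(positions, refs, alts)
    ]


# ---------------------------------------------------------------------------
# Pedigrees
# ---------------------------------------------------------------------------

def _meiosis(
    rng: np.random.Generator,
    parent_haps: np.ndarray,
    positions: np.ndarray,
    rate: float = RECOMB_RATE_PER_BP,
) -> tuple[np.ndarray, np.ndarray]:
    """One gamete: crossover mosaic of the parent's two haplotypes.

    Returns (gamete alleles, transmitted hap index per site).
    """
    m = positions.size
    switch = np.empty(m, dtype=bool)
    switch[0] = True
    if m > 1:
        p_sw = 1.0 - np.exp(-rate * np.diff(positions))
        switch[1:] = rng.random(m - 1) < p_sw
    cand = rng.integers(0, 2, size=m)
    last = np.maximum.accumulate(np.where(switch, np.arange(m), -1))
    idx = cand[last]
    return parent_haps[idx, np.arange(m)], idx


def _founder_haps(rng: np.random.Generator, af: np.ndarray, n_haps: int = 2) -> np.ndarray:
    """Unlinked founder haplotypes drawn from per-site allele frequencies."""
    return (rng.random((n_haps, af.size)) < af[None, :]).astype(np.int8)


def simulate_pedigree(panel: HaplotypePanel, ped: PedigreeSpec) -> PedigreeResult:
    """Extend a founder panel with Mendelian relatives.

    Trios consume two panel founders as visible parents; a duo consumes one
    (the co-parent is a hidden founder). Sibling and cousin pairs are grafted
    onto hidden founders drawn from the panel's empirical allele frequencies,
    so only the named relatives join the output panel. The truth table lists
    every related pair with its expected kinship and IBD0.
    """
    need = 2 * ped.n_trios + ped.n_duos
    if need > panel.n_samples:
        raise ValueError(
            f"pedigree requires {need} founders but panel has {panel.n_samples}"
        )
    rng = np.random.default_rng(ped.seed)
    positions = panel.positions
    af = panel.haps.mean(axis=0)

    new_samples: list[str] = []
    new_rows: list[np.ndarray] = []
    rows_truth: list[dict] = []
    transmissions: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    founder_cursor = 0

    def child_of(hapsA: np.ndarray, hapsB: np.ndarray, name: str) -> np.ndarray:
        gamA, idxA = _meiosis(rng, hapsA, positions, ped.recomb_rate_per_bp)
        gamB, idxB = _meiosis(rng, hapsB, positions, ped.recomb_rate_per_bp)
        transmissions[name] = (idxA, idxB)
        return np.vstack([gamA, gamB]).astype(np.int8)

    def add(name: str, haps: np.ndarray) -> None:
        new_samples.append(name)
        new_rows.append(haps)

    for t in range(ped.n_trios):
        pa = panel.samples[founder_cursor]
        pb = panel.samples[founder_cursor + 1]
        founder_cursor += 2
        child = f"trio{t}_child"
        add(child, child_of(panel.sample_haps(founder_cursor - 2),
                            panel.sample_haps(founder_cursor - 1), child))
        for parent in (pa, pb):
            rows_truth.append(_pair(child, parent, "parent_child", 0.25, 0.0))

    for d in range(ped.n_duos):
        parent = panel.samples[founder_cursor]
        parent_haps = panel.sample_haps(founder_cursor)
        founder_cursor += 1
        mate = _founder_haps(rng, af)
        child = f"duo{d}_child"
        add(child, child_of(parent_haps, mate, child))
        rows_truth.append(_pair(child, parent, "parent_child", 0.25, 0.0))

    for s in range(ped.n_sib_pairs):
        mother, father = _founder_haps(rng, af), _founder_haps(rng, af)
        a, b = f"sib{s}_a", f"sib{s}_b"
        add(a, child_of(mother, father, a))
        add(b, child_of(mother, father, b))
        rows_truth.append(_pair(a, b, "sibling", 0.25, 0.25))

    for c in range(ped.n_cousin_pairs):
        # shared grandparental couple -> two siblings -> each mated out
        gm, gf = _founder_haps(rng, af), _founder_haps(rng, af)
        sib1 = child_of(gm, gf, f"_cousin{c}_p1")
        sib2 = child_of(gm, gf, f"_cousin{c}_p2")
        a, b = f"cousin{c}_a", f"cousin{c}_b"
        add(a, child_of(sib1, _founder_haps(rng, af), a))
        add(b, child_of(sib2, _founder_haps(rng, af), b))
        rows_truth.append(_pair(a, b, "first_cousin", 0.0625, 0.75))

    if not new_samples:
        return PedigreeResult(panel=panel, truth=_truth_frame(rows_truth))

    haps = np.vstack([panel.haps] + new_rows)
    out = HaplotypePanel(list(panel.samples) + new_samples, list(panel.variants), haps)
    return PedigreeResult(panel=out, truth=_truth_frame(rows_truth), transmissions=transmissions)


def _pair(s1: str, s2: str, rel: str, kin: float, ibd0: float) -> dict:
    return {
        "sample1": s1,
        "sample2": s2,
        "relationship": rel,
        "expected_kinship": kin,
        "expected_ibd0": ibd0,
    }


def _truth_frame(rows: list[dict]) -> pd.DataFrame:
    cols = ["sample1", "sample2", "relationship", "expected_kinship", "expected_ibd0"]
    return pd.DataFrame(rows, columns=cols)


def write_pedigree_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Sequencing / array / dosage corruption
# ---------------------------------------------------------------------------

def simulate_sequencing(
    panel: HaplotypePanel, params: SeqSimParams, seed: int = 0
) -> GenotypeMatrix:
    """Emulate short-read genotype calling on the true panel genotypes.

    Per call: depth ~ Poisson(mean_coverage); alt reads ~ Binomial(depth, q)
    with q = base_error, 1/2 or 1-base_error for true genotypes 0/1/2; the
    hard call maximizes the binomial likelihood under a flat genotype prior;
    GQ is the phred-scaled posterior error probability capped at ``gq_cap``.
    Zero-depth calls are missing.
    """
    truth = panel.genotypes()
    rng = np.random.default_rng(seed)
    n, m = truth.n_samples, truth.n_variants
    g = truth.gt
    e = params.base_error
    q_by_g = np.array([e, 0.5, 1.0 - e])

    depth = rng.poisson(params.mean_coverage, size=(n, m))
    alt = rng.binomial(depth, q_by_g[g])

    # log-likelihoods of the three candidate genotypes (binomial coeff cancels)
    k, d = alt.astype(np.float64), depth.astype(np.float64)
    ll = np.stack(
        [k * np.log(q) + (d - k) * np.log(1.0 - q) for q in q_by_g], axis=0
    )
    ll -= ll.max(axis=0, keepdims=True)
    post = np.exp(ll)
    post /= post.sum(axis=0, keepdims=True)
    call = post.argmax(axis=0).astype(np.int16)
    p_err = np.clip(1.0 - post.max(axis=0), 1e-15, 1.0)
    gq = np.minimum(np.round(-10.0 * np.log10(p_err)), params.gq_cap).astype(np.int32)

    nocall = depth == 0
    call[nocall] = MISSING
    gq[nocall] = MISSING
    return GenotypeMatrix(
        list(truth.samples), list(truth.variants), call, gq, depth.astype(np.int32)
    )


def emulate_array(
    truth: GenotypeMatrix, site_fraction: float, call_error: float, seed: int = 0
) -> GenotypeMatrix:
    """Restrict truth to a random microarray site subset with call errors.

    Errors are independent per call: with probability ``call_error`` the
    genotype is replaced by one of the two other genotypes uniformly.
    """
    if not 0 < site_fraction <= 1:
        raise ValueError("site_fraction must be in (0, 1]")
    if not 0 <= call_error < 1:
        raise ValueError("call_error must be in [0, 1)")
    rng = np.random.default_rng(seed)
    k = int(round(site_fraction * truth.n_variants))
    if k == 0:
        raise ValueError("site subset is empty; increase site_fraction")
    idx = np.sort(rng.choice(truth.n_variants, size=k, replace=False))
    sub = truth.take_variants(idx)
    if call_error > 0:
        flip = (rng.random(sub.gt.shape) < call_error) & (sub.gt != MISSING)
        delta = rng.integers(1, 3, size=sub.gt.shape)
        sub.gt = np.where(flip, (sub.gt + delta) % 3, sub.gt).astype(np.int16)
    sub.gq = None
    sub.dp = None
    return sub


def corrupt_dosages(
    truth: GenotypeMatrix,
    target_r2,
    bins=None,
    seed: int = 0,
) -> DosageMatrix:
    """Produce imputed-like dosages with a chosen per-AF-bin correlation.

    Within each allele-frequency bin (cohort alt AF), dosage = genotype +
    Gaussian noise with variance Var(g) * (1 - r) / r, then clipped to
    [0, 2]; the pooled squared correlation with truth approaches the bin's
    target r as the pair count grows (clipping introduces a small bias that
    is tolerated, not corrected). ``target_r2`` is a scalar or one value per
    bin. Bins with zero genotype variance are skipped with a warning.
    """
    from .imputeval import BinSpec  # local import: imputeval owns BinSpec

    if bins is None:
        bins = BinSpec()
    targets = np.atleast_1d(np.asarray(target_r2, dtype=np.float64))
    if targets.size == 1:
        targets = np.full(bins.n_bins, float(targets[0]))
    if targets.size != bins.n_bins:
        raise ValueError(f"need {bins.n_bins} targets, got {targets.size}")
    if np.any((targets <= 0) | (targets > 1)):
        raise ValueError("each target_r2 must be in (0, 1]")

    rng = np.random.default_rng(seed)
    af = truth.alt_allele_frequency()
    bin_of = bins.assign(af)
    g = np.where(truth.gt == MISSING, 0, truth.gt).astype(np.float64)
    ds = g.copy()
    for b in range(bins.n_bins):
        cols = np.flatnonzero(bin_of == b)
        if cols.size == 0:
            continue
        r = targets[b]
        if r >= 1.0:
            continue
        pooled = truth.gt[:, cols]
        vals = pooled[pooled != MISSING].astype(np.float64)
        var = vals.var() if vals.size else 0.0
        if var == 0.0:
            warnings.warn(
                f"bin {b} ({bins.label(b)}) has zero genotype variance; skipped",
                stacklevel=2,
            )
            continue
        sd = np.sqrt(var * (1.0 - r) / r)
        z = rng.normal(0.0, 1.0, size=(truth.n_samples, cols.size))
        called = pooled != MISSING
        gv = g[:, cols]

        def realized_r2(scale: float) -> float:
            clipped = np.clip(gv + scale * z, 0.0, 2.0)
            c = np.corrcoef(gv[called], clipped[called])[0, 1]
            return float(c * c)

        # clipping attenuates the injected noise, biasing the pooled R^2
        # upward; calibrate the scale against the realized correlation
        lo, hi = 0.0, sd
        while realized_r2(hi) > r and hi < 8.0 * sd + 1.0:
            hi *= 2.0
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            if realized_r2(mid) > r:
                lo = mid
            else:
                hi = mid
        scale = 0.5 * (lo + hi)
        ds[:, cols] = np.clip(gv + scale * z, 0.0, 2.0)
    return DosageMatrix(list(truth.samples), list(truth.variants), ds)
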