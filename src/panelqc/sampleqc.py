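"""Sample-level QC: coverage/contamination gates, robust kinship + IBD0
estimation, relationship-degree classification, and clique-based pruning of
close relatives.

The kinship estimator is the allele-frequency-robust ("KING-robust" style)
heterozygote-sharing statistic

    phi = (N_AaAa - 2 * N_AA,aa) / (N_Aa,i + N_Aa,j)

where N_AaAa counts sites at which both samples are heterozygous, N_AA,aa
counts opposite homozygotes, and N_Aa,* are the per-sample heterozygote
counts over the pairwise-complete sites. IBD0 is the opposite-homozygote
count normalized by its expectation under unrelatedness and HWE,
2 * sum_s p_s^2 (1 - p_s)^2, with p_s the cohort alt allele frequency.
Duplicates give phi = 0.5 and IBD0 = 0; unrelated pairs give phi ~ 0 and
IBD0 ~ 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .containers import MISSING, GenotypeMatrix

DEGREES = (
    "duplicate",
    "parent_child",
    "sibling",
    "second_degree",
    "third_degree",
    "unrelated",
)

#: Standard kinship inference bands at powers of 1/sqrt(2).
_DUP_MIN = 0.354
_FIRST_MIN = 0.177
_SECOND_MIN = 0.0884
_THIRD_MIN = 0.0442
_PARENT_CHILD_MAX_IBD0 = 0.1


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    aligned_coverage: float
    contamination: float

    def __post_init__(self) -> None:
        if self.aligned_coverage < 0:
            raise ValueError("coverage must be >= 0")
        if not 0 <= self.contamination <= 1:
            raise ValueError("contamination must be in [0, 1]")


@dataclass
class KinshipResult:
    pair: tuple[str, str]
    kinship: float
    ibd0: float
    degree: str | None = None
    n_sites: int = 0


class InsufficientDataError(ValueError):
    """Too few pairwise-complete informative sites for kinship."""


class UnresolvedCliqueError(ValueError):
    """A related component larger than a pair survived child removal."""

    def __init__(self, component: Iterable[str]):
        self.component = sorted(component)
        super().__init__(f"unresolved relatedness clique: {self.component}")


def sample_passes_qc(
    meta: SampleMeta, min_coverage: float = 3.0, max_contamination: float = 0.05
) -> tuple[bool, list[str]]:
    """Coverage/contamination gate; returns (passed, reasons-for-failure)."""
    reasons = []
    if meta.aligned_coverage < min_coverage:
        reasons.append("coverage")
    if meta.contamination > max_contamination:
        reasons.append("contamination")
    return (not reasons, reasons)


def king_kinship(
    gi: np.ndarray,
    gj: np.ndarray,
    af: np.ndarray | None = None,
    min_informative: int = 100,
    pair: tuple[str, str] = ("i", "j"),
) -> KinshipResult:
    """Robust kinship and IBD0 for one sample pair.

    ``af`` supplies per-site cohort alt allele frequencies for the IBD0
    normalization; when omitted it is estimated from the pair itself (noisy —
    prefer passing cohort frequencies).
    """
    gi = np.asarray(gi)
    gj = np.asarray(gj)
    if gi.shape != gj.shape:
        raise ValueError("genotype vectors must have equal length")
    ok = (gi != MISSING) & (gj != MISSING)
    gi, gj = gi[ok], gj[ok]

    het_i = gi == 1
    het_j = gj == 1
    n_het_i = int(het_i.sum())
    n_het_j = int(het_j.sum())
    n_het_both = int((het_i & het_j).sum())
    n_opp_hom = int((((gi == 0) & (gj == 2)) | ((gi == 2) & (gj == 0))).sum())

    informative = n_het_i + n_het_j
    if informative < min_informative:
        raise InsufficientDataError(
            f"{informative} informative sites < {min_informative}"
        )
    kinship = (n_het_both - 2.0 * n_opp_hom) / informative

    if af is None:
        p = (gi + gj) / 4.0
    else:
        p = np.asarray(af, dtype=np.float64)[ok]
    expected_opp = 2.0 * float(np.sum(p**2 * (1.0 - p) ** 2))
    ibd0 = n_opp_hom / expected_opp if expected_opp > 0 else np.nan
    return KinshipResult(pair=pair, kinship=kinship, ibd0=ibd0, n_sites=int(ok.sum()))


def classify_degree(kinship: float, ibd0: float) -> str:
    """Relationship degree from (kinship, IBD0) at the standard bands."""
    if not (np.isfinite(kinship) and np.isfinite(ibd0)):
        raise ValueError("kinship and ibd0 must be finite")
    if kinship > _DUP_MIN:
        return "duplicate"
    if kinship > _FIRST_MIN:
        return "parent_child" if ibd0 < _PARENT_CHILD_MAX_IBD0 else "sibling"
    if kinship > _SECOND_MIN:
        return "second_degree"
    if kinship > _THIRD_MIN:
        return "third_degree"
    return "unrelated"


def pairwise_kinship(
    matrix: GenotypeMatrix,
    pairs: Sequence[tuple[str, str]] | None = None,
    min_informative: int = 100,
) -> list[KinshipResult]:
    """Kinship for the given sample pairs (default: all pairs), degrees filled."""
    af = matrix.alt_allele_frequency()
    af = np.where(np.isnan(af), 0.0, af)
    if pairs is None:
        pairs = list(combinations(matrix.samples, 2))
    out = []
    for s1, s2 in pairs:
        res = king_kinship(
            matrix.gt[matrix.sample_index(s1)],
            matrix.gt[matrix.sample_index(s2)],
            af=af,
            min_informative=min_informative,
            pair=(s1, s2),
        )
        res.degree = classify_degree(res.kinship, res.ibd0)
        out.append(res)
    return out


def prune_relatives(
    results: Sequence[KinshipResult], meta: Sequence[SampleMeta]
) -> tuple[list[str], list[str]]:
    """Remove close relatives, preferring to keep higher-coverage samples.

    Step 1 removes every identified child: in a trio the sample with
    parent_child edges to two mutually-unrelated partners; in a duo the
    orientation is unidentifiable from kinship alone, so the lower-coverage
    member is removed as the assumed child. Step 2 requires all remaining
    related components to be pairs and removes the lower-coverage member of
    each (coverage ties broken by removing the lexicographically larger id).
    """
    coverage = {m.sample_id: m.aligned_coverage for m in meta}
    graph = nx.Graph()
    graph.add_nodes_from(coverage)
    for r in results:
        if r.degree is None:
            raise ValueError(f"degree not classified for pair {r.pair}")
        if r.degree != "unrelated":
            graph.add_edge(*r.pair, degree=r.degree)

    removed: list[str] = []

    def lower_coverage(a: str, b: str) -> str:
        ca, cb = coverage.get(a, 0.0), coverage.get(b, 0.0)
        if ca != cb:
            return a if ca < cb else b
        return max(a, b)  # tie: lexicographically larger id goes

    # step 1a: trio children — parent_child edges to >= 2 mutually-unrelated partners
    for node in list(graph.nodes):
        partners = [
            nbr
            for nbr in graph.neighbors(node)
            if graph.edges[node, nbr]["degree"] == "parent_child"
        ]
        if len(partners) >= 2 and any(
            not graph.has_edge(a, b) for a, b in combinations(partners, 2)
        ):
            removed.append(node)
    graph.remove_nodes_from(removed)

    # step 1b: duos — assumed child = lower-coverage member
    duo_removed = []
    for a, b, data in list(graph.edges(data=True)):
        if data["degree"] == "parent_child" and graph.has_node(a) and graph.has_node(b):
            duo_removed.append(lower_coverage(a, b))
    graph.remove_nodes_from(duo_removed)
    removed.extend(duo_removed)

    # step 2: remaining components must be pairs; keep the higher-coverage member
    for component in list(nx.connected_components(graph)):
        if len(component) > 2:
            raise UnresolvedCliqueError(component)
        if len(component) == 2:
            a, b = sorted(component)
            removed.append(lower_coverage(a, b))

    removed_set = set(removed)
    kept = sorted(s for s in coverage if s not in removed_set)
    return kept, sorted(removed_set)
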