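"""Cluster-based GO annotation transfer.

The procedure mirrors large-scale comparative annotation servers: all
sequences are pairwise locally aligned, sequences sharing more than 40%
identity over at least 90% coverage are joined by single linkage into
clusters, GO terms over-represented within a cluster (one-sided Fisher
exact test, Bonferroni-corrected at the 1% level) are transferred to the
cluster members not yet carrying them, and annotation pools are merged
keeping, for each (protein, term, aspect), the entry with the highest
evidence quality (manually curated > electronically inferred > transferred).

Alignments use exact Smith-Waterman (BLOSUM62, gap open 11 / extend 1)
rather than a heuristic search engine: inputs here are desk-scale, and
the identity/coverage thresholds — not the engine — define the method.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio import Align
from Bio.Align import substitution_matrices
from scipy.stats import hypergeom

from .io_formats import GOAnnotation, ProteinRecord

IDENTITY_THRESHOLD = 40.0  # percent, strict (> 40)
COVERAGE_THRESHOLD = 90.0  # percent, inclusive (>= 90)
ALPHA = 0.01

#: evidence-quality tiers, best first
EVIDENCE_RANK: dict[str, int] = {"GOA_manual": 0, "GOA_IEA": 1, "BAR": 2}

TRANSFER_EVIDENCE_CODE = "IEA"


@dataclass(frozen=True)
class PairwiseHit:
    """Identity/coverage summary of one local alignment, symmetric in (a, b)."""

    id_a: str
    id_b: str
    identity: float  # identities / alignment columns * 100
    coverage: float  # aligned span on the shorter sequence / its length * 100
    alignment_length: int

    def passes(
        self,
        identity_threshold: float = IDENTITY_THRESHOLD,
        coverage_threshold: float = COVERAGE_THRESHOLD,
    ) -> bool:
        return self.identity > identity_threshold and self.coverage >= coverage_threshold


@dataclass(frozen=True)
class SequenceCluster:
    members: frozenset[str]

    @property
    def singleton(self) -> bool:
        return len(self.members) == 1

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class EnrichmentResult:
    cluster_members: frozenset[str]
    term: str
    aspect: str
    k: int  # cluster members carrying the term
    n: int  # cluster members in the annotation universe
    K: int  # universe proteins carrying the term
    N: int  # universe size
    p_value: float
    n_terms_tested: int
    significant: bool


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    # affine cost 11 + g per gap of length g (the BLAST protein default)
    aligner.open_gap_score = -12.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _make_aligner()


def align_pair(a: ProteinRecord, b: ProteinRecord) -> PairwiseHit:
    """Best local alignment of two sequences, reduced to identity/coverage.

    Identity is identities over alignment columns (gaps included);
    coverage is the aligned span on the shorter of the two sequences over
    that sequence's length — the strictest symmetric reading.
    """
    alignments = _ALIGNER.align(a.sequence, b.sequence)
    try:
        alignment = alignments[0]
    except IndexError:
        # no positive-scoring local alignment exists
        return PairwiseHit(a.id, b.id, 0.0, 0.0, 0)
    counts = alignment.counts()
    aln_len = counts.identities + counts.mismatches + counts.gaps
    if aln_len == 0:
        return PairwiseHit(a.id, b.id, 0.0, 0.0, 0)
    identity = 100.0 * counts.identities / aln_len
    shorter_idx = 0 if len(a) <= len(b) else 1
    segs = alignment.aligned[shorter_idx]
    span = int(segs[-1][1] - segs[0][0])
    shorter_len = min(len(a), len(b))
    coverage = 100.0 * span / shorter_len
    return PairwiseHit(a.id, b.id, identity, coverage, int(aln_len))


def build_clusters(
    records: Sequence[ProteinRecord],
    identity_threshold: float = IDENTITY_THRESHOLD,
    coverage_threshold: float = COVERAGE_THRESHOLD,
) -> list[SequenceCluster]:
    """Single-linkage clusters over the identity/coverage graph.

    An edge joins a pair iff identity > identity_threshold AND coverage
    >= coverage_threshold; clusters are the connected components, and
    every unconnected sequence is a singleton.  Clusters partition the
    input.
    """
    if len(records) == 0:
        raise ValueError("need at least one record")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate protein ids in input")
    parent = {i: i for i in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(len(records)):
        for j in range(i + 1, len(records)):
            hit = align_pair(records[i], records[j])
            if hit.passes(identity_threshold, coverage_threshold):
                parent[find(ids[i])] = find(ids[j])
    groups: dict[str, set[str]] = {}
    for pid in ids:
        groups.setdefault(find(pid), set()).add(pid)
    return [SequenceCluster(frozenset(members)) for members in groups.values()]


def overrepresentation_pvalue(k: int, n: int, K: int, N: int) -> float:
    """One-sided Fisher exact p-value P(X >= k) for over-representation.

    X is hypergeometric: the number of term-carrying proteins in a sample
    of n cluster members drawn from a universe of N proteins of which K
    carry the term.
    """
    if not (0 <= k <= n <= N and 0 <= K <= N and k <= K):
        raise ValueError(f"inconsistent 2x2 table k={k} n={n} K={K} N={N}")
    return float(min(hypergeom.sf(k - 1, N, K, n), 1.0))


def enrich_cluster(
    cluster: SequenceCluster,
    annotations: Iterable[GOAnnotation],
    background: Iterable[GOAnnotation],
    alpha: float = ALPHA,
) -> list[EnrichmentResult]:
    """One-sided Fisher over-representation test for every term in the cluster.

    The universe is the set of proteins appearing in the background
    annotation pool plus the cluster members; the p-value for a term is
    the hypergeometric upper tail P(X >= k) of drawing k term-carrying
    proteins when sampling the cluster from the universe.  The Bonferroni
    divisor is the number of terms tested for this cluster.
    """
    background = list(background)
    annotations = list(annotations)
    if not background:
        raise ValueError("empty background annotation pool")
    pool = {a.key() for a in background} | {a.key() for a in annotations}
    universe = {pid for pid, _, _ in pool} | set(cluster.members)
    N = len(universe)
    n = len(cluster.members)

    term_aspect: dict[str, str] = {}
    carriers: dict[str, set[str]] = {}
    for pid, term, aspect in pool:
        carriers.setdefault(term, set()).add(pid)
        term_aspect[term] = aspect

    cluster_terms = sorted(
        {term for (pid, term, _a) in pool if pid in cluster.members}
    )
    m = len(cluster_terms)
    results = []
    for term in cluster_terms:
        K = len(carriers[term])
        k = len(carriers[term] & cluster.members)
        p = overrepresentation_pvalue(k, n, K, N)
        results.append(
            EnrichmentResult(
                cluster_members=cluster.members,
                term=term,
                aspect=term_aspect[term],
                k=k,
                n=n,
                K=K,
                N=N,
                p_value=min(p, 1.0),
                n_terms_tested=m,
                significant=p <= alpha / m,
            )
        )
    return results


def transfer_annotations(
    cluster: SequenceCluster,
    enriched: Sequence[EnrichmentResult],
    existing: Iterable[GOAnnotation] = (),
) -> list[GOAnnotation]:
    """Assign every significant term to cluster members not already carrying it.

    Transferred annotations get source ``BAR`` and an electronic evidence
    code; existing (protein, term) pairs are never duplicated and never
    removed.
    """
    have = {(a.protein_id, a.term) for a in existing}
    out = []
    for res in enriched:
        if not res.significant:
            continue
        if res.cluster_members != cluster.members:
            raise ValueError("enrichment results computed on a different cluster")
        for pid in sorted(cluster.members):
            if (pid, res.term) not in have:
                out.append(
                    GOAnnotation(
                        protein_id=pid,
                        term=res.term,
                        aspect=res.aspect,
                        evidence=TRANSFER_EVIDENCE_CODE,
                        source="BAR",
                    )
                )
                have.add((pid, res.term))
    return out


def merge_annotations(*pools: Iterable[GOAnnotation]) -> list[GOAnnotation]:
    """Collapse duplicated (protein, term, aspect) entries across pools,
    retaining the one with the highest-quality evidence source."""
    best: dict[tuple[str, str, str], GOAnnotation] = {}
    for pool in pools:
        for ann in pool:
            if ann.source not in EVIDENCE_RANK:
                raise ValueError(f"unknown annotation source {ann.source!r}")
            key = ann.key()
            cur = best.get(key)
            if cur is None or EVIDENCE_RANK[ann.source] < EVIDENCE_RANK[cur.source]:
                best[key] = ann
    return list(best.values())
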