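"""Protein family clustering by pairwise alignment bit-score density.

Re-implements the BLASTCLUST edge criterion: two sequences are linked when
their Smith–Waterman local alignment (affine gaps, BLOSUM62 by default) has
bit-score density (bit score per alignment column) at or above a threshold
and satisfies a coverage criterion; families are the connected components
of that graph (single linkage).  Small or divergent clusters can then be
merged into larger ones when independent evidence supports it: reciprocal
best hits between representatives, shared profile-family annotations, or an
identical conserved genome-context signature.

The raw-to-bit conversion uses published gapped BLOSUM62 constants
(lambda = 0.267, K = 0.041): bits = (lambda * raw - ln K) / ln 2.  The
constants only set the scale of the density threshold, which is exposed in
:class:`ScoringParams` anyway.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices


@dataclass(frozen=True)
class ScoringParams:
    matrix_name: str = "BLOSUM62"
    gap_open: float = 11.0  # cost of opening a gap (first gapped position pays open+extend)
    gap_extend: float = 1.0
    lambda_: float = 0.267
    K: float = 0.041
    density_threshold: float = 0.8  # bits per alignment column
    coverage_threshold: float = 0.6
    coverage_mode: str = "both"  # or "shorter"

    def __post_init__(self):
        if self.lambda_ <= 0 or self.K <= 0:
            raise ValueError("lambda_ and K must be positive")
        if self.density_threshold <= 0:
            raise ValueError("density_threshold must be positive")
        if not 0 < self.coverage_threshold <= 1:
            raise ValueError("coverage_threshold must lie in (0, 1]")
        if self.coverage_mode not in ("both", "shorter"):
            raise ValueError("coverage_mode must be 'both' or 'shorter'")


@dataclass(frozen=True)
class PairScore:
    id_a: str
    id_b: str
    raw_score: float
    bit_score: float
    aligned_cols: int
    coverage_a: float
    coverage_b: float

    @property
    def density(self) -> float:
        return self.bit_score / self.aligned_cols


@dataclass(frozen=True)
class FamilyCluster:
    cluster_id: str
    members: tuple[str, ...]
    representative: str


def bit_score(raw: float, params: ScoringParams) -> float:
    return (params.lambda_ * raw - math.log(params.K)) / math.log(2.0)


@lru_cache(maxsize=8)
def _aligner(matrix_name: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix_name)
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def pairwise_score(
    id_a: str, seq_a: str, id_b: str, seq_b: str, params: ScoringParams
) -> PairScore | None:
    """Smith–Waterman local alignment of two sequences with bit conversion.

    Returns None when no positive-scoring local alignment exists.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be nonempty")
    aligner = _aligner(params.matrix_name, params.gap_open, params.gap_extend)
    alignments = aligner.align(seq_a, seq_b)
    if len(alignments) == 0:
        return None
    aln = alignments[0]
    raw = float(aln.score)
    if raw <= 0:
        return None
    blocks_a, blocks_b = aln.aligned
    cov_a = sum(int(e - s) for s, e in blocks_a) / len(seq_a)
    cov_b = sum(int(e - s) for s, e in blocks_b) / len(seq_b)
    return PairScore(
        id_a=id_a,
        id_b=id_b,
        raw_score=raw,
        bit_score=bit_score(raw, params),
        aligned_cols=int(aln.length),
        coverage_a=cov_a,
        coverage_b=cov_b,
    )


def passes_edge(ps: PairScore, len_a: int, len_b: int, params: ScoringParams) -> bool:
    """BLASTCLUST-style edge criterion: density plus coverage."""
    if ps.aligned_cols < 1 or ps.density < params.density_threshold:
        return False
    if params.coverage_mode == "both":
        return min(ps.coverage_a, ps.coverage_b) >= params.coverage_threshold
    cov_shorter = ps.coverage_a if len_a <= len_b else ps.coverage_b
    return cov_shorter >= params.coverage_threshold


def passing_pairs(
    sequences: Mapping[str, str], params: ScoringParams
) -> list[tuple[str, str]]:
    """All-vs-all edge list under the density/coverage criterion."""
    ids = sorted(sequences)
    edges = []
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            ps = pairwise_score(a, sequences[a], b, sequences[b], params)
            if ps is not None and passes_edge(ps, len(sequences[a]), len(sequences[b]), params):
                edges.append((a, b))
    return edges


def _make_clusters(
    components: Iterable[Iterable[str]], sequences: Mapping[str, str]
) -> list[FamilyCluster]:
    comps = [tuple(sorted(c)) for c in components]
    comps.sort(key=lambda c: c[0])
    clusters = []
    for i, members in enumerate(comps):
        rep = max(members, key=lambda m: (len(sequences[m]), tuple(-ord(c) for c in m)))
        clusters.append(
            FamilyCluster(cluster_id=f"C{i + 1:04d}", members=members, representative=rep)
        )
    return clusters


def cluster(sequences: Mapping[str, str], params: ScoringParams) -> list[FamilyCluster]:
    """Single-linkage clustering: connected components of the edge graph.

    Cluster ids are assigned in order of each cluster's smallest member id,
    so the output is independent of input ordering.
    """
    graph = nx.Graph()
    graph.add_nodes_from(sequences)
    graph.add_edges_from(passing_pairs(sequences, params))
    return _make_clusters(nx.connected_components(graph), sequences)


# ---------------------------------------------------------------------------
# evidence-based merging


@dataclass(frozen=True)
class MergeEvent:
    cluster_a: str
    cluster_b: str
    evidence: str  # "reciprocal_best_hit" | "shared_family" | "shared_context"


def merge_clusters(
    clusters: Sequence[FamilyCluster],
    sequences: Mapping[str, str],
    params: ScoringParams,
    protein_families: Mapping[str, frozenset] | None = None,
    context_signatures: Mapping[str, frozenset] | None = None,
    merge_E: float = 1e-3,
    merge_frac: float = 0.5,
) -> tuple[list[FamilyCluster], list[MergeEvent]]:
    """Merge clusters supported by independent evidence, transitively.

    Evidence classes:
      * representatives are reciprocal best hits with E <= merge_E, where
        E = len_a * len_b * 2**(-bit score) (search-space E-value);
      * at least ``merge_frac`` of each cluster's members carry the same
        profile family annotation (``protein_families``: protein -> families);
      * the clusters have identical non-empty conserved-context signatures
        (``context_signatures``: protein -> set of (anchor, partner) family
        pairs its neighborhood participates in).

    Returns the merged clustering plus an audit log of the merges applied.
    """
    clusters = list(clusters)
    graph = nx.Graph()
    graph.add_nodes_from(c.cluster_id for c in clusters)
    log: list[MergeEvent] = []

    # (a) reciprocal best hits between representatives
    reps = {c.cluster_id: c.representative for c in clusters}
    ids = sorted(reps)
    best: dict[str, tuple[float, str, float]] = {}
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            ps = pairwise_score(reps[a], sequences[reps[a]], reps[b], sequences[reps[b]], params)
            if ps is None:
                continue
            e = len(sequences[reps[a]]) * len(sequences[reps[b]]) * 2.0 ** (-ps.bit_score)
            for src, dst in ((a, b), (b, a)):
                if src not in best or ps.bit_score > best[src][0]:
                    best[src] = (ps.bit_score, dst, e)
    for a in ids:
        if a in best:
            _, b, e = best[a]
            if best.get(b, (None, None, None))[1] == a and e <= merge_E and not graph.has_edge(a, b):
                graph.add_edge(a, b)
                log.append(MergeEvent(min(a, b), max(a, b), "reciprocal_best_hit"))

    # (b) shared profile-family annotation in a majority of both clusters
    if protein_families:
        frac: dict[str, dict[str, float]] = {}
        for c in clusters:
            counts: dict[str, int] = {}
            for m in c.members:
                for fam in protein_families.get(m, frozenset()):
                    counts[fam] = counts.get(fam, 0) + 1
            frac[c.cluster_id] = {f: n / len(c.members) for f, n in counts.items()}
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                shared = set(frac.get(a, {})) & set(frac.get(b, {}))
                if any(frac[a][f] >= merge_frac and frac[b][f] >= merge_frac for f in shared):
                    if not graph.has_edge(a, b):
                        graph.add_edge(a, b)
                        log.append(MergeEvent(a, b, "shared_family"))

    # (c) identical non-empty conserved-context signatures
    if context_signatures:
        sigs: dict[str, frozenset] = {}
        for c in clusters:
            sig = frozenset().union(
                *(context_signatures.get(m, frozenset()) for m in c.members)
            )
            sigs[c.cluster_id] = sig
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                if sigs[a] and sigs[a] == sigs[b] and not graph.has_edge(a, b):
                    graph.add_edge(a, b)
                    log.append(MergeEvent(a, b, "shared_context"))

    by_id = {c.cluster_id: c for c in clusters}
    merged_members = []
    for comp in nx.connected_components(graph):
        members: list[str] = []
        for cid in comp:
            members.extend(by_id[cid].members)
        merged_members.append(members)
    return _make_clusters(merged_members, sequences), sorted(
        log, key=lambda e: (e.cluster_a, e.cluster_b)
    )


# ---------------------------------------------------------------------------
# table I/O


def clusters_to_frame(clusters: Sequence[FamilyCluster]) -> pd.DataFrame:
    rows = [
        {
            "cluster_id": c.cluster_id,
            "protein_id": m,
            "is_representative": int(m == c.representative),
        }
        for c in clusters
        for m in c.members
    ]
    return pd.DataFrame(rows, columns=["cluster_id", "protein_id", "is_representative"])


def write_clusters(clusters: Sequence[FamilyCluster], path) -> None:
    clusters_to_frame(clusters).to_csv(path, sep="\t", index=False, lineterminator="\n")
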