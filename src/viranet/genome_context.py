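"""Domain architectures, conserved gene neighborhoods and contextual absence.

A gene neighborhood is the run of genes around an anchor bounded by an
inter-gene distance cutoff (default 100 nt), used as an operon proxy.
Recurrent (anchor family, partner family) co-memberships across genomes —
filtered by support and by a phyletic criterion (distinct taxids) — are
reported as conserved contexts.  The contextual-absence query inverts the
logic: it finds loci where a target family occurs with no member of a
specified partner set anywhere in its filtered neighborhood.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .dataset_io import Collection, ProteinRecord
from .profile_scan import DomainHit


# ---------------------------------------------------------------------------
# domain architectures


@dataclass(frozen=True)
class Architecture:
    protein_id: str
    families: tuple[str, ...]  # ordered by ali_start

    @property
    def architecture_string(self) -> str:
        return "+".join(self.families)


def _overlap(a: DomainHit, b: DomainHit) -> int:
    return max(0, min(a.ali_end, b.ali_end) - max(a.ali_start, b.ali_start) + 1)


def detect_architectures(
    hits: Iterable[DomainHit], overlap_frac: float = 0.5
) -> list[Architecture]:
    """Resolve overlapping hits per protein greedily by descending score.

    A hit is dropped when it overlaps an already-retained hit by more than
    ``overlap_frac`` of the shorter span.  Surviving hits, ordered by start
    position, define the protein's architecture string (e.g. "NADAR+Macro").
    """
    by_protein: dict[str, list[DomainHit]] = defaultdict(list)
    for h in hits:
        by_protein[h.protein_id].append(h)
    out = []
    for pid in sorted(by_protein):
        ranked = sorted(
            by_protein[pid], key=lambda h: (-h.score, h.ali_start, h.family_id)
        )
        retained: list[DomainHit] = []
        for h in ranked:
            span_h = h.ali_end - h.ali_start + 1
            ok = True
            for r in retained:
                shorter = min(span_h, r.ali_end - r.ali_start + 1)
                if _overlap(h, r) > overlap_frac * shorter:
                    ok = False
                    break
            if ok:
                retained.append(h)
        retained.sort(key=lambda h: (h.ali_start, h.family_id))
        out.append(Architecture(protein_id=pid, families=tuple(h.family_id for h in retained)))
    return out


# ---------------------------------------------------------------------------
# neighborhoods


@dataclass(frozen=True)
class NeighborhoodMember:
    protein_id: str
    strand_rel: str  # strand relative to the anchor, after canonicalization
    gap_prev: int | None  # nt gap to the previous member (canonical order)


@dataclass(frozen=True)
class Neighborhood:
    genome_id: str
    anchor_id: str
    members: tuple[NeighborhoodMember, ...]  # contiguous; includes the anchor


def intergene_gap(prev: ProteinRecord, nxt: ProteinRecord) -> int:
    """Nucleotides between consecutive genes; overlaps count as 0."""
    return max(0, nxt.start - prev.end - 1)


def extract_neighborhood(
    collection: Collection,
    anchor_id: str,
    window: int = 5,
    gap_cutoff: int = 100,
) -> Neighborhood:
    """Walk outward from the anchor, at most ``window`` genes per side,
    stopping a side when the next inter-gene gap exceeds ``gap_cutoff``.

    The result is canonicalized: if the anchor lies on the minus strand,
    member order is reversed and relative strands flipped, so the anchor
    always reads left-to-right on plus.
    """
    anchor = collection.protein(anchor_id)
    genes = collection.proteins_of(anchor.genome_id)
    pos = next(i for i, p in enumerate(genes) if p.protein_id == anchor_id)

    lo = pos
    while lo > 0 and pos - (lo - 1) <= window:
        if intergene_gap(genes[lo - 1], genes[lo]) > gap_cutoff:
            break
        lo -= 1
    hi = pos
    while hi < len(genes) - 1 and (hi + 1) - pos <= window:
        if intergene_gap(genes[hi], genes[hi + 1]) > gap_cutoff:
            break
        hi += 1

    run = genes[lo : hi + 1]
    gaps = [None] + [intergene_gap(a, b) for a, b in zip(run, run[1:])]
    rel = ["+" if p.strand == anchor.strand else "-" for p in run]
    if anchor.strand == "-":
        run = run[::-1]
        rel = rel[::-1]
        gaps = [None] + gaps[1:][::-1]
    members = tuple(
        NeighborhoodMember(protein_id=p.protein_id, strand_rel=s, gap_prev=g)
        for p, s, g in zip(run, rel, gaps)
    )
    return Neighborhood(genome_id=anchor.genome_id, anchor_id=anchor_id, members=members)


def extract_neighborhoods(
    collection: Collection,
    anchors: Iterable[str],
    window: int = 5,
    gap_cutoff: int = 100,
) -> list[Neighborhood]:
    return [
        extract_neighborhood(collection, a, window=window, gap_cutoff=gap_cutoff)
        for a in sorted(anchors)
    ]


# ---------------------------------------------------------------------------
# conserved contexts


@dataclass(frozen=True)
class NeighborhoodContext:
    anchor_family: str
    partner_family: str
    orientation: str  # same_strand | opposite | any
    support: int  # distinct supporting genomes
    supporting_genomes: tuple[str, ...]
    distinct_taxa: int


def mine_contexts(
    neighborhoods: Sequence[Neighborhood],
    annotations: Mapping[str, frozenset | set],
    genome_taxids: Mapping[str, int],
    min_support: int = 3,
    min_taxa: int = 2,
    orientation_consensus: float = 0.8,
) -> list[NeighborhoodContext]:
    """Aggregate recurrent (anchor family, partner family) associations.

    For every neighborhood whose anchor carries a family annotation, each
    annotated non-anchor member contributes one instance per family pair.
    Pairs are emitted when supported by at least ``min_support`` distinct
    genomes spanning at least ``min_taxa`` distinct taxids (phyletic
    filter).  Orientation is called same_strand/opposite when at least
    ``orientation_consensus`` of instances agree, otherwise "any".
    """
    genomes: dict[tuple[str, str], set] = defaultdict(set)
    strands: dict[tuple[str, str], list[str]] = defaultdict(list)
    for nb in neighborhoods:
        anchor_fams = annotations.get(nb.anchor_id, frozenset())
        if not anchor_fams:
            continue
        for m in nb.members:
            if m.protein_id == nb.anchor_id:
                continue
            for pf in annotations.get(m.protein_id, frozenset()):
                for af in anchor_fams:
                    key = (af, pf)
                    genomes[key].add(nb.genome_id)
                    strands[key].append(m.strand_rel)
    out = []
    for (af, pf), gset in sorted(genomes.items()):
        support = len(gset)
        taxa = len({genome_taxids[g] for g in gset})
        if support < min_support or taxa < min_taxa:
            continue
        ss = strands[(af, pf)]
        frac_same = ss.count("+") / len(ss)
        if frac_same >= orientation_consensus:
            orientation = "same_strand"
        elif (1.0 - frac_same) >= orientation_consensus:
            orientation = "opposite"
        else:
            orientation = "any"
        out.append(
            NeighborhoodContext(
                anchor_family=af,
                partner_family=pf,
                orientation=orientation,
                support=support,
                supporting_genomes=tuple(sorted(gset)),
                distinct_taxa=taxa,
            )
        )
    return out


def contexts_to_frame(contexts: Sequence[NeighborhoodContext]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "anchor_family": c.anchor_family,
                "partner_family": c.partner_family,
                "orientation": c.orientation,
                "support": c.support,
                "distinct_taxa": c.distinct_taxa,
                "genome_ids": ",".join(c.supporting_genomes),
            }
            for c in contexts
        ],
        columns=[
            "anchor_family",
            "partner_family",
            "orientation",
            "support",
            "distinct_taxa",
            "genome_ids",
        ],
    )


# ---------------------------------------------------------------------------
# contextual absence


@dataclass(frozen=True)
class CandidateLocus:
    genome_id: str
    protein_id: str
    target_family: str
    neighbor_families: tuple[str, ...]  # what IS present nearby


def absence_query(
    collection: Collection,
    annotations: Mapping[str, frozenset | set],
    target_families: Iterable[str],
    excluded_partner_families: Iterable[str],
    window: int = 5,
    gap_cutoff: int = 100,
) -> list[CandidateLocus]:
    """Loci where a target family occurs uncoupled from any excluded partner.

    A locus is reported when the target protein's filtered neighborhood —
    including the target protein's own other domains — contains no member
    of ``excluded_partner_families``.  Each candidate lists the families
    that are present in the neighborhood, for downstream inspection.
    """
    targets = set(target_families)
    excluded = set(excluded_partner_families)
    if not targets:
        return []
    out = []
    for p in collection.proteins:
        fams = annotations.get(p.protein_id, frozenset())
        hit_targets = sorted(targets & set(fams))
        if not hit_targets:
            continue
        nb = extract_neighborhood(collection, p.protein_id, window=window, gap_cutoff=gap_cutoff)
        nearby: list[str] = []
        for m in nb.members:
            for f in sorted(annotations.get(m.protein_id, frozenset())):
                if m.protein_id == p.protein_id and f in targets:
                    continue
                nearby.append(f)
        if excluded & set(nearby):
            continue
        for tf in hit_targets:
            out.append(
                CandidateLocus(
                    genome_id=p.genome_id,
                    protein_id=p.protein_id,
                    target_family=tf,
                    neighbor_families=tuple(sorted(set(nearby))),
                )
            )
    return out
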