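"""Architectures, neighborhood extraction, context mining, absence queries."""

import pytest

from viranet import genome_context as gc
from viranet.dataset_io import Collection, GenomeRecord
from viranet.profile_scan import DomainHit

from conftest import make_protein


def _hit(pid, fam, start, end, score=100.0, it=1):
    return DomainHit(pid, fam, start, end, score, 1e-5, it)


class TestArchitectures:
    def test_non_overlapping_hits_ordered_by_start(self):
        arcs = gc.detect_architectures(
            [_hit("p", "Macro", 100, 220), _hit("p", "NADAR", 5, 80)]
        )
        assert arcs[0].architecture_string == "NADAR+Macro"

    def test_identical_span_keeps_higher_score(self):
        arcs = gc.detect_architectures(
            [_hit("p", "A", 10, 60, score=50), _hit("p", "B", 10, 60, score=30)]
        )
        assert arcs[0].families == ("A",)

    def test_partial_overlap_below_threshold_kept(self):
        # overlap 26 of the 51-residue shorter span (51%) -> dropped at 0.5,
        # kept at 0.6
        hits = [_hit("p", "A", 1, 60, score=90), _hit("p", "B", 35, 85, score=50)]
        assert gc.detect_architectures(hits, overlap_frac=0.5)[0].families == ("A",)
        assert gc.detect_architectures(hits, overlap_frac=0.6)[0].families == ("A", "B")

    def test_matches_stepwise_greedy_oracle(self, rng):
        for _ in range(30):
            hits = []
            for i in range(5):
                s = int(rng.integers(1, 150))
                hits.append(
                    _hit("p", f"F{i}", s, s + int(rng.integers(20, 80)),
                         score=float(rng.integers(10, 100)))
                )
            got = gc.detect_architectures(hits, overlap_frac=0.5)[0].families
            # independent reimplementation of the stated greedy rule
            kept = []
            for h in sorted(hits, key=lambda h: (-h.score, h.ali_start, h.family_id)):
                ok = True
                for r in kept:
                    ov = min(h.ali_end, r.ali_end) - max(h.ali_start, r.ali_start) + 1
                    shorter = min(h.ali_end - h.ali_start, r.ali_end - r.ali_start) + 1
                    if ov > 0.5 * shorter:
                        ok = False
                if ok:
                    kept.append(h)
            expected = tuple(
                h.family_id for h in sorted(kept, key=lambda h: (h.ali_start, h.family_id))
            )
            assert got == expected


def _linear_genome(strands=("+", "+", "+"), coords=((100, 400), (500, 900), (1100, 1500))):
    genomes = [GenomeRecord("g1", 7, 5000, "dsDNA", "bacteria")]
    proteins = [
        make_protein(f"g1_p{i}", "g1", s, e, strand=st, seq="M" * 50)
        for i, ((s, e), st) in enumerate(zip(coords, strands))
    ]
    return Collection(genomes=genomes, proteins=proteins)


class TestNeighborhoods:
    def test_gap_cutoff_stops_walk(self):
        # gaps are 99 (passes) and 199 (stops): neighborhood is two genes
        coll = _linear_genome()
        nb = gc.extract_neighborhood(coll, "g1_p0", gap_cutoff=100)
        assert [m.protein_id for m in nb.members] == ["g1_p0", "g1_p1"]
        assert nb.members[1].gap_prev == 99

    def test_isolated_anchor_is_alone(self):
        coll = _linear_genome(coords=((100, 400), (1500, 1900), (3000, 3400)))
        nb = gc.extract_neighborhood(coll, "g1_p1", gap_cutoff=100)
        assert [m.protein_id for m in nb.members] == ["g1_p1"]

    def test_window_limits_extent(self):
        coords = tuple((1 + 350 * i, 300 + 350 * i) for i in range(12))
        coll = _linear_genome(strands=("+",) * 12, coords=coords)
        nb = gc.extract_neighborhood(coll, "g1_p0", window=5, gap_cutoff=100)
        assert len(nb.members) == 6  # anchor plus 5 downstream

    def test_minus_anchor_canonicalized(self):
        # anchor on minus with one plus neighbor downstream: canonical view
        # puts the neighbor upstream on the minus strand
        coll = _linear_genome(strands=("-", "+", "+"),
                              coords=((100, 400), (450, 900), (2000, 2400)))
        nb = gc.extract_neighborhood(coll, "g1_p0", gap_cutoff=100)
        assert [m.protein_id for m in nb.members] == ["g1_p1", "g1_p0"]
        assert [m.strand_rel for m in nb.members] == ["-", "+"]

    def test_canonicalization_is_involutive(self):
        # flipping the entire genome's strands and coordinates reproduces
        # the same canonical neighborhood shape
        coll = _linear_genome(strands=("-", "-", "+"))
        nb = gc.extract_neighborhood(coll, "g1_p1", gap_cutoff=200)
        L = 5000
        flipped = Collection(
            genomes=[GenomeRecord("g1", 7, 5000, "dsDNA", "bacteria")],
            proteins=[
                make_protein(
                    p.protein_id, "g1", L - p.end + 1, L - p.start + 1,
                    strand="+" if p.strand == "-" else "-", seq=p.sequence,
                )
                for p in coll.proteins
            ],
        )
        nb2 = gc.extract_neighborhood(flipped, "g1_p1", gap_cutoff=200)
        assert [m.protein_id for m in nb.members] == [m.protein_id for m in nb2.members]
        assert [m.strand_rel for m in nb.members] == [m.strand_rel for m in nb2.members]
        assert [m.gap_prev for m in nb.members] == [m.gap_prev for m in nb2.members]

    def test_unknown_anchor_raises(self):
        with pytest.raises(KeyError):
            gc.extract_neighborhood(_linear_genome(), "nope")


def _context_fixture(n_genomes=7, taxids=(1, 1, 2, 2, 3, 3, 4)):
    genomes, proteins = [], []
    for i in range(n_genomes):
        gid = f"g{i}"
        genomes.append(GenomeRecord(gid, taxids[i], 10_000, "dsDNA", "bacteria"))
        proteins += [
            make_protein(f"{gid}_a", gid, 100, 400, seq="M" * 40),
            make_protein(f"{gid}_b", gid, 450, 800, seq="M" * 40),
        ]
    coll = Collection(genomes=genomes, proteins=proteins)
    annotations = {}
    for i in range(n_genomes):
        annotations[f"g{i}_a"] = frozenset({"NADAR"})
        annotations[f"g{i}_b"] = frozenset({"NadM"})
    return coll, annotations


class TestMineContexts:
    def test_planted_adjacency_counted_across_taxa(self):
        coll, ann = _context_fixture()
        nbs = gc.extract_neighborhoods(coll, sorted(ann))
        ctxs = gc.mine_contexts(nbs, ann, coll.genome_taxids, min_support=3, min_taxa=2)
        pair = {(c.anchor_family, c.partner_family): c for c in ctxs}
        c = pair[("NADAR", "NadM")]
        assert c.support == 7 and c.distinct_taxa == 4
        assert c.orientation == "same_strand"

    def test_support_below_threshold_not_emitted(self):
        coll, ann = _context_fixture(n_genomes=2, taxids=(1, 2))
        nbs = gc.extract_neighborhoods(coll, sorted(ann))
        assert gc.mine_contexts(nbs, ann, coll.genome_taxids, min_support=3) == []

    def test_single_taxon_support_fails_phyletic_filter(self):
        coll, ann = _context_fixture(n_genomes=5, taxids=(9, 9, 9, 9, 9))
        nbs = gc.extract_neighborhoods(coll, sorted(ann))
        assert gc.mine_contexts(nbs, ann, coll.genome_taxids, min_support=3, min_taxa=2) == []

    def test_support_matches_bruteforce_pair_counting(self, rng):
        coll, ann = _context_fixture()
        nbs = gc.extract_neighborhoods(coll, sorted(ann))
        ctxs = gc.mine_contexts(nbs, ann, coll.genome_taxids, min_support=1, min_taxa=1)
        # brute force: count genomes per (anchor fam, partner fam) pair
        expected = {}
        for nb in nbs:
            for af in ann.get(nb.anchor_id, ()):
                for m in nb.members:
                    if m.protein_id == nb.anchor_id:
                        continue
                    for pf in ann.get(m.protein_id, ()):
                        expected.setdefault((af, pf), set()).add(nb.genome_id)
        got = {(c.anchor_family, c.partner_family): set(c.supporting_genomes) for c in ctxs}
        assert got == expected


class TestAbsenceQuery:
    def _fixture(self):
        genomes = [
            GenomeRecord("coupled", 1, 10_000, "dsDNA", "bacteria"),
            GenomeRecord("free", 2, 10_000, "dsDNA", "bacteria"),
        ]
        proteins = [
            make_protein("coupled_arg", "coupled", 100, 400, seq="M" * 40),
            make_protein("coupled_art", "coupled", 450, 800, seq="M" * 40),
            make_protein("free_arg", "free", 100, 400, seq="M" * 40),
            make_protein("free_tf", "free", 450, 800, seq="M" * 40),
            make_protein("free_ph", "free", 850, 1200, seq="M" * 40),
        ]
        coll = Collection(genomes=genomes, proteins=proteins)
        ann = {
            "coupled_arg": frozenset({"ARG"}),
            "coupled_art": frozenset({"ART"}),
            "free_arg": frozenset({"ARG"}),
            "free_tf": frozenset({"NudixTF"}),
            "free_ph": frozenset({"Phosphatase"}),
        }
        return coll, ann

    def test_coupled_locus_excluded_free_locus_reported(self):
        coll, ann = self._fixture()
        out = gc.absence_query(coll, ann, ["ARG"], ["ART", "Sir2"])
        assert [c.protein_id for c in out] == ["free_arg"]
        assert out[0].neighbor_families == ("NudixTF", "Phosphatase")

    def test_empty_target_set_gives_empty_result(self):
        coll, ann = self._fixture()
        assert gc.absence_query(coll, ann, [], ["ART"]) == []

    def test_fused_excluded_partner_blocks_locus(self):
        coll, ann = self._fixture()
        ann = dict(ann)
        ann["free_arg"] = frozenset({"ARG", "ART"})  # fusion carries the partner
        out = gc.absence_query(coll, ann, ["ARG"], ["ART"])
        assert out == []
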