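import numpy as np
import pytest

from viranet.dataset_io import Collection, GenomeRecord, ProteinRecord


def make_protein(pid, gid, start, end, strand="+", seq="MKV"):
    return ProteinRecord(
        protein_id=pid, genome_id=gid, start=start, end=end, strand=strand, sequence=seq
    )


@pytest.fixture
def tiny_collection():
    """Two genomes, five proteins, deliberately passed in unsorted order."""
    genomes = [
        GenomeRecord("gA", 101, 5000, "dsDNA", "bacteria", "myovirus"),
        GenomeRecord("gB", 102, 3000, "ssRNA_pos", "eukaryote"),
    ]
    proteins = [
        make_protein("gA_p2", "gA", 1200, 2100),
        make_protein("gA_p1", "gA", 100, 1000),
        make_protein("gA_p3", "gA", 2200, 3000, strand="-"),
        make_protein("gB_p2", "gB", 900, 1800),
        make_protein("gB_p1", "gB", 10, 800),
    ]
    return Collection(genomes=genomes, proteins=proteins)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_protein_sequence(rng, length):
    from viranet.dataset_io import AA_ALPHABET

    return "".join(rng.choice(list(AA_ALPHABET), size=length))


def planted_proteins(rng, family, n_planted, n_background, identity=0.9, length=240):
    """Background proteins plus proteins carrying a planted family segment."""
    from viranet import synthetic_genomes as sg

    cons = sg.family_consensus(family)
    prots = []
    for i in range(n_planted):
        bg = random_protein_sequence(rng, length)
        seg = sg.mutate_sequence(cons, identity, rng)
        pos = int(rng.integers(0, length - len(seg)))
        seq = bg[:pos] + seg + bg[pos + len(seg):]
        prots.append(ProteinRecord(f"plant{i:03d}", "G0", 1 + 10 * i, 3 + 10 * i, "+", seq))
    for i in range(n_background):
        prots.append(
            ProteinRecord(
                f"bg{i:03d}", "G0", 100_000 + 10 * i, 100_002 + 10 * i, "+",
                random_protein_sequence(rng, length),
            )
        )
    return prots


def distant_subfamily_case():
    """A seed family, intermediates at ~50% identity, and a distant relative
    sharing only 6/60 consensus positions: the distant sequence is reachable
    only after the intermediates broaden the profile."""
    import numpy as np

    from viranet import synthetic_genomes as sg
    from viranet.dataset_io import AA_ALPHABET

    cons = sg.family_consensus("STEP")
    rng = np.random.default_rng(0)
    other = {}
    for i, c in enumerate(cons):
        choices = [a for a in AA_ALPHABET if a != c]
        other[i] = choices[int(rng.integers(0, 19))]
    distant = "".join(other[i] if i >= 6 else cons[i] for i in range(60))
    intermediate = "".join(other[i] if i < 30 else cons[i] for i in range(60))
    prots = [ProteinRecord("distant", "G0", 500, 600, "+", distant)]
    for i in range(6):
        prots.append(
            ProteinRecord(f"mid{i}", "G0", 1000 + 10 * i, 1005 + 10 * i, "+", intermediate)
        )
    for i in range(25):
        prots.append(
            ProteinRecord(
                f"bg{i:02d}", "G0", 2000 + 10 * i, 2005 + 10 * i, "+",
                random_protein_sequence(rng, 60),
            )
        )
    return prots
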