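"""Synthetic viral genome collections with planted, parameterized structure.

The generator emits collections that echo the statistical features of a
real viral survey — genome-length-dependent domain carriage with distinct
DNA/RNA midpoints, morphology-biased carriage in tailed phages, conserved
gene neighborhoods (anchor/partner genes co-inserted within a small
inter-gene gap), and positive pairwise co-occurrence of selected families —
together with complete truth tables, so that every downstream stage
(scanning, clustering, context mining, statistics) can be scored against
known ground truth.

Carriage model: for family *f* in a genome of length L, the carriage
probability is ``max_prob * expit(slope * (log10 L - log10 midpoint))``
with a per-morphology log-odds shift, or an explicit per-size-class
probability table when one is configured.  Pairwise dependence between the
families in ``cooccur_group`` is induced by a Gaussian copula with
equicorrelation ``cooccur_rho`` (rho = 0 recovers independence).

Carried families are realized by splicing a domain segment — the family
consensus mutated to ``identity_target`` — into a background gene drawn
from fixed standard amino-acid frequencies.  Family consensus sequences are
derived deterministically from the family name, so the seed alignments used
for scanning and the planted segments agree by construction.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit, ndtr

from .dataset_io import (
    AA_ALPHABET,
    Collection,
    GenomeRecord,
    ProteinRecord,
)
from .netstats import SizeClassConfig
from .profile_scan import BACKGROUND

_LETTERS = np.array(list(AA_ALPHABET))
_CUM_BG = np.cumsum(BACKGROUND)
RNA_CLASSES = frozenset({"dsRNA", "ssRNA_pos", "ssRNA_neg", "retro"})


class GenerationError(RuntimeError):
    """A genome cannot host its planted genes (infeasible layout)."""


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class FamilyParams:
    """Carriage model for one planted domain family.

    Either a logistic curve in log10 genome length (slope, per-group
    midpoint, ceiling ``max_prob``), a constant (``const_prob``), or an
    explicit per-size-class table (``class_probs``).  ``morphology_shift``
    is a log-odds increment applied to myoviruses on top of any model.
    """

    classes: tuple[str, ...] = ("dsDNA",)
    slope: float = 6.0
    midpoint_dna: float = 60_000.0
    midpoint_rna: float = 17_500.0
    max_prob: float = 0.8
    morphology_shift: float = 0.0
    const_prob: float | None = None
    class_probs: tuple[tuple[str, float], ...] | None = None
    segment_length: int = 60


@dataclass(frozen=True)
class ContextRule:
    """Planted neighborhood: when the anchor family is carried, the partner
    gene is co-inserted adjacently (same strand, gap <= max_gap nt) with
    the given probability."""

    anchor: str
    partner: str
    prob: float
    max_gap: int = 100


@dataclass(frozen=True)
class GapModel:
    within_operon: tuple[int, int] = (0, 60)
    between_operon: tuple[int, int] = (150, 500)
    operon_break_prob: float = 0.25


DEFAULT_FAMILY_PARAMS: dict[str, FamilyParams] = {
    "ART": FamilyParams(slope=5.0, midpoint_dna=55_000, max_prob=0.75, morphology_shift=1.2),
    "Macro": FamilyParams(classes=("dsDNA", "ssRNA_pos"), midpoint_dna=70_000, max_prob=0.6),
    "NADAR": FamilyParams(
        classes=("dsDNA", "ssRNA_pos"), midpoint_dna=80_000, midpoint_rna=18_000, max_prob=0.5
    ),
    "SLOG": FamilyParams(midpoint_dna=90_000, max_prob=0.4),
    "Nudix": FamilyParams(slope=5.0, midpoint_dna=70_000, max_prob=0.5, morphology_shift=0.5),
    "NadM": FamilyParams(midpoint_dna=100_000, max_prob=0.3),
    "NadV": FamilyParams(midpoint_dna=90_000, max_prob=0.35),
    "ARG": FamilyParams(slope=5.0, midpoint_dna=100_000, max_prob=0.25),
    "Sir2": FamilyParams(slope=5.0, midpoint_dna=80_000, max_prob=0.3),
    # terminase large subunit: phage hallmark gene used as a neighborhood
    # anchor; not part of the NAD+/ADPr network itself
    "TerL": FamilyParams(const_prob=0.95),
}

DEFAULT_NETWORK_FAMILIES = tuple(
    f for f in sorted(DEFAULT_FAMILY_PARAMS) if f != "TerL"
)

DEFAULT_CONTEXT_RULES = (
    ContextRule("NADAR", "NadM", 0.7),
    ContextRule("NadM", "NadV", 0.8),
    ContextRule("TerL", "ART", 0.5),
    ContextRule("Macro", "SLOG", 0.4),
)

DEFAULT_CLASS_MIX = (
    (("dsDNA", "bacteria"), 0.62),
    (("ssDNA", "bacteria"), 0.05),
    (("dsDNA", "eukaryote"), 0.08),
    (("ssRNA_pos", "eukaryote"), 0.17),
    (("ssRNA_neg", "eukaryote"), 0.04),
    (("dsRNA", "eukaryote"), 0.03),
    (("retro", "eukaryote"), 0.01),
)

DEFAULT_LENGTH_MODEL = {
    "dsDNA": ("lognormal", math.log(50_000.0), 0.9),
    "ssDNA": ("lognormal", math.log(5_500.0), 0.35),
    "ssRNA_pos": ("lognormal", math.log(12_000.0), 0.45),
    "ssRNA_neg": ("lognormal", math.log(11_000.0), 0.35),
    "dsRNA": ("lognormal", math.log(9_000.0), 0.4),
    "retro": ("lognormal", math.log(8_000.0), 0.25),
}

DEFAULT_MORPHOLOGY_MIX = (
    ("myovirus", 0.35),
    ("siphovirus", 0.45),
    ("podovirus", 0.15),
    ("other", 0.05),
)


@dataclass
class GeneratorConfig:
    n_genomes: int = 300
    seed: int = 0
    class_mix: tuple = DEFAULT_CLASS_MIX
    length_model: Mapping[str, tuple] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_MODEL)
    )
    gene_length_model: tuple[float, float] = (3.0, 80.0)  # gamma shape, scale (codons)
    min_gene_codons: int = 60
    gap_model: GapModel = field(default_factory=GapModel)
    morphology_mix: tuple = DEFAULT_MORPHOLOGY_MIX
    family_params: Mapping[str, FamilyParams] = field(
        default_factory=lambda: dict(DEFAULT_FAMILY_PARAMS)
    )
    context_params: tuple[ContextRule, ...] = DEFAULT_CONTEXT_RULES
    cooccur_rho: float = 0.4
    cooccur_group: tuple[str, ...] = ("Macro", "NADAR", "SLOG", "Nudix")
    identity_target: float = 0.9
    network_families: tuple[str, ...] = DEFAULT_NETWORK_FAMILIES
    size_classes: SizeClassConfig = field(default_factory=SizeClassConfig)
    emit_proteins: bool = True
    taxid_dup_prob: float = 0.0
    min_genome_length: int = 1200

    def __post_init__(self):
        total = sum(p for _, p in self.class_mix)
        if not math.isclose(total, 1.0, abs_tol=1e-6):
            raise ValueError("class_mix proportions must sum to 1")
        if not 0.0 <= self.cooccur_rho < 1.0:
            raise ValueError("cooccur_rho must lie in [0, 1)")
        if not 0.0 < self.identity_target <= 1.0:
            raise ValueError("identity_target must lie in (0, 1]")


# ---------------------------------------------------------------------------
# truth tables


@dataclass(frozen=True)
class ContextTruth:
    genome_id: str
    anchor_protein: str
    partner_protein: str
    anchor_family: str
    partner_family: str


@dataclass
class TruthTables:
    genome_truth: dict[str, frozenset]  # genome_id -> planted families
    hit_truth: dict[str, tuple[str, int, int]]  # protein_id -> (family, start, end)
    context_truth: list[ContextTruth]


# ---------------------------------------------------------------------------
# deterministic family sequences


def _family_rng(family_id: str, salt: str = "") -> np.random.Generator:
    return np.random.default_rng(zlib.crc32(f"{family_id}/{salt}".encode()) & 0x7FFFFFFF)


def _background_indices(rng: np.random.Generator, n: int) -> np.ndarray:
    return np.searchsorted(_CUM_BG, rng.random(n))


def family_consensus(family_id: str, length: int = 60) -> str:
    """Deterministic consensus sequence for a family, derived from its name."""
    rng = _family_rng(family_id, "consensus")
    return "".join(_LETTERS[_background_indices(rng, length)])


def mutate_sequence(seq: str, identity: float, rng: np.random.Generator) -> str:
    """Point-mutate: each position is replaced by a background draw with
    probability 1 - identity (the draw may coincide with the original)."""
    arr = np.array(list(seq))
    mask = rng.random(len(arr)) < (1.0 - identity)
    n_mut = int(mask.sum())
    if n_mut:
        arr[mask] = _LETTERS[_background_indices(rng, n_mut)]
    return "".join(arr)


def seed_alignment(
    family_id: str, n_seqs: int = 6, identity: float = 0.9, length: int = 60
) -> list[str]:
    """Deterministic gap-free seed alignment: consensus plus mutated copies."""
    rng = _family_rng(family_id, "seed")
    cons = family_consensus(family_id, length)
    return [cons] + [mutate_sequence(cons, identity, rng) for _ in range(n_seqs - 1)]


def write_seed_alignments(
    families: Iterable[str], out_dir, n_seqs: int = 6, identity: float = 0.9, length: int = 60
) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for fam in sorted(families):
        rows = seed_alignment(fam, n_seqs=n_seqs, identity=identity, length=length)
        path = out / f"{fam}.afa"
        with open(path, "w") as fh:
            for i, row in enumerate(rows):
                fh.write(f">{fam}_seed{i}\n{row}\n")
        paths[fam] = path
    return paths


# ---------------------------------------------------------------------------
# carriage model


def carriage_probability(
    fp: FamilyParams,
    na_class: str,
    genome_length: float,
    morphology: str,
    size_classes: SizeClassConfig,
) -> float:
    """Probability that a genome of this class/length/morphology carries the family."""
    if na_class not in fp.classes:
        return 0.0
    if fp.const_prob is not None:
        p = fp.const_prob
    elif fp.class_probs is not None:
        table = dict(fp.class_probs)
        name = size_classes.classify(genome_length)
        p = table.get(name if name is not None else "unclassed", table.get("unclassed", 0.0))
    else:
        mid = fp.midpoint_rna if na_class in RNA_CLASSES else fp.midpoint_dna
        eta = fp.slope * (math.log10(genome_length) - math.log10(mid))
        p = fp.max_prob * expit(eta)
    if morphology == "myovirus" and fp.morphology_shift != 0.0 and 0.0 < p < 1.0:
        p = float(expit(logit(min(max(p, 1e-12), 1.0 - 1e-12)) + fp.morphology_shift))
    return float(min(max(p, 0.0), 1.0))


def _draw_carriage(
    config: GeneratorConfig,
    fams: Sequence[str],
    probs: np.ndarray,
    rng: np.random.Generator,
) -> set[str]:
    u = rng.random(len(fams))
    group = [i for i, f in enumerate(fams) if f in config.cooccur_group]
    if config.cooccur_rho > 0.0 and len(group) > 1:
        shared = rng.standard_normal()
        eps = rng.standard_normal(len(group))
        z = math.sqrt(config.cooccur_rho) * shared + math.sqrt(1.0 - config.cooccur_rho) * eps
        u[group] = ndtr(z)
    return {f for f, ui, pi in zip(fams, u, probs) if ui < pi}


# ---------------------------------------------------------------------------
# genome assembly


def _draw_length(config: GeneratorConfig, na_class: str, rng: np.random.Generator) -> int:
    model = config.length_model[na_class]
    kind = model[0]
    if kind == "lognormal":
        L = rng.lognormal(mean=model[1], sigma=model[2])
    elif kind == "uniform":
        L = rng.uniform(model[1], model[2])
    else:
        raise ValueError(f"unknown length model {kind!r}")
    return max(int(round(L)), config.min_genome_length)


def _pick(rng: np.random.Generator, options: Sequence, probs: Sequence[float]):
    return options[rng.choice(len(options), p=np.asarray(probs) / np.sum(probs))]


def _gene_codons(config: GeneratorConfig, rng: np.random.Generator, min_codons: int = 0) -> int:
    shape, scale = config.gene_length_model
    return max(config.min_gene_codons, min_codons, int(round(rng.gamma(shape, scale))))


def generate_collection(config: GeneratorConfig) -> tuple[Collection, TruthTables]:
    """Generate a collection plus truth tables under the configured model.

    With ``emit_proteins=False`` only genome records and the genome-level
    carriage truth are produced (no gene layout or sequences) — a fast path
    for statistical calibration at large genome counts.
    """
    rng = np.random.default_rng(config.seed)
    fams = sorted(config.family_params)
    consensi = {
        f: family_consensus(f, config.family_params[f].segment_length) for f in fams
    }
    class_opts = [c for c, _ in config.class_mix]
    class_probs = [p for _, p in config.class_mix]
    morph_opts = [m for m, _ in config.morphology_mix]
    morph_probs = [p for _, p in config.morphology_mix]

    genomes: list[GenomeRecord] = []
    proteins: list[ProteinRecord] = []
    truth = TruthTables(genome_truth={}, hit_truth={}, context_truth=[])
    next_taxid = 1000
    prev_taxid = None

    for i in range(config.n_genomes):
        gid = f"G{i:05d}"
        na_class, host = _pick(rng, class_opts, class_probs)
        if na_class == "dsDNA" and host == "bacteria":
            morphology = _pick(rng, morph_opts, morph_probs)
        else:
            morphology = "unknown"
        if prev_taxid is not None and rng.random() < config.taxid_dup_prob:
            taxid = prev_taxid
        else:
            taxid = next_taxid
            next_taxid += 1
        prev_taxid = taxid
        L = _draw_length(config, na_class, rng)

        probs = np.array(
            [
                carriage_probability(
                    config.family_params[f], na_class, L, morphology, config.size_classes
                )
                for f in fams
            ]
        )
        carried = _draw_carriage(config, fams, probs, rng)

        # planted neighborhoods: co-insert partner next to anchor
        bundles: list[ContextRule] = []
        bundled: set[str] = set()
        for rule in config.context_params:
            if (
                rule.anchor in carried
                and rule.anchor not in bundled
                and rule.partner not in bundled
                and rng.random() < rule.prob
            ):
                carried.add(rule.partner)
                bundles.append(rule)
                bundled.update((rule.anchor, rule.partner))
        singles = [f for f in sorted(carried) if f not in bundled]

        if not config.emit_proteins:
            genomes.append(
                GenomeRecord(
                    genome_id=gid, taxid=taxid, genome_length=L, na_class=na_class,
                    host=host, morphology=morphology, protein_count=0,
                )
            )
            truth.genome_truth[gid] = frozenset(carried)
            continue

        genome_proteins, max_end = _layout_genome(
            config, gid, L, bundles, singles, consensi, rng, truth
        )
        genomes.append(
            GenomeRecord(
                genome_id=gid,
                taxid=taxid,
                genome_length=max(L, max_end),
                na_class=na_class,
                host=host,
                morphology=morphology,
                protein_count=len(genome_proteins),
            )
        )
        truth.genome_truth[gid] = frozenset(carried)
        proteins.extend(genome_proteins)

    return Collection(genomes=genomes, proteins=proteins), truth


def _layout_genome(
    config: GeneratorConfig,
    gid: str,
    L: int,
    bundles: list[ContextRule],
    singles: list[str],
    consensi: Mapping[str, str],
    rng: np.random.Generator,
    truth: TruthTables,
) -> tuple[list[ProteinRecord], int]:
    """Tile one genome with genes and return its proteins and last end."""
    gm = config.gap_model
    # items: tuples of gene slots; each slot is a family name or None
    items: list[tuple[str | None, ...]] = [(r.anchor, r.partner) for r in bundles]
    items += [(f,) for f in singles]
    n_special_genes = sum(len(it) for it in items)

    shape, scale = config.gene_length_model
    mean_gene_nt = 3.0 * max(shape * scale, config.min_gene_codons)
    mean_gap = (
        gm.operon_break_prob * np.mean(gm.between_operon)
        + (1 - gm.operon_break_prob) * np.mean(gm.within_operon)
    )
    n_target = max(1, int(L // (mean_gene_nt + mean_gap)))
    n_bg = max(0, n_target - n_special_genes)
    items += [(None,) for _ in range(n_bg)]

    # feasibility: the largest single planted gene must fit
    for it in items[: len(bundles) + len(singles)]:
        for fam in it:
            need = 3 * (len(consensi[fam]) + 20)
            if need > L:
                raise GenerationError(
                    f"genome {gid}: planted {fam} gene ({need} nt) exceeds genome length {L}"
                )

    order = rng.permutation(len(items))
    cur = 1 + int(rng.integers(0, 50))
    strand = "+" if rng.random() < 0.5 else "-"
    placed: list[tuple[int, int, str, str | None]] = []  # start, end, strand, family
    max_end = 0
    for k, idx in enumerate(order):
        item = items[idx]
        is_special = item[0] is not None
        if not is_special and cur > L - int(mean_gene_nt):
            continue  # genome full; only planted genes may still be placed
        bundle_rule = None
        if len(item) == 2:
            bundle_rule = next(r for r in bundles if (r.anchor, r.partner) == item)
        for j, fam in enumerate(item):
            if fam is not None:
                codons = _gene_codons(config, rng, min_codons=len(consensi[fam]) + 20)
            else:
                codons = _gene_codons(config, rng)
            nt = 3 * codons
            start, end = cur, cur + nt - 1
            placed.append((start, end, strand, fam))
            max_end = max(max_end, end)
            # gap and strand to the next gene
            if bundle_rule is not None and j == 0:
                gap = int(rng.integers(0, min(gm.within_operon[1], bundle_rule.max_gap) + 1))
            elif rng.random() < gm.operon_break_prob:
                gap = int(rng.integers(gm.between_operon[0], gm.between_operon[1] + 1))
                strand = "+" if rng.random() < 0.5 else "-"
            else:
                gap = int(rng.integers(gm.within_operon[0], gm.within_operon[1] + 1))
            cur = end + 1 + gap

    placed.sort(key=lambda t: t[0])

    # sequences: one background draw for the whole genome, then splice domains
    lengths_aa = [(e - s + 1) // 3 for s, e, _, _ in placed]
    total = sum(lengths_aa)
    residues = _LETTERS[_background_indices(rng, total)]
    seqs: list[str] = []
    offset = 0
    for (s, e, st, fam), n_aa in zip(placed, lengths_aa):
        block = residues[offset : offset + n_aa]
        offset += n_aa
        seqs.append("".join(block))

    out: list[ProteinRecord] = []
    context_slots: dict[tuple[int, int], tuple[str, str]] = {}
    pid_of_index: dict[int, str] = {}
    for serial, ((s, e, st, fam), seq) in enumerate(zip(placed, seqs)):
        pid = f"{gid}_p{serial:03d}"
        pid_of_index[serial] = pid
        if fam is not None:
            segment = mutate_sequence(consensi[fam], config.identity_target, rng)
            pos = int(rng.integers(0, len(seq) - len(segment) + 1))
            seq = seq[:pos] + segment + seq[pos + len(segment) :]
            truth.hit_truth[pid] = (fam, pos + 1, pos + len(segment))
        out.append(
            ProteinRecord(
                protein_id=pid, genome_id=gid, start=s, end=e, strand=st, sequence=seq
            )
        )

    # record planted context pairs by locating the adjacent planted genes
    fam_by_pid = {p.protein_id: f for p, (_, _, _, f) in zip(out, placed)}
    for rule in bundles:
        anchor_pid = partner_pid = None
        for a, b in zip(out, out[1:]):
            fa, fb = fam_by_pid[a.protein_id], fam_by_pid[b.protein_id]
            if {fa, fb} == {rule.anchor, rule.partner}:
                anchor_pid = a.protein_id if fa == rule.anchor else b.protein_id
                partner_pid = b.protein_id if fa == rule.anchor else a.protein_id
                break
        if anchor_pid is not None:
            truth.context_truth.append(
                ContextTruth(
                    genome_id=gid,
                    anchor_protein=anchor_pid,
                    partner_protein=partner_pid,
                    anchor_family=rule.anchor,
                    partner_family=rule.partner,
                )
            )
    return out, max_end


# ---------------------------------------------------------------------------
# truth I/O


def write_truth(truth: TruthTables, out_dir) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome_truth": out / "genome_truth.tsv",
        "hit_truth": out / "hit_truth.tsv",
        "context_truth": out / "context_truth.tsv",
    }
    pd.DataFrame(
        [
            {"genome_id": g, "families": ",".join(sorted(fs))}
            for g, fs in sorted(truth.genome_truth.items())
        ],
        columns=["genome_id", "families"],
    ).to_csv(paths["genome_truth"], sep="\t", index=False, lineterminator="\n")
    pd.DataFrame(
        [
            {"protein_id": p, "family": f, "ali_start": s, "ali_end": e}
            for p, (f, s, e) in sorted(truth.hit_truth.items())
        ],
        columns=["protein_id", "family", "ali_start", "ali_end"],
    ).to_csv(paths["hit_truth"], sep="\t", index=False, lineterminator="\n")
    pd.DataFrame(
        [
            {
                "genome_id": c.genome_id,
                "anchor_protein": c.anchor_protein,
                "partner_protein": c.partner_protein,
                "anchor_family": c.anchor_family,
                "partner_family": c.partner_family,
            }
            for c in truth.context_truth
        ],
        columns=[
            "genome_id", "anchor_protein", "partner_protein", "anchor_family", "partner_family",
        ],
    ).to_csv(paths["context_truth"], sep="\t", index=False, lineterminator="\n")
    return paths


def read_truth(truth_dir) -> TruthTables:
    d = Path(truth_dir)
    gt = pd.read_csv(d / "genome_truth.tsv", sep="\t", keep_default_na=False)
    ht = pd.read_csv(d / "hit_truth.tsv", sep="\t")
    ct = pd.read_csv(d / "context_truth.tsv", sep="\t")
    genome_truth = {
        str(r.genome_id): frozenset(f for f in str(r.families).split(",") if f)
        for r in gt.itertuples(index=False)
    }
    hit_truth = {
        str(r.protein_id): (str(r.family), int(r.ali_start), int(r.ali_end))
        for r in ht.itertuples(index=False)
    }
    context_truth = [
        ContextTruth(
            genome_id=str(r.genome_id),
            anchor_protein=str(r.anchor_protein),
            partner_protein=str(r.partner_protein),
            anchor_family=str(r.anchor_family),
            partner_family=str(r.partner_family),
        )
        for r in ct.itertuples(index=False)
    ]
    return TruthTables(
        genome_truth=genome_truth, hit_truth=hit_truth, context_truth=context_truth
    )
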