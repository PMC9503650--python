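"""Collection data model and I/O for genome metadata, gene coordinates and proteins.

A :class:`Collection` holds the survey's working set: one
:class:`GenomeRecord` per viral genome (taxonomy, length, nucleic-acid
class, host, virion morphology) and the genome's protein-coding genes as
:class:`ProteinRecord` objects (1-based inclusive genomic coordinates,
strand, amino-acid sequence).  On-disk representation is a metadata TSV, a
CDS-only GFF3 and a protein FASTA; ``read_collection`` and
``write_collection`` are exact inverses of each other.

The module also implements the non-redundancy step used to build the
working database: one genome per NCBI taxid, keeping the largest proteome.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping
from urllib.parse import quote, unquote

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

NA_CLASSES = ("dsDNA", "ssDNA", "dsRNA", "ssRNA_pos", "ssRNA_neg", "retro")
HOSTS = ("bacteria", "archaea", "eukaryote", "unknown")
MORPHOLOGIES = ("myovirus", "siphovirus", "podovirus", "other", "unknown")

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AA_ALPHABET)

METADATA_COLUMNS = (
    "genome_id",
    "taxid",
    "genome_length",
    "na_class",
    "host",
    "morphology",
)


class CollectionError(ValueError):
    """A collection violates a structural invariant."""


class ParseError(CollectionError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, path: str | os.PathLike = "", line: int | None = None):
        loc = f"{path}:{line}: " if line is not None else (f"{path}: " if path else "")
        super().__init__(f"{loc}{message}")
        self.line = line


class LoadError(CollectionError):
    """Cross-references between metadata, GFF3 and FASTA are inconsistent."""


def sanitize_protein_sequence(seq: str) -> str:
    """Uppercase and map any residue outside the 20-letter alphabet to X."""
    seq = seq.upper()
    if all(c in _AA_SET for c in seq):
        return seq
    return "".join(c if c in _AA_SET else "X" for c in seq)


@dataclass(frozen=True)
class GenomeRecord:
    genome_id: str
    taxid: int
    genome_length: int
    na_class: str
    host: str = "unknown"
    morphology: str = "unknown"
    protein_count: int = 0

    def __post_init__(self):
        if self.genome_length <= 0:
            raise CollectionError(f"genome {self.genome_id}: genome_length must be > 0")
        if self.protein_count < 0:
            raise CollectionError(f"genome {self.genome_id}: protein_count must be >= 0")
        if self.na_class not in NA_CLASSES:
            raise CollectionError(
                f"genome {self.genome_id}: unknown na_class {self.na_class!r}"
            )
        if self.host not in HOSTS:
            object.__setattr__(self, "host", "unknown")
        if self.morphology not in MORPHOLOGIES:
            object.__setattr__(self, "morphology", "unknown")


@dataclass(frozen=True)
class ProteinRecord:
    protein_id: str
    genome_id: str
    start: int
    end: int
    strand: str
    sequence: str

    def __post_init__(self):
        if self.end < self.start:
            raise CollectionError(
                f"protein {self.protein_id}: end ({self.end}) < start ({self.start})"
            )
        if self.strand not in ("+", "-"):
            raise CollectionError(f"protein {self.protein_id}: bad strand {self.strand!r}")
        if len(self.sequence) < 1:
            raise CollectionError(f"protein {self.protein_id}: empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class Collection:
    """Genomes plus their proteins, grouped by genome and ordered by start."""

    genomes: list[GenomeRecord]
    proteins: list[ProteinRecord]
    _by_genome: dict[str, list[ProteinRecord]] = field(
        init=False, repr=False, compare=False, default_factory=dict
    )
    _genome_index: dict[str, GenomeRecord] = field(
        init=False, repr=False, compare=False, default_factory=dict
    )

    def __post_init__(self):
        self._reindex()
        self.validate()

    def _reindex(self) -> None:
        self._genome_index = {g.genome_id: g for g in self.genomes}
        by_genome: dict[str, list[ProteinRecord]] = {g.genome_id: [] for g in self.genomes}
        for p in self.proteins:
            if p.genome_id not in by_genome:
                raise CollectionError(
                    f"protein {p.protein_id} references unknown genome {p.genome_id}"
                )
            by_genome[p.genome_id].append(p)
        for gid in by_genome:
            by_genome[gid].sort(key=lambda p: (p.start, p.end, p.protein_id))
        self._by_genome = by_genome
        # canonical protein order: genome order, then start
        self.proteins = [p for g in self.genomes for p in by_genome[g.genome_id]]

    def validate(self) -> None:
        if len(self._genome_index) != len(self.genomes):
            raise CollectionError("duplicate genome_id in collection")
        seen: set[str] = set()
        for p in self.proteins:
            if p.protein_id in seen:
                raise CollectionError(f"duplicate protein_id {p.protein_id}")
            seen.add(p.protein_id)

    def genome(self, genome_id: str) -> GenomeRecord:
        return self._genome_index[genome_id]

    def proteins_of(self, genome_id: str) -> list[ProteinRecord]:
        return self._by_genome[genome_id]

    @property
    def genome_taxids(self) -> dict[str, int]:
        return {g.genome_id: g.taxid for g in self.genomes}

    def protein(self, protein_id: str) -> ProteinRecord:
        if not hasattr(self, "_protein_index") or len(self._protein_index) != len(self.proteins):
            self._protein_index = {p.protein_id: p for p in self.proteins}
        return self._protein_index[protein_id]

    def __len__(self) -> int:
        return len(self.genomes)


# ---------------------------------------------------------------------------
# readers / writers


def _read_metadata(path: str | os.PathLike) -> list[GenomeRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"genome_id": str})
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"metadata missing columns {missing}", path)
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            records.append(
                GenomeRecord(
                    genome_id=str(row.genome_id),
                    taxid=int(row.taxid),
                    genome_length=int(row.genome_length),
                    na_class=str(row.na_class),
                    host=str(row.host),
                    morphology=str(row.morphology),
                )
            )
        except (CollectionError, ValueError) as exc:
            raise ParseError(str(exc), path, line=i) from exc
    return records


def _read_gff3_cds(path: str | os.PathLike) -> list[tuple[str, str, int, int, str]]:
    """Return (protein_id, genome_id, start, end, strand) for each CDS row."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"expected 9 columns, got {len(fields)}", path, lineno)
            seqid, _source, ftype, start_s, end_s, _score, strand, _phase, attrs = fields
            if ftype != "CDS":
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"non-integer coordinates {start_s!r}/{end_s!r}", path, lineno) from exc
            if end < start:
                raise ParseError(f"CDS end ({end}) < start ({start})", path, lineno)
            if strand not in ("+", "-"):
                raise ParseError(f"bad strand {strand!r}", path, lineno)
            attr_map = {}
            for item in attrs.split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    attr_map[k.strip()] = unquote(v)
            if "ID" not in attr_map:
                raise ParseError("CDS row lacks ID attribute", path, lineno)
            rows.append((attr_map["ID"], unquote(seqid), start, end, strand))
    return rows


def read_collection(
    metadata_path: str | os.PathLike,
    gff_path: str | os.PathLike,
    fasta_path: str | os.PathLike,
) -> Collection:
    """Load a collection from its three on-disk files and cross-validate ids."""
    genomes = _read_metadata(metadata_path)
    genome_ids = {g.genome_id for g in genomes}
    cds_rows = _read_gff3_cds(gff_path)
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        sequences[rec.id] = sanitize_protein_sequence(str(rec.seq))

    cds_ids = {r[0] for r in cds_rows}
    orphan_fasta = sorted(set(sequences) - cds_ids)
    if orphan_fasta:
        raise LoadError(f"FASTA records with no matching CDS: {', '.join(orphan_fasta)}")
    orphan_cds = sorted(cds_ids - set(sequences))
    if orphan_cds:
        raise LoadError(f"CDS features with no FASTA sequence: {', '.join(orphan_cds)}")

    proteins = []
    counts: dict[str, int] = {}
    for pid, gid, start, end, strand in cds_rows:
        if gid not in genome_ids:
            raise LoadError(f"CDS {pid} references unknown genome {gid}")
        proteins.append(
            ProteinRecord(
                protein_id=pid,
                genome_id=gid,
                start=start,
                end=end,
                strand=strand,
                sequence=sequences[pid],
            )
        )
        counts[gid] = counts.get(gid, 0) + 1
    genomes = [replace(g, protein_count=counts.get(g.genome_id, 0)) for g in genomes]
    return Collection(genomes=genomes, proteins=proteins)


def write_collection(collection: Collection, out_dir: str | os.PathLike) -> dict[str, Path]:
    """Write metadata.tsv, genomes.gff3 and proteins.faa; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "metadata": out / "metadata.tsv",
        "gff": out / "genomes.gff3",
        "fasta": out / "proteins.faa",
    }

    meta = pd.DataFrame(
        [
            {
                "genome_id": g.genome_id,
                "taxid": g.taxid,
                "genome_length": g.genome_length,
                "na_class": g.na_class,
                "host": g.host,
                "morphology": g.morphology,
            }
            for g in collection.genomes
        ],
        columns=list(METADATA_COLUMNS),
    )
    meta.to_csv(paths["metadata"], sep="\t", index=False, lineterminator="\n")

    with open(paths["gff"], "w") as fh:
        fh.write("##gff-version 3\n")
        for g in collection.genomes:
            for p in collection.proteins_of(g.genome_id):
                attrs = f"ID={quote(p.protein_id, safe='')};Parent={quote(p.protein_id, safe='')}"
                fh.write(
                    f"{quote(g.genome_id, safe='')}\tviranet\tCDS\t{p.start}\t{p.end}"
                    f"\t.\t{p.strand}\t0\t{attrs}\n"
                )

    records = [
        SeqRecord(Seq(p.sequence), id=p.protein_id, description="")
        for p in collection.proteins
    ]
    with open(paths["fasta"], "w") as fh:
        SeqIO.write(records, fh, "fasta")
    return paths


# ---------------------------------------------------------------------------
# non-redundancy


def deduplicate_by_taxid(collection: Collection) -> tuple[Collection, list[str]]:
    """Keep one genome per taxid — the largest proteome — and drop the rest.

    Proteome size is the CDS count.  Ties are broken by larger
    genome_length, then by lexicographically smallest genome_id, so the
    result is deterministic.  Returns the reduced collection and the sorted
    list of dropped genome_ids.
    """
    best: dict[int, GenomeRecord] = {}
    for g in collection.genomes:
        cur = best.get(g.taxid)
        if cur is None or _dedup_key(g) > _dedup_key(cur):
            best[g.taxid] = g
    keep_ids = {g.genome_id for g in best.values()}
    kept_genomes = [g for g in collection.genomes if g.genome_id in keep_ids]
    kept_proteins = [p for p in collection.proteins if p.genome_id in keep_ids]
    dropped = sorted(g.genome_id for g in collection.genomes if g.genome_id not in keep_ids)
    return Collection(genomes=kept_genomes, proteins=kept_proteins), dropped


def _dedup_key(g: GenomeRecord) -> tuple:
    # larger proteome, then longer genome, then smallest id wins; the id is
    # negated lexicographically by inverting each character's ordinal
    inv_id = tuple(-ord(c) for c in g.genome_id)
    return (g.protein_count, g.genome_length, inv_id)
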