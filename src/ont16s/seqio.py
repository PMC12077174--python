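"""Sequence I/O: FASTQ reads, centroid-style reference FASTA, taxonomy tables.

The reference database is a curated set of representative ("centroid") 16S
rRNA sequences, one per species group, carried as FASTA whose headers embed
the taxonomy: ``>accession|genus|species_epithet`` or
``>accession|Genus species``.  Alternatively a plain FASTA may be paired
with a taxonomy TSV (columns: accession, genus, species).

Qualities are Phred+33 (Sanger / Illumina 1.8+); other encodings are
rejected rather than guessed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTN")


class ParseError(ValueError):
    """Raised when an input file violates the expected dialect."""


@dataclass
class Read:
    """One sequenced amplicon read with per-base Phred qualities."""

    read_id: str
    sequence: str
    quals: list[int]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quals):
            raise ParseError(
                f"read {self.read_id!r}: sequence length {len(self.sequence)} "
                f"!= quality length {len(self.quals)}"
            )
        if not self.sequence:
            raise ParseError(f"read {self.read_id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def mean_quality(self) -> float:
        return sum(self.quals) / len(self.quals)


@dataclass
class CentroidRecord:
    """One representative 16S sequence for a species group."""

    accession: str
    genus: str
    species: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ParseError(f"centroid {self.accession!r}: empty sequence")
        if self.species.split()[0] != self.genus:
            raise ParseError(
                f"centroid {self.accession!r}: species {self.species!r} does "
                f"not start with genus {self.genus!r}"
            )


@dataclass
class ReferenceDB:
    """Centroid records plus an index from genus to record positions."""

    records: list[CentroidRecord]
    genus_index: dict[str, list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.genus_index:
            self.genus_index = _build_genus_index(self.records)
        seen: set[str] = set()
        for rec in self.records:
            if rec.accession in seen:
                raise ParseError(f"duplicate accession {rec.accession!r}")
            seen.add(rec.accession)
        if not self.genus_index:
            raise ParseError("reference database contains no genera")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def genera(self) -> list[str]:
        return sorted(self.genus_index)

    def records_for_genus(self, genus: str) -> list[CentroidRecord]:
        return [self.records[i] for i in self.genus_index.get(genus, [])]


def _build_genus_index(records: list[CentroidRecord]) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i, rec in enumerate(records):
        index.setdefault(rec.genus, []).append(i)
    return index


def _clean_sequence(raw: str, where: str) -> str:
    seq = raw.upper()
    bad = set(seq) - VALID_BASES
    if bad:
        raise ParseError(f"{where}: invalid characters {sorted(bad)}")
    return seq


def read_fastq(path: str | Path) -> list[Read]:
    """Parse a Phred+33 FASTQ file into a list of reads.

    Record order is preserved.  A record whose quality string does not match
    its sequence length is a parse error naming the record.
    """
    reads: list[Read] = []
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            seq = _clean_sequence(str(rec.seq), f"read {rec.id!r}")
            reads.append(
                Read(rec.id, seq, list(rec.letter_annotations["phred_quality"]))
            )
    except ValueError as exc:  # Biopython flags seq/qual length mismatch
        raise ParseError(f"{path}: {exc}") from exc
    return reads


def write_fastq(reads: Iterable[Read], path: str | Path) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.read_id, description="")
        rec.letter_annotations["phred_quality"] = list(r.quals)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


_HEADER_RE = re.compile(
    r"^(?P<acc>[^|\s]+)\|(?P<genus>[^|\s]+)(?:\|(?P<epithet>\S+)|\s+(?P<epithet2>\S+))$"
)


def _parse_header(header: str) -> tuple[str, str, str]:
    m = _HEADER_RE.match(header.strip())
    if not m:
        raise ParseError(
            f"header {header!r} does not match 'accession|genus|epithet' or "
            f"'accession|Genus epithet'"
        )
    epithet = m.group("epithet") or m.group("epithet2")
    genus = m.group("genus")
    return m.group("acc"), genus, f"{genus} {epithet}"


def read_reference_fasta(
    path: str | Path, taxonomy: str | Path | None = None
) -> ReferenceDB:
    """Load a centroid reference database from FASTA.

    Headers carry the taxonomy unless a TSV mapping (accession, genus,
    species) is given, in which case headers are bare accessions.
    """
    taxmap = read_taxonomy_tsv(taxonomy) if taxonomy is not None else None
    records: list[CentroidRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.description if rec.description else rec.id
        seq = _clean_sequence(str(rec.seq), f"record {rec.id!r}")
        if taxmap is not None:
            acc = rec.id
            if acc not in taxmap:
                raise ParseError(f"accession {acc!r} missing from taxonomy table")
            genus, species = taxmap[acc]
        else:
            acc, genus, species = _parse_header(header)
        records.append(CentroidRecord(acc, genus, species, seq))
    return ReferenceDB(records)


def write_reference_fasta(db: ReferenceDB, path: str | Path, width: int = 70) -> None:
    """Write a database back to the pipe-delimited FASTA dialect."""
    with open(path, "w") as fh:
        for rec in db.records:
            epithet = rec.species.split(maxsplit=1)[1]
            fh.write(f">{rec.accession}|{rec.genus}|{epithet}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_taxonomy_tsv(path: str | Path) -> dict[str, tuple[str, str]]:
    """Parse a TSV with columns accession, genus, species (header optional)."""
    out: dict[str, tuple[str, str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "accession":
                continue
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected 3 columns")
            acc, genus, species = parts[0], parts[1], parts[2]
            if not species.startswith(genus):
                species = f"{genus} {species}"
            if acc in out:
                raise ParseError(f"{path}:{lineno}: duplicate accession {acc!r}")
            out[acc] = (genus, species)
    return out


def write_consensus_fasta(name: str, sequence: str, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(sequence), 70):
            fh.write(sequence[i : i + 70] + "\n")
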