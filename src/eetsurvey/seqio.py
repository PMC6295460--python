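"""Sequence and annotation I/O.

Core record types (:class:`ProteinRecord`, :class:`GeneRecord`) and readers/
writers for the plain-text formats the survey touches: FASTA proteomes,
GFF3 / GenBank gene annotations and TSV tables.

Coordinate conventions
----------------------
Gene coordinates are stored 1-based inclusive (the native GFF3/GenBank
convention).  All protein-internal indices elsewhere in the package are
0-based half-open; conversion happens only at I/O boundaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO as _BioSeqIO

logger = logging.getLogger("eetsurvey")

#: The 20 standard amino acids plus X for anything unresolved.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALLOWED_LETTERS = frozenset(AMINO_ACIDS + "X")


class SurveyError(Exception):
    """Base class for errors raised by this package."""


class UsageError(SurveyError):
    """A caller passed arguments that violate an operation's contract."""


class FormatError(SurveyError):
    """An input file does not parse in the declared dialect."""


class ConsistencyError(SurveyError):
    """Internal data structures disagree (e.g. a hit outside its sequence)."""


@dataclass
class ProteinRecord:
    """One amino-acid sequence: the survey's unit of analysis."""

    id: str
    sequence: str
    description: str = ""
    taxonomy: Optional[dict] = None
    source: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"protein {self.id!r} has an empty sequence")
        seq = self.sequence.upper()
        bad = set(seq) - ALLOWED_LETTERS
        if bad:
            # Non-standard residues (B, Z, U, O, *, ...) map to X: survey data
            # includes metagenome-derived ORFs with ambiguity codes.
            logger.warning(
                "protein %s: mapping non-standard residues %s to X",
                self.id, "".join(sorted(bad)),
            )
            seq = "".join(c if c in ALLOWED_LETTERS else "X" for c in seq)
        self.sequence = seq

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneRecord:
    """A protein-coding feature on a contig, 1-based inclusive coordinates."""

    id: str
    contig: str
    start: int
    end: int
    strand: str
    product: str = ""
    protein_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise FormatError(
                f"gene {self.id!r}: invalid coordinates {self.start}..{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.id!r}: strand must be + or -, got {self.strand!r}")


def read_fasta(path) -> list[ProteinRecord]:
    """Read a protein FASTA file into a list of :class:`ProteinRecord`.

    Sequences are upper-cased; letters outside the 21-letter alphabet are
    mapped to X with a logged warning.  Duplicate ids and empty sequences are
    errors.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in _BioSeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
        records.append(
            ProteinRecord(id=rec.id, sequence=str(rec.seq), description=desc, source=str(path))
        )
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path, width: int = 60) -> None:
    """Write records as FASTA, wrapped at ``width`` columns."""
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}" + (f" {rec.description}" if rec.description else "")
            fh.write(header + "\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


def write_gapped_fasta(ids: Iterable[str], rows: Iterable[str], path, width: int = 60) -> None:
    """Write an alignment (gapped rows) as aligned FASTA."""
    with open(path, "w") as fh:
        for rid, row in zip(ids, rows):
            fh.write(f">{rid}\n")
            for i in range(0, len(row), width):
                fh.write(row[i:i + width] + "\n")


def _read_gff3(path: Path) -> list[GeneRecord]:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneRecord] = []
    for feat in db.features_of_type("CDS"):
        if feat.end < feat.start:
            raise FormatError(f"CDS {feat.id!r}: end {feat.end} < start {feat.start}")
        attrs = feat.attributes
        fid = attrs.get("ID", [feat.id])[0]
        protein_id = (attrs.get("protein_id") or attrs.get("Name") or [None])[0]
        product = (attrs.get("product") or [""])[0]
        strand = feat.strand if feat.strand in ("+", "-") else "+"
        genes.append(
            GeneRecord(id=fid, contig=feat.seqid, start=feat.start, end=feat.end,
                       strand=strand, product=product, protein_id=protein_id)
        )
    return genes


def _read_genbank(path: Path) -> list[GeneRecord]:
    genes: list[GeneRecord] = []
    n = 0
    for rec in _BioSeqIO.parse(str(path), "genbank"):
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            n += 1
            # Biopython locations are 0-based half-open; normalize to 1-based
            # inclusive to match GFF3.
            start = int(feat.location.start) + 1
            end = int(feat.location.end)
            if end < start:
                raise FormatError(f"CDS in {rec.id}: end {end} < start {start}")
            strand = "-" if feat.location.strand == -1 else "+"
            quals = feat.qualifiers
            protein_id = quals.get("protein_id", [None])[0]
            locus = quals.get("locus_tag", [f"{rec.id}_cds{n}"])[0]
            product = quals.get("product", [""])[0]
            genes.append(
                GeneRecord(id=locus, contig=rec.id, start=start, end=end,
                           strand=strand, product=product, protein_id=protein_id)
            )
    return genes


def read_annotation(path, format: str) -> list[GeneRecord]:
    """Read protein-coding features from GFF3 or GenBank.

    Returns one :class:`GeneRecord` per CDS feature, sorted by
    ``(contig, start)``, with both dialects normalized to 1-based inclusive
    coordinates.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    if format == "gff3":
        genes = _read_gff3(path)
    elif format == "genbank":
        genes = _read_genbank(path)
    else:
        raise UsageError(f"unknown annotation format {format!r} (expected gff3 or genbank)")
    genes.sort(key=lambda g: (g.contig, g.start))
    return genes


def write_tsv(rows: Iterable[dict], path, columns: Optional[list[str]] = None) -> None:
    """Write dict rows as a TSV table with a header row."""
    rows = list(rows)
    if columns is None:
        columns = list(rows[0].keys()) if rows else []
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(str(row.get(c, "")) for c in columns) + "\n")
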