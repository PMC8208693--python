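"""Readers and writers for the formats every pipeline stage consumes.

FASTA (via Bio.SeqIO), BLAST tabular ("outfmt 6", 12 standard columns with
an optional ``qcovs`` 13th), GFF3, and the pipeline's own TSV/JSON report.
Coordinates are 1-based inclusive everywhere (the GFF3 convention).
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from typing import IO, Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

NT_ALPHABET = set("ACGTURYSWKMBDHVN")
AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")

#: standard 12-column BLAST tabular layout
BLAST6_COLUMNS = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)


class FormatError(ValueError):
    """Malformed input in one of the supported text formats."""


@dataclass
class SequenceRecord:
    """A named sequence over a declared alphabet (``nt`` or ``aa``)."""

    id: str
    residues: str
    alphabet: str = "nt"
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise FormatError(f"sequence id must be a non-empty token, got {self.id!r}")
        if self.alphabet not in ("nt", "aa"):
            raise FormatError(f"alphabet must be 'nt' or 'aa', got {self.alphabet!r}")
        allowed = NT_ALPHABET if self.alphabet == "nt" else AA_ALPHABET
        for ch in self.residues:
            if ch not in allowed:
                raise FormatError(
                    f"record {self.id!r}: character {ch!r} not in the "
                    f"{self.alphabet} alphabet"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class HomologyHit:
    """One row of tabular homology-search output.

    ``subject_group`` ('donor', 'recipient' or 'other') is assigned by the
    caller from its own taxon lists; the reader leaves it as 'other'.
    """

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    evalue: float
    bit_score: float
    query_coverage: float = 100.0
    subject_group: str = "other"

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise FormatError(f"negative E value {self.evalue!r}")
        if not 0 <= self.percent_identity <= 100:
            raise FormatError(f"percent identity out of [0,100]: {self.percent_identity!r}")
        if not 0 <= self.query_coverage <= 100:
            raise FormatError(f"coverage out of [0,100]: {self.query_coverage!r}")
        if self.subject_group not in ("donor", "recipient", "other"):
            raise FormatError(f"unknown subject group {self.subject_group!r}")


@dataclass
class GenomicFeature:
    """A located feature (gene, MGE, ...) on a named sequence, 1-based inclusive."""

    seq_id: str
    feature_type: str
    start: int
    end: int
    strand: str = "+"
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise FormatError(
                f"invalid coordinates {self.start}..{self.end} on {self.seq_id!r}"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _as_text_stream(stream) -> IO[str]:
    if isinstance(stream, str):
        return io.StringIO(stream)
    return stream


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(stream, alphabet: str = "nt") -> list[SequenceRecord]:
    """Read a (possibly line-wrapped) multi-record FASTA stream.

    Residues are uppercased; a trailing/embedded ``*`` stop symbol is
    stripped from protein records with a warning flag in the description.
    An empty stream yields an empty list.
    """
    records = []
    for rec in SeqIO.parse(_as_text_stream(stream), "fasta"):
        residues = str(rec.seq).upper().replace(" ", "")
        if alphabet == "aa" and "*" in residues:
            residues = residues.replace("*", "")
            desc = (rec.description + " [stop-codons-stripped]").strip()
        else:
            desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(
            SequenceRecord(id=rec.id, residues=residues, alphabet=alphabet,
                           description=desc)
        )
    return records


def write_fasta(records: Iterable[SequenceRecord], stream, width: int = 70) -> None:
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(bio, stream, "fasta")


# ---------------------------------------------------------------------------
# BLAST tabular (outfmt 6)

def read_blast6(stream, column_spec: Optional[Sequence[str]] = None) -> list[HomologyHit]:
    """Read BLAST tabular output (default 12-column layout, optional qcovs).

    Exact-zero E values ("0" / "0.0") are preserved as 0.0 and remain
    distinguishable from the smallest positive float. Extra unknown columns
    beyond ``column_spec`` are ignored for tool-version tolerance.
    """
    columns = list(column_spec) if column_spec is not None else list(BLAST6_COLUMNS)
    required = len(columns)
    hits = []
    for lineno, line in enumerate(_as_text_stream(stream), start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < required:
            raise FormatError(
                f"row {lineno}: expected {required} columns, found {len(fields)}"
            )
        row = dict(zip(columns, fields))
        try:
            evalue = float(row["evalue"])
        except ValueError as exc:
            raise FormatError(f"row {lineno}: non-numeric E value {row['evalue']!r}") from exc
        try:
            hits.append(
                HomologyHit(
                    query_id=row["qseqid"],
                    subject_id=row["sseqid"],
                    percent_identity=float(row["pident"]),
                    alignment_length=int(row["length"]),
                    evalue=evalue,
                    bit_score=float(row["bitscore"]),
                    query_coverage=float(row.get("qcovs", 100.0)),
                )
            )
        except ValueError as exc:
            raise FormatError(f"row {lineno}: {exc}") from exc
    return hits


def write_blast6(hits: Iterable[HomologyHit], stream, qcovs: bool = False) -> None:
    """Write hits back out in the 12-column layout (alignment coordinates,
    mismatches and gap opens are not tracked and are written as 0/1..length)."""
    for h in hits:
        fields = [
            h.query_id, h.subject_id, f"{h.percent_identity:g}",
            str(h.alignment_length), "0", "0",
            "1", str(h.alignment_length), "1", str(h.alignment_length),
            _format_evalue(h.evalue), f"{h.bit_score:g}",
        ]
        if qcovs:
            fields.append(f"{h.query_coverage:g}")
        stream.write("\t".join(fields) + "\n")


def _format_evalue(e: float) -> str:
    return "0.0" if e == 0 else repr(e)


# ---------------------------------------------------------------------------
# GFF3

def read_gff3(stream) -> list[GenomicFeature]:
    """Read GFF3 into GenomicFeature records (1-based inclusive, as in GFF3).

    Strand "." is mapped to "+" and flagged with ``strand_imputed=true`` in
    the attributes.
    """
    features = []
    for lineno, line in enumerate(_as_text_stream(stream), start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 9:
            raise FormatError(f"line {lineno}: GFF3 needs 9 columns, found {len(cols)}")
        seq_id, _source, ftype, start_s, end_s, _score, strand, _phase, attrs_s = cols[:9]
        try:
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise FormatError(f"line {lineno}: non-integer coordinates") from exc
        if start > end:
            raise FormatError(f"line {lineno}: start {start} > end {end}")
        attributes = {}
        for item in attrs_s.split(";"):
            item = item.strip()
            if not item:
                continue
            key, _, value = item.partition("=")
            attributes[key] = value
        if strand == ".":
            strand = "+"
            attributes["strand_imputed"] = "true"
        features.append(
            GenomicFeature(seq_id=seq_id, feature_type=ftype, start=start,
                           end=end, strand=strand, attributes=attributes)
        )
    return features


def write_gff3(features: Iterable[GenomicFeature], stream) -> None:
    stream.write("##gff-version 3\n")
    for f in features:
        attrs = ";".join(f"{k}={v}" for k, v in f.attributes.items()) or "."
        stream.write(
            "\t".join([f.seq_id, "hgt_evidence", f.feature_type, str(f.start),
                       str(f.end), ".", f.strand, ".", attrs]) + "\n"
        )


# ---------------------------------------------------------------------------
# Pipeline report

REPORT_COLUMNS = (
    "gene_id", "motif_start", "motif_window", "motif_mismatches",
    "alien_index", "ai_category", "gene_gc", "host_gc", "donor_gc",
    "gc_verdict", "nearest_leaf", "congruent", "mge_within_flank", "verdict",
)


def write_report_tsv(rows: Iterable[dict], stream) -> None:
    """Fixed-header TSV report; absent stages are written as empty fields."""
    df = pd.DataFrame(list(rows), columns=list(REPORT_COLUMNS))
    df.to_csv(stream, sep="\t", index=False)


def write_report_json(rows: Iterable[dict], stream) -> None:
    json.dump(list(rows), stream, indent=2, default=str)
    stream.write("\n")
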