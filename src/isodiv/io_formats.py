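"""Domain types and file formats.

Every other module consumes only the in-memory types defined here:
stranded exon-structured transcript models, per-isoform expression
records with 95% confidence bounds, and position frequency matrices.
Coordinates are 0-based half-open internally; GTF's 1-based inclusive
convention is converted at the I/O boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STRANDS = ("+", "-")
DNA_ALPHABET = frozenset("ACGTN")
_BASE_ORDER = "ACGT"


class ParseError(ValueError):
    """A file violated its format contract."""


class ValidationError(ValueError):
    """Parsed content violated a domain invariant."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open, 0-based stranded interval on a contig."""

    contig: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"interval requires 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class TranscriptModel:
    """A stranded multi-exon transcript; exons sorted by genomic start."""

    transcript_id: str
    gene_id: str
    contig: str
    strand: str
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValidationError(f"bad strand {self.strand!r} on {self.transcript_id}")
        if not self.exons:
            raise ValidationError(f"transcript {self.transcript_id} has no exons")
        for ex in self.exons:
            if ex.contig != self.contig or ex.strand != self.strand:
                raise ValidationError(
                    f"transcript {self.transcript_id}: exon on {ex.contig}{ex.strand} "
                    f"does not match transcript {self.contig}{self.strand}"
                )
        starts = [ex.start for ex in self.exons]
        if starts != sorted(starts):
            raise ValidationError(f"transcript {self.transcript_id}: exons not sorted")
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValidationError(
                    f"transcript {self.transcript_id}: overlapping exons "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.contig, self.exons[0].start, self.exons[-1].end, self.strand
        )

    def exons_in_transcription_order(self) -> tuple[GenomicInterval, ...]:
        return self.exons if self.strand == "+" else tuple(reversed(self.exons))

    def introns(self) -> tuple[tuple[int, int], ...]:
        """Genomic (donor_end, acceptor_start) pairs between consecutive exons."""
        return tuple(
            (a.end, b.start) for a, b in zip(self.exons, self.exons[1:])
        )


@dataclass(frozen=True)
class IsoformExpressionRecord:
    """FPKM estimate with 95% CI bounds for one transcript in one condition.

    A lower confidence bound of exactly 0 is the 'unreliable' signal used
    by the reliability model; it is retained, never rejected.
    """

    transcript_id: str
    gene_id: str
    condition: str
    fpkm: float
    conf_lo: float
    conf_hi: float
    status: str = "OK"

    def __post_init__(self) -> None:
        if self.conf_lo < 0:
            raise ValidationError(
                f"{self.transcript_id}/{self.condition}: conf_lo < 0"
            )
        if not (self.conf_lo <= self.fpkm <= self.conf_hi):
            raise ValidationError(
                f"{self.transcript_id}/{self.condition}: require "
                f"conf_lo <= fpkm <= conf_hi, got "
                f"({self.conf_lo}, {self.fpkm}, {self.conf_hi})"
            )


@dataclass(frozen=True)
class PWM:
    """Position frequency matrix, rows in A,C,G,T order."""

    motif_id: str
    name: str
    counts: np.ndarray = field(compare=False)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2 or counts.shape[0] != 4 or counts.shape[1] < 1:
            raise ValidationError(
                f"PWM {self.motif_id}: counts must be 4xL with L >= 1, "
                f"got shape {counts.shape}"
            )
        if np.any(counts < 0):
            raise ValidationError(f"PWM {self.motif_id}: negative counts")
        if np.any(counts.sum(axis=0) <= 0):
            raise ValidationError(f"PWM {self.motif_id}: column with zero total count")

    def __len__(self) -> int:
        return self.counts.shape[1]

    def consensus(self) -> str:
        """Column-argmax string; ties broken in A,C,G,T order."""
        return "".join(_BASE_ORDER[i] for i in np.argmax(self.counts, axis=0))


# ---------------------------------------------------------------------------
# GTF


def _parse_gtf_attributes(raw: str, lineno: int) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in raw.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        parts = chunk.split(None, 1)
        if len(parts) != 2:
            raise ParseError(f"line {lineno}: malformed attribute {chunk!r}")
        attrs[parts[0]] = parts[1].strip().strip('"')
    return attrs


def read_gtf(path) -> list[TranscriptModel]:
    """Parse exon features of a GTF 2.2 file into transcript models.

    Non-exon feature types (CDS, start_codon, ...) are ignored. 1-based
    inclusive coordinates become 0-based half-open. Raises ParseError
    naming the offending line on malformed input; ValidationError if a
    transcript mixes strands or contigs.
    """
    exons: dict[str, list[GenomicInterval]] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # tid -> (gene, contig, strand)
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(
                    f"line {lineno}: expected 9 tab-delimited fields, got {len(fields)}"
                )
            contig, _source, feature, start_s, end_s, _score, strand, _frame, attr_s = fields
            if feature != "exon":
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(f"line {lineno}: non-integer coordinates") from None
            if strand not in STRANDS:
                raise ParseError(f"line {lineno}: bad strand {strand!r}")
            attrs = _parse_gtf_attributes(attr_s, lineno)
            try:
                tid, gid = attrs["transcript_id"], attrs["gene_id"]
            except KeyError as e:
                raise ParseError(f"line {lineno}: exon missing {e.args[0]}") from None
            if tid not in exons:
                exons[tid] = []
                meta[tid] = (gid, contig, strand)
                order.append(tid)
            elif meta[tid] != (gid, contig, strand):
                raise ValidationError(
                    f"line {lineno}: transcript {tid} spans mixed "
                    "gene/contig/strand assignments"
                )
            exons[tid].append(GenomicInterval(contig, start1 - 1, end1, strand))
    models = []
    for tid in order:
        gid, contig, strand = meta[tid]
        models.append(
            TranscriptModel(
                tid, gid, contig, strand, tuple(sorted(exons[tid], key=lambda e: e.start))
            )
        )
    return models


def write_gtf(models: Iterable[TranscriptModel], path) -> None:
    """Write exon features; inverse of read_gtf on valid models."""
    with open(path, "w") as fh:
        for m in models:
            for ex in m.exons:
                attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
                fh.write(
                    "\t".join(
                        [
                            m.contig,
                            "isodiv",
                            "exon",
                            str(ex.start + 1),
                            str(ex.end),
                            ".",
                            m.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> dict[str, str]:
    """Read FASTA into {first header token: uppercase sequence}.

    Rejects empty files, duplicate ids and characters outside A,C,G,T,N.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ParseError(f"duplicate sequence id {rec.id!r}")
        seq = str(rec.seq).upper()
        bad = set(seq) - DNA_ALPHABET
        if bad:
            raise ParseError(
                f"record {rec.id!r}: illegal characters {sorted(bad)}"
            )
        seqs[rec.id] = seq
    if not seqs:
        raise ParseError(f"no FASTA records in {path}")
    return seqs


def write_fasta(seqs: Mapping[str, str], path, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# JASPAR PFM


def read_jaspar(path) -> list[PWM]:
    """Parse JASPAR PFM text, accepting bracketed ("A [ 1 2 ]") and bare
    ("A 1 2") row dialects; rows may appear in any A/C/G/T label order.
    """
    motifs: list[PWM] = []
    header: tuple[str, str] | None = None
    rows: dict[str, list[float]] = {}

    def flush() -> None:
        nonlocal header, rows
        if header is None:
            return
        missing = [b for b in _BASE_ORDER if b not in rows]
        if missing:
            raise ParseError(f"motif {header[0]}: missing base row(s) {missing}")
        lengths = {len(rows[b]) for b in _BASE_ORDER}
        if len(lengths) != 1:
            raise ParseError(f"motif {header[0]}: rows of unequal length")
        counts = np.array([rows[b] for b in _BASE_ORDER], dtype=float)
        motifs.append(PWM(header[0], header[1], counts))
        header, rows = None, {}

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                parts = line[1:].split(None, 1)
                if not parts:
                    raise ParseError(f"line {lineno}: empty motif header")
                header = (parts[0], parts[1] if len(parts) > 1 else parts[0])
            else:
                if header is None:
                    raise ParseError(f"line {lineno}: counts before any '>' header")
                base = line[0].upper()
                if base not in _BASE_ORDER:
                    raise ParseError(f"line {lineno}: unknown base row {line[0]!r}")
                body = line[1:].replace("[", " ").replace("]", " ")
                try:
                    values = [float(v) for v in body.split()]
                except ValueError:
                    raise ParseError(f"line {lineno}: non-numeric count") from None
                if base in rows:
                    raise ParseError(f"line {lineno}: duplicate {base} row")
                rows[base] = values
    flush()
    if not motifs:
        raise ParseError(f"no motifs in {path}")
    return motifs


def write_jaspar(pwms: Iterable[PWM], path, bracketed: bool = True) -> None:
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.motif_id} {pwm.name}\n")
            for base, row in zip(_BASE_ORDER, pwm.counts):
                body = " ".join(f"{v:g}" for v in row)
                if bracketed:
                    fh.write(f"{base} [ {body} ]\n")
                else:
                    fh.write(f"{base} {body}\n")


# ---------------------------------------------------------------------------
# fpkm_tracking-style expression tables

#: accepted aliases for the per-condition column stems
_TRACKING_STEMS = ("FPKM", "conf_lo", "conf_hi", "status")


def read_fpkm_tracking(path) -> list[IsoformExpressionRecord]:
    """Read a tracking-style TSV into one record per (transcript, condition).

    The header must contain tracking_id, gene_id and, for each condition
    ``c``, columns ``c_FPKM``, ``c_conf_lo``, ``c_conf_hi`` (``c_status``
    optional). Rows violating conf_lo <= FPKM <= conf_hi are collected and
    reported together.
    """
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    for col in ("tracking_id", "gene_id"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    conditions = sorted(
        {c[: -len("_FPKM")] for c in df.columns if c.endswith("_FPKM")}
    )
    if not conditions:
        raise ParseError(f"{path}: no *_FPKM columns found")
    records: list[IsoformExpressionRecord] = []
    bad_rows: list[str] = []
    for _, row in df.iterrows():
        for cond in conditions:
            try:
                rec = IsoformExpressionRecord(
                    transcript_id=str(row["tracking_id"]),
                    gene_id=str(row["gene_id"]),
                    condition=cond,
                    fpkm=float(row[f"{cond}_FPKM"]),
                    conf_lo=float(row[f"{cond}_conf_lo"]),
                    conf_hi=float(row[f"{cond}_conf_hi"]),
                    status=str(row.get(f"{cond}_status", "OK")),
                )
            except ValidationError as e:
                bad_rows.append(str(e))
                continue
            records.append(rec)
    if bad_rows:
        raise ValidationError(
            "invalid expression rows:\n  " + "\n  ".join(bad_rows)
        )
    return records


def write_fpkm_tracking(records: Sequence[IsoformExpressionRecord], path) -> None:
    """Write records back to the wide tracking layout read by read_fpkm_tracking."""
    conditions = sorted({r.condition for r in records})
    by_tid: dict[str, dict] = {}
    order: list[str] = []
    for r in records:
        if r.transcript_id not in by_tid:
            by_tid[r.transcript_id] = {"tracking_id": r.transcript_id, "gene_id": r.gene_id}
            order.append(r.transcript_id)
        row = by_tid[r.transcript_id]
        row[f"{r.condition}_FPKM"] = r.fpkm
        row[f"{r.condition}_conf_lo"] = r.conf_lo
        row[f"{r.condition}_conf_hi"] = r.conf_hi
        row[f"{r.condition}_status"] = r.status
    cols = ["tracking_id", "gene_id"]
    for c in conditions:
        cols += [f"{c}_FPKM", f"{c}_conf_lo", f"{c}_conf_hi", f"{c}_status"]
    pd.DataFrame([by_tid[t] for t in order], columns=cols).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return str(Seq(seq).reverse_complement())
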