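"""Isoform feature classification and expressed-set diversity summaries.

Isoforms of a gene are distinguished by three positional features:

* TSS — the first transcribed base (strand-aware beginning of the first exon),
* internal exon chain — exon 2 through the second-to-last exon, the
  structural proxy for a coding-sequence change,
* last exon — the structural proxy for the 3' UTR.

Transcripts with one or two exons have an empty internal chain and can
therefore never differ "in CDS" under this rule; that is a documented
consequence of the positional definition, not a bug. No ORF prediction
or translation is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .io_formats import GenomicInterval, IsoformExpressionRecord, TranscriptModel

#: default expression floor in FPKM units (inclusive)
DEFAULT_FPKM_THRESHOLD = 50.0


@dataclass(frozen=True)
class IsoformFeatureKey:
    """Hashable triple of the three isoform-distinguishing features."""

    tss: tuple[str, int, str]
    internal_chain: tuple[tuple[int, int], ...]
    last_exon: tuple[str, int, int, str]


@dataclass(frozen=True)
class DiversitySummary:
    """Expressed-set sizes and distinct-feature counts for one group."""

    n_genes: int
    n_isoforms: int
    n_distinct_tss: int
    n_distinct_cds: int
    n_distinct_utr3: int


def tss_of(transcript: TranscriptModel) -> tuple[str, int, str]:
    """0-based position of the first transcribed base.

    Plus strand: smallest exon start. Minus strand: largest exon end - 1.
    """
    if transcript.strand == "+":
        pos = transcript.exons[0].start
    else:
        pos = transcript.exons[-1].end - 1
    return (transcript.contig, pos, transcript.strand)


def feature_key(transcript: TranscriptModel) -> IsoformFeatureKey:
    """TSS / internal exon chain / last exon triple, in transcription order."""
    ordered = transcript.exons_in_transcription_order()
    internal = tuple((e.start, e.end) for e in ordered[1:-1])
    last = ordered[-1]
    return IsoformFeatureKey(
        tss=tss_of(transcript),
        internal_chain=internal,
        last_exon=(transcript.contig, last.start, last.end, transcript.strand),
    )


def feature_differences(
    a: TranscriptModel, b: TranscriptModel
) -> dict[str, bool]:
    """Which of the three features differ between two transcripts."""
    ka, kb = feature_key(a), feature_key(b)
    return {
        "tss": ka.tss != kb.tss,
        "cds": ka.internal_chain != kb.internal_chain,
        "utr3": ka.last_exon != kb.last_exon,
    }


def compare_to_reference(
    query: TranscriptModel, reference: Sequence[TranscriptModel]
) -> str:
    """Classify a query against a reference set as '=', 'j' or 'u'.

    '=' — some same-contig, same-strand reference transcript has an
    identical intron chain (for single-exon queries: an identical exon);
    'j' — otherwise, the query shares at least one splice junction with,
    or overlaps at least one exon of, a same-strand reference transcript;
    'u' — no same-strand evidence at all (antisense overlap maps here).
    """
    q_introns = set(query.introns())
    for ref in reference:
        if ref.contig != query.contig or ref.strand != query.strand:
            continue
        if len(query.exons) == 1 and len(ref.exons) == 1:
            qe, re = query.exons[0], ref.exons[0]
            if (qe.start, qe.end) == (re.start, re.end):
                return "="
        elif q_introns and q_introns == set(ref.introns()):
            return "="
    for ref in reference:
        if ref.contig != query.contig or ref.strand != query.strand:
            continue
        if q_introns & set(ref.introns()):
            return "j"
        if any(qe.overlaps(re) for qe in query.exons for re in ref.exons):
            return "j"
    return "u"


def expressed_set(
    records: Iterable[IsoformExpressionRecord],
    threshold: float = DEFAULT_FPKM_THRESHOLD,
    strict_gt: bool = False,
) -> dict[str, set[str]]:
    """Transcript ids passing the FPKM floor, per condition.

    The floor is inclusive (FPKM >= threshold) by default; ``strict_gt``
    switches to a strict comparison.
    """
    if threshold < 0:
        raise ValueError(f"threshold must be non-negative, got {threshold}")
    out: dict[str, set[str]] = {}
    for rec in records:
        out.setdefault(rec.condition, set())
        passed = rec.fpkm > threshold if strict_gt else rec.fpkm >= threshold
        if passed:
            out[rec.condition].add(rec.transcript_id)
    return out


def _summary_for(models: Mapping[str, TranscriptModel], tids: set[str]) -> DiversitySummary:
    # CDS (internal-chain) distinctness is counted within each gene: an
    # empty internal chain is shared by every 1-2 exon transcript and must
    # not collapse across unrelated loci.
    keyed = [(models[t].gene_id, feature_key(models[t])) for t in tids]
    return DiversitySummary(
        n_genes=len({g for g, _ in keyed}),
        n_isoforms=len(tids),
        n_distinct_tss=len({k.tss for _, k in keyed}),
        n_distinct_cds=len({(g, k.internal_chain) for g, k in keyed}),
        n_distinct_utr3=len({k.last_exon for _, k in keyed}),
    )


def diversity_summary(
    models: Sequence[TranscriptModel],
    expressed_a: set[str],
    expressed_b: set[str],
) -> dict:
    """Shared/unique gene and isoform sets and diversity counts.

    A gene counts as expressed in a condition iff at least one of its
    isoforms is in that condition's expressed set. Distinct TSS/CDS/3'UTR
    are counted over the isoforms of the uniquely expressed genes of each
    condition.
    """
    by_id = {m.transcript_id: m for m in models}
    for label, tids in (("A", expressed_a), ("B", expressed_b)):
        missing = sorted(tids - by_id.keys())
        if missing:
            raise ValueError(
                f"expressed set {label} contains ids absent from models: {missing}"
            )
    genes_a = {by_id[t].gene_id for t in expressed_a}
    genes_b = {by_id[t].gene_id for t in expressed_b}
    shared_genes = genes_a & genes_b
    unique_genes_a = genes_a - genes_b
    unique_genes_b = genes_b - genes_a

    unique_iso_a = {t for t in expressed_a if by_id[t].gene_id in unique_genes_a}
    unique_iso_b = {t for t in expressed_b if by_id[t].gene_id in unique_genes_b}

    return {
        "shared_genes": shared_genes,
        "unique_genes_a": unique_genes_a,
        "unique_genes_b": unique_genes_b,
        "unique_isoforms_a": unique_iso_a,
        "unique_isoforms_b": unique_iso_b,
        "summary_a": _summary_for(by_id, unique_iso_a),
        "summary_b": _summary_for(by_id, unique_iso_b),
        "summary_shared": _summary_for(
            by_id,
            {t for t in (expressed_a & expressed_b) if by_id[t].gene_id in shared_genes},
        ),
    }
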