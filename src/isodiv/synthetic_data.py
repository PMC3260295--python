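"""Synthetic two-population transcriptome generator with ground truth.

Generates the statistical structure the downstream analysis assumes,
without any read-level simulation:

* genes placed without overlap on both strands of random contigs, with
  multi-isoform loci realizing the three variation modes the catalog
  classifies (alternative first exon / altered internal exon chain /
  alternative last exon);
* heavy-tailed abundances from a discrete Zipf law truncated at FPKM
  10^6, two conditions with shared and condition-unique genes, planted
  e-fold expression differences, and log-normal replicate jitter;
* 95% CI lower bounds that are 0 with probability logistic in log10
  FPKM (the reliability process);
* promoter/3'UTR sequences with motif sites planted at controlled
  per-bp Poisson rates, never overlapping, with every position recorded.

Every quantity needed to score the pipeline is recorded in a
TruthLedger; all randomness flows from the single config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import PWM, IsoformExpressionRecord, GenomicInterval, TranscriptModel

#: contig flank and inter-gene spacing, sized so every promoter window fits
GENE_FLANK = 1400

_VARIATION_MODES = ("tss", "cds", "utr3")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the generator.

    isoforms_per_gene is a categorical distribution over isoform counts;
    the default puts ~18% of loci at more than one isoform. The
    reliability logistic coefficients act on log10 FPKM. de_ln_effect is
    the planted |ln fold change| between conditions.
    """

    n_genes: int = 300
    isoforms_per_gene: tuple[tuple[int, float], ...] = (
        (1, 0.82),
        (2, 0.10),
        (3, 0.05),
        (4, 0.03),
    )
    frac_shared_genes: float = 0.52
    powerlaw_exponent: float = 1.5
    reliability_beta0: float = -3.0
    reliability_beta1: float = 2.0
    de_fraction: float = 0.10
    de_ln_effect: float = 2.0
    n_replicates: int = 3
    replicate_sigma: float = 0.2
    promoter_len: int = 1300
    utr_len_range: tuple[int, int] = (200, 1000)
    motif_plant_rate_group: float = 5e-3
    motif_plant_rate_bg: float = 1e-3
    fpkm_max: float = 1e6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        probs = [p for _, p in self.isoforms_per_gene]
        if abs(sum(probs) - 1.0) > 1e-9 or any(p < 0 for p in probs):
            raise ValueError("isoforms_per_gene probabilities must sum to 1")
        if not (0.0 <= self.frac_shared_genes <= 1.0):
            raise ValueError("frac_shared_genes must be in [0, 1]")
        if self.powerlaw_exponent <= 0:
            raise ValueError("powerlaw_exponent must be positive")
        if not (0.0 <= self.de_fraction <= 1.0):
            raise ValueError("de_fraction must be in [0, 1]")
        if self.de_ln_effect < 0:
            raise ValueError("de_ln_effect must be non-negative")
        if self.promoter_len <= 0:
            raise ValueError("promoter_len must be positive")
        if self.motif_plant_rate_group < 0 or self.motif_plant_rate_bg < 0:
            raise ValueError("plant rates must be non-negative")


@dataclass
class TruthLedger:
    """Ground truth for every generated entity.

    transcripts: one row per transcript with its gene, whether it is the
    gene's base isoform, and the variation-mode flags (diff_tss,
    diff_cds, diff_utr3) relative to that base isoform.
    expression: one row per transcript with condition membership, true
    condition means, planted DE flag and signed ln effect, and realized
    expressed flags at the FPKM >= 50 floor.
    sites: one row per planted motif site (sequence id, motif id,
    position, site string).
    """

    transcripts: pd.DataFrame = field(default_factory=pd.DataFrame)
    expression: pd.DataFrame = field(default_factory=pd.DataFrame)
    sites: pd.DataFrame = field(default_factory=pd.DataFrame)


# ---------------------------------------------------------------------------
# transcript models


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def _base_exon_layout(
    rng: np.random.Generator, cfg: SimulationConfig
) -> list[tuple[int, int]]:
    """Exon (offset, length) pairs in genomic order within a gene slot."""
    n_exons = int(rng.integers(4, 9))
    lens = rng.integers(100, 301, size=n_exons)
    lens[-1] = rng.integers(cfg.utr_len_range[0], cfg.utr_len_range[1] + 1)
    introns = rng.integers(100, 501, size=n_exons - 1)
    out, pos = [], 0
    for i, L in enumerate(lens):
        out.append((pos, int(L)))
        pos += int(L) + (int(introns[i]) if i < n_exons - 1 else 0)
    return out


def _variant_exons(
    base: list[tuple[int, int]],
    mode: str,
    strand: str,
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """Apply one variation mode to a genomic-order (offset, length) layout."""
    exons = [list(e) for e in base]
    first_idx = 0 if strand == "+" else len(exons) - 1
    last_idx = len(exons) - 1 if strand == "+" else 0
    if mode == "tss":
        # truncate the transcription-order first exon at its 5' end
        off, L = exons[first_idx]
        delta = int(rng.integers(20, max(21, L - 50)))
        if strand == "+":
            exons[first_idx] = [off + delta, L - delta]
        else:
            exons[first_idx] = [off, L - delta]
    elif mode == "cds":
        # drop one internal exon (transcription-order exon 2..n-1)
        internal = [i for i in range(len(exons)) if i not in (first_idx, last_idx)]
        exons.pop(int(rng.choice(internal)))
    elif mode == "utr3":
        # shrink the transcription-order last exon at its 3' end
        off, L = exons[last_idx]
        delta = int(rng.integers(20, max(21, L - 50)))
        if strand == "+":
            exons[last_idx] = [off, L - delta]
        else:
            exons[last_idx] = [off + delta, L - delta]
    else:  # pragma: no cover
        raise ValueError(f"unknown variation mode {mode!r}")
    return [tuple(e) for e in exons]


def generate_transcriptome(
    config: SimulationConfig,
) -> tuple[dict[str, str], list[TranscriptModel], TruthLedger]:
    """Random genome, transcript models and per-transcript truth.

    Genes are placed left to right in non-overlapping slots on contigs of
    up to 50 genes each, alternating strand at random; variant isoforms
    cycle through the three variation modes, and the mode of each variant
    relative to the gene's base isoform is recorded in the ledger.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    genes_per_contig = 50
    ks = [k for k, _ in cfg.isoforms_per_gene]
    ps = [p for _, p in cfg.isoforms_per_gene]

    models: list[TranscriptModel] = []
    rows: list[dict] = []
    contig_lens: dict[str, int] = {}
    pos = GENE_FLANK
    contig_i = 0

    for g in range(cfg.n_genes):
        if g and g % genes_per_contig == 0:
            contig_lens[f"chr{contig_i + 1}"] = pos + GENE_FLANK
            contig_i += 1
            pos = GENE_FLANK
        contig = f"chr{contig_i + 1}"
        gene_id = f"G{g:05d}"
        strand = "+" if rng.random() < 0.5 else "-"
        base = _base_exon_layout(rng, cfg)
        n_iso = int(rng.choice(ks, p=ps))
        layouts = [("", base)]
        for v in range(1, n_iso):
            mode = _VARIATION_MODES[(v - 1) % len(_VARIATION_MODES)]
            layouts.append((mode, _variant_exons(base, mode, strand, rng)))
        span = max(off + L for off, L in base)
        for idx, (mode, layout) in enumerate(layouts):
            tid = f"{gene_id}.{idx + 1}"
            exons = tuple(
                GenomicInterval(contig, pos + off, pos + off + L, strand)
                for off, L in sorted(layout)
            )
            models.append(TranscriptModel(tid, gene_id, contig, strand, exons))
            rows.append(
                {
                    "transcript_id": tid,
                    "gene_id": gene_id,
                    "is_base": idx == 0,
                    "mode": mode,
                    "diff_tss": mode == "tss",
                    "diff_cds": mode == "cds",
                    "diff_utr3": mode == "utr3",
                }
            )
        pos += span + GENE_FLANK
    contig_lens[f"chr{contig_i + 1}"] = pos + GENE_FLANK

    genome = {name: _random_dna(rng, n) for name, n in contig_lens.items()}
    ledger = TruthLedger(transcripts=pd.DataFrame(rows))
    return genome, models, ledger


# ---------------------------------------------------------------------------
# expression


def _truncated_zipf(
    rng: np.random.Generator, r: float, n: int, xmax: float
) -> np.ndarray:
    """Discrete power-law draws P(k) ~ k^-r, resampled above xmax."""
    if r <= 0:
        raise ValueError("power-law exponent must be positive")
    out = stats.zipf.rvs(r, size=n, random_state=rng).astype(float)
    bad = out > xmax
    while bad.any():
        out[bad] = stats.zipf.rvs(r, size=int(bad.sum()), random_state=rng)
        bad = out > xmax
    return out


@dataclass
class ExpressionTables:
    """Pooled per-condition records with CIs plus replicate matrices."""

    transcript_ids: list[str]
    records: list[IsoformExpressionRecord]  # conditions "A" and "B"
    replicates_a: np.ndarray  # R x T
    replicates_b: np.ndarray  # R x T


def _ci_bounds(
    rng: np.random.Generator, fpkm: float, beta0: float, beta1: float
) -> tuple[float, float]:
    if fpkm <= 0:
        return 0.0, 0.0
    p_reliable = 1.0 / (1.0 + np.exp(-(beta0 + beta1 * np.log10(fpkm))))
    if rng.random() < p_reliable:
        lo = float(rng.uniform(0.2, 0.8) * fpkm)
    else:
        lo = 0.0
    hi = float(fpkm * rng.uniform(1.2, 1.8))
    return lo, hi


def generate_expression(
    models: Sequence[TranscriptModel],
    config: SimulationConfig,
    ledger: TruthLedger | None = None,
) -> tuple[ExpressionTables, TruthLedger]:
    """Two-condition expression with planted DE and reliability structure.

    Gene condition membership is shared with probability
    frac_shared_genes, else A-only or B-only with equal probability; a
    transcript's condition mean is 0 outside its membership. Planted DE
    (a de_fraction of shared isoforms) splits the ln effect symmetrically
    across the two conditions so the marginal abundance law is preserved.
    """
    if not models:
        raise ValueError("models must be nonempty")
    cfg = config
    rng = np.random.default_rng(cfg.seed + 1)
    ledger = ledger or TruthLedger()

    gene_ids = sorted({m.gene_id for m in models})
    membership: dict[str, str] = {}
    for gid in gene_ids:
        u = rng.random()
        if u < cfg.frac_shared_genes:
            membership[gid] = "shared"
        else:
            membership[gid] = "a_only" if rng.random() < 0.5 else "b_only"

    tids = [m.transcript_id for m in models]
    base = _truncated_zipf(rng, cfg.powerlaw_exponent, len(models), cfg.fpkm_max)

    shared_idx = [
        i for i, m in enumerate(models) if membership[m.gene_id] == "shared"
    ]
    n_de = int(round(cfg.de_fraction * len(shared_idx)))
    de_idx = set(
        rng.choice(shared_idx, size=n_de, replace=False).tolist() if n_de else []
    )

    mean_a = np.zeros(len(models))
    mean_b = np.zeros(len(models))
    ln_effect = np.zeros(len(models))
    for i, m in enumerate(models):
        mem = membership[m.gene_id]
        if mem in ("shared", "a_only"):
            mean_a[i] = base[i]
        if mem in ("shared", "b_only"):
            mean_b[i] = base[i]
        if i in de_idx:
            eff = cfg.de_ln_effect * (1 if rng.random() < 0.5 else -1)
            mean_a[i] = base[i] * np.exp(-eff / 2.0)
            mean_b[i] = base[i] * np.exp(eff / 2.0)
            ln_effect[i] = eff

    R = cfg.n_replicates
    jitter_a = np.exp(rng.normal(0.0, cfg.replicate_sigma, size=(R, len(models))))
    jitter_b = np.exp(rng.normal(0.0, cfg.replicate_sigma, size=(R, len(models))))
    reps_a = mean_a[None, :] * jitter_a
    reps_b = mean_b[None, :] * jitter_b

    records: list[IsoformExpressionRecord] = []
    for i, m in enumerate(models):
        for cond, mean in (("A", mean_a[i]), ("B", mean_b[i])):
            lo, hi = _ci_bounds(
                rng, mean, cfg.reliability_beta0, cfg.reliability_beta1
            )
            records.append(
                IsoformExpressionRecord(
                    transcript_id=m.transcript_id,
                    gene_id=m.gene_id,
                    condition=cond,
                    fpkm=float(mean),
                    conf_lo=lo,
                    conf_hi=hi,
                )
            )

    ledger.expression = pd.DataFrame(
        {
            "transcript_id": tids,
            "gene_id": [m.gene_id for m in models],
            "membership": [membership[m.gene_id] for m in models],
            "mean_a": mean_a,
            "mean_b": mean_b,
            "is_de": [i in de_idx for i in range(len(models))],
            "ln_effect": ln_effect,
            "expressed_a": mean_a >= 50.0,
            "expressed_b": mean_b >= 50.0,
        }
    )
    tables = ExpressionTables(tids, records, reps_a, reps_b)
    return tables, ledger


# ---------------------------------------------------------------------------
# motif planting


def _site_string(motif: PWM | str) -> str:
    if isinstance(motif, PWM):
        return motif.consensus()
    return str(motif).upper().replace("U", "T")


def plant_motif_sites(
    sequences: Mapping[str, str],
    motif: PWM | str,
    rate: float,
    rng: np.random.Generator | int | None = None,
    motif_id: str | None = None,
    max_retries: int = 200,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Write motif sites into sequences at a per-bp Poisson rate.

    For a PWM the consensus (column-argmax) string is planted; for a
    miRNA pass the 8mer site string (see seed_site_string). Each
    sequence receives Poisson(rate * len) sites at uniform positions,
    never overlapping one another; placement failing after bounded
    retries raises. Returns the mutated sequences and a ledger frame of
    (seq_id, motif_id, position, site).
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    site = _site_string(motif)
    L = len(site)
    mid = motif_id or (motif.motif_id if isinstance(motif, PWM) else site)
    for name, seq in sequences.items():
        if L > len(seq):
            raise ValueError(
                f"site length {L} exceeds sequence {name!r} length {len(seq)}"
            )
    out: dict[str, str] = {}
    rows: list[dict] = []
    for name, seq in sequences.items():
        n_sites = int(rng.poisson(rate * len(seq)))
        if n_sites == 0:
            out[name] = seq
            continue
        chars = list(seq)
        occupied: list[tuple[int, int]] = []
        placed = 0
        attempts = 0
        while placed < n_sites:
            attempts += 1
            if attempts > max_retries * n_sites:
                raise RuntimeError(
                    f"could not place {n_sites} non-overlapping sites of "
                    f"length {L} in sequence {name!r} (rate too high?)"
                )
            p = int(rng.integers(0, len(seq) - L + 1))
            if any(p < e and s < p + L for s, e in occupied):
                continue
            chars[p:p + L] = site
            occupied.append((p, p + L))
            rows.append({"seq_id": name, "motif_id": mid, "position": p, "site": site})
            placed += 1
        out[name] = "".join(chars)
    ledger = pd.DataFrame(rows, columns=["seq_id", "motif_id", "position", "site"])
    return out, ledger
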