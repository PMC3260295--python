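"""Promoter/3'UTR motif scanning and over/under-representation Z-scores.

Promoters are the window -1000..+300 around each isoform's TSS on the
transcription strand; 3'UTRs are the strand-wise last exon. Promoters
are scanned with JASPAR-style position weight matrices (log-odds vs. a
uniform background, relative score threshold, both strands); 3'UTRs are
scanned for miRNA seed-complementary sites in the three TargetScan
classes (8mer, 7mer-m8, 7mer-1A; 8mer dominates).

Per-bp site frequencies in a sequence group are compared against a
random background set under a binomial model: with background rate
f_bg = bg_hits / bg_bp and E = f_bg * group_bp,

    z = (observed - E) / sqrt(E * (1 - f_bg)),

so z = 0 exactly at observed = expected. Informative motifs are those at
least one column SD away from the column mean in at least one group;
rows are then ordered by average-linkage hierarchical clustering on
correlation distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .io_formats import PWM, TranscriptModel, revcomp

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}

PROMOTER_UPSTREAM = 1000
PROMOTER_DOWNSTREAM = 300
DEFAULT_BACKGROUND_N = 5000
SEED_CLASSES = ("8mer", "7mer-m8", "7mer-1A")


# ---------------------------------------------------------------------------
# sequence extraction


def extract_promoter(
    transcript: TranscriptModel,
    genome: Mapping[str, str],
    upstream: int = PROMOTER_UPSTREAM,
    downstream: int = PROMOTER_DOWNSTREAM,
) -> str:
    """Promoter window around the TSS, 5'->3' on the transcription strand.

    Covers transcription coordinates TSS-upstream .. TSS+downstream-1
    (the TSS sits at offset ``upstream``). Windows running off the
    contig are clipped with a warning, never padded.
    """
    from .isoform_catalog import tss_of

    contig, tss, strand = tss_of(transcript)
    seq = genome[contig]
    if strand == "+":
        lo, hi = tss - upstream, tss + downstream
    else:
        lo, hi = tss - downstream + 1, tss + upstream + 1
    clo, chi = max(lo, 0), min(hi, len(seq))
    if (clo, chi) != (lo, hi):
        warnings.warn(
            f"promoter window [{lo}, {hi}) for {transcript.transcript_id} "
            f"clipped to [{clo}, {chi}) (effective length {chi - clo})",
            stacklevel=2,
        )
    window = seq[clo:chi]
    return window if strand == "+" else revcomp(window)


def extract_utr3(transcript: TranscriptModel, genome: Mapping[str, str]) -> str:
    """Sequence of the strand-wise last exon, 5'->3' of the gene.

    For single-exon transcripts the whole transcript is its 3'UTR under
    the last-exon rule.
    """
    last = transcript.exons_in_transcription_order()[-1]
    seq = genome[transcript.contig][last.start:last.end]
    return seq if transcript.strand == "+" else revcomp(seq)


# ---------------------------------------------------------------------------
# PWM scanning


@dataclass(frozen=True)
class PWMScanResult:
    count: int
    positions: tuple[tuple[int, str], ...]  # (window start on forward coords, strand)
    n_windows: int  # N-free windows actually scanned, both strands


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_BASE_INDEX[c] for c in seq), dtype=np.int8, count=len(seq))


def _scan_one_strand(codes: np.ndarray, logodds: np.ndarray, cutoff: float):
    L = logodds.shape[1]
    if codes.size < L:
        return np.empty(0, dtype=int), 0
    win = np.lib.stride_tricks.sliding_window_view(codes, L)
    valid = ~(win == 4).any(axis=1)
    scores = np.full(win.shape[0], -np.inf)
    v = win[valid]
    if v.size:
        scores[valid] = logodds[v, np.arange(L)].sum(axis=1)
    hits = np.flatnonzero(valid & (scores >= cutoff - 1e-12))
    return hits, int(valid.sum())


def scan_pwm(
    sequence: str,
    pwm: PWM,
    rel_threshold: float = 0.80,
    pseudocount: float = 0.01,
) -> PWMScanResult:
    """Count PWM hits on both strands of a sequence.

    Column counts become frequencies, a pseudocount is added, and each
    window is scored as the summed log-odds against a uniform 0.25
    background. A window is a hit when its score reaches
    ``min + rel_threshold * (max - min)`` of the attainable score range.
    Overlapping hits count separately; windows containing N are skipped.
    Raises ValueError if the sequence is shorter than the motif or the
    threshold is outside [0, 1].
    """
    if not (0.0 <= rel_threshold <= 1.0):
        raise ValueError(f"rel_threshold must be in [0, 1], got {rel_threshold}")
    L = len(pwm)
    if len(sequence) < L:
        raise ValueError(
            f"sequence length {len(sequence)} shorter than motif length {L}"
        )
    freqs = pwm.counts / pwm.counts.sum(axis=0, keepdims=True) + pseudocount
    logodds = np.log(freqs / 0.25)
    smax = logodds.max(axis=0).sum()
    smin = logodds.min(axis=0).sum()
    cutoff = smin + rel_threshold * (smax - smin)

    codes_fwd = _encode(sequence.upper())
    codes_rev = _encode(revcomp(sequence.upper()))
    hits_f, nw_f = _scan_one_strand(codes_fwd, logodds, cutoff)
    hits_r, nw_r = _scan_one_strand(codes_rev, logodds, cutoff)
    n = len(sequence)
    positions = [(int(i), "+") for i in hits_f] + [
        (int(n - i - L), "-") for i in hits_r
    ]
    return PWMScanResult(
        count=len(positions),
        positions=tuple(sorted(positions)),
        n_windows=nw_f + nw_r,
    )


# ---------------------------------------------------------------------------
# miRNA seed sites


def count_seed_sites(utr: str, mirna: str) -> dict[str, int]:
    """Count seed-complementary sites in a 3'UTR by TargetScan class.

    With S7 = the reverse complement of miRNA positions 2-8 (written
    5'->3' of the mRNA) and S6 = the reverse complement of positions 2-7:
    an S7 occurrence followed by A is an 8mer, otherwise a 7mer-m8; an S6
    occurrence followed by A that does not extend to an S7 match (the
    preceding base does not pair position 8) is a 7mer-1A. Each
    occurrence belongs to exactly one class; 8mer dominates. U is mapped
    to T on both inputs.
    """
    mirna = mirna.upper().replace("U", "T")
    if len(mirna) < 8:
        raise ValueError(f"miRNA must be at least 8 nt, got {len(mirna)}")
    utr = utr.upper().replace("U", "T")
    s7 = revcomp(mirna[1:8])  # complements positions 2-8
    s6 = revcomp(mirna[1:7])  # complements positions 2-7
    m8_comp = revcomp(mirna[7])  # base pairing miRNA position 8

    counts = {c: 0 for c in SEED_CLASSES}
    # S7 occurrences: 8mer when followed by A, else 7mer-m8
    start = utr.find(s7)
    while start != -1:
        nxt = utr[start + 7: start + 8]
        counts["8mer" if nxt == "A" else "7mer-m8"] += 1
        start = utr.find(s7, start + 1)
    # S6 + A occurrences not already covered by an S7 match
    start = utr.find(s6)
    while start != -1:
        followed_by_a = utr[start + 6: start + 7] == "A"
        extends_to_m8 = start > 0 and utr[start - 1] == m8_comp
        if followed_by_a and not extends_to_m8:
            counts["7mer-1A"] += 1
        start = utr.find(s6, start + 1)
    return counts


def seed_site_string(mirna: str, site_class: str = "8mer") -> str:
    """The genomic site string a given seed-match class looks for."""
    mirna = mirna.upper().replace("U", "T")
    if len(mirna) < 8:
        raise ValueError("miRNA must be at least 8 nt")
    if site_class == "8mer":
        return revcomp(mirna[1:8]) + "A"
    if site_class == "7mer-m8":
        return revcomp(mirna[1:8])
    if site_class == "7mer-1A":
        return revcomp(mirna[1:7]) + "A"
    raise ValueError(f"unknown seed site class {site_class!r}")


# ---------------------------------------------------------------------------
# background and Z-scores


def sample_background(
    pool: Sequence[str], n: int = DEFAULT_BACKGROUND_N, seed: int | None = None
) -> list[str]:
    """Uniform sample of n sequences without replacement; errors if the
    pool is smaller than n (silent reuse would bias the background)."""
    if len(pool) < n:
        raise ValueError(f"background pool has {len(pool)} < n = {n} sequences")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=n, replace=False)
    return [pool[i] for i in sorted(idx)]


@dataclass(frozen=True)
class EnrichmentZ:
    motif_id: str
    group_id: str
    observed: float
    group_bp: float
    f_bg: float
    expected: float
    z: float
    degenerate: bool = False


def enrichment_z(
    observed: float,
    group_bp: float,
    bg_hits: float,
    bg_bp: float,
    motif_id: str = "",
    group_id: str = "",
) -> EnrichmentZ:
    """Binomial Z-score of a group's per-bp site frequency vs. background.

    group_bp scanned positions at the background rate f_bg give
    E = f_bg * group_bp and variance E * (1 - f_bg). bg_hits = 0 yields a
    degenerate (z = nan) result rather than an error; f_bg >= 1 is an
    error (a per-position rate cannot reach 1 under non-overlap).
    """
    if group_bp <= 0 or bg_bp <= 0:
        raise ValueError("group_bp and bg_bp must be positive")
    f_bg = bg_hits / bg_bp
    if f_bg >= 1.0:
        raise ValueError(f"background rate {f_bg} per bp is >= 1")
    if bg_hits < 1:
        return EnrichmentZ(
            motif_id, group_id, observed, group_bp, f_bg, 0.0, float("nan"), True
        )
    expected = f_bg * group_bp
    z = (observed - expected) / np.sqrt(expected * (1.0 - f_bg))
    return EnrichmentZ(motif_id, group_id, observed, group_bp, f_bg, expected, float(z))


def pwm_group_counts(
    sequences: Sequence[str], pwm: PWM, rel_threshold: float = 0.80
) -> tuple[int, int]:
    """(total hits, total scanned windows) of one PWM over a group."""
    hits = windows = 0
    for seq in sequences:
        if len(seq) < len(pwm):
            continue
        res = scan_pwm(seq, pwm, rel_threshold=rel_threshold)
        hits += res.count
        windows += res.n_windows
    return hits, windows


def seed_group_counts(sequences: Sequence[str], mirna: str) -> tuple[int, int]:
    """(total seed sites of all three classes, total bp) over a group."""
    hits = sum(sum(count_seed_sites(s, mirna).values()) for s in sequences)
    bp = sum(len(s) for s in sequences)
    return hits, bp


def compute_zmatrix(
    groups: Mapping[str, Sequence[str]],
    background: Sequence[str],
    motifs: Sequence[PWM] | Mapping[str, str],
    rel_threshold: float = 0.80,
) -> "ZMatrix":
    """Z-score matrix of motifs x groups against one shared background.

    ``motifs`` is either a list of PWMs (promoter scanning) or a mapping
    of miRNA name -> mature sequence (3'UTR seed-site scanning).
    """
    rows = {}
    if isinstance(motifs, Mapping):
        items = [(name, ("seed", seq)) for name, seq in motifs.items()]
    else:
        items = [(p.motif_id, ("pwm", p)) for p in motifs]
    for motif_id, (kind, obj) in items:
        if kind == "pwm":
            bg_hits, bg_bp = pwm_group_counts(background, obj, rel_threshold)
        else:
            bg_hits, bg_bp = seed_group_counts(background, obj)
        row = {}
        for gid, seqs in groups.items():
            if kind == "pwm":
                obs, gbp = pwm_group_counts(seqs, obj, rel_threshold)
            else:
                obs, gbp = seed_group_counts(seqs, obj)
            row[gid] = enrichment_z(obs, gbp, bg_hits, bg_bp, motif_id, gid).z
        rows[motif_id] = row
    df = pd.DataFrame.from_dict(rows, orient="index")[list(groups)]
    return ZMatrix(df)


# ---------------------------------------------------------------------------
# Z-matrix selection and clustering


@dataclass
class ZMatrix:
    """motifs x groups Z-score matrix with optional clustering state."""

    values: pd.DataFrame
    linkage: np.ndarray | None = field(default=None, compare=False)
    row_order: list[str] | None = None
    cluster_labels: dict[str, int] | None = None

    @property
    def motif_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def group_ids(self) -> list[str]:
        return list(self.values.columns)


def select_informative(zmatrix: ZMatrix, n_sd: float = 1.0) -> ZMatrix:
    """Keep motifs at least n_sd column SDs from the column mean somewhere.

    Columns with zero SD contribute no selections (flagged with a
    warning). Selection is invariant to adding a constant to a column.
    """
    df = zmatrix.values
    if df.shape[0] < 2:
        raise ValueError("need at least 2 motifs to select against")
    keep = pd.Series(False, index=df.index)
    for col in df.columns:
        mu, sd = df[col].mean(), df[col].std(ddof=0)
        if sd == 0:
            warnings.warn(f"column {col!r} has zero SD; contributes no selections")
            continue
        keep |= (df[col] - mu).abs() >= n_sd * sd
    return ZMatrix(df.loc[keep])


def _correlation_distance(df: pd.DataFrame) -> np.ndarray:
    """Condensed 1 - Pearson distance across columns, with constant rows
    handled deterministically (two equal constant rows are at distance 0,
    a constant vs. anything else at distance 1)."""
    vals = df.to_numpy(float)
    centered = vals - vals.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    n = vals.shape[0]
    out = []
    for i in range(n):
        for j in range(i + 1, n):
            if norms[i] == 0 and norms[j] == 0:
                d = 0.0 if np.allclose(vals[i], vals[j]) else 1.0
            elif norms[i] == 0 or norms[j] == 0:
                d = 1.0
            else:
                d = 1.0 - float(centered[i] @ centered[j] / (norms[i] * norms[j]))
            out.append(max(d, 0.0))
    return np.asarray(out)


def hierarchical_cluster(zmatrix: ZMatrix, k: int) -> ZMatrix:
    """Average-linkage clustering of motifs on correlation distance.

    Rows are pre-sorted by motif id so equal-distance merges are
    reproducible. Returns a ZMatrix carrying the linkage, the dendrogram
    leaf order and a k-cut cluster label per motif.
    """
    df = zmatrix.values.sort_index()
    n = df.shape[0]
    if n < 2:
        raise ValueError("need at least 2 motifs to cluster")
    if k > n:
        raise ValueError(f"k = {k} exceeds number of motifs {n}")
    dist = _correlation_distance(df)
    link = hierarchy.linkage(dist, method="average")
    leaves = hierarchy.leaves_list(link)
    labels = hierarchy.fcluster(link, t=k, criterion="maxclust")
    order = [df.index[i] for i in leaves]
    return ZMatrix(
        df.loc[order],
        linkage=link,
        row_order=order,
        cluster_labels={df.index[i]: int(labels[i]) for i in range(n)},
    )


def dendrogram_newick(zmatrix: ZMatrix) -> str:
    """Newick string of the clustering dendrogram with branch lengths."""
    if zmatrix.linkage is None:
        raise ValueError("ZMatrix has no linkage; run hierarchical_cluster first")
    tree = hierarchy.to_tree(zmatrix.linkage)
    ids = list(zmatrix.values.index)

    def walk(node, parent_dist: float) -> str:
        length = max(parent_dist - node.dist, 0.0)
        if node.is_leaf():
            return f"{ids[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"


# ---------------------------------------------------------------------------
# one-step interaction network

SIGN_TOKENS = ("activation", "inhibition")


def direct_interactions(
    tf_set: set[str], mirna_set: set[str], edges: pd.DataFrame
) -> pd.DataFrame:
    """Direct (one-step) edges whose endpoints both lie in the TF/miRNA sets.

    ``edges`` needs columns source, target, sign with sign in
    {activation, inhibition}; either direction qualifies.
    """
    for col in ("source", "target", "sign"):
        if col not in edges.columns:
            raise ValueError(f"edge table missing column {col!r}")
    bad = set(edges["sign"]) - set(SIGN_TOKENS)
    if bad:
        raise ValueError(f"unknown sign token(s): {sorted(bad)}")
    members = tf_set | mirna_set
    mask = edges["source"].isin(members) & edges["target"].isin(members)
    return edges.loc[mask].reset_index(drop=True)


def plot_zmatrix_heatmap(zmatrix: ZMatrix, ax=None):
    """Minimal Z-score heatmap; the numbers, not the figure, are the contract."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(
            figsize=(2 + len(zmatrix.group_ids), 1 + 0.25 * len(zmatrix.motif_ids))
        )
    im = ax.imshow(zmatrix.values.to_numpy(float), aspect="auto", cmap="RdYlGn")
    ax.set_xticks(range(len(zmatrix.group_ids)), zmatrix.group_ids, rotation=90)
    ax.set_yticks(range(len(zmatrix.motif_ids)), zmatrix.motif_ids, fontsize=6)
    ax.figure.colorbar(im, ax=ax, label="Z-score")
    return ax
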