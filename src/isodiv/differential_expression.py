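"""Differential isoform expression between two conditions.

The test statistic is the square root of the Jensen-Shannon divergence
(natural-log entropy, so the statistic lives in [0, sqrt(ln 2)] and the
fold-change criterion is in e-fold units throughout). For each isoform
the statistic compares the two-condition composition
(m_A, m_B) / (m_A + m_B) of its replicate-mean abundances against the
balanced (1/2, 1/2) — a bounded, monotone transform of |ln(m_B/m_A)|
defined for every isoform, including those of single-isoform genes. A
gene-level composition-switch statistic over isoform-share vectors is
provided separately (gene_js_switch).

Significance comes from a replicate-label permutation scheme: each
isoform contributes the statistics of all non-trivial relabellings of
its replicates, and the pipeline pools these permutation statistics
across isoforms into one empirical null, which gives usable p-value
resolution at the small replicate counts (2-3 per condition) typical of
RNA-Seq designs. p-values are Benjamini-Hochberg adjusted, and the
final call requires the adjusted p, an e-fold change, and an abundance
floor on the larger condition mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np

SQRT_LN2 = float(np.sqrt(np.log(2.0)))

#: permutation-set size above which random sampling replaces enumeration
MAX_EXHAUSTIVE = 500
N_RANDOM_PERMUTATIONS = 1000
#: minimum distinct permutation statistic values for a testable isoform
MIN_DISTINCT_NULL = 10


@dataclass(frozen=True)
class DEResult:
    transcript_id: str
    fpkm_a: float
    fpkm_b: float
    ln_ratio: float  # ln(fpkm_b / fpkm_a)
    sqrt_js: float
    p_raw: float
    q_bh: float
    test_ok: bool
    significant: bool = False
    direction: str = ""  # "higher_in_a" / "higher_in_b" when significant


def normalize_upper_quartile(
    matrix: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Scale each sample (row) by its upper quartile of nonzero values.

    The grand scale is preserved by multiplying back the geometric mean
    of the per-sample quartiles, so two proportional samples become
    identical while a single sample is returned unchanged.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise ValueError("expected a samples x transcripts matrix")
    factors = np.empty(m.shape[0])
    for i, row in enumerate(m):
        nz = row[row > 0]
        if nz.size == 0:
            raise ValueError(f"sample {i} has no positive values")
        factors[i] = np.percentile(nz, 75)
    grand = float(np.exp(np.mean(np.log(factors))))
    scaled = m / factors[:, None] * grand
    return scaled, factors


def sqrt_js_divergence(p: Sequence[float], q: Sequence[float]) -> float:
    """Square root of the Jensen-Shannon divergence in nats.

    JSD = H((p+q)/2) - (H(p) + H(q))/2 with natural-log entropy and the
    convention 0*ln 0 = 0; the square root is a metric bounded by
    sqrt(ln 2).
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("p and q must have the same length")
    if np.any(p < 0) or np.any(q < 0):
        raise ValueError("probability vectors must be nonnegative")
    if abs(p.sum() - 1.0) > 1e-9 or abs(q.sum() - 1.0) > 1e-9:
        raise ValueError("probability vectors must sum to 1 (within 1e-9)")

    def entropy(v: np.ndarray) -> float:
        v = v[v > 0]
        return float(-(v * np.log(v)).sum())

    jsd = entropy((p + q) / 2.0) - (entropy(p) + entropy(q)) / 2.0
    return float(np.sqrt(max(jsd, 0.0)))


def _composition_stat(mean_a: np.ndarray, mean_b: np.ndarray) -> np.ndarray:
    """Vectorized sqrt JS between (m_a, m_b)/(m_a+m_b) and (1/2, 1/2)."""
    ma = np.asarray(mean_a, dtype=float)
    mb = np.asarray(mean_b, dtype=float)
    tot = ma + mb
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = np.where(tot > 0, ma / np.where(tot > 0, tot, 1.0), 0.5)
    p = np.stack([p1, 1.0 - p1])
    m = (p + 0.5) / 2.0

    def ent(v: np.ndarray) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            t = np.where(v > 0, v * np.log(v), 0.0)
        return -t.sum(axis=0)

    jsd = ent(m) - (ent(p) + np.log(2.0)) / 2.0
    return np.sqrt(np.clip(jsd, 0.0, None))


def _assignments(
    n_a: int, n_b: int, rng: np.random.Generator | None
) -> list[tuple[int, ...]]:
    """Index sets for group A over the pooled replicates, trivial ones last.

    The original assignment and (for balanced designs) its complement are
    trivial: they reproduce the observed statistic by construction and
    are excluded from the null.
    """
    from math import comb

    n = n_a + n_b
    total = comb(n, n_a)
    identity = tuple(range(n_a))
    complement = tuple(range(n_a, n)) if n_a == n_b else None
    if total <= MAX_EXHAUSTIVE:
        return [
            c
            for c in combinations(range(n), n_a)
            if c != identity and c != complement
        ]
    if rng is None:
        rng = np.random.default_rng(0)
    out: list[tuple[int, ...]] = []
    while len(out) < N_RANDOM_PERMUTATIONS:
        c = tuple(sorted(rng.choice(n, size=n_a, replace=False).tolist()))
        if c != identity and c != complement:
            out.append(c)
    return out


@dataclass(frozen=True)
class DETestOutcome:
    sqrt_js: float
    p_raw: float
    test_ok: bool
    null_stats: np.ndarray


def de_test(
    replicates_a: Sequence[float],
    replicates_b: Sequence[float],
    rng: np.random.Generator | None = None,
) -> DETestOutcome:
    """Permutation test of one isoform's replicate FPKMs.

    The observed statistic is compared to the statistics of all
    non-trivial replicate-label reassignments (exhaustive when the
    assignment count is at most 500, else 1000 seeded random draws);
    p_raw = (1 + #null >= observed) / (1 + #null). test_ok is False with
    a single replicate in either condition or when the permutation
    statistic set is degenerate (fewer than 10 distinct values over all
    assignments), mirroring an aligner-side test-eligibility rule.
    """
    a = np.asarray(replicates_a, dtype=float)
    b = np.asarray(replicates_b, dtype=float)
    obs = float(_composition_stat(a.mean(), b.mean()))
    if a.size < 2 or b.size < 2:
        return DETestOutcome(obs, float("nan"), False, np.empty(0))
    pooled = np.concatenate([a, b])
    n = pooled.size
    null = []
    all_stats = [obs]
    for idx in _assignments(a.size, b.size, rng):
        mask = np.zeros(n, dtype=bool)
        mask[list(idx)] = True
        s = float(_composition_stat(pooled[mask].mean(), pooled[~mask].mean()))
        null.append(s)
        all_stats.append(s)
    null_arr = np.asarray(null)
    distinct = np.unique(np.round(all_stats, 12)).size
    test_ok = distinct >= MIN_DISTINCT_NULL
    p_raw = float((1 + (null_arr >= obs - 1e-12).sum()) / (1 + null_arr.size))
    return DETestOutcome(obs, p_raw, test_ok, null_arr)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p))):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty_like(p)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def de_analyze(
    replicates_a: np.ndarray,
    replicates_b: np.ndarray,
    transcript_ids: Sequence[str],
    normalize: bool = True,
    rng: np.random.Generator | None = None,
) -> list[DEResult]:
    """Full per-isoform differential test between two replicate matrices.

    ``replicates_a`` and ``replicates_b`` are replicates x transcripts
    FPKM matrices over the same transcript columns. After optional
    upper-quartile normalization across all replicates, every isoform is
    permutation-tested and the permutation statistics of all testable
    isoforms are pooled into a single empirical null, against which each
    observed statistic is ranked. q-values are BH-adjusted over the
    testable isoforms. Significance calls are left to de_filter.
    """
    a = np.atleast_2d(np.asarray(replicates_a, dtype=float))
    b = np.atleast_2d(np.asarray(replicates_b, dtype=float))
    if a.shape[1] != b.shape[1] or a.shape[1] != len(transcript_ids):
        raise ValueError("replicate matrices must share the transcript axis")
    if normalize:
        stacked, _ = normalize_upper_quartile(np.vstack([a, b]))
        a, b = stacked[: a.shape[0]], stacked[a.shape[0]:]

    outcomes = [de_test(a[:, j], b[:, j], rng=rng) for j in range(a.shape[1])]

    pooled_null = np.concatenate(
        [o.null_stats for o in outcomes if o.test_ok] or [np.empty(0)]
    )
    results: list[DEResult] = []
    testable_idx = [j for j, o in enumerate(outcomes) if o.test_ok]
    p_pooled = np.full(len(outcomes), np.nan)
    if pooled_null.size:
        for j in testable_idx:
            obs = outcomes[j].sqrt_js
            p_pooled[j] = (1 + (pooled_null >= obs - 1e-12).sum()) / (
                1 + pooled_null.size
            )
    q = np.full(len(outcomes), np.nan)
    if testable_idx:
        q[testable_idx] = bh_adjust(p_pooled[testable_idx])

    mean_a, mean_b = a.mean(axis=0), b.mean(axis=0)
    for j, tid in enumerate(transcript_ids):
        with np.errstate(divide="ignore", invalid="ignore"):
            if mean_a[j] > 0 and mean_b[j] > 0:
                lr = float(np.log(mean_b[j] / mean_a[j]))
            elif mean_b[j] > 0:
                lr = float("inf")
            elif mean_a[j] > 0:
                lr = float("-inf")
            else:
                lr = 0.0
        results.append(
            DEResult(
                transcript_id=str(tid),
                fpkm_a=float(mean_a[j]),
                fpkm_b=float(mean_b[j]),
                ln_ratio=lr,
                sqrt_js=outcomes[j].sqrt_js,
                p_raw=float(p_pooled[j]),
                q_bh=float(q[j]),
                test_ok=outcomes[j].test_ok,
            )
        )
    return results


def de_filter(
    results: Sequence[DEResult],
    fc_cut: float = 1.0,
    q_cut: float = 0.05,
    fpkm_floor: float = 50.0,
    fc_ge: bool = False,
) -> list[DEResult]:
    """Apply the three-part significance filter and attach directions.

    significant iff test_ok, q < q_cut, |ln ratio| > fc_cut (>= with
    ``fc_ge``), and max(condition means) >= fpkm_floor. Returns the full
    result list with significance/direction fields set.
    """
    out: list[DEResult] = []
    for r in results:
        abs_lr = abs(r.ln_ratio)
        fc_pass = abs_lr >= fc_cut if fc_ge else abs_lr > fc_cut
        sig = (
            r.test_ok
            and np.isfinite(r.q_bh)
            and r.q_bh < q_cut
            and fc_pass
            and max(r.fpkm_a, r.fpkm_b) >= fpkm_floor
        )
        direction = ""
        if sig:
            direction = "higher_in_b" if r.ln_ratio > 0 else "higher_in_a"
        out.append(
            DEResult(
                transcript_id=r.transcript_id,
                fpkm_a=r.fpkm_a,
                fpkm_b=r.fpkm_b,
                ln_ratio=r.ln_ratio,
                sqrt_js=r.sqrt_js,
                p_raw=r.p_raw,
                q_bh=r.q_bh,
                test_ok=r.test_ok,
                significant=bool(sig),
                direction=direction,
            )
        )
    return out


def gene_js_switch(
    iso_fpkm_a: Sequence[float], iso_fpkm_b: Sequence[float]
) -> float:
    """sqrt JS between a gene's isoform-share vectors in two conditions.

    Measures isoform-composition switching; degenerate (0.0) for
    single-isoform genes and for genes silent in either condition.
    """
    a = np.asarray(iso_fpkm_a, dtype=float)
    b = np.asarray(iso_fpkm_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("isoform vectors must have equal length")
    if a.sum() <= 0 or b.sum() <= 0:
        return 0.0
    return sqrt_js_divergence(a / a.sum(), b / b.sum())
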