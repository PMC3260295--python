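"""Expression-estimate reliability and the heavy-tailed abundance model.

An FPKM estimate whose 95% confidence interval has a lower bound of
exactly 0 carries no evidence that the transcript is expressed at all;
such estimates are labelled *unreliable*, those with a strictly positive
lower bound *reliable*. The probability of reliability is modelled as
logistic in log10 FPKM, and an expression floor is chosen on a candidate
grid so that the two misclassification rates (unreliable called
expressed vs. reliable called not expressed) are as balanced as
possible. The marginal abundance distribution itself is summarized by a
power-law fit P(k) ~ k^-r on log-binned densities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .io_formats import IsoformExpressionRecord


@dataclass(frozen=True)
class ReliabilityModel:
    """Logistic model P(reliable) = expit(beta0 + beta1 * log10 FPKM)."""

    beta0: float
    beta1: float
    se_beta0: float
    se_beta1: float
    n_obs: int
    n_excluded_zero: int
    converged: bool
    separation: bool = False

    def predict(self, fpkm: np.ndarray) -> np.ndarray:
        from scipy.special import expit

        return expit(self.beta0 + self.beta1 * np.log10(np.asarray(fpkm, float)))


@dataclass(frozen=True)
class ThresholdReport:
    threshold: float
    fp_rate: float  # unreliable with FPKM >= threshold
    fn_rate: float  # reliable with FPKM < threshold


@dataclass(frozen=True)
class PowerLawFit:
    exponent: float  # r > 0, magnitude of the log-log slope
    intercept: float
    r_squared: float
    n_bins: int


def label_reliability(records: Iterable[IsoformExpressionRecord]) -> list[bool]:
    """True iff the 95% CI lower bound strictly exceeds 0."""
    return [rec.conf_lo > 0.0 for rec in records]


def fit_reliability_logistic(
    labels: Sequence[bool], fpkms: Sequence[float]
) -> ReliabilityModel:
    """Maximum-likelihood logistic regression of reliability on log10 FPKM.

    Zero-FPKM records are excluded (log undefined) and their count
    reported. Complete separation is reported via converged=False and
    separation=True rather than silently returning infinite coefficients.
    Raises ValueError on single-class input.
    """
    labels = np.asarray(labels, dtype=bool)
    fpkms = np.asarray(fpkms, dtype=float)
    if labels.shape != fpkms.shape:
        raise ValueError("labels and fpkms must have equal length")
    keep = fpkms > 0
    n_excluded = int((~keep).sum())
    y, x = labels[keep].astype(float), np.log10(fpkms[keep])
    if y.size < 2:
        raise ValueError("need at least 2 positive-FPKM observations")
    if y.min() == y.max():
        raise ValueError("both reliability classes must be present")

    X = sm.add_constant(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=False, maxiter=200)
        except (sm.tools.sm_exceptions.PerfectSeparationError, np.linalg.LinAlgError):
            return ReliabilityModel(
                np.nan, np.nan, np.nan, np.nan, int(y.size), n_excluded,
                converged=False, separation=True,
            )
    params = np.asarray(res.params, float)
    bse = np.asarray(res.bse, float)
    # quasi-separation: coefficients diverge without an exception
    diverged = (not res.mle_retvals.get("converged", False)) or np.any(
        ~np.isfinite(bse)
    ) or np.abs(params[1]) > 50
    return ReliabilityModel(
        beta0=float(params[0]),
        beta1=float(params[1]),
        se_beta0=float(bse[0]),
        se_beta1=float(bse[1]),
        n_obs=int(y.size),
        n_excluded_zero=n_excluded,
        converged=not diverged,
        separation=bool(diverged),
    )


def classification_rates(
    labels: Sequence[bool], fpkms: Sequence[float], threshold: float
) -> tuple[float, float]:
    """(fp_rate, fn_rate) at one threshold.

    fp = fraction of unreliable records called expressed (FPKM >= T);
    fn = fraction of reliable records called not expressed (FPKM < T).
    """
    labels = np.asarray(labels, dtype=bool)
    fpkms = np.asarray(fpkms, dtype=float)
    unreliable = ~labels
    fp = float((fpkms[unreliable] >= threshold).mean()) if unreliable.any() else 0.0
    fn = float((fpkms[labels] < threshold).mean()) if labels.any() else 0.0
    return fp, fn


def select_fpkm_threshold(
    labels: Sequence[bool],
    fpkms: Sequence[float],
    grid: Sequence[float] | None = None,
) -> ThresholdReport:
    """Grid point minimizing |fp_rate - fn_rate|; ties go to the smaller T.

    Default grid: the integers 1..200 FPKM.
    """
    if grid is None:
        grid = np.arange(1.0, 201.0)
    grid = np.asarray(sorted(grid), dtype=float)
    if grid.size == 0:
        raise ValueError("candidate grid is empty")
    labels = np.asarray(labels, dtype=bool)
    if not labels.any() or labels.all():
        raise ValueError("both reliability classes must be present")
    best: ThresholdReport | None = None
    for t in grid:
        fp, fn = classification_rates(labels, fpkms, t)
        if best is None or abs(fp - fn) < abs(best.fp_rate - best.fn_rate) - 1e-15:
            best = ThresholdReport(float(t), fp, fn)
    assert best is not None
    return best


def fit_power_law(
    fpkms: Sequence[float], n_bins: int = 30
) -> PowerLawFit:
    """OLS fit of log10 density vs log10 abundance on log-spaced bins.

    Bin probabilities are normalized by bin width (a density), and only
    bins with nonzero counts enter the regression. Returns the slope
    magnitude r and the regression R^2.
    """
    x = np.asarray(fpkms, dtype=float)
    x = x[x > 0]
    if x.size < 3:
        raise ValueError("need at least 3 positive values")
    lo, hi = x.min(), x.max()
    if lo == hi:
        raise ValueError("fewer than 3 nonempty bins (all values identical)")
    edges = np.logspace(np.log10(lo), np.log10(hi) * (1 + 1e-12), n_bins + 1)
    counts, edges = np.histogram(x, bins=edges)
    widths = np.diff(edges)
    centers = np.sqrt(edges[:-1] * edges[1:])
    density = counts / counts.sum() / widths
    nz = counts > 0
    if nz.sum() < 3:
        raise ValueError("fewer than 3 nonempty bins")
    reg = stats.linregress(np.log10(centers[nz]), np.log10(density[nz]))
    return PowerLawFit(
        exponent=float(-reg.slope),
        intercept=float(reg.intercept),
        r_squared=float(reg.rvalue**2),
        n_bins=int(nz.sum()),
    )
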