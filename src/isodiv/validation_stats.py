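"""Cross-platform validation arithmetic: rank concordance and qPCR.

Agreement between RNA-Seq fold changes and qPCR relative expression is
summarized by Kendall's tau-b (tie-corrected) and its implied
probability of concordance (1 + tau)/2 — the chance that two randomly
chosen paired observations move in the same direction, 0.5 under the
null. qPCR relative expression uses the Livak 2^-ddCt method.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

#: packaged 18-pair (RNA-Seq fold change, qPCR relative expression) table
_PAIRS_RESOURCE = "qpcr_fpkm_pairs.tsv"


@dataclass(frozen=True)
class PairedMeasurement:
    label: str
    x: float  # RNA-Seq fold change (FPKM ratio)
    y: float  # qPCR relative expression (2^-ddCt)


def load_validation_pairs() -> pd.DataFrame:
    """The packaged 18 (FPKM, qPCR) comparison pairs."""
    with resources.files("isodiv.data").joinpath(_PAIRS_RESOURCE).open() as fh:
        return pd.read_csv(fh, sep="\t")


def kendall_tau_b(x, y) -> float:
    """Tie-corrected Kendall rank correlation.

    tau-b = (C - D) / sqrt((n0 - n1)(n0 - n2)) with n0 = n(n-1)/2 and
    n1, n2 the tied pair counts in x and y; ties count toward neither C
    nor D. Errors when either variable is entirely tied (undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    if x.size < 2:
        raise ValueError("need at least 2 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("tau-b undefined when all x or all y are tied")
    tau = stats.kendalltau(x, y, variant="b").statistic
    return float(tau)


def concordance_prob(tau: float) -> float:
    """(1 + tau)/2 — probability that two random pairs are concordant."""
    if not -1.0 <= tau <= 1.0:
        raise ValueError(f"tau must lie in [-1, 1], got {tau}")
    return (1.0 + tau) / 2.0


def ddct(
    ct_target_test: float,
    ct_ref_test: float,
    ct_target_calib: float,
    ct_ref_calib: float,
) -> float:
    """Livak relative expression 2^-ddCt.

    dCt = Ct(target) - Ct(reference) per sample; ddCt = dCt(test) -
    dCt(calibrator); relative expression = 2^-ddCt.
    """
    cts = (ct_target_test, ct_ref_test, ct_target_calib, ct_ref_calib)
    if not all(np.isfinite(c) for c in cts):
        raise ValueError("Ct values must be finite")
    d_test = ct_target_test - ct_ref_test
    d_calib = ct_target_calib - ct_ref_calib
    return float(2.0 ** -(d_test - d_calib))
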