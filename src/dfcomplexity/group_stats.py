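"""Group comparison, multiple-testing correction, cost-effect tests and
cost-AUC summarization.

Group differences are tested per cost with a two-sample t-test when both
groups pass Shapiro-Wilk normality and Levene's equal-variance gate
(alpha = 0.05 each), and with a Mann-Whitney U test otherwise; p-values
are corrected per panel by Benjamini-Hochberg FDR.  The effect of cost is
assessed with a Friedman test plus Kendall's W concordance, and the
cost dimension is collapsed by the trapezoidal area under the
value-versus-cost curve (AUC).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import InsufficientDataError, InvalidParameterError

__all__ = [
    "GroupComparison",
    "compare_groups",
    "fdr_bh",
    "friedman_kendall",
    "auc_over_costs",
]


@dataclass(frozen=True)
class GroupComparison:
    test_name: str  # "t" or "mwu"
    statistic: float
    p: float


def compare_groups(a, b, alpha_gate: float = 0.05) -> GroupComparison:
    """Two-sample comparison with a normality / equal-variance gate.

    Shapiro-Wilk on each group and Levene's test decide the branch: all
    pass -> equal-variance two-sample t-test; otherwise Mann-Whitney U
    (two-sided).  Zero-variance groups go to the U branch (normality is
    untestable there).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise InsufficientDataError("each group needs >= 3 values")
    parametric = True
    for g in (a, b):
        if np.ptp(g) == 0:
            parametric = False
            break
        if sps.shapiro(g).pvalue < alpha_gate:
            parametric = False
            break
    if parametric and sps.levene(a, b).pvalue < alpha_gate:
        parametric = False
    if parametric:
        res = sps.ttest_ind(a, b, equal_var=True)
        return GroupComparison("t", float(res.statistic), float(res.pvalue))
    res = sps.mannwhitneyu(a, b, alternative="two-sided")
    return GroupComparison("mwu", float(res.statistic), float(res.pvalue))


def fdr_bh(pvals, alpha: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up: reject all p_(i) with
    i <= max{i : p_(i) <= (i/m) alpha}.  Returns a boolean mask."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise InvalidParameterError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    below = ranked <= alpha * np.arange(1, m + 1) / m
    mask = np.zeros(m, dtype=bool)
    if below.any():
        k = int(np.max(np.nonzero(below)[0]))
        mask[order[: k + 1]] = True
    return mask


def friedman_kendall(values: np.ndarray) -> tuple[float, float, float]:
    """Friedman rank test across costs plus Kendall's W concordance.

    ``values`` is subjects x costs.  Returns (chi2, p, W) with
    W = chi2 / (n (k - 1)); W = 1 means every subject ranks the costs
    identically.  Rows with ties use midranks (scipy's tie correction).
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise InvalidParameterError("values must be subjects x costs")
    n, k = values.shape
    if k < 3 or n < 2:
        raise InsufficientDataError("need >= 3 costs and >= 2 subjects")
    if np.all(np.ptp(values, axis=1) == 0):
        return 0.0, 1.0, 0.0  # every row constant: no concordance information
    chi2, p = sps.friedmanchisquare(*values.T)
    w = float(chi2) / (n * (k - 1))
    return float(chi2), float(p), w


def auc_over_costs(values, costs) -> float:
    """Trapezoidal area under value-versus-cost; costs must be ascending."""
    values = np.asarray(values, dtype=float)
    c = np.asarray(list(costs), dtype=float)
    if len(c) < 2:
        raise InsufficientDataError("AUC needs >= 2 costs")
    if np.any(np.diff(c) <= 0):
        raise InvalidParameterError("costs must be strictly ascending")
    if values.shape[-1] != len(c):
        raise InvalidParameterError("values must align with costs")
    return float(np.trapezoid(values, c))
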