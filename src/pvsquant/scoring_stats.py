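"""Count condensation and agreement/association statistics.

The raw computational PVS count is condensed into the 0-4 ordinal
categories of the clinical visual rating scale so the two can be
compared on the same footing.  The printed scales overlap at the bin
edges (10 appears in both score 1 and score 2 of the visual scale; 40
in both score 3 and 4 of the computational one); the half-open
convention adopted here —

    0: count 0        1: 1-10        2: 11-20        3: 21-39        4: >= 40

— is the unique monotone reconciliation of both printed forms.  A case
flagged for high background intensity is assigned score 4 outright,
mirroring the visual raters' convention for uncountable backgrounds.

Observer agreement is assessed in the Bland-Altman framework (mean and
SD of paired differences, limits of agreement at +/- 1.96 SD), and
count/volume/score associations with simple ordinary least squares.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm

from .errors import ConstantPredictorError, InsufficientDataError

__all__ = [
    "ScoreCategory",
    "AgreementStats",
    "AssociationResult",
    "condense_score",
    "bland_altman",
    "plot_bland_altman",
    "ols_association",
]

# Upper count bound of each category (score 4 is unbounded).
_SCORE_UPPER_BOUNDS = (0, 10, 20, 39)


@dataclass(frozen=True)
class ScoreCategory:
    """An ordinal 0-4 PVS severity category."""

    value: int
    scheme: str = "computational"

    def __post_init__(self) -> None:
        if self.value not in (0, 1, 2, 3, 4):
            raise ValueError("score must be an integer in 0..4")
        if self.scheme not in ("computational", "visual"):
            raise ValueError("scheme must be 'computational' or 'visual'")


@dataclass(frozen=True)
class AgreementStats:
    """Bland-Altman summary of paired measurements."""

    n: int
    mean_difference: float
    sd_difference: float

    @property
    def limits_of_agreement(self) -> tuple[float, float]:
        lo = self.mean_difference - 1.96 * self.sd_difference
        hi = self.mean_difference + 1.96 * self.sd_difference
        return lo, hi


@dataclass(frozen=True)
class AssociationResult:
    """Simple OLS fit of y on x with 95% CI on the slope."""

    slope: float
    intercept: float
    ci_low: float
    ci_high: float
    p_value: float
    stderr: float
    n: int
    degenerate: bool = False


def condense_score(count: int, high_background: bool = False) -> ScoreCategory:
    """Condense a raw PVS count into the 0-4 rating categories.

    ``high_background=True`` forces score 4 regardless of the count.
    """
    if count < 0:
        raise ValueError("count must be non-negative")
    if high_background:
        return ScoreCategory(4)
    for score, upper in enumerate(_SCORE_UPPER_BOUNDS):
        if count <= upper:
            return ScoreCategory(score)
    return ScoreCategory(4)


def bland_altman(pairs: Sequence[tuple[float, float]]) -> AgreementStats:
    """Bland-Altman agreement of paired measurements.

    Differences are ``a - b`` per pair; the SD uses the sample (n-1)
    denominator and the limits of agreement are mean +/- 1.96 SD.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be a sequence of (a, b) tuples")
    if arr.shape[0] < 2:
        raise InsufficientDataError("Bland-Altman needs at least 2 pairs")
    if not np.all(np.isfinite(arr)):
        raise ValueError("pairs must be finite")
    diffs = arr[:, 0] - arr[:, 1]
    return AgreementStats(
        n=arr.shape[0],
        mean_difference=float(diffs.mean()),
        sd_difference=float(diffs.std(ddof=1)),
    )


def plot_bland_altman(pairs: Sequence[tuple[float, float]], ax=None):
    """Standard Bland-Altman plot: per-pair mean vs difference with the
    bias line and limits of agreement."""
    import matplotlib.pyplot as plt

    stats = bland_altman(pairs)
    arr = np.asarray(pairs, dtype=float)
    means = arr.mean(axis=1)
    diffs = arr[:, 0] - arr[:, 1]
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(means, diffs, s=18, alpha=0.8)
    ax.axhline(stats.mean_difference, color="k", lw=1)
    for limit in stats.limits_of_agreement:
        ax.axhline(limit, color="k", lw=1, ls="--")
    ax.set_xlabel("mean of pair")
    ax.set_ylabel("difference (a - b)")
    return ax


def ols_association(x: Sequence[float], y: Sequence[float]) -> AssociationResult:
    """Simple linear regression of ``y`` on ``x`` with a 95% slope CI.

    The CI is ``slope +/- t_{0.975, n-2} * SE(slope)`` and the p-value is
    the two-sided t test of zero slope.  A perfect fit (zero residual
    variance) is flagged ``degenerate``: the CI collapses to the slope
    and the p-value is reported as 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D and of equal length")
    if x.size < 3:
        raise InsufficientDataError("regression needs at least 3 observations")
    if np.ptp(x) == 0:
        raise ConstantPredictorError("predictor is constant")

    model = sm.OLS(y, sm.add_constant(x)).fit()
    slope = float(model.params[1])
    intercept = float(model.params[0])
    resid_var = float(model.ssr) / (x.size - 2)
    if np.isclose(resid_var, 0.0, atol=1e-24 * max(1.0, float(np.var(y)))):
        return AssociationResult(
            slope=slope,
            intercept=intercept,
            ci_low=slope,
            ci_high=slope,
            p_value=0.0,
            stderr=0.0,
            n=int(x.size),
            degenerate=True,
        )
    ci = model.conf_int(alpha=0.05)
    return AssociationResult(
        slope=slope,
        intercept=intercept,
        ci_low=float(ci[1][0]),
        ci_high=float(ci[1][1]),
        p_value=float(model.pvalues[1]),
        stderr=float(model.bse[1]),
        n=int(x.size),
        degenerate=False,
    )
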