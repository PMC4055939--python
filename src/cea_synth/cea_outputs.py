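"""CEA summaries of a posterior sample: ICER, credible intervals,
cost-effectiveness plane export, and the acceptability curve (CEAC).

All statistics are weighted by the sample's normalized weights, so the
same code serves no-evidence, rejection, and importance runs (the first
two simply carry uniform weights).  The ICER is the ratio of weighted-mean
incremental cost to weighted-mean incremental effectiveness — never a mean
of per-draw ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .synthesis import PosteriorSample

#: Default willingness-to-pay grid: 0..500,000 in steps of 5,000.
DEFAULT_LAMBDA_GRID = np.arange(0, 500_001, 5_000, dtype=float)


def weighted_percentile(
    values: Sequence[float], weights: Sequence[float], q: float
) -> float:
    """Inverse of the weighted empirical (step) CDF at quantile ``q``.

    Returns the smallest value whose cumulative weight reaches ``q``.
    With uniform weights this matches the unweighted ``inverted_cdf``
    quantile convention (at q=0.5 on odd n, the middle order statistic).
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.size == 0:
        raise ValidationError("weighted_percentile: empty input")
    if v.shape != w.shape:
        raise ValidationError("values and weights must have the same length")
    if not 0 <= q <= 1:
        raise ValueError(f"quantile must be in [0, 1], got {q!r}")
    order = np.argsort(v, kind="stable")
    v = v[order]
    cum = np.cumsum(w[order])
    total = cum[-1]
    if not total > 0:
        raise ValidationError("weights sum to zero")
    cum /= total
    idx = int(np.searchsorted(cum, q, side="left"))
    return float(v[min(idx, v.size - 1)])


def _weighted_mean_sd(x: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    mean = float(np.dot(w, x))
    var = float(np.dot(w, (x - mean) ** 2))
    return mean, math.sqrt(max(var, 0.0))


@dataclass(frozen=True)
class ArmSummary:
    cost_mean: float
    cost_sd: float
    qaly_mean: float
    qaly_sd: float
    events_mean: float
    events_sd: float


@dataclass(frozen=True)
class CEAResult:
    """Incremental cost-effectiveness summaries for one comparison pair."""

    comparison: tuple[str, str]
    level: float
    arm_stats: dict[str, ArmSummary]
    delta_cost: float
    delta_cost_sd: float
    delta_cost_ci: tuple[float, float]
    delta_qaly: float
    delta_qaly_sd: float
    delta_qaly_ci: tuple[float, float]
    icer: Optional[float]
    icer_numerator: float
    icer_denominator: float
    interval_method: str = "weighted_percentile"
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "comparison": list(self.comparison),
            "credible_level": self.level,
            "arms": {
                a: {
                    "cost_mean": s.cost_mean,
                    "cost_sd": s.cost_sd,
                    "qaly_mean": s.qaly_mean,
                    "qaly_sd": s.qaly_sd,
                    "events_mean": s.events_mean,
                    "events_sd": s.events_sd,
                }
                for a, s in self.arm_stats.items()
            },
            "delta_cost": self.delta_cost,
            "delta_cost_sd": self.delta_cost_sd,
            "delta_cost_ci": list(self.delta_cost_ci),
            "delta_qaly": self.delta_qaly,
            "delta_qaly_sd": self.delta_qaly_sd,
            "delta_qaly_ci": list(self.delta_qaly_ci),
            "icer": self.icer,
            "icer_numerator": self.icer_numerator,
            "icer_denominator": self.icer_denominator,
            "interval_method": self.interval_method,
            "diagnostics": self.diagnostics,
        }


def summarize(
    sample: PosteriorSample, level: float = 0.95
) -> CEAResult:
    """Weighted CEA summary of a posterior sample.

    Expectations and SDs are normalized-weight means / weighted SDs over
    the draws; credible intervals are weighted percentiles.  If the
    weighted mean incremental effectiveness is exactly zero the ICER is
    undefined (``None``) but numerator and denominator are still reported.
    """
    if sample.m == 0:
        raise ValidationError("empty posterior sample")
    if not 0 < level < 1:
        raise ValueError(f"credible level must be in (0, 1), got {level!r}")
    if sample.scheme == "importance":
        ess = sample.effective_sample_size
        if ess is None or ess <= 1:
            raise ValidationError(
                f"importance sample too degenerate to summarize (ESS={ess!r})"
            )
    w = sample.normalized_weights
    arm_stats = {}
    for arm in sample.arms:
        c_mean, c_sd = _weighted_mean_sd(sample.column(f"cost_{arm}"), w)
        q_mean, q_sd = _weighted_mean_sd(sample.column(f"qaly_{arm}"), w)
        e_mean, e_sd = _weighted_mean_sd(sample.column(f"events_{arm}"), w)
        arm_stats[arm] = ArmSummary(c_mean, c_sd, q_mean, q_sd, e_mean, e_sd)

    dc = sample.delta_cost
    de = sample.delta_qaly
    dc_mean, dc_sd = _weighted_mean_sd(dc, w)
    de_mean, de_sd = _weighted_mean_sd(de, w)
    alpha = (1 - level) / 2
    dc_ci = (weighted_percentile(dc, w, alpha), weighted_percentile(dc, w, 1 - alpha))
    de_ci = (weighted_percentile(de, w, alpha), weighted_percentile(de, w, 1 - alpha))
    icer = dc_mean / de_mean if de_mean != 0 else None
    return CEAResult(
        comparison=sample.comparison,
        level=level,
        arm_stats=arm_stats,
        delta_cost=dc_mean,
        delta_cost_sd=dc_sd,
        delta_cost_ci=dc_ci,
        delta_qaly=de_mean,
        delta_qaly_sd=de_sd,
        delta_qaly_ci=de_ci,
        icer=icer,
        icer_numerator=dc_mean,
        icer_denominator=de_mean,
        diagnostics=sample.diagnostics(),
    )


@dataclass(frozen=True)
class CEACCurve:
    """Probability of cost-effectiveness over a willingness-to-pay grid."""

    lambdas: np.ndarray
    probabilities: np.ndarray

    def crossing(self, p: float = 0.5) -> Optional[float]:
        """Smallest λ on the grid with probability >= ``p`` (None if never)."""
        above = np.flatnonzero(self.probabilities >= p)
        return float(self.lambdas[above[0]]) if above.size else None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"lambda": self.lambdas, "probability": self.probabilities}
        )


def ceac(
    sample: PosteriorSample,
    lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
) -> CEACCurve:
    """Cost-effectiveness acceptability curve for the sample's comparison.

    At each willingness-to-pay λ the value is the weighted probability of
    positive net monetary benefit, Σᵢ wᵢ·1(λ·ΔEᵢ − ΔCᵢ > 0).  At λ=0 this
    is P(ΔC < 0); as λ→∞ it converges to P(ΔE > 0).
    """
    if sample.m == 0:
        raise ValidationError("empty posterior sample")
    grid = np.asarray(lambda_grid, dtype=float)
    if (grid < 0).any():
        raise ValueError("lambda grid must be nonnegative")
    w = sample.normalized_weights
    dc = sample.delta_cost
    de = sample.delta_qaly
    nmb = grid[:, None] * de[None, :] - dc[None, :]
    probs = (nmb > 0) @ w
    return CEACCurve(lambdas=grid, probabilities=probs)


def export_plane(sample: PosteriorSample, path) -> None:
    """Write the per-draw cost-effectiveness plane (ΔE, ΔC, weight) as CSV."""
    if sample.m == 0:
        raise ValidationError("empty posterior sample")
    pd.DataFrame(
        {
            "delta_e": sample.delta_qaly,
            "delta_c": sample.delta_cost,
            "weight": sample.normalized_weights,
        }
    ).to_csv(path, index=False)
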