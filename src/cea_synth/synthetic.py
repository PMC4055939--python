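"""Synthetic trial generation and validation oracles.

Two independent oracles live here alongside the generator:

* :func:`conjugate_posterior` — the closed-form normal-normal posterior the
  samplers should approach when the bootstrap distribution of the log rate
  ratio is approximately normal (large arms).
* :func:`enumerate_ordinary_bootstrap` — exhaustive enumeration of every
  ordinary-bootstrap resample of a tiny trial, giving the evidence-weighted
  expectation of any statistic exactly.

The generator produces multi-arm trials with the structure the method
assumes: per-patient event counts are Poisson, costs are right-skewed
(gamma base cost) and rise with events, QALYs fall with events.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .evidence import EvidenceWeight
from .resampling import BootstrapWeights
from .synthesis import PosteriorDraw, compute_theta
from .trial_io import IMPUTABLE_FIELDS, TrialData


@dataclass(frozen=True)
class ArmSpec:
    """Generative model for one arm.

    ``event_rate`` is the expected number of events per follow-up period.
    Cost = Gamma(base_cost_shape, base_cost_mean/base_cost_shape)
    + cost_per_event × events; QALY = qaly_baseline − qaly_per_event × events
    + N(0, qaly_noise_sd), clamped to [0, followup/52].
    """

    name: str
    size: int
    event_rate: float
    base_cost_mean: float = 2000.0
    base_cost_shape: float = 2.0
    cost_per_event: float = 800.0
    qaly_baseline: float = 0.75
    qaly_per_event: float = 0.02
    qaly_noise_sd: float = 0.05


@dataclass(frozen=True)
class SynthTrialSpec:
    arms: tuple[ArmSpec, ...]
    followup: float = 52.0

    def __post_init__(self) -> None:
        if len(self.arms) < 2:
            raise ValidationError("need at least 2 arms")
        names = [a.name for a in self.arms]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate arm names")
        for a in self.arms:
            if a.size < 2:
                raise ValidationError(f"arm {a.name!r}: size must be >= 2")
            if a.event_rate <= 0:
                raise ValidationError(f"arm {a.name!r}: event_rate must be > 0")
            if a.base_cost_mean <= 0 or a.base_cost_shape <= 0:
                raise ValidationError(f"arm {a.name!r}: invalid cost model")
            if a.qaly_noise_sd < 0:
                raise ValidationError(f"arm {a.name!r}: negative noise scale")
        if self.followup <= 0:
            raise ValidationError("followup must be positive")


def default_trial_spec() -> SynthTrialSpec:
    """Three-arm trial (159/148/145) with an expensive low-event third arm.

    The comparator arm C has a lower event rate but a much higher base
    cost than reference arm A, and arm B is dominated — so external
    evidence favoring C's event reduction should lower the C-vs-A ICER.
    """
    return SynthTrialSpec(
        arms=(
            ArmSpec("A", 150, event_rate=2.0, base_cost_mean=2000.0),
            ArmSpec("B", 150, event_rate=2.05, base_cost_mean=3000.0),
            ArmSpec("C", 150, event_rate=1.6, base_cost_mean=3400.0),
        )
    )


def generate_trial(
    spec: SynthTrialSpec, rng: np.random.Generator
) -> TrialData:
    """Draw one synthetic trial from ``spec``.

    Events ~ Poisson(rate); cost and QALY follow the per-arm models with
    positive cost-event and negative QALY-event correlation within arm.
    Byte-identical for a given generator state.
    """
    rows = []
    qaly_cap = spec.followup / 52.0
    for arm in spec.arms:
        events = rng.poisson(arm.event_rate, size=arm.size)
        base = rng.gamma(
            arm.base_cost_shape,
            arm.base_cost_mean / arm.base_cost_shape,
            size=arm.size,
        )
        cost = base + arm.cost_per_event * events
        qaly = (
            arm.qaly_baseline
            - arm.qaly_per_event * events
            + rng.normal(0.0, arm.qaly_noise_sd, size=arm.size)
        )
        qaly = np.clip(qaly, 0.0, qaly_cap)
        for i in range(arm.size):
            rows.append(
                {
                    "patient_id": f"{arm.name}-{i + 1:04d}",
                    "arm": arm.name,
                    "cost": float(cost[i]),
                    "qaly": float(qaly[i]),
                    "events": float(events[i]),
                    "followup": spec.followup,
                }
            )
    return TrialData(pd.DataFrame(rows))


def generate_missingness(
    data: TrialData,
    fraction: float,
    rng: np.random.Generator,
    fields: Sequence[str] = IMPUTABLE_FIELDS,
) -> TrialData:
    """Flag ``fraction`` of cost/QALY/event cells missing completely at random.

    Raises if the realized mask would leave an arm with no observed value
    for some field (the fraction was too high for the guarantee).
    """
    if not 0 <= fraction < 1:
        raise ValidationError(f"fraction must be in [0, 1), got {fraction!r}")
    bad = set(fields) - set(IMPUTABLE_FIELDS)
    if bad:
        raise ValidationError(f"cannot mask fields {sorted(bad)}")
    if fraction == 0:
        return data.copy()
    table = data.table.copy()
    n = len(table)
    for fld in fields:
        mask = rng.random(n) < fraction
        col = table[fld].to_numpy().copy()
        col[mask] = np.nan
        table[fld] = col
    out = TrialData(table, validate=False)
    for arm in out.arms:
        sub = out.arm_table(arm)
        for fld in fields:
            if sub[fld].isna().all():
                raise ValidationError(
                    f"missingness fraction {fraction} left arm {arm!r} with no "
                    f"observed {fld!r} values"
                )
    return out


@dataclass(frozen=True)
class ConjugatePosterior:
    """Normal-likelihood × normal-prior posterior for a scalar parameter."""

    mean: float
    sd: float

    @property
    def precision(self) -> float:
        return 1.0 / (self.sd * self.sd)


def conjugate_posterior(
    data_mean: float, data_se: float, prior_mean: float, prior_sd: float
) -> ConjugatePosterior:
    """Closed-form posterior: precisions add, means combine precision-weighted.

    posterior mean = (data_mean/se² + prior_mean/sd²) / (1/se² + 1/sd²);
    posterior variance = 1 / (1/se² + 1/sd²).
    """
    if data_se <= 0 or prior_sd <= 0:
        raise ValueError("scales must be positive")
    prec_d = 1.0 / (data_se * data_se)
    prec_p = 1.0 / (prior_sd * prior_sd)
    prec = prec_d + prec_p
    mean = (data_mean * prec_d + prior_mean * prec_p) / prec
    return ConjugatePosterior(mean=mean, sd=math.sqrt(1.0 / prec))


# ---------------------------------------------------------------------------
# exhaustive ordinary-bootstrap enumeration
# ---------------------------------------------------------------------------

_MAX_ENUM_PATIENTS = 8


def _compositions(n: int):
    """All count vectors (c₁..cₙ) with Σc = n: the ordinary bootstrap support."""
    for cuts in itertools.combinations(range(n + n - 1), n - 1):
        counts = []
        prev = -1
        for c in cuts:
            counts.append(c - prev - 1)
            prev = c
        counts.append(n + n - 2 - prev)
        yield tuple(counts)


def enumerate_ordinary_bootstrap(
    data: TrialData,
    evidence: EvidenceWeight,
    statistic: Callable[[PosteriorDraw], float],
    comparison: tuple[str, str],
    zero_event_correction: float = 0.0,
) -> float:
    """Exact evidence-weighted bootstrap expectation of ``statistic``.

    Enumerates every combination of per-arm multinomial resamples, weighting
    each by its multinomial probability times the evidence weight of its
    log rate ratio, and returns the normalized expectation.  Exact to
    floating precision; feasible only for tiny trials (≤ 8 patients total).
    """
    if data.n_patients > _MAX_ENUM_PATIENTS:
        raise ValidationError(
            f"enumeration limited to {_MAX_ENUM_PATIENTS} patients, "
            f"got {data.n_patients}"
        )
    if data.has_missing:
        raise ValidationError("enumeration requires complete data")
    arms = data.arms
    sizes = data.arm_sizes
    per_arm: list[list[tuple[np.ndarray, float]]] = []
    for arm in arms:
        n = sizes[arm]
        p = np.full(n, 1.0 / n)
        options = []
        for counts in _compositions(n):
            prob = float(stats.multinomial.pmf(counts, n, p))
            options.append((np.array(counts, dtype=float) / n, prob))
        per_arm.append(options)

    num = 0.0
    den = 0.0
    for combo in itertools.product(*per_arm):
        weights = BootstrapWeights(
            scheme="ordinary",
            arm_weights={arm: w for arm, (w, _) in zip(arms, combo)},
        )
        prob = math.prod(p for _, p in combo)
        draw = compute_theta(data, weights, comparison, zero_event_correction)
        mass = prob * evidence.sampling_weight(draw.theta_e)
        if mass == 0.0:
            continue
        num += mass * statistic(draw)
        den += mass
    if den <= 0:
        raise ValidationError(
            "evidence weight is zero on every bootstrap resample"
        )
    return num / den
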