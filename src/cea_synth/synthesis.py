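"""Posterior sampling: convert bootstrap replicates into draws from the
evidence-updated posterior.

The bootstrap stream is the proposal: each replicate yields weighted arm
means (cost, effectiveness, events) and the log rate ratio θₑ between a
designated comparison pair.  The evidence weight w(θₑ*) ∈ [0, 1] then either
thins the stream (rejection sampling: keep a replicate with probability
w(θₑ*)) or reweights it (importance sampling: keep everything, normalize
the weights).  With flat evidence both reduce to the plain bootstrap.

Replicate order of operations is fixed: draw weights → impute missing
values → compute θ → draw the rejection uniform.  Because the uniform is
drawn last from the replicate's own substream, rejection, importance, and
no-evidence runs sharing a seed see identical replicate values (common
random numbers).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateSampleError, PriorDataConflictError, ValidationError
from .evidence import EvidenceWeight
from .resampling import BootstrapWeights, draw_replicate, replicate_rng
from .trial_io import TrialData, impute_within_replicate

logger = logging.getLogger(__name__)

POSTERIOR_SCHEMES = ("none", "rejection", "importance")

#: Log progress every this many attempts.
LOG_EVERY = 5000


@dataclass
class PosteriorDraw:
    """Arm-level summaries of one retained bootstrap replicate."""

    replicate_index: int
    arm_cost: dict[str, float]
    arm_qaly: dict[str, float]
    arm_events: dict[str, float]
    theta_e: float  # NaN when the log rate ratio is undefined (zero events)
    raw_weight: float = float("nan")

    @property
    def theta_valid(self) -> bool:
        return math.isfinite(self.theta_e)


@dataclass
class PosteriorSample:
    """An ordered collection of posterior draws plus sampling diagnostics.

    ``table`` has one row per retained draw with columns ``replicate``,
    ``cost_<arm>``/``qaly_<arm>``/``events_<arm>`` per arm, ``theta_e`` and
    ``raw_weight``.  ``normalized_weights`` sums to 1; for schemes ``none``
    and ``rejection`` every weight is 1/M.
    """

    table: pd.DataFrame
    arms: list[str]
    comparison: tuple[str, str]
    scheme: str
    bootstrap: str
    normalized_weights: np.ndarray
    attempts: int
    acceptance_rate: Optional[float] = None
    effective_sample_size: Optional[float] = None
    n_invalid_theta: int = 0
    seed: Optional[int] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scheme not in POSTERIOR_SCHEMES:
            raise ValidationError(f"unknown posterior scheme {self.scheme!r}")
        w = np.asarray(self.normalized_weights, dtype=float)
        self.normalized_weights = w
        m = len(self.table)
        if w.size != m:
            raise ValidationError("normalized weight length != number of draws")
        if m and abs(w.sum() - 1.0) > 1e-10:
            raise ValidationError(f"normalized weights sum to {w.sum()!r}")
        if self.scheme in ("none", "rejection") and m:
            if not np.allclose(w, 1.0 / m, atol=1e-12):
                raise ValidationError(
                    f"scheme {self.scheme!r} requires uniform weights"
                )
        if self.effective_sample_size is not None and m:
            if not (0 < self.effective_sample_size <= m + 1e-9):
                raise ValidationError(
                    f"effective sample size {self.effective_sample_size!r} "
                    f"outside (0, {m}]"
                )

    @property
    def m(self) -> int:
        return len(self.table)

    def column(self, name: str) -> np.ndarray:
        return self.table[name].to_numpy()

    @property
    def theta_e(self) -> np.ndarray:
        return self.column("theta_e")

    @property
    def delta_cost(self) -> np.ndarray:
        ref, comp = self.comparison
        return self.column(f"cost_{comp}") - self.column(f"cost_{ref}")

    @property
    def delta_qaly(self) -> np.ndarray:
        ref, comp = self.comparison
        return self.column(f"qaly_{comp}") - self.column(f"qaly_{ref}")

    @property
    def draws(self) -> Iterator[PosteriorDraw]:
        for row in self.table.itertuples(index=False):
            d = row._asdict()
            yield PosteriorDraw(
                replicate_index=int(d["replicate"]),
                arm_cost={a: d[f"cost_{a}"] for a in self.arms},
                arm_qaly={a: d[f"qaly_{a}"] for a in self.arms},
                arm_events={a: d[f"events_{a}"] for a in self.arms},
                theta_e=d["theta_e"],
                raw_weight=d["raw_weight"],
            )

    def expectation(self, values: np.ndarray) -> float:
        """Normalized-weight mean of ``values``.

        Entries carrying exactly zero weight contribute nothing even when
        non-finite (draws with an undefined θₑ keep NaN in the table but
        have zero weight).
        """
        v = np.asarray(values, dtype=float)
        w = self.normalized_weights
        keep = w > 0
        return float(w[keep] @ v[keep])

    def diagnostics(self) -> dict:
        return {
            "scheme": self.scheme,
            "bootstrap": self.bootstrap,
            "draws": self.m,
            "attempts": self.attempts,
            "acceptance_rate": self.acceptance_rate,
            "effective_sample_size": self.effective_sample_size,
            "n_invalid_theta": self.n_invalid_theta,
            "seed": self.seed,
            "comparison": list(self.comparison),
        }


# ---------------------------------------------------------------------------
# θ computation
# ---------------------------------------------------------------------------


def _arm_arrays(data: TrialData) -> dict[str, tuple[np.ndarray, ...]]:
    """Per-arm (cost, qaly, events, followup) arrays, extracted once."""
    out = {}
    t = data.table
    arm_col = t["arm"].to_numpy()
    cost = t["cost"].to_numpy()
    qaly = t["qaly"].to_numpy()
    events = t["events"].to_numpy()
    followup = t["followup"].to_numpy()
    for arm in data.arms:
        sel = arm_col == arm
        out[arm] = (cost[sel], qaly[sel], events[sel], followup[sel])
    return out


def _theta_from_arrays(
    arrays: dict[str, tuple[np.ndarray, ...]],
    weights: BootstrapWeights,
    comparison: tuple[str, str],
    replicate_index: int,
    zero_event_correction: float,
) -> PosteriorDraw:
    arm_cost, arm_qaly, arm_events = {}, {}, {}
    event_total = {}
    followup_total = {}
    for arm, (cost, qaly, events, followup) in arrays.items():
        w = weights.arm_weights[arm]
        arm_cost[arm] = float(np.dot(w, cost))
        arm_qaly[arm] = float(np.dot(w, qaly))
        arm_events[arm] = float(np.dot(w, events))
        event_total[arm] = arm_events[arm]
        followup_total[arm] = float(np.dot(w, followup))

    ref, comp = comparison
    e_ref, e_comp = event_total[ref], event_total[comp]
    if zero_event_correction > 0 and (e_ref <= 0 or e_comp <= 0):
        e_ref += zero_event_correction
        e_comp += zero_event_correction
    if e_ref <= 0 or e_comp <= 0:
        theta = float("nan")
    else:
        rate_ref = e_ref / followup_total[ref]
        rate_comp = e_comp / followup_total[comp]
        theta = math.log(rate_comp / rate_ref)
    return PosteriorDraw(
        replicate_index=replicate_index,
        arm_cost=arm_cost,
        arm_qaly=arm_qaly,
        arm_events=arm_events,
        theta_e=theta,
    )


def compute_theta(
    data: TrialData,
    weights: BootstrapWeights,
    comparison: tuple[str, str],
    zero_event_correction: float = 0.0,
) -> PosteriorDraw:
    """Weighted arm means and the log rate ratio for one replicate.

    ``comparison`` is ``(reference_arm, comparator_arm)``; the returned
    θₑ is ``ln(rate(comparator) / rate(reference))`` with
    ``rate(a) = Σ wᵢ·eventsᵢ / Σ wᵢ·followupᵢ`` over arm ``a``.  Under a
    constant follow-up this is the ratio of weighted mean event counts.

    If either arm's weighted event total is zero the log rate ratio is
    undefined: θₑ is NaN unless ``zero_event_correction`` (> 0, e.g. 0.5)
    is given, in which case the correction is added to both arms' weighted
    event totals.

    ``data`` must be complete (impute first).
    """
    for arm in comparison:
        if arm not in data.arms:
            raise ValidationError(
                f"comparison arm {arm!r} not in trial arms {data.arms}"
            )
    if data.has_missing:
        raise ValidationError(
            "trial data contains missing values; run imputation first"
        )
    weights.check_conforms(data)
    return _theta_from_arrays(
        _arm_arrays(data), weights, comparison, -1, zero_event_correction
    )


# ---------------------------------------------------------------------------
# the replicate stream
# ---------------------------------------------------------------------------


def _replicate_stream(
    data: TrialData,
    comparison: tuple[str, str],
    bootstrap: str,
    seed: int,
    impute_method: str,
    zero_event_correction: float,
) -> Iterator[tuple[PosteriorDraw, np.random.Generator]]:
    """Yield (draw, rng) per replicate index 0, 1, 2, ...

    The rng handed back is the replicate's own substream, positioned after
    every draw the replicate consumed, so the caller's rejection uniform is
    reproducible and does not perturb later replicates.
    """
    needs_impute = data.has_missing
    arrays = None if needs_impute else _arm_arrays(data)
    index = 0
    while True:
        rng = replicate_rng(seed, index)
        weights = draw_replicate(data, bootstrap, rng)
        if needs_impute:
            completed = impute_within_replicate(data, weights, impute_method, rng)
            rep_arrays = _arm_arrays(completed)
        else:
            rep_arrays = arrays
        draw = _theta_from_arrays(
            rep_arrays, weights, comparison, index, zero_event_correction
        )
        yield draw, rng
        index += 1


def _validate_common(data: TrialData, comparison: tuple[str, str], m: int) -> None:
    if m < 1:
        raise ValueError("number of draws M must be >= 1")
    for arm in comparison:
        if arm not in data.arms:
            raise ValidationError(
                f"comparison arm {arm!r} not in trial arms {data.arms}"
            )


def _build_table(draws: list[PosteriorDraw], arms: Sequence[str]) -> pd.DataFrame:
    cols: dict[str, list] = {"replicate": [d.replicate_index for d in draws]}
    for a in arms:
        cols[f"cost_{a}"] = [d.arm_cost[a] for d in draws]
        cols[f"qaly_{a}"] = [d.arm_qaly[a] for d in draws]
        cols[f"events_{a}"] = [d.arm_events[a] for d in draws]
    cols["theta_e"] = [d.theta_e for d in draws]
    cols["raw_weight"] = [d.raw_weight for d in draws]
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# samplers
# ---------------------------------------------------------------------------


def bootstrap_sample(
    data: TrialData,
    m: int,
    comparison: tuple[str, str],
    bootstrap: str = "bayesian",
    seed: int = 0,
    impute_method: str = "weighted_arm_mean",
    zero_event_correction: float = 0.0,
) -> PosteriorSample:
    """Plain bootstrap posterior (no external evidence): M uniform draws."""
    _validate_common(data, comparison, m)
    stream = _replicate_stream(
        data, comparison, bootstrap, seed, impute_method, zero_event_correction
    )
    draws = []
    n_invalid = 0
    for draw, _rng in stream:
        draw.raw_weight = 1.0
        if not draw.theta_valid:
            n_invalid += 1
        draws.append(draw)
        if len(draws) >= m:
            break
    return PosteriorSample(
        table=_build_table(draws, data.arms),
        arms=data.arms,
        comparison=comparison,
        scheme="none",
        bootstrap=bootstrap,
        normalized_weights=np.full(m, 1.0 / m),
        attempts=m,
        n_invalid_theta=n_invalid,
        seed=seed,
    )


def rejection_sample(
    data: TrialData,
    evidence: EvidenceWeight,
    m: int,
    comparison: tuple[str, str],
    bootstrap: str = "bayesian",
    seed: int = 0,
    max_attempts: Optional[int] = None,
    impute_method: str = "weighted_arm_mean",
    zero_event_correction: float = 0.0,
) -> PosteriorSample:
    """Accept each replicate with probability equal to its evidence weight.

    Runs until exactly ``m`` replicates are accepted; replicates with an
    undefined θₑ get weight 0 and are rejected.  If ``max_attempts``
    (default 100·m) is exhausted first, a :class:`PriorDataConflictError`
    reports the running acceptance rate — the symptom of external evidence
    in strong conflict with the trial data.
    """
    _validate_common(data, comparison, m)
    if max_attempts is None:
        max_attempts = 100 * m
    stream = _replicate_stream(
        data, comparison, bootstrap, seed, impute_method, zero_event_correction
    )
    draws: list[PosteriorDraw] = []
    attempts = 0
    n_invalid = 0
    for draw, rng in stream:
        attempts += 1
        p = evidence.sampling_weight(draw.theta_e)
        if not draw.theta_valid:
            n_invalid += 1
        u = rng.uniform()
        if u <= p:
            draw.raw_weight = p
            draws.append(draw)
            if len(draws) >= m:
                break
        if attempts % LOG_EVERY == 0:
            logger.info(
                "rejection sampling: %d/%d accepted after %d attempts "
                "(rate %.4f)",
                len(draws), m, attempts, len(draws) / attempts,
            )
        if attempts >= max_attempts:
            raise PriorDataConflictError(
                f"only {len(draws)}/{m} draws accepted after {attempts} "
                f"attempts (acceptance rate {len(draws) / attempts:.5f}); "
                "the external evidence likely conflicts with the trial data",
                attempts=attempts,
                accepted=len(draws),
            )
    return PosteriorSample(
        table=_build_table(draws, data.arms),
        arms=data.arms,
        comparison=comparison,
        scheme="rejection",
        bootstrap=bootstrap,
        normalized_weights=np.full(m, 1.0 / m),
        attempts=attempts,
        acceptance_rate=m / attempts,
        n_invalid_theta=n_invalid,
        seed=seed,
    )


def importance_sample(
    data: TrialData,
    evidence: EvidenceWeight,
    m: int,
    comparison: tuple[str, str],
    bootstrap: str = "bayesian",
    seed: int = 0,
    impute_method: str = "weighted_arm_mean",
    zero_event_correction: float = 0.0,
) -> PosteriorSample:
    """Keep every replicate; weight it by its evidence weight.

    All ``m`` replicates are retained; normalized weights are the raw
    evidence weights divided by their sum, and the effective sample size
    (Σw)²/Σw² is recorded.  Replicates with undefined θₑ get raw weight 0.
    On a shared seed the first ``m`` replicates coincide with a rejection
    run's attempt stream (common random numbers).
    """
    _validate_common(data, comparison, m)
    stream = _replicate_stream(
        data, comparison, bootstrap, seed, impute_method, zero_event_correction
    )
    draws: list[PosteriorDraw] = []
    n_invalid = 0
    for draw, _rng in stream:
        draw.raw_weight = evidence.sampling_weight(draw.theta_e)
        if not draw.theta_valid:
            n_invalid += 1
        draws.append(draw)
        if len(draws) >= m:
            break
    raw = np.array([d.raw_weight for d in draws])
    total = raw.sum()
    if total <= 0:
        raise DegenerateSampleError(
            "all importance weights are zero; the external evidence puts no "
            "mass on any attainable theta"
        )
    ess = float(total * total / np.dot(raw, raw))
    logger.info("importance sampling: M=%d, ESS=%.1f", m, ess)
    return PosteriorSample(
        table=_build_table(draws, data.arms),
        arms=data.arms,
        comparison=comparison,
        scheme="importance",
        bootstrap=bootstrap,
        normalized_weights=raw / total,
        attempts=m,
        effective_sample_size=ess,
        n_invalid_theta=n_invalid,
        seed=seed,
    )
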