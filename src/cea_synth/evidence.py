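"""External-evidence weight functions on the log-effect scale.

External evidence (e.g., a published rate ratio with a 95% CI) is turned
into a bounded, continuous weight function w(θ) ∈ (0, 1] on the log scale:
the normal kernel exp(−(θ − μ)² / (2σ²)), scaled so its maximum is exactly
1 at θ = μ.  Scaling to a maximum of 1 is what makes the weights usable as
acceptance probabilities in rejection sampling.

Only bounded continuous weight functions are supported.  Mixed-type
("lump-and-smear") priors with point masses have unbounded densities and
are rejected by the configuration layer; see :mod:`cea_synth.config`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

#: Two-sided 95% normal quantile used to recover a standard error from a CI.
Z_95 = 1.959963984540054

CI_CONVENTIONS = ("upper_half", "symmetric")


class EvidenceWeight:
    """Base class: a bounded continuous weight function on θ."""

    parameter_name: str

    def weight(self, theta_e: float) -> float:
        raise NotImplementedError

    def sampling_weight(self, theta_e: float) -> float:
        """Weight used by the samplers: 0 for invalid (non-finite) θ."""
        if not math.isfinite(theta_e):
            return 0.0
        return self.weight(theta_e)


@dataclass(frozen=True)
class ExternalEvidence(EvidenceWeight):
    """Normal likelihood on the log-effect scale, scaled to max 1.

    ``provenance`` records how (μ, σ) were obtained: the reported point
    estimate and CI, the between-study variance added, and the CI-to-SE
    convention used.
    """

    parameter_name: str
    mu: float
    sigma: float
    provenance: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not math.isfinite(self.mu):
            raise ValueError("mu must be finite")
        if not (self.sigma > 0 and math.isfinite(self.sigma)):
            raise ValueError("sigma must be positive and finite")

    def weight(self, theta_e: float) -> float:
        if not math.isfinite(theta_e):
            raise ValueError(f"theta_e must be finite, got {theta_e!r}")
        z = (theta_e - self.mu) / self.sigma
        return math.exp(-0.5 * z * z)


@dataclass(frozen=True)
class FlatEvidence(EvidenceWeight):
    """Weight identically 1: the no-evidence limit.

    Under flat evidence rejection sampling accepts everything and
    importance sampling assigns uniform weights, so both schemes reproduce
    the plain bootstrap posterior.  Replicates with an invalid θ are kept
    (weight 1), matching the no-evidence run draw-for-draw.
    """

    parameter_name: str = "flat"

    def weight(self, theta_e: float) -> float:
        return 1.0

    def sampling_weight(self, theta_e: float) -> float:
        return 1.0


@dataclass(frozen=True)
class CustomEvidence(EvidenceWeight):
    """User-supplied bounded continuous weight function, validated on a grid."""

    parameter_name: str
    fn: Callable[[float], float] = None  # type: ignore[assignment]

    def weight(self, theta_e: float) -> float:
        if not math.isfinite(theta_e):
            raise ValueError(f"theta_e must be finite, got {theta_e!r}")
        return float(self.fn(theta_e))


def flat_evidence() -> FlatEvidence:
    """The flat (no-information) evidence weight."""
    return FlatEvidence()


def pool_evidence(
    point: float,
    ci_low: float,
    ci_high: float,
    between_study_variance: float = 0.0,
    *,
    parameter_name: str = "log_effect",
    ci_convention: str = "upper_half",
) -> ExternalEvidence:
    """Pool a reported ratio estimate with a between-study variance.

    The point estimate and its 95% CI (all on the ratio scale) are moved to
    the log scale; the within-study standard error is recovered from the CI
    and inflated by the between-study variance:

        mu    = ln(point)
        SE    = (ln(ci_high) − ln(point)) / 1.959964        [upper_half]
              = (ln(ci_high) − ln(ci_low)) / (2 × 1.959964) [symmetric]
        sigma = sqrt(SE² + between_study_variance)

    ``upper_half`` is the default convention.  Provenance records every
    input and the convention used.
    """
    if not (0 < ci_low < point < ci_high):
        raise ValueError(
            f"need 0 < ci_low < point < ci_high, got "
            f"({ci_low!r}, {point!r}, {ci_high!r})"
        )
    if between_study_variance < 0:
        raise ValueError("between_study_variance must be >= 0")
    if ci_convention not in CI_CONVENTIONS:
        raise ValueError(
            f"ci_convention must be one of {CI_CONVENTIONS}, got {ci_convention!r}"
        )
    mu = math.log(point)
    if ci_convention == "upper_half":
        se = (math.log(ci_high) - math.log(point)) / Z_95
    else:
        se = (math.log(ci_high) - math.log(ci_low)) / (2 * Z_95)
    sigma = math.sqrt(se * se + between_study_variance)
    return ExternalEvidence(
        parameter_name=parameter_name,
        mu=mu,
        sigma=sigma,
        provenance={
            "point": point,
            "ci_low": ci_low,
            "ci_high": ci_high,
            "between_study_variance": between_study_variance,
            "within_study_se": se,
            "ci_convention": ci_convention,
        },
    )


def evidence_weight(theta_e: float, evidence: EvidenceWeight) -> float:
    """Evaluate the scaled external likelihood at ``theta_e`` (∈ (0, 1])."""
    return evidence.weight(theta_e)


def as_weight_function(
    fn: Callable[[float], float],
    probe_grid: Sequence[float],
    parameter_name: str = "custom",
) -> CustomEvidence:
    """Wrap a user weight function, rejecting it if it exceeds 1 anywhere
    on ``probe_grid`` (the samplers need weights usable as probabilities).
    """
    grid = np.asarray(probe_grid, dtype=float)
    if grid.size < 2:
        raise ValueError("probe_grid needs at least 2 points")
    vals = np.array([fn(x) for x in grid], dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError("weight function returned non-finite values on the grid")
    if (vals < 0).any():
        raise ValueError("weight function returned negative values on the grid")
    if (vals > 1 + 1e-12).any():
        worst = grid[int(np.argmax(vals))]
        raise ValueError(
            f"weight function exceeds 1 (at theta={worst!r}); scale it so "
            "its maximum is 1"
        )
    return CustomEvidence(parameter_name=parameter_name, fn=fn)
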