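"""Per-arm bootstrap probability vectors.

One replicate assigns each arm a probability vector over its patients:
Dirichlet(1, ..., 1) for the Bayesian bootstrap, or scaled multinomial
counts (resampling with replacement) for the ordinary bootstrap.  Arms are
always resampled independently.

The RNG contract is one master seed with per-replicate substreams derived
deterministically from the replicate index, so two runs sharing a seed see
the same replicate sequence regardless of how many replicates each consumes
(common random numbers across rejection/importance/no-evidence runs).
"""

from __future__ import annotations

from dataclasses import InitVar, dataclass, field

import numpy as np

from .errors import ValidationError
from .trial_io import TrialData

SCHEMES = ("bayesian", "ordinary")

#: Tolerance on the per-arm simplex constraint.
SIMPLEX_TOL = 1e-12


def replicate_rng(seed: int, index: int) -> np.random.Generator:
    """Deterministic RNG substream for replicate ``index`` under ``seed``."""
    if index < 0:
        raise ValueError("replicate index must be nonnegative")
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(index,))
    )


@dataclass
class BootstrapWeights:
    """Per-arm probability vectors for one bootstrap replicate."""

    scheme: str
    arm_weights: dict[str, np.ndarray] = field(default_factory=dict)
    #: internal escape hatch for vectors that are valid by construction
    check: InitVar[bool] = True

    def __post_init__(self, check: bool = True) -> None:
        if not check:
            return
        if self.scheme not in SCHEMES:
            raise ValidationError(f"unknown bootstrap scheme {self.scheme!r}")
        for arm, w in self.arm_weights.items():
            w = np.asarray(w, dtype=float)
            self.arm_weights[arm] = w
            if w.ndim != 1 or w.size < 1:
                raise ValidationError(f"arm {arm!r}: weight vector must be 1-D")
            if (w < 0).any():
                raise ValidationError(f"arm {arm!r}: negative weight")
            if abs(w.sum() - 1.0) > SIMPLEX_TOL:
                raise ValidationError(
                    f"arm {arm!r}: weights sum to {w.sum()!r}, not 1"
                )
            if self.scheme == "ordinary":
                counts = w * w.size
                if not np.allclose(counts, np.round(counts), atol=1e-9):
                    raise ValidationError(
                        f"arm {arm!r}: ordinary weights must be multiples of 1/n"
                    )

    def check_conforms(self, data: TrialData) -> None:
        """Raise unless arms and vector lengths match ``data``."""
        sizes = data.arm_sizes
        if set(self.arm_weights) != set(sizes):
            raise ValidationError(
                f"weight arms {sorted(self.arm_weights)} do not match "
                f"trial arms {sorted(sizes)}"
            )
        for arm, w in self.arm_weights.items():
            if w.size != sizes[arm]:
                raise ValidationError(
                    f"arm {arm!r}: weight length {w.size} != arm size {sizes[arm]}"
                )


def draw_bayesian_weights(n: int, rng: np.random.Generator) -> np.ndarray:
    """Dirichlet(1, ..., 1) draw of length ``n``.

    Realized as normalized unit-rate exponential variates.
    """
    if n < 1:
        raise ValueError("arm size must be >= 1")
    g = rng.standard_exponential(n)
    return g / g.sum()


def draw_ordinary_weights(n: int, rng: np.random.Generator) -> np.ndarray:
    """Scaled Multinomial(n; 1/n, ..., 1/n) draw: resampling with replacement."""
    if n < 1:
        raise ValueError("arm size must be >= 1")
    counts = rng.multinomial(n, np.full(n, 1.0 / n))
    return counts / n


def draw_replicate(
    data: TrialData, scheme: str, rng: np.random.Generator
) -> BootstrapWeights:
    """Draw one independent probability vector per arm, all under ``scheme``."""
    if scheme not in SCHEMES:
        raise ValidationError(f"unknown bootstrap scheme {scheme!r}")
    draw = draw_bayesian_weights if scheme == "bayesian" else draw_ordinary_weights
    sizes = data.arm_sizes
    return BootstrapWeights(
        scheme=scheme,
        arm_weights={arm: draw(sizes[arm], rng) for arm in data.arms},
        check=False,
    )
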