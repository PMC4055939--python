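import numpy as np
import pandas as pd
import pytest

from cea_synth import (
    ArmSpec,
    SynthTrialSpec,
    TrialData,
    default_trial_spec,
    generate_trial,
    pool_evidence,
)


def make_trial(arm_events: dict[str, list[float]], followup: float = 52.0,
               cost_fn=None, qaly_fn=None) -> TrialData:
    """Deterministic trial built from per-arm event lists."""
    cost_fn = cost_fn or (lambda arm, i, e: 100.0 + 50.0 * e + 10.0 * i)
    qaly_fn = qaly_fn or (lambda arm, i, e: 0.8 - 0.02 * e)
    rows = []
    for arm, events in arm_events.items():
        for i, e in enumerate(events):
            rows.append(
                {
                    "patient_id": f"{arm}{i}",
                    "arm": arm,
                    "cost": float(cost_fn(arm, i, e)),
                    "qaly": float(qaly_fn(arm, i, e)),
                    "events": float(e),
                    "followup": followup,
                }
            )
    return TrialData(pd.DataFrame(rows))


@pytest.fixture
def tiny_trial() -> TrialData:
    """Two arms of four patients: small enough for exhaustive enumeration."""
    return make_trial({"X": [1, 2, 0, 3], "Y": [2, 1, 1, 4]})


@pytest.fixture(scope="session")
def synth_trial() -> TrialData:
    """Default three-arm synthetic trial (150 patients per arm), seed 11."""
    return generate_trial(default_trial_spec(), np.random.default_rng(11))


@pytest.fixture(scope="session")
def case_evidence():
    """Pooled external rate ratio 0.38 (95% CI 0.25-0.57), tau2 0.01783."""
    return pool_evidence(0.38, 0.25, 0.57, 0.01783)


@pytest.fixture
def two_arm_spec() -> SynthTrialSpec:
    return SynthTrialSpec(
        arms=(
            ArmSpec("A", 600, event_rate=3.0, base_cost_mean=2000.0),
            ArmSpec("B", 600, event_rate=1.5, base_cost_mean=3400.0),
        )
    )


def weighted_se_mean(x: np.ndarray, w: np.ndarray) -> float:
    """Monte-Carlo SE of a normalized-weight mean estimate.

    Zero-weight entries are dropped first so NaN values carrying no weight
    (invalid θ draws) cannot poison the estimate.
    """
    x = np.asarray(x, dtype=float)
    w = np.asarray(w, dtype=float)
    keep = w > 0
    x, w = x[keep], w[keep]
    mean = float(w @ x)
    return float(np.sqrt(np.sum((w * (x - mean)) ** 2)))


def icer_se(dc: np.ndarray, de: np.ndarray, w: np.ndarray) -> float:
    """Delta-method SE of the ratio of weighted means E[dC]/E[dE]."""
    mc = float(w @ dc)
    me = float(w @ de)
    var_c = float(np.sum((w * (dc - mc)) ** 2))
    var_e = float(np.sum((w * (de - me)) ** 2))
    cov = float(np.sum(w * w * (dc - mc) * (de - me)))
    r = mc / me
    return abs(r) * np.sqrt(
        var_c / mc**2 + var_e / me**2 - 2 * cov / (mc * me)
    )
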