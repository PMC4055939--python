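"""Run configuration and end-to-end orchestration.

A :class:`RunConfig` bundles everything one analysis needs: the trial file,
the evidence block, sampler scheme, bootstrap type, seed, comparison pair,
λ grid, and output directory.  :func:`run_analysis` executes it and writes
a self-describing artifact bundle:

* ``draws.csv``      — one row per retained draw (arm means, θₑ, weights)
* ``result.json``    — arm summaries, incremental stats, ICER, intervals
* ``ceac.csv``       — (λ, probability) grid
* ``plane.csv``      — per-draw (ΔE, ΔC, weight)
* ``run_log.json``   — config echo plus sampling diagnostics

Runs are deterministic given the seed; the bundle contains no timestamps
so identical configs produce identical bytes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cea_outputs import DEFAULT_LAMBDA_GRID, ceac, export_plane, summarize
from .errors import ConfigError
from .evidence import EvidenceWeight, ExternalEvidence, flat_evidence, pool_evidence
from .synthesis import (
    PosteriorSample,
    bootstrap_sample,
    importance_sample,
    rejection_sample,
)
from .trial_io import read_trial


def evidence_from_dict(block: Mapping | None) -> EvidenceWeight:
    """Build an evidence weight from a config block.

    Supported kinds: ``normal`` (either ``point``/``ci_low``/``ci_high``
    [/``between_study_variance``/``ci_convention``] or direct
    ``mu``/``sigma``) and ``flat``.  Anything else — in particular
    mixed-type "lump-and-smear" priors with point masses — is rejected:
    such weight functions are unbounded and break the samplers'
    boundedness requirement.
    """
    if block is None:
        return flat_evidence()
    kind = str(block.get("kind", "normal")).lower()
    if kind == "flat":
        return flat_evidence()
    if kind != "normal":
        raise ConfigError(
            f"unsupported evidence kind {kind!r}: only 'normal' (log-scale) "
            "and 'flat' are supported; mixed-type (lump-and-smear) priors "
            "have unbounded densities and cannot be used as sampling weights"
        )
    name = str(block.get("parameter", "log_effect"))
    if "point" in block:
        if "ci_low" not in block or "ci_high" not in block:
            raise ConfigError(
                "normal evidence from a point estimate also needs "
                "ci_low and ci_high"
            )
        return pool_evidence(
            float(block["point"]),
            float(block["ci_low"]),
            float(block["ci_high"]),
            float(block.get("between_study_variance", 0.0)),
            parameter_name=name,
            ci_convention=str(block.get("ci_convention", "upper_half")),
        )
    if "mu" in block and "sigma" in block:
        return ExternalEvidence(
            parameter_name=name,
            mu=float(block["mu"]),
            sigma=float(block["sigma"]),
            provenance={"direct": True},
        )
    raise ConfigError(
        "normal evidence needs either point/ci_low/ci_high or mu/sigma"
    )


@dataclass
class RunConfig:
    trial_path: str
    comparison: tuple[str, str]
    scheme: str = "rejection"
    bootstrap: str = "bayesian"
    draws: int = 10_000
    seed: int = 0
    max_attempts: Optional[int] = None
    evidence: Optional[Mapping] = None
    lambda_grid: np.ndarray = field(
        default_factory=lambda: DEFAULT_LAMBDA_GRID.copy()
    )
    credible_level: float = 0.95
    impute_method: str = "weighted_arm_mean"
    zero_event_correction: float = 0.0
    dialect: Optional[Mapping[str, str]] = None
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if self.scheme not in ("none", "rejection", "importance"):
            raise ConfigError(f"unknown scheme {self.scheme!r}")
        if self.bootstrap not in ("bayesian", "ordinary"):
            raise ConfigError(f"unknown bootstrap type {self.bootstrap!r}")
        if self.draws < 1:
            raise ConfigError("draws must be >= 1")
        if not 0 < self.credible_level < 1:
            raise ConfigError("credible_level must be in (0, 1)")
        if len(self.comparison) != 2 or self.comparison[0] == self.comparison[1]:
            raise ConfigError("comparison must be two distinct arm labels")
        self.comparison = (str(self.comparison[0]), str(self.comparison[1]))

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        """Load a YAML config; keyword overrides (CLI flags) win."""
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {
            "trial_path": raw.get("trial"),
            "comparison": tuple(raw.get("comparison", ())),
            "scheme": raw.get("scheme", "rejection"),
            "bootstrap": raw.get("bootstrap", "bayesian"),
            "draws": int(raw.get("draws", 10_000)),
            "seed": int(raw.get("seed", 0)),
            "max_attempts": raw.get("max_attempts"),
            "evidence": raw.get("evidence"),
            "credible_level": float(raw.get("credible_level", 0.95)),
            "impute_method": raw.get("impute_method", "weighted_arm_mean"),
            "zero_event_correction": float(raw.get("zero_event_correction", 0.0)),
            "dialect": raw.get("dialect"),
            "out_dir": raw.get("out", "results"),
        }
        if "lambda_max" in raw or "lambda_step" in raw:
            kwargs["lambda_grid"] = np.arange(
                0.0,
                float(raw.get("lambda_max", 500_000)) + 1e-9,
                float(raw.get("lambda_step", 5_000)),
            )
        kwargs.update({k: v for k, v in overrides.items() if v is not None})
        if not kwargs.get("trial_path"):
            raise ConfigError("no trial file given (config key 'trial')")
        if not kwargs.get("comparison"):
            raise ConfigError("no comparison pair given (config key 'comparison')")
        return cls(**kwargs)

    def echo(self) -> dict:
        """JSON-serializable record of the effective configuration."""
        return {
            "trial": str(self.trial_path),
            "comparison": list(self.comparison),
            "scheme": self.scheme,
            "bootstrap": self.bootstrap,
            "draws": self.draws,
            "seed": self.seed,
            "max_attempts": self.max_attempts,
            "evidence": dict(self.evidence) if self.evidence else None,
            "lambda_grid": {
                "min": float(self.lambda_grid[0]),
                "max": float(self.lambda_grid[-1]),
                "n": int(len(self.lambda_grid)),
            },
            "credible_level": self.credible_level,
            "impute_method": self.impute_method,
            "zero_event_correction": self.zero_event_correction,
            "package_version": __version__,
        }


def run_analysis(config: RunConfig) -> dict:
    """Execute one configured analysis and write the artifact bundle.

    Returns a dict with the in-memory ``sample``, ``result``, ``curve``
    and the paths written.
    """
    data = read_trial(config.trial_path, config.dialect)
    for arm in config.comparison:
        if arm not in data.arms:
            raise ConfigError(
                f"comparison arm {arm!r} not in trial arms {data.arms}"
            )
    common = dict(
        comparison=config.comparison,
        bootstrap=config.bootstrap,
        seed=config.seed,
        impute_method=config.impute_method,
        zero_event_correction=config.zero_event_correction,
    )
    if config.scheme == "none":
        sample = bootstrap_sample(data, config.draws, **common)
    else:
        evidence = evidence_from_dict(config.evidence)
        if config.scheme == "rejection":
            sample = rejection_sample(
                data, evidence, config.draws,
                max_attempts=config.max_attempts, **common,
            )
        else:
            sample = importance_sample(data, evidence, config.draws, **common)

    result = summarize(sample, config.credible_level)
    curve = ceac(sample, config.lambda_grid)

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    draws_path = out / "draws.csv"
    table = sample.table.copy()
    table["weight"] = sample.normalized_weights
    table.to_csv(draws_path, index=False)
    result_path = out / "result.json"
    result_path.write_text(json.dumps(result.to_dict(), indent=2) + "\n")
    ceac_path = out / "ceac.csv"
    curve.to_frame().to_csv(ceac_path, index=False)
    plane_path = out / "plane.csv"
    export_plane(sample, plane_path)
    log_path = out / "run_log.json"
    log_path.write_text(
        json.dumps(
            {
                "config": config.echo(),
                "arms": sample.arms,
                "diagnostics": sample.diagnostics(),
            },
            indent=2,
        )
        + "\n"
    )
    return {
        "sample": sample,
        "result": result,
        "curve": curve,
        "paths": {
            "draws": draws_path,
            "result": result_path,
            "ceac": ceac_path,
            "plane": plane_path,
            "run_log": log_path,
        },
    }


def load_sample(run_dir) -> PosteriorSample:
    """Rebuild a :class:`PosteriorSample` from a written artifact bundle."""
    run_dir = Path(run_dir)
    log = json.loads((run_dir / "run_log.json").read_text())
    diag = log["diagnostics"]
    table = pd.read_csv(run_dir / "draws.csv")
    weights = table.pop("weight").to_numpy()
    weights = weights / weights.sum()
    return PosteriorSample(
        table=table,
        arms=list(log["arms"]),
        comparison=tuple(diag["comparison"]),
        scheme=diag["scheme"],
        bootstrap=diag["bootstrap"],
        normalized_weights=weights,
        attempts=diag["attempts"],
        acceptance_rate=diag["acceptance_rate"],
        effective_sample_size=diag["effective_sample_size"],
        n_invalid_theta=diag["n_invalid_theta"],
        seed=diag["seed"],
    )
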