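"""Patient-level trial data model, CSV I/O, validation, and within-replicate
missing-value imputation.

The central container is :class:`TrialData`, a validated table with one row
per randomized patient carrying arm label, total cost, effectiveness (QALY),
event count, and follow-up time.  Costs, QALYs, and event counts may be
missing; missingness is represented by NaN and is preserved through I/O
("NA" on disk, "NA" or empty cell accepted on read).

Imputation is deliberately *within-replicate*: it consumes the bootstrap
probability vector of the current replicate so that imputation uncertainty
propagates through the resampling loop rather than being resolved once up
front.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterator, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ImputationError, ParseError, ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .resampling import BootstrapWeights

#: Canonical column names; external files may use any names via a dialect map.
CANONICAL_COLUMNS = ("patient_id", "arm", "cost", "qaly", "events", "followup")

#: Fields that may carry missing values and are subject to imputation.
IMPUTABLE_FIELDS = ("cost", "qaly", "events")

#: Follow-up (weeks) assumed when the input file has no followup column.
DEFAULT_FOLLOWUP = 52.0

#: Strings treated as missing on read; "NA" is written on output.
NA_VALUES = ("", "NA")


@dataclass(frozen=True)
class PatientRecord:
    """One patient's observed outcomes.

    ``cost``, ``qaly``, and ``events`` are ``None`` when missing; ``followup``
    must always be observed and positive.
    """

    patient_id: str
    arm: str
    cost: Optional[float]
    qaly: Optional[float]
    events: Optional[int]
    followup: float = DEFAULT_FOLLOWUP


class TrialData:
    """Validated multi-arm patient-level trial data.

    Parameters
    ----------
    table:
        DataFrame with the canonical columns.  ``cost``, ``qaly``, ``events``
        are floats with NaN marking missing values; ``events`` must be
        integer-valued where observed.
    validate:
        Run the full invariant check (default).  Internal callers that have
        just produced a known-valid table may skip it.
    """

    def __init__(self, table: pd.DataFrame, validate: bool = True):
        table = table.reset_index(drop=True)
        missing_cols = [c for c in CANONICAL_COLUMNS if c not in table.columns]
        if missing_cols:
            raise ValidationError(f"missing required columns: {missing_cols}")
        table = table.loc[:, list(CANONICAL_COLUMNS)].copy()
        table["patient_id"] = table["patient_id"].astype(str)
        table["arm"] = table["arm"].astype(str)
        for col in ("cost", "qaly", "events", "followup"):
            table[col] = pd.to_numeric(table[col], errors="raise").astype(float)
        self._table = table
        # arms in order of first appearance; sizes cached (table is immutable)
        self._arms = list(dict.fromkeys(table["arm"]))
        counts = table["arm"].value_counts()
        self._arm_sizes = {a: int(counts[a]) for a in self._arms}
        if validate:
            self._validate()

    # -- structural invariants ------------------------------------------------

    def _validate(self) -> None:
        t = self._table
        if len(t) == 0:
            raise ValidationError("trial has no patient records")
        if (t["arm"].str.len() == 0).any():
            raise ValidationError("empty arm label")
        if len(self._arms) < 2:
            raise ValidationError(
                f"trial must have at least 2 arms, found {len(self._arms)}"
            )
        sizes = t["arm"].value_counts()
        small = sizes[sizes < 2]
        if len(small):
            raise ValidationError(
                f"every arm needs at least 2 patients; too small: {dict(small)}"
            )
        cost = t["cost"]
        if (cost.dropna() < 0).any():
            raise ValidationError("negative cost value")
        ev = t["events"].dropna()
        if (ev < 0).any():
            raise ValidationError("negative event count")
        if not np.allclose(ev, np.round(ev), atol=1e-9):
            raise ValidationError("event counts must be integers")
        fu = t["followup"]
        if fu.isna().any() or (fu <= 0).any():
            raise ValidationError("followup must be present and positive")

    # -- accessors ------------------------------------------------------------

    @property
    def table(self) -> pd.DataFrame:
        """The underlying table (do not mutate)."""
        return self._table

    @property
    def arms(self) -> list[str]:
        """Arm labels in order of first appearance."""
        return list(self._arms)

    @property
    def arm_sizes(self) -> dict[str, int]:
        return dict(self._arm_sizes)

    @property
    def n_patients(self) -> int:
        return len(self._table)

    @property
    def has_missing(self) -> bool:
        return bool(self._table[list(IMPUTABLE_FIELDS)].isna().any().any())

    def arm_table(self, arm: str) -> pd.DataFrame:
        if arm not in self._arms:
            raise ValidationError(f"unknown arm {arm!r}; arms are {self._arms}")
        return self._table[self._table["arm"] == arm]

    @property
    def records(self) -> Iterator[PatientRecord]:
        for row in self._table.itertuples(index=False):
            yield PatientRecord(
                patient_id=row.patient_id,
                arm=row.arm,
                cost=None if math.isnan(row.cost) else float(row.cost),
                qaly=None if math.isnan(row.qaly) else float(row.qaly),
                events=None if math.isnan(row.events) else int(round(row.events)),
                followup=float(row.followup),
            )

    @classmethod
    def from_records(cls, records: Sequence[PatientRecord]) -> "TrialData":
        rows = [
            {
                "patient_id": r.patient_id,
                "arm": r.arm,
                "cost": np.nan if r.cost is None else r.cost,
                "qaly": np.nan if r.qaly is None else r.qaly,
                "events": np.nan if r.events is None else float(r.events),
                "followup": r.followup,
            }
            for r in records
        ]
        return cls(pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS)))

    def copy(self) -> "TrialData":
        return TrialData(self._table.copy(), validate=False)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TrialData):
            return NotImplemented
        try:
            pd.testing.assert_frame_equal(self._table, other._table)
        except AssertionError:
            return False
        return True

    def __repr__(self) -> str:  # pragma: no cover
        return f"TrialData(n={self.n_patients}, arms={self.arm_sizes})"


def read_trial(path, dialect: Mapping[str, str] | None = None) -> TrialData:
    """Read a trial CSV into a validated :class:`TrialData`.

    Parameters
    ----------
    path:
        CSV file with a header row (UTF-8).  Missing cells may be empty or
        the literal string ``NA``.
    dialect:
        Optional mapping from canonical column names to the names used in
        the file, e.g. ``{"qaly": "QALY_total"}``.  Unmapped canonical names
        are looked up verbatim.  A missing ``followup`` column defaults to
        a constant 52 weeks.

    Raises
    ------
    ParseError
        Malformed numeric cells (the error names the offending row).
    ValidationError
        Structural invariant violations (arm sizes, negative costs, ...).
    """
    dialect = dict(dialect or {})
    raw = pd.read_csv(
        path,
        dtype=str,
        na_values=list(NA_VALUES),
        keep_default_na=False,
        skip_blank_lines=True,
        encoding="utf-8",
    )
    colmap = {canon: dialect.get(canon, canon) for canon in CANONICAL_COLUMNS}
    required = [c for c in CANONICAL_COLUMNS if c != "followup"]
    absent = [colmap[c] for c in required if colmap[c] not in raw.columns]
    if absent:
        raise ParseError(f"{path}: required columns not found: {absent}")

    out = pd.DataFrame()
    out["patient_id"] = raw[colmap["patient_id"]].fillna("")
    out["arm"] = raw[colmap["arm"]].fillna("")
    for canon in ("cost", "qaly", "events", "followup"):
        src = colmap[canon]
        if src not in raw.columns:
            if canon == "followup":
                out["followup"] = DEFAULT_FOLLOWUP
                continue
            raise ParseError(f"{path}: required column {src!r} not found")
        parsed = pd.to_numeric(raw[src], errors="coerce")
        bad = parsed.isna() & raw[src].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise ParseError(
                f"{path}: malformed value {raw[src][row]!r} in column {src!r}, "
                f"data row {row + 1}"
            )
        out[canon] = parsed.astype(float)
    if out["arm"].eq("").any():
        row = int(out["arm"].eq("").idxmax())
        raise ValidationError(f"{path}: missing arm label at data row {row + 1}")
    return TrialData(out)


def write_trial(data: TrialData, path) -> None:
    """Write ``data`` as CSV; round-trips through :func:`read_trial` exactly.

    Missing values are written as ``NA``.
    """
    data._validate()
    out = data.table.copy()
    # events are integer-valued; avoid "3.0" on disk
    out["events"] = out["events"].map(
        lambda v: "NA" if pd.isna(v) else str(int(round(v)))
    )
    out.to_csv(path, index=False, na_rep="NA")


def impute_within_replicate(
    data: TrialData,
    weights: "BootstrapWeights",
    method: str = "weighted_arm_mean",
    rng: np.random.Generator | None = None,
) -> TrialData:
    """Return a completed copy of ``data`` with no missing values.

    ``weighted_arm_mean`` replaces each missing value with the
    bootstrap-weighted mean of the observed same-arm values for that field
    (event counts rounded to the nearest integer).  ``hot_deck`` draws a
    donor from the observed same-arm values with probability proportional
    to the donor's bootstrap weight; it requires ``rng``.

    Observed values are never altered.  If every observed donor in an arm
    happens to carry zero bootstrap weight (possible under the ordinary
    bootstrap), the fallback is a uniform distribution over the observed
    donors.

    Raises
    ------
    ImputationError
        An arm has a missing value in a field with no observed values.
    """
    if method not in ("weighted_arm_mean", "hot_deck"):
        raise ValueError(f"unknown imputation method {method!r}")
    if method == "hot_deck" and rng is None:
        raise ValueError("hot_deck imputation requires an rng")
    weights.check_conforms(data)
    if not data.has_missing:
        return data.copy()

    table = data.table.copy()
    for arm in data.arms:
        idx = np.flatnonzero((table["arm"] == arm).to_numpy())
        w = weights.arm_weights[arm]
        for field in IMPUTABLE_FIELDS:
            col = table[field].to_numpy()
            vals = col[idx]
            miss = np.isnan(vals)
            if not miss.any():
                continue
            obs = vals[~miss]
            if obs.size == 0:
                raise ImputationError(
                    f"arm {arm!r} has no observed {field!r} values to impute from"
                )
            w_obs = w[~miss]
            total = w_obs.sum()
            if method == "weighted_arm_mean":
                if total > 0:
                    fill = float(np.dot(w_obs, obs) / total)
                else:
                    fill = float(obs.mean())
                if field == "events":
                    fill = float(np.rint(fill))
                col[idx[miss]] = fill
            else:  # hot_deck
                p = w_obs / total if total > 0 else np.full(obs.size, 1.0 / obs.size)
                donors = rng.choice(obs, size=int(miss.sum()), replace=True, p=p)
                col[idx[miss]] = donors
            table[field] = col
    return TrialData(table, validate=False)
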