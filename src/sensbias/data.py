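"""Triples I/O, scale harmonization, exclusion filters and subset selection.

The canonical long format is one row per (participant, step): previous
self-evaluation ``a_t``, feedback ``f_t``, next self-evaluation ``a_next``,
with intensity ``delta_t = |f_t - a_t|`` and the feedback sign, joined to
per-participant covariates (trust 0-10, gender, self-esteem 1-4, scale
condition, anchor, interview time).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import TRIPLE_COLUMNS, PARTICIPANT_COLUMNS

__all__ = [
    "SampleFrame",
    "SelectionCriteria",
    "ValidationError",
    "rank_to_score",
    "harmonize_scale",
    "build_frame",
    "filter_excluded",
    "subset",
    "read_triples",
    "write_triples",
    "read_participants",
    "write_participants",
    "apply_column_mapping",
    "validate_triples",
]

logger = logging.getLogger(__name__)

COVARIATE_COLUMNS = [c for c in PARTICIPANT_COLUMNS if c != "participant_id"]


class ValidationError(ValueError):
    """Raised with an itemized report of rows violating the schema/invariants."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__(
            f"{len(violations)} validation problem(s):\n" + "\n".join(violations[:50])
        )


@dataclass(frozen=True)
class SelectionCriteria:
    """Filters defining an analysis subset.

    ``trust_range`` and ``timestep_range`` are inclusive on both ends.
    ``self_esteem`` splits at 3: "low" keeps <= 3, "high" keeps > 3.
    """

    trust_range: tuple[int, int] = (0, 10)
    timestep_range: tuple[int, int] = (1, 4)
    scale: Optional[str] = None
    gender: Optional[str] = None
    self_esteem: Optional[str] = None
    min_interview_time: Optional[float] = None
    require_complete_series: bool = False

    def __post_init__(self):
        lo, hi = self.trust_range
        if not (0 <= lo <= hi <= 10):
            raise ValueError(f"trust_range must lie in [0, 10]: {self.trust_range}")
        t0, t1 = self.timestep_range
        if not (1 <= t0 <= t1 <= 4):
            raise ValueError(f"timestep_range must lie in [1, 4]: {self.timestep_range}")
        if self.scale not in (None, "rank", "score"):
            raise ValueError(f"scale filter must be rank/score: {self.scale}")
        if self.self_esteem not in (None, "low", "high"):
            raise ValueError(f"self_esteem filter must be low/high: {self.self_esteem}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SampleFrame:
    """Triples joined to covariates, plus the selection that produced them."""

    data: pd.DataFrame
    selection: dict = field(default_factory=dict)

    @property
    def n_triples(self) -> int:
        return len(self.data)

    @property
    def n_participants(self) -> int:
        return int(self.data["participant_id"].nunique())

    @property
    def empty(self) -> bool:
        return self.data.empty


def rank_to_score(value):
    """Map a rank (1 best) to the increasing score scale: ``100 - rank``.

    Values below rank 1 are not expected; a rank of 101 (worst possible)
    maps to -1 and is clamped to 0 by `harmonize_scale`.
    """
    return 100 - value


def harmonize_scale(
    triples: pd.DataFrame, participants: pd.DataFrame
) -> pd.DataFrame:
    """Express all rank-condition rows on the score scale.

    Applies ``100 - v`` to a_t, f_t and a_next of rows whose participant is
    in the rank condition, clamping the (edge-case) result -1 to 0 with a
    log entry, and recomputes the feedback sign; score rows pass through
    unchanged.  ``delta_t`` is invariant under the transform.
    """
    out = triples.copy()
    scale = participants.set_index("participant_id")["scale"]
    is_rank = out["participant_id"].map(scale).eq("rank").to_numpy()
    for col in ("a_t", "f_t", "a_next"):
        vals = out.loc[is_rank, col]
        mapped = rank_to_score(vals)
        n_clamped = int((mapped < 0).sum())
        if n_clamped:
            logger.warning("harmonize_scale: clamped %d %s value(s) below 0", n_clamped, col)
        out.loc[is_rank, col] = mapped.clip(lower=0)
    out["sign"] = np.sign(out["f_t"] - out["a_t"]).astype(int)
    return out


def build_frame(
    triples: pd.DataFrame,
    participants: pd.DataFrame,
    selection: Optional[dict] = None,
) -> SampleFrame:
    """Join triples to covariates into a SampleFrame (inner join on participant_id)."""
    missing = set(COVARIATE_COLUMNS) - set(participants.columns)
    if missing:
        raise ValidationError([f"participants table missing column(s): {sorted(missing)}"])
    data = triples.merge(
        participants[["participant_id"] + COVARIATE_COLUMNS], on="participant_id", how="inner"
    )
    return SampleFrame(data=data, selection=dict(selection or {}))


def filter_excluded(
    frame: SampleFrame, delta: float = 13.0, epsilon: float = 1.0
) -> SampleFrame:
    """Drop every triple of any participant with an off-protocol feedback.

    A participant is excluded when any of their intensities falls outside
    ``{delta - epsilon, delta + epsilon}`` (a truncated feedback), when a
    ``truncated`` flag is set on any row, or when a pre-computed ``excluded``
    covariate marks them.
    """
    data = frame.data
    ok_intensity = np.isclose(data["delta_t"], delta - epsilon) | np.isclose(
        data["delta_t"], delta + epsilon
    )
    bad = set(data.loc[~ok_intensity, "participant_id"])
    if "truncated" in data.columns:
        bad |= set(data.loc[data["truncated"].astype(bool), "participant_id"])
    if "excluded" in data.columns:
        bad |= set(data.loc[data["excluded"].astype(bool), "participant_id"])
    kept = data[~data["participant_id"].isin(bad)].reset_index(drop=True)
    logger.info("filter_excluded: removed %d participant(s)", len(bad))
    selection = dict(frame.selection)
    selection["excluded_participants"] = len(bad)
    return SampleFrame(data=kept, selection=selection)


def subset(frame: SampleFrame, criteria: SelectionCriteria) -> SampleFrame:
    """Rows satisfying all criteria; the criteria are recorded as metadata."""
    data = frame.data
    lo, hi = criteria.trust_range
    mask = (data["trust"] >= lo) & (data["trust"] <= hi)
    t0, t1 = criteria.timestep_range
    mask &= (data["t"] >= t0) & (data["t"] <= t1)
    if criteria.scale is not None:
        mask &= data["scale"] == criteria.scale
    if criteria.gender is not None:
        mask &= data["gender"] == criteria.gender
    if criteria.self_esteem == "low":
        mask &= data["self_esteem"] <= 3
    elif criteria.self_esteem == "high":
        mask &= data["self_esteem"] > 3
    if criteria.min_interview_time is not None:
        mask &= data["interview_time"] >= criteria.min_interview_time
    out = data[mask]
    if criteria.require_complete_series:
        needed = set(range(t0, t1 + 1))
        steps = out.groupby("participant_id")["t"].agg(lambda s: set(s))
        complete = steps[steps.apply(lambda s: needed <= s)].index
        out = out[out["participant_id"].isin(complete)]
    selection = dict(frame.selection)
    selection.update(criteria.to_dict())
    selection["empty"] = bool(out.empty)
    if out.empty:
        logger.warning("subset produced an empty frame: %s", criteria)
    return SampleFrame(data=out.reset_index(drop=True), selection=selection)


# ---------------------------------------------------------------------------
# I/O


def validate_triples(triples: pd.DataFrame) -> list[str]:
    """Return an itemized list of schema/invariant violations (empty if clean)."""
    violations: list[str] = []
    missing = set(TRIPLE_COLUMNS) - {"truncated"} - set(triples.columns)
    if missing:
        return [f"missing column(s): {sorted(missing)}"]
    truncated = (
        triples["truncated"].astype(bool)
        if "truncated" in triples.columns
        else pd.Series(False, index=triples.index)
    )
    for idx, row in triples.iterrows():
        lo, hi = min(row["a_t"], row["f_t"]), max(row["a_t"], row["f_t"])
        if not lo <= row["a_next"] <= hi:
            violations.append(
                f"row {idx}: a_next={row['a_next']} outside [{lo}, {hi}]"
            )
        if not truncated.loc[idx] and row["delta_t"] <= 0:
            violations.append(f"row {idx}: nonpositive intensity {row['delta_t']}")
        if abs(row["delta_t"] - abs(row["f_t"] - row["a_t"])) > 1e-9:
            violations.append(
                f"row {idx}: delta_t={row['delta_t']} != |f_t - a_t|"
            )
        if row["t"] not in (1, 2, 3, 4):
            violations.append(f"row {idx}: step t={row['t']} outside 1..4")
    return violations


def read_triples(path: str | Path, validate: bool = True) -> pd.DataFrame:
    """Read a triples CSV, checking schema and row invariants."""
    df = pd.read_csv(path)
    if validate:
        violations = validate_triples(df)
        if violations:
            raise ValidationError(violations)
    return df


def write_triples(triples: pd.DataFrame, path: str | Path) -> None:
    triples.to_csv(path, index=False)


def read_participants(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(COVARIATE_COLUMNS) - {"excluded"} - set(df.columns)
    if missing:
        raise ValidationError([f"participants file missing column(s): {sorted(missing)}"])
    return df


def write_participants(participants: pd.DataFrame, path: str | Path) -> None:
    participants.to_csv(path, index=False)


def apply_column_mapping(df: pd.DataFrame, mapping: Mapping[str, str]) -> pd.DataFrame:
    """Rename externally-named columns to the canonical schema.

    ``mapping`` maps canonical name -> source column name (typically loaded
    from a user-editable YAML file when adapting a deposited data set).
    """
    inverse = {src: canon for canon, src in mapping.items()}
    missing = set(mapping.values()) - set(df.columns)
    if missing:
        raise ValidationError([f"mapped source column(s) not found: {sorted(missing)}"])
    return df.rename(columns=inverse)
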