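"""Bootstrap uncertainty and effect sizes.

Two resampling schemes: plain row (triple) resampling for measures defined
on arbitrary row subsets, and participant-level resampling that keeps the
four triples of each drawn participant together so series-level measures
(total bias, hence the measured decomposition) stay computable on every
bootstrap sample.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Callable, Literal, Mapping, Union

import numpy as np
import pandas as pd

from .data import SampleFrame
from .estimators import IncompleteSeriesError

__all__ = [
    "BootstrapSummary",
    "EffectSize",
    "bootstrap_triples",
    "bootstrap_participants",
    "effect_size",
]

Measure = Callable[[pd.DataFrame], float]

#: Effect-size thresholds: lower bound of each label band.
EFFECT_SIZE_BANDS = (
    (1.3, "very large"),
    (0.8, "large"),
    (0.5, "medium"),
    (0.2, "small"),
    (0.0, "negligible"),
)


@dataclass(frozen=True)
class BootstrapSummary:
    measure: str
    mean: float
    sd: float
    n_samples: int
    seed: int
    scheme: Literal["triple", "participant"]

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class EffectSize:
    s: float
    label: str


def _df(frame: Union[SampleFrame, pd.DataFrame]) -> pd.DataFrame:
    return frame.data if isinstance(frame, SampleFrame) else frame


def _summarize(values, name, n_samples, seed, scheme) -> BootstrapSummary:
    arr = np.asarray(values, dtype=float)
    return BootstrapSummary(
        measure=name,
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
        n_samples=n_samples,
        seed=seed,
        scheme=scheme,
    )


def bootstrap_triples(
    frame: Union[SampleFrame, pd.DataFrame],
    measure: Measure,
    n_samples: int = 200,
    seed: int = 0,
    name: str = "measure",
) -> BootstrapSummary:
    """Row-resampling bootstrap of a measure computable on arbitrary subsets.

    Measures needing complete per-participant series (the total bias and
    anything built on it) are refused: use `bootstrap_participants`.
    """
    data = _df(frame).reset_index(drop=True)
    if data.empty:
        raise ValueError("cannot bootstrap an empty frame")
    rng = np.random.default_rng(seed)
    n = len(data)
    values = []
    for _ in range(n_samples):
        sample = data.iloc[rng.integers(0, n, size=n)]
        try:
            values.append(measure(sample))
        except IncompleteSeriesError as err:
            raise ValueError(
                "measure requires complete series; use bootstrap_participants"
            ) from err
    return _summarize(values, name, n_samples, seed, "triple")


def bootstrap_participants(
    frame: Union[SampleFrame, pd.DataFrame],
    measures: Mapping[str, Measure],
    n_samples: int = 200,
    seed: int = 0,
) -> dict[str, BootstrapSummary]:
    """Participant-level bootstrap: whole 4-triple series drawn with replacement.

    Every measure in ``measures`` is evaluated on each bootstrap sample, so
    total, enhancement and both decreasing-sensitivity biases share the same
    resamples.  Drawn participants are relabeled so duplicates count as
    distinct participants in per-participant means.
    """
    data = _df(frame).reset_index(drop=True)
    if data.empty:
        raise ValueError("cannot bootstrap an empty frame")
    counts = data.groupby("participant_id")["t"].agg(["count", "nunique"])
    incomplete = counts[(counts["count"] != 4) | (counts["nunique"] != 4)]
    if not incomplete.empty:
        raise IncompleteSeriesError(
            f"{len(incomplete)} participant(s) lack complete 4-step series"
        )
    rng = np.random.default_rng(seed)
    pids = data["participant_id"].unique()
    rows_by_pid = {pid: idx.to_numpy() for pid, idx in data.groupby("participant_id").groups.items()}
    values: dict[str, list[float]] = {name: [] for name in measures}
    for _ in range(n_samples):
        drawn = rng.choice(pids, size=len(pids), replace=True)
        row_idx = np.concatenate([rows_by_pid[pid] for pid in drawn])
        sample = data.iloc[row_idx].copy()
        sample["participant_id"] = np.repeat(np.arange(len(drawn)), 4)
        for name, fn in measures.items():
            values[name].append(fn(sample))
    return {
        name: _summarize(vals, name, n_samples, seed, "participant")
        for name, vals in values.items()
    }


def effect_size(summary1: BootstrapSummary, summary2: BootstrapSummary) -> EffectSize:
    """``|m1 - m2| / sd1`` with a verbal label.

    Deliberately asymmetric: the denominator is the bootstrap sd of the
    *first* summary, so swapping arguments changes the value.
    """
    if summary1.measure != summary2.measure:
        raise ValueError(
            f"summaries measure different things: {summary1.measure} vs {summary2.measure}"
        )
    if summary1.sd == 0:
        raise ZeroDivisionError("effect size undefined: first summary has sd 0")
    s = abs(summary1.mean - summary2.mean) / summary1.sd
    label = next(lbl for bound, lbl in EFFECT_SIZE_BANDS if s >= bound)
    return EffectSize(s=s, label=label)
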