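"""Sensitivity regressions and the bias decomposition.

The outcome of every regression is the normalized absolute self-evaluation
change ``|a_next - a_t| / delta_t`` and the predictor is ``a_t / 100``, so
the fitted line is directly a sensitivity curve estimate (intercept ``b``,
slope ``c`` per unit of normalized self-evaluation).

Bias measures are all expressed as a percent of the feedback intensity:

* total bias ``B``: mean over participants of ``(a_5 - a_1)`` divided by
  half the summed intensities of their four triples, x100;
* enhancement bias ``E``: mean over triples of the fitted gap between the
  positive- and negative-feedback sensitivities, x100;
* theoretical decreasing-sensitivity bias ``S'``: mean over triples of
  ``-c_m (c_m a_t/100 + b_m) delta_t`` with the averaged fitted curve
  (already a percent, the intensity factor standing in for the x100);
* measured decreasing-sensitivity bias ``S = B - E``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Optional, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .data import SampleFrame

__all__ = [
    "LinearFit",
    "BiasEstimates",
    "FitError",
    "fit_sensitivity",
    "fit_sensitivity_mixed",
    "total_bias",
    "enhancement_bias",
    "sensitivity_bias_theoretical",
    "decompose",
]

Scope = Literal["all", "positive", "negative"]


class FitError(ValueError):
    """A regression could not be computed on the given frame."""


class IncompleteSeriesError(ValueError):
    """A participant lacks one of the four steps needed for the total bias."""


@dataclass(frozen=True)
class LinearFit:
    """Estimated sensitivity line: slope ``c``, intercept ``b``."""

    slope: float
    intercept: float
    p_slope: Optional[float]
    n: int
    feedback_scope: Scope = "all"
    method: Literal["ols", "mixed"] = "ols"

    def predict(self, a):
        """Fitted sensitivity at self-evaluation ``a`` (0-100 scale)."""
        return self.intercept + self.slope * np.asarray(a, dtype=float) / 100.0


@dataclass(frozen=True)
class BiasEstimates:
    """The four bias measures on a common percent-of-intensity unit."""

    B: float
    E: float
    S_measured: float
    S_theoretical: float
    units_note: str = "percent of delta"


def _df(frame: Union[SampleFrame, pd.DataFrame]) -> pd.DataFrame:
    return frame.data if isinstance(frame, SampleFrame) else frame


def _design(data: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    y = (np.abs(data["a_next"] - data["a_t"]) / data["delta_t"]).to_numpy(float)
    x = (data["a_t"] / 100.0).to_numpy(float)
    return y, x


def _scoped(data: pd.DataFrame, scope: Scope) -> pd.DataFrame:
    if scope == "positive":
        return data[data["sign"] > 0]
    if scope == "negative":
        return data[data["sign"] < 0]
    return data


def fit_sensitivity(
    frame: Union[SampleFrame, pd.DataFrame], scope: Scope = "all"
) -> LinearFit:
    """OLS of normalized absolute change on normalized self-evaluation.

    ``scope`` restricts to positive- or negative-intensity triples.  The
    slope p-value is two-sided.
    """
    data = _scoped(_df(frame), scope)
    if len(data) < 3:
        raise FitError(f"need >= 3 triples, got {len(data)} (scope={scope})")
    if (data["delta_t"] <= 0).any():
        raise FitError("nonpositive intensities present; filter the frame first")
    y, x = _design(data)
    if np.ptp(x) == 0:
        raise FitError("zero variance in the predictor")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return LinearFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        p_slope=float(res.pvalues[1]),
        n=len(data),
        feedback_scope=scope,
        method="ols",
    )


def fit_sensitivity_mixed(frame: Union[SampleFrame, pd.DataFrame]) -> LinearFit:
    """Mixed-effects variant: participant-level random intercept, ML fit.

    Applicable only when the frame spans at least three time steps (the
    repeated-measures structure is otherwise too thin); no slope p-value is
    reported.
    """
    data = _df(frame)
    if data["t"].nunique() < 3:
        raise FitError(
            f"mixed model needs >= 3 time steps, frame spans {sorted(data['t'].unique())}"
        )
    if len(data) < 3:
        raise FitError(f"need >= 3 triples, got {len(data)}")
    y, x = _design(data)
    if np.ptp(x) == 0:
        raise FitError("zero variance in the predictor")
    groups = data["participant_id"].to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # boundary variance warnings on clean data
        model = sm.MixedLM(y, sm.add_constant(x), groups=groups)
        res = model.fit(reml=False)
    return LinearFit(
        slope=float(res.fe_params[1]),
        intercept=float(res.fe_params[0]),
        p_slope=None,
        n=len(data),
        feedback_scope="all",
        method="mixed",
    )


def _series_table(data: pd.DataFrame) -> pd.DataFrame:
    """Per-participant (a_1, a_5, sum of intensities); errors on incomplete series."""
    by_pid = data.groupby("participant_id")
    counts = by_pid["t"].agg(["count", "nunique", "min", "max"])
    bad = counts[
        (counts["count"] != 4) | (counts["nunique"] != 4)
        | (counts["min"] != 1) | (counts["max"] != 4)
    ].index.tolist()
    if bad:
        raise IncompleteSeriesError(
            f"{len(bad)} participant(s) lack a complete 4-step series: {bad[:10]}"
        )
    first = data[data["t"] == 1].set_index("participant_id")["a_t"]
    last = data[data["t"] == 4].set_index("participant_id")["a_next"]
    dsum = by_pid["delta_t"].sum()
    return pd.DataFrame({"a1": first, "a5": last, "delta_sum": dsum})


def total_bias(frame: Union[SampleFrame, pd.DataFrame]) -> float:
    """Mean participant-level change per unit intensity, as a percent.

    Each participant contributes ``(a_5 - a_1) / (0.5 * sum_t delta_t)``;
    the mean over participants is multiplied by 100.
    """
    tab = _series_table(_df(frame))
    per = (tab["a5"] - tab["a1"]) / (0.5 * tab["delta_sum"])
    return float(100.0 * per.mean())


def enhancement_bias(
    frame: Union[SampleFrame, pd.DataFrame], fit_p: LinearFit, fit_n: LinearFit
) -> float:
    """Mean fitted positive-minus-negative sensitivity over triples, x100."""
    data = _df(frame)
    gap = (fit_p.slope - fit_n.slope) * data["a_t"] / 100.0 + (
        fit_p.intercept - fit_n.intercept
    )
    return float(100.0 * gap.mean())


def sensitivity_bias_theoretical(
    frame: Union[SampleFrame, pd.DataFrame], fit_p: LinearFit, fit_n: LinearFit
) -> float:
    """Mean of ``-c_m (c_m a_t/100 + b_m) delta_t`` over triples (a percent).

    ``c_m``/``b_m`` average the positive and negative fits.  Multiplying by
    the intensity ``delta_t`` (instead of the second-order ``delta_t**2 /
    100``-style raw change) expresses the measure directly as a percent of
    intensity, commensurable with the other biases.
    """
    data = _df(frame)
    cm = (fit_p.slope + fit_n.slope) / 2.0
    bm = (fit_p.intercept + fit_n.intercept) / 2.0
    per_triple = -cm * (cm * data["a_t"] / 100.0 + bm) * data["delta_t"]
    return float(per_triple.mean())


def decompose(
    frame: Union[SampleFrame, pd.DataFrame],
    fit_p: Optional[LinearFit] = None,
    fit_n: Optional[LinearFit] = None,
) -> BiasEstimates:
    """Full decomposition B = E + S on a complete-series frame.

    Fits for the two feedback scopes are computed from the frame when not
    supplied.  ``S_measured`` is exactly ``B - E``.
    """
    if fit_p is None:
        fit_p = fit_sensitivity(frame, scope="positive")
    if fit_n is None:
        fit_n = fit_sensitivity(frame, scope="negative")
    B = total_bias(frame)
    E = enhancement_bias(frame, fit_p, fit_n)
    S_prime = sensitivity_bias_theoretical(frame, fit_p, fit_n)
    return BiasEstimates(B=B, E=E, S_measured=B - E, S_theoretical=S_prime)


def decomposition_measures() -> dict:
    """Bootstrap-ready measure callables for B, E, S and S'.

    The four callables share one decomposition per sample (memoized on the
    sample object), so passing them together to a bootstrap evaluates the
    fits once instead of four times.
    """
    cache: dict = {}

    def _est(df):
        key = (id(df), len(df))
        if cache.get("key") != key:
            cache["key"] = key
            cache["est"] = decompose(df)
        return cache["est"]

    return {
        "B": lambda df: _est(df).B,
        "E": lambda df: _est(df).E,
        "S_measured": lambda df: _est(df).S_measured,
        "S_theoretical": lambda df: _est(df).S_theoretical,
    }
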