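"""Agent update model: sensitivity curves and closed-form bias predictions.

The core object is a *sensitivity curve* ``h(a)``: the fraction of the gap
between a feedback and the current self-evaluation that the agent adopts,
as a function of the current self-evaluation ``a`` on a 0-100 scale.  A
single update is ``a' = a + h(a) * (f - a)``.  When ``h`` is decreasing in
``a``, balanced pairs of opposite feedbacks drift the self-evaluation
upward; the functions below give that drift exactly (by sequential
evaluation) and to first order in the feedback intensity.

Slope convention
----------------
For the linear family ``h(a) = b + c * a / 100``: the slope ``c`` is per
unit of *normalized* self-evaluation ``a/100``; the derivative per raw
self-evaluation unit is therefore ``c / 100``.  Every closed-form formula
in this module uses the raw-unit derivative internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np

__all__ = [
    "SensitivityCurve",
    "BiasPrediction",
    "NoiseSpec",
    "evaluate_sensitivity",
    "apply_feedback",
    "pair_bias_exact",
    "pair_bias_first_order",
    "enhancement_at",
    "avg_pair_bias",
    "random_bias_theory",
    "simulate_random_feedback_series",
]

PairOrder = Literal["+-", "-+"]


class InvalidCurveError(ValueError):
    """Raised when a sensitivity evaluates outside its valid range along a trajectory."""


@dataclass(frozen=True)
class SensitivityCurve:
    """A sensitivity-to-feedback function on the 0-100 self-evaluation scale.

    Families:

    * ``"linear"`` (default): ``h(a) = b + c * a / 100``.  ``c = 0`` gives a
      constant curve.
    * ``"logistic"``: ``h(a) = lo + (hi - lo) / (1 + exp((a - mid) / width))``,
      a smooth decreasing curve with nonzero curvature; ``b`` is reused as
      ``hi``, ``c`` as ``lo`` and the extra ``mid``/``width`` fields apply.

    ``clip=True`` clamps every evaluated value to [0, 1] (the regime used in
    simulation, where responses are constrained); analytic bias formulas
    should use unclipped curves.
    """

    b: float
    c: float = 0.0
    clip: bool = False
    family: Literal["linear", "logistic"] = "linear"
    mid: float = 50.0
    width: float = 15.0

    def __call__(self, a):
        return self.value(a)

    def value(self, a):
        """Evaluate h(a) for scalar or array ``a`` in [0, 100]."""
        arr = np.asarray(a, dtype=float)
        if np.any(arr < 0.0) or np.any(arr > 100.0):
            raise ValueError(f"self-evaluation outside [0, 100]: {a!r}")
        if self.family == "linear":
            out = self.b + self.c * arr / 100.0
        else:
            lo, hi = self.c, self.b
            out = lo + (hi - lo) / (1.0 + np.exp((arr - self.mid) / self.width))
        if self.clip:
            out = np.clip(out, 0.0, 1.0)
        return out.item() if np.isscalar(a) or arr.ndim == 0 else out

    def derivative(self, a) -> float:
        """dh/da per *raw* self-evaluation unit (c/100 for the linear family)."""
        arr = np.asarray(a, dtype=float)
        if self.family == "linear":
            out = np.full_like(arr, self.c / 100.0)
        else:
            lo, hi = self.c, self.b
            z = np.exp((arr - self.mid) / self.width)
            out = -(hi - lo) * z / (self.width * (1.0 + z) ** 2)
        return out.item() if np.isscalar(a) or arr.ndim == 0 else out

    def average_with(self, other: "SensitivityCurve") -> "SensitivityCurve":
        """Pointwise average of two linear curves: slope and intercept averaged."""
        if self.family != "linear" or other.family != "linear":
            raise ValueError("average_with is defined for linear curves only")
        return SensitivityCurve(
            b=(self.b + other.b) / 2.0, c=(self.c + other.c) / 2.0, clip=self.clip
        )

    # -- plain key-value serialization -------------------------------------
    def to_dict(self) -> dict:
        d = {"family": self.family, "b": self.b, "c": self.c, "clip": self.clip}
        if self.family == "logistic":
            d.update(mid=self.mid, width=self.width)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SensitivityCurve":
        known = {k: d[k] for k in ("family", "b", "c", "clip", "mid", "width") if k in d}
        return cls(**known)


@dataclass(frozen=True)
class BiasPrediction:
    """A predicted self-evaluation change, on three equivalent scales."""

    raw_change: float
    delta: float

    @property
    def as_fraction_of_delta(self) -> float:
        return self.raw_change / self.delta

    @property
    def as_percent_of_delta(self) -> float:
        return 100.0 * self.as_fraction_of_delta


@dataclass(frozen=True)
class NoiseSpec:
    """Mean-zero random feedback perturbation, characterized by its variance."""

    var_theta: float

    def __post_init__(self):
        if self.var_theta < 0:
            raise ValueError("variance must be nonnegative")

    @property
    def sd(self) -> float:
        return math.sqrt(self.var_theta)


def evaluate_sensitivity(curve: SensitivityCurve, a: float) -> float:
    """Sensitivity fraction at self-evaluation ``a`` (domain-checked)."""
    return curve.value(a)


def apply_feedback(a_t: float, f_t: float, h_value: float) -> float:
    """One update ``a + h * (f - a)``; the result lies between ``a_t`` and ``f_t``."""
    if not 0.0 <= h_value <= 1.0:
        raise ValueError(f"sensitivity value outside [0, 1]: {h_value}")
    return a_t + h_value * (f_t - a_t)


def _checked_h(curve: SensitivityCurve, a: float) -> float:
    h = curve.value(a)
    if h < 0.0:
        raise InvalidCurveError(f"sensitivity negative at a={a}: h={h}")
    return h


def pair_bias_exact(
    a1: float, curve: SensitivityCurve, delta: float, order: PairOrder = "+-"
) -> BiasPrediction:
    """Net change after a +delta/-delta feedback pair, by sequential evaluation.

    ``order="+-"`` applies the positive feedback first; ``"-+"`` the negative
    first.  For a strictly decreasing positive curve the change is positive
    for both orders, and for linear curves the two orders agree exactly.
    """
    s1 = 1.0 if order == "+-" else -1.0
    h1 = _checked_h(curve, a1)
    a2 = a1 + h1 * s1 * delta
    h2 = _checked_h(curve, a2)
    a3 = a2 + h2 * (-s1) * delta
    return BiasPrediction(raw_change=a3 - a1, delta=delta)


def pair_bias_first_order(
    a1: float, curve: SensitivityCurve, delta: float
) -> BiasPrediction:
    """First-order prediction ``-h'(a1) * h(a1) * delta**2`` (raw-unit derivative).

    Exact for linear curves; off by O(delta^3) otherwise.
    """
    raw = -curve.derivative(a1) * curve.value(a1) * delta**2
    return BiasPrediction(raw_change=raw, delta=delta)


def enhancement_at(
    a: float,
    curve_p: SensitivityCurve,
    curve_n: SensitivityCurve,
    delta: float,
) -> BiasPrediction:
    """Asymmetric-reaction change ``(h_p(a) - h_n(a)) * delta`` at one point."""
    raw = (curve_p.value(a) - curve_n.value(a)) * delta
    return BiasPrediction(raw_change=raw, delta=delta)


def avg_pair_bias(
    a: float,
    curve_p: SensitivityCurve,
    curve_n: SensitivityCurve,
    delta: float,
) -> BiasPrediction:
    """Order-averaged decreasing-sensitivity drift ``-h_m'(a) h_m(a) delta**2``.

    ``h_m`` is the pointwise average of the positive- and negative-feedback
    curves; this equals the mean of the four order-specific second-order
    terms ``-h_x'(a) h_y(a) delta**2`` over x, y in {p, n}.
    """
    hm = curve_p.average_with(curve_n)
    raw = -hm.derivative(a) * hm.value(a) * delta**2
    return BiasPrediction(raw_change=raw, delta=delta)


def random_bias_theory(
    a1: float, curve: SensitivityCurve, noise: NoiseSpec
) -> BiasPrediction:
    """Expected drift after two feedbacks fluctuating around ``a1``.

    Returns ``-h'(a1) * h(a1)**2 * var_theta`` in raw units; strictly
    positive for a decreasing curve with nonzero noise.  ``delta`` of the
    returned prediction is set to ``noise.sd`` for scale bookkeeping.
    """
    raw = -curve.derivative(a1) * curve.value(a1) ** 2 * noise.var_theta
    return BiasPrediction(raw_change=raw, delta=noise.sd if noise.sd > 0 else 1.0)


def simulate_random_feedback_series(
    a1: float,
    curve: SensitivityCurve,
    noise: NoiseSpec,
    n_steps: int,
    n_reps: int,
    seed: int,
    bound_policy: Literal["clamp", "discard"] = "clamp",
) -> dict:
    """Monte-Carlo mean terminal drift under feedbacks ``f_t = a1 + theta_t``.

    Each of ``n_reps`` replicates starts at ``a1`` and receives ``n_steps``
    feedbacks drawn around the *initial* value; the update is
    ``a += h(a) * (f - a)``.  Trajectories leaving [0, 100] are clamped (and
    counted) or discarded according to ``bound_policy``.

    Returns a dict with ``mean_bias``, its standard error ``se``,
    ``n_effective`` and ``n_out_of_bounds``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    a = np.full(n_reps, float(a1))
    hit_bound = np.zeros(n_reps, dtype=bool)
    for _ in range(n_steps):
        theta = rng.normal(0.0, noise.sd, size=n_reps)
        f = a1 + theta
        h = curve.value(np.clip(a, 0.0, 100.0))
        a = a + h * (f - a)
        out = (a < 0.0) | (a > 100.0)
        hit_bound |= out
        a = np.clip(a, 0.0, 100.0)
    if bound_policy == "discard":
        keep = ~hit_bound
        if not keep.any():
            raise InvalidCurveError("all trajectories left [0, 100]")
        bias = a[keep] - a1
    else:
        bias = a - a1
    return {
        "mean_bias": float(bias.mean()),
        "se": float(bias.std(ddof=1) / math.sqrt(len(bias))) if len(bias) > 1 else 0.0,
        "n_effective": int(len(bias)),
        "n_out_of_bounds": int(hit_bound.sum()),
    }
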