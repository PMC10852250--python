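"""Synthetic cohort generator following the four-step feedback protocol.

Each participant starts from an experimenter-chosen anchor, states a first
self-evaluation, then four times receives a feedback ``f_t = a_t +/- (delta
+/- epsilon)`` (two positive, two negative, in one of the six balanced
orders) and states a new self-evaluation constrained between the previous
one and the feedback.  Responses are driven by latent per-participant
sensitivity curves, one for positive and one for negative feedbacks, with
configurable group-level variation.

The latent process runs on the increasing (score) scale; participants
assigned the rank scale have their recorded values mirrored (``100 - v``),
so applying the rank-to-score transform downstream recovers the latent
values exactly.

All randomness flows from a single seed through one generator, so a fixed
config yields byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import SensitivityCurve

__all__ = [
    "SEQUENCES",
    "FeedbackPlan",
    "ParticipantProfile",
    "CohortConfig",
    "enumerate_sequences",
    "draw_anchor",
    "plan_feedback",
    "respond",
    "simulate_experiment",
]

#: The six balanced sign sequences (two positive, two negative), fixed order.
SEQUENCES: tuple[tuple[int, ...], ...] = (
    (+1, +1, -1, -1),
    (+1, -1, +1, -1),
    (+1, -1, -1, +1),
    (-1, +1, +1, -1),
    (-1, +1, -1, +1),
    (-1, -1, +1, +1),
)

TRIPLE_COLUMNS = [
    "participant_id",
    "t",
    "a_t",
    "f_t",
    "a_next",
    "delta_t",
    "sign",
    "truncated",
]

PARTICIPANT_COLUMNS = [
    "participant_id",
    "trust",
    "gender",
    "self_esteem",
    "scale",
    "anchor",
    "interview_time",
    "excluded",
]


class DegenerateFeedbackError(ValueError):
    """Feedback equals the current self-evaluation; no update is defined."""


def enumerate_sequences() -> list[tuple[int, ...]]:
    """All length-4 sign tuples with exactly two +1 and two -1, in canonical order."""
    return list(SEQUENCES)


@dataclass(frozen=True)
class FeedbackPlan:
    """Signed feedback schedule for one participant."""

    signs: tuple[int, int, int, int]
    delta: float = 13.0
    epsilon: float = 1.0

    def __post_init__(self):
        if tuple(sorted(self.signs)) != (-1, -1, 1, 1):
            raise ValueError(f"signs must hold two +1 and two -1, got {self.signs}")
        if not self.delta > self.epsilon >= 0:
            raise ValueError("need delta > epsilon >= 0")


@dataclass
class ParticipantProfile:
    """Latent and observed attributes of one simulated participant."""

    id: int
    curve_p: SensitivityCurve
    curve_n: SensitivityCurve
    trust: int
    gender: str
    self_esteem: float
    scale: str  # "rank" | "score"
    anchor: int
    response_noise_sd: float
    interview_time: float

    def __post_init__(self):
        if not 0 <= self.trust <= 10:
            raise ValueError("trust must be in [0, 10]")
        if not (15 <= self.anchor <= 40 or 60 <= self.anchor <= 85):
            raise ValueError("anchor must lie in [15, 40] or [60, 85]")
        if not 1.0 <= self.self_esteem <= 4.0:
            raise ValueError("self_esteem must be in [1, 4]")


@dataclass
class CohortConfig:
    """Generator parameters.

    ``group_offsets`` maps covariate name -> level -> additive adjustments of
    the base curve parameters (keys among b_p, c_p, b_n, c_n).  The defaults
    give a decreasing mean sensitivity and a mild score-condition
    self-derogation; they are conventions of this generator, not measured
    quantities.  ``trust_slope_coupling`` gamma steepens both slopes by
    ``-gamma * trust / 10``, producing a trust gradient when positive.
    """

    n_participants: int = 1500
    seed: int = 0
    delta: float = 13.0
    epsilon: float = 1.0
    p_high_anchor: float = 2.0 / 3.0
    p_rank_scale: float = 0.5
    b_p: float = 0.65
    c_p: float = -0.12
    b_n: float = 0.65
    c_n: float = -0.12
    response_noise_sd: float = 0.15
    anchor_noise_sd: float = 5.0
    participant_b_sd: float = 0.0
    trust_slope_coupling: float = 0.0
    group_offsets: Mapping[str, Mapping[str, Mapping[str, float]]] = field(
        default_factory=lambda: {"scale": {"score": {"b_n": 0.05}}}
    )

    def __post_init__(self):
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        for p in (self.p_high_anchor, self.p_rank_scale):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        valid = {"b_p", "c_p", "b_n", "c_n"}
        for cov, levels in self.group_offsets.items():
            if cov not in {"scale", "gender", "self_esteem", "trust"}:
                raise ValueError(f"unknown covariate in group_offsets: {cov}")
            for level, adj in levels.items():
                bad = set(adj) - valid
                if bad:
                    raise ValueError(f"unknown curve parameters {bad} for {cov}={level}")


def draw_anchor(rng: np.random.Generator, p_high: float = 2.0 / 3.0) -> int:
    """Integer anchor: uniform on [60, 85] w.p. ``p_high``, else on [15, 40]."""
    if rng.random() < p_high:
        return int(rng.integers(60, 86))
    return int(rng.integers(15, 41))


def plan_feedback(
    a_t: float,
    sign: int,
    delta: float,
    epsilon: float,
    rng: np.random.Generator,
) -> tuple[int, bool]:
    """Feedback ``a_t + sign*(delta +/- epsilon)`` clamped to [1, 100].

    The epsilon jitter is a fair coin.  Returns ``(value, truncated)`` where
    ``truncated`` marks a clamped feedback (realized intensity differs from
    the planned ``delta +/- epsilon``).
    """
    if not 1 <= a_t <= 100:
        raise ValueError(f"a_t outside [1, 100]: {a_t}")
    jitter = epsilon if rng.random() < 0.5 else -epsilon
    raw = a_t + sign * (delta + jitter)
    clamped = min(max(raw, 1.0), 100.0)
    return int(round(clamped)), clamped != raw


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def respond(
    a_t: int, f_t: int, profile: ParticipantProfile, rng: np.random.Generator
) -> int:
    """Participant's next self-evaluation, constrained between ``a_t`` and ``f_t``.

    Effective sensitivity is the latent curve value (positive- or
    negative-feedback curve by the sign of ``f_t - a_t``) plus Gaussian
    noise, clamped to [0, 1]; the response is rounded half-away-from-zero.
    """
    if f_t == a_t:
        raise DegenerateFeedbackError(f"feedback equals self-evaluation ({a_t})")
    curve = profile.curve_p if f_t > a_t else profile.curve_n
    sens = curve.value(float(np.clip(a_t, 0, 100)))
    if profile.response_noise_sd > 0:
        sens += rng.normal(0.0, profile.response_noise_sd)
    sens = min(max(sens, 0.0), 1.0)
    a_next = _round_half_away(a_t + sens * (f_t - a_t))
    lo, hi = min(a_t, f_t), max(a_t, f_t)
    return min(max(a_next, lo), hi)


def _build_curves(config: CohortConfig, scale: str, gender: str,
                  self_esteem: float, trust: int) -> tuple[SensitivityCurve, SensitivityCurve]:
    params = {"b_p": config.b_p, "c_p": config.c_p, "b_n": config.b_n, "c_n": config.c_n}
    levels = {
        "scale": scale,
        "gender": gender,
        "self_esteem": "high" if self_esteem > 3 else "low",
        "trust": "high" if trust >= 7 else "low",
    }
    for cov, by_level in config.group_offsets.items():
        adj = by_level.get(levels[cov])
        if adj:
            for k, v in adj.items():
                params[k] += v
    if config.trust_slope_coupling:
        steepen = config.trust_slope_coupling * trust / 10.0
        params["c_p"] -= steepen
        params["c_n"] -= steepen
    curve_p = SensitivityCurve(b=params["b_p"], c=params["c_p"], clip=True)
    curve_n = SensitivityCurve(b=params["b_n"], c=params["c_n"], clip=True)
    return curve_p, curve_n


def _draw_profile(pid: int, config: CohortConfig, rng: np.random.Generator) -> ParticipantProfile:
    scale = "rank" if rng.random() < config.p_rank_scale else "score"
    anchor = draw_anchor(rng, config.p_high_anchor)
    trust = int(rng.integers(0, 11))
    gender = "female" if rng.random() < 0.5 else "male"
    self_esteem = float(np.clip(round(rng.normal(3.0, 0.5), 1), 1.0, 4.0))
    interview_time = float(np.round(rng.lognormal(math.log(350.0), 0.5), 1))
    curve_p, curve_n = _build_curves(config, scale, gender, self_esteem, trust)
    if config.participant_b_sd > 0:
        shift = rng.normal(0.0, config.participant_b_sd)
        curve_p = SensitivityCurve(b=curve_p.b + shift, c=curve_p.c, clip=True)
        curve_n = SensitivityCurve(b=curve_n.b + shift, c=curve_n.c, clip=True)
    return ParticipantProfile(
        id=pid,
        curve_p=curve_p,
        curve_n=curve_n,
        trust=trust,
        gender=gender,
        self_esteem=self_esteem,
        scale=scale,
        anchor=anchor,
        response_noise_sd=config.response_noise_sd,
        interview_time=interview_time,
    )


def simulate_experiment(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full protocol for every participant.

    Returns ``(triples, participants)``: four triples per participant
    (before any exclusion) and one covariate row per participant.  Values
    for rank-scale participants are recorded as ``100 - v``; their signs are
    recorded on the same mirrored scale.  A participant with any truncated
    feedback carries ``excluded=True``.
    """
    rng = np.random.default_rng(config.seed)
    triple_rows: list[tuple] = []
    participant_rows: list[tuple] = []
    for pid in range(1, config.n_participants + 1):
        profile = _draw_profile(pid, config, rng)
        a = int(np.clip(
            _round_half_away(profile.anchor + rng.normal(0.0, config.anchor_noise_sd)),
            1, 100,
        ))
        signs = SEQUENCES[int(rng.integers(0, len(SEQUENCES)))]
        any_truncated = False
        mirror = profile.scale == "rank"
        for t, sign in enumerate(signs, start=1):
            f, truncated = plan_feedback(a, sign, config.delta, config.epsilon, rng)
            if f == a:  # fully truncated feedback; no update possible
                a_next, truncated = a, True
            else:
                a_next = respond(a, f, profile, rng)
            any_truncated |= truncated
            rec_a, rec_f, rec_next = (
                (100 - a, 100 - f, 100 - a_next) if mirror else (a, f, a_next)
            )
            rec_sign = int(np.sign(rec_f - rec_a))
            triple_rows.append(
                (pid, t, rec_a, rec_f, rec_next, abs(f - a), rec_sign, truncated)
            )
            a = a_next
        participant_rows.append(
            (
                pid,
                profile.trust,
                profile.gender,
                profile.self_esteem,
                profile.scale,
                100 - profile.anchor if mirror else profile.anchor,
                profile.interview_time,
                any_truncated,
            )
        )
    triples = pd.DataFrame(triple_rows, columns=TRIPLE_COLUMNS)
    participants = pd.DataFrame(participant_rows, columns=PARTICIPANT_COLUMNS)
    return triples, participants
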