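import pandas as pd
import pytest

from sensbias import (
    CohortConfig,
    build_frame,
    filter_excluded,
    harmonize_scale,
    simulate_experiment,
)


def make_frame(config: CohortConfig):
    """Simulate a cohort and run the standard preparation chain."""
    triples, participants = simulate_experiment(config)
    triples = harmonize_scale(triples, participants)
    return filter_excluded(build_frame(triples, participants))


@pytest.fixture(scope="session")
def small_cohort():
    """Raw (triples, participants) pair, 300 participants, mixed scales."""
    return simulate_experiment(CohortConfig(n_participants=300, seed=7))


@pytest.fixture(scope="session")
def small_frame(small_cohort):
    triples, participants = small_cohort
    return filter_excluded(build_frame(harmonize_scale(triples, participants), participants))


@pytest.fixture(scope="session")
def symmetric_frame():
    """Noisy but symmetric cohort (equal curves for both feedback signs)."""
    return make_frame(
        CohortConfig(
            n_participants=500,
            seed=11,
            c_p=-0.15,
            c_n=-0.15,
            response_noise_sd=0.12,
            group_offsets={},
        )
    )


def exact_update_frame(curve_p, curve_n, anchors, delta=13.0, sequence=(1, 1, -1, -1)):
    """Noise-free, no-rounding frame built directly from the update rule.

    Independent of the cohort generator: applies a' = a + h(a)(f - a) with
    float arithmetic, a fixed sign sequence and exact intensity delta, so
    regressions recover the generating curves to machine precision.
    """
    rows = []
    for pid, a1 in enumerate(anchors, start=1):
        a = float(a1)
        for t, sign in enumerate(sequence, start=1):
            f = a + sign * delta
            curve = curve_p if sign > 0 else curve_n
            a_next = a + curve.value(a) * (f - a)
            rows.append(
                {
                    "participant_id": pid,
                    "t": t,
                    "a_t": a,
                    "f_t": f,
                    "a_next": a_next,
                    "delta_t": delta,
                    "sign": sign,
                    "truncated": False,
                    "trust": 5,
                    "gender": "female",
                    "self_esteem": 3.0,
                    "scale": "score",
                    "anchor": a1,
                    "interview_time": 300.0,
                    "excluded": False,
                }
            )
            a = a_next
    return pd.DataFrame(rows)
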