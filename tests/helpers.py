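"""Shared test construction helpers."""

from __future__ import annotations

import numpy as np

from bayesrar import OutcomeCategory, PatientRecord, PosteriorSummary

Q = OutcomeCategory.QUIT
E = OutcomeCategory.NOTQUIT_EFF
N = OutcomeCategory.NOTQUIT_NOEFF

_COUNTER = [0]


def rec(arm, y4=None, y8=None, y12=None, enrollment_week=0.0):
    """Record with the given visit categories (None = unobserved)."""
    _COUNTER[0] += 1
    visits = {
        w: c for w, c in zip((4, 8, 12), (y4, y8, y12)) if c is not None
    }
    return PatientRecord(
        patient_id=f"T{_COUNTER[0]:05d}",
        arm=arm,
        enrollment_week=enrollment_week,
        baseline_pain=8.0,
        visit_outcomes=visits,
    )


def complete_records(counts_per_arm):
    """Complete records realizing given per-arm week-12 count triples.

    ``counts_per_arm`` maps arm -> (n_quit, n_eff, n_noeff); interim visits
    mirror the final category so transition models see consistent paths.
    """
    out = []
    for arm, (nq, ne, nn) in counts_per_arm.items():
        out += [rec(arm, Q, Q, Q) for _ in range(nq)]
        out += [rec(arm, E, E, E) for _ in range(ne)]
        out += [rec(arm, N, N, N) for _ in range(nn)]
    return out


def summary_from(p_max, var_utility=None, n=None, mean_utility=None):
    """Hand-built PosteriorSummary for decision-rule tests."""
    p_max = np.asarray(p_max, dtype=float)
    A = len(p_max)
    return PosteriorSummary(
        p_max=p_max,
        mean_utility=np.asarray(
            mean_utility if mean_utility is not None else np.full(A, 1.0)
        ),
        var_utility=np.asarray(
            var_utility if var_utility is not None else np.full(A, 0.02)
        ),
        n_enrolled=np.asarray(n if n is not None else np.full(A, 20), dtype=np.int64),
        n_draws=10_000,
        m_imputations=20,
        seed=0,
    )
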