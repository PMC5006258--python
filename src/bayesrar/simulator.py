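"""Virtual-trial simulator and design operating characteristics.

Synthetic patients follow the longitudinal structure the design assumes:
the week-4 outcome is drawn from a per-arm category distribution, later
visits evolve by per-arm transition triples conditional on the current
non-quit state, and quitting is absorbing. Trials are simulated on a
calendar: patients accrue at a fixed rate, take the next slot of the
allocation table, the first interim analysis fires when the burn-in
completes, and further interims follow every adaptation interval. Each
interim sees only outcomes whose visit date has passed, imputes the rest,
and applies the loser and early-success rules. Repeating the simulation
estimates the design's operating characteristics: power or Type I error,
expected sample size, allocation shares, and duration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .adaptation import (
    AllocationTable,
    RandomizationVector,
    adapt_table,
    assign_next,
    check_losers,
    check_success,
    make_burnin_table,
    randomization_vector,
)
from .config import TrialConfig
from .errors import InvalidInputError
from .outcomes import OutcomeCategory, PatientRecord
from .posterior import PosteriorSummary, summarize_arrays

#: default generative null: week-4 quit/efficacy/no-efficacy rates shared by
#: all arms, with transitions at the elicited conditional prior means. The
#: original design's simulation scenarios were never published, so this is a
#: package assumption, stated in the methods note.
NULL_P4 = (0.30, 0.25, 0.45)
NULL_T_EFF = (0.10, 0.70, 0.20)
NULL_T_NOEFF = (0.10, 0.20, 0.70)


@dataclass(frozen=True)
class ScenarioTruth:
    """Generative truth of one simulation scenario.

    ``p4`` holds each arm's week-4 category probabilities; ``t_eff`` and
    ``t_noeff`` the next-visit category probabilities conditional on the
    current visit being efficacious / non-efficacious on drug. The same
    transitions drive the 4→8 and 8→12 steps unless late-step overrides
    are given. Quit is absorbing.
    """

    p4: np.ndarray  # (A, 3)
    t_eff: np.ndarray  # (A, 3)
    t_noeff: np.ndarray  # (A, 3)
    t_eff_late: np.ndarray | None = None
    t_noeff_late: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in ("p4", "t_eff", "t_noeff", "t_eff_late", "t_noeff_late"):
            arr = getattr(self, name)
            if arr is None:
                continue
            arr = np.atleast_2d(np.asarray(arr, dtype=float))
            object.__setattr__(self, name, arr)
            if arr.shape[1] != 3 or np.any(arr < 0) or np.any(
                np.abs(arr.sum(axis=1) - 1.0) > 1e-9
            ):
                raise InvalidInputError(f"{name} rows must lie on the 3-simplex")

    @property
    def n_arms(self) -> int:
        return self.p4.shape[0]

    @classmethod
    def null(cls, n_arms: int = 4) -> "ScenarioTruth":
        """All arms generatively identical (the Type I error scenario)."""
        return cls(
            p4=np.tile(NULL_P4, (n_arms, 1)),
            t_eff=np.tile(NULL_T_EFF, (n_arms, 1)),
            t_noeff=np.tile(NULL_T_NOEFF, (n_arms, 1)),
        )

    @classmethod
    def from_week4(
        cls,
        p4_rows: Sequence[Sequence[float]],
        t_eff: Sequence[float] = NULL_T_EFF,
        t_noeff: Sequence[float] = NULL_T_NOEFF,
    ) -> "ScenarioTruth":
        """Scenario with per-arm week-4 triples and shared transitions."""
        n = len(p4_rows)
        return cls(
            p4=np.asarray(p4_rows, dtype=float),
            t_eff=np.tile(np.asarray(t_eff, float), (n, 1)),
            t_noeff=np.tile(np.asarray(t_noeff, float), (n, 1)),
        )

    def _step_matrix(self, arm0: int, late: bool) -> np.ndarray:
        te = self.t_eff_late if (late and self.t_eff_late is not None) else self.t_eff
        tn = (
            self.t_noeff_late
            if (late and self.t_noeff_late is not None)
            else self.t_noeff
        )
        return np.array([[1.0, 0.0, 0.0], te[arm0], tn[arm0]])

    def week12_marginal(self) -> np.ndarray:
        """Closed-form (A, 3) marginal of the final-visit categories."""
        out = np.empty_like(self.p4)
        for a in range(self.n_arms):
            out[a] = self.p4[a] @ self._step_matrix(a, False) @ self._step_matrix(a, True)
        return out

    def true_utility(self, weight: float = 0.75) -> np.ndarray:
        marg = self.week12_marginal()
        return weight * marg[:, 1] + 1.0 - marg[:, 0]

    def to_dict(self) -> dict:
        d = {
            "p4": self.p4.tolist(),
            "t_eff": self.t_eff.tolist(),
            "t_noeff": self.t_noeff.tolist(),
        }
        if self.t_eff_late is not None:
            d["t_eff_late"] = self.t_eff_late.tolist()
        if self.t_noeff_late is not None:
            d["t_noeff_late"] = self.t_noeff_late.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioTruth":
        return cls(**{k: np.asarray(v, dtype=float) for k, v in d.items()})


@dataclass
class SimulatedPatient(PatientRecord):
    """A fully simulated trajectory, carrying the raw scores behind each visit.

    ``pain_scores`` / ``quit_flags`` let a simulated cohort round-trip
    through the raw patient-records CSV and the outcome classifier.
    """

    pain_scores: dict[int, float | None] = field(default_factory=dict)
    quit_flags: dict[int, bool] = field(default_factory=dict)


@dataclass(frozen=True)
class TrialResult:
    """Outcome of one simulated trial."""

    success: bool
    winner: int | None
    stopped_early: bool
    n_enrolled: int
    n_per_arm: np.ndarray
    duration_weeks: float
    losers: frozenset[int]
    interim_history: list[tuple[float, PosteriorSummary, RandomizationVector | None]]
    #: per-patient enrollment log in enrollment order
    enroll_weeks: np.ndarray = field(default_factory=lambda: np.empty(0))
    arms_assigned: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.success != (self.winner is not None):
            raise InvalidInputError("winner must be present iff success")


def _simulate_trajectory(
    truth: ScenarioTruth, arm: int, rng: np.random.Generator
) -> tuple[int, int, int]:
    """Category codes at the three visits for one patient on ``arm``."""
    a0 = arm - 1
    cats = []
    state = _draw_cat(truth.p4[a0], rng)
    cats.append(state)
    for late in (False, True):
        if state == 0:
            cats.append(0)
            continue
        row = (
            (truth.t_eff_late if (late and truth.t_eff_late is not None) else truth.t_eff)
            if state == 1
            else (truth.t_noeff_late if (late and truth.t_noeff_late is not None) else truth.t_noeff)
        )
        state = _draw_cat(row[a0], rng)
        cats.append(state)
    return tuple(cats)


def _draw_cat(p: np.ndarray, rng: np.random.Generator) -> int:
    u = rng.random()
    if u < p[0]:
        return 0
    if u < p[0] + p[1]:
        return 1
    return 2


def generate_patient(
    truth: ScenarioTruth,
    arm: int,
    enrollment_week: float,
    rng: np.random.Generator,
    patient_id: str | None = None,
    schedule: tuple[int, ...] = (4, 8, 12),
) -> SimulatedPatient:
    """Simulate one patient's full trajectory on ``arm``.

    All visits are generated up front (masking by calendar time is the
    trial loop's job). Raw baseline/follow-up pain scores consistent with
    each category are synthesized so the record survives a round trip
    through the outcome classifier: efficacious visits score strictly
    below half of baseline, non-efficacious visits strictly above, and
    quit visits carry no score.
    """
    if not 1 <= arm <= truth.n_arms:
        raise InvalidInputError(f"arm {arm} out of range 1..{truth.n_arms}")
    cats = _simulate_trajectory(truth, arm, rng)
    baseline = float(rng.integers(4, 11))  # moderate-to-severe pain at entry
    visits: dict[int, OutcomeCategory] = {}
    pains: dict[int, float | None] = {}
    quits: dict[int, bool] = {}
    for week, code in zip(schedule, cats):
        cat = OutcomeCategory(code)
        visits[week] = cat
        if cat is OutcomeCategory.QUIT:
            pains[week] = None
            quits[week] = True
        else:
            quits[week] = False
            if cat is OutcomeCategory.NOTQUIT_EFF:
                pains[week] = 0.5 * baseline * rng.random()  # in [0, b/2)
            else:
                pains[week] = 0.5 * baseline * (1.0 + (1.0 - rng.random()))  # in (b/2, b]
    return SimulatedPatient(
        patient_id=patient_id or "S0000",
        arm=arm,
        enrollment_week=float(enrollment_week),
        baseline_pain=baseline,
        visit_outcomes=visits,
        pain_scores=pains,
        quit_flags=quits,
    )


def run_trial(
    truth: ScenarioTruth,
    config: TrialConfig,
    accrual_rate: float = 4.0,
    rng: np.random.Generator | int | None = None,
) -> TrialResult:
    """Simulate one complete adaptive trial on a calendar.

    Patients enroll at ``accrual_rate`` per week (uniform spacing), each
    taking the next slot of the allocation table. The first interim runs
    at the calendar week of the burn-in's completion and repeats every
    ``adaptation_interval_weeks`` while enrollment is open; each interim
    uses every patient with at least one visit elapsed, masks outcomes the
    calendar has not reached, updates the loser set and the allocation
    table, and stops the trial on early success. Absent early success,
    enrollment continues to ``max_n`` and the success rule is applied once
    more after the last enrollee's final visit, on complete data.
    """
    if accrual_rate <= 0:
        raise InvalidInputError("accrual_rate must be positive")
    seed = rng if isinstance(rng, (int, np.integer)) else None
    rng = np.random.default_rng(rng)
    A = config.n_arms
    schedule = config.visit_weeks
    final_week = schedule[-1]

    table = make_burnin_table(config, rng)
    arm_of = np.zeros(config.max_n, dtype=np.int64)
    enroll_wk = np.zeros(config.max_n)
    traj = np.zeros((config.max_n, len(schedule)), dtype=np.int8)

    losers: frozenset[int] = frozenset()
    history: list[tuple[float, PosteriorSummary, RandomizationVector | None]] = []
    winner: int | None = None
    stopped_early = False
    n = 0
    next_interim: float | None = None

    def do_interim(week: float, adapt: bool) -> bool:
        """Run one interim at ``week``; returns True if the trial stops."""
        nonlocal losers, winner, stopped_early, table
        obs = enroll_wk[:n, None] + np.asarray(schedule)[None, :] <= week
        codes = np.where(obs, traj[:n], -1).astype(np.int8)
        elig = codes[:, 0] >= 0  # at least the first visit elapsed
        child_seed = int(rng.integers(2**31))
        summary = summarize_arrays(arm_of[:n][elig], codes[elig], config, child_seed)
        losers = check_losers(summary, config.loser_threshold, losers)
        win = check_success(summary, config.success_threshold)
        if win is not None:
            winner = win
            stopped_early = True
            history.append((week, summary, None))
            return True
        q = randomization_vector(summary, losers)
        history.append((week, summary, q))
        if adapt:
            table = adapt_table(table, q, config.block_size, rng)
        return False

    while n < config.max_n:
        t = n / accrual_rate
        while next_interim is not None and next_interim < t:
            if do_interim(next_interim, adapt=True):
                break
            next_interim += config.adaptation_interval_weeks
        if stopped_early:
            break
        arm, table = assign_next(table)
        arm_of[n] = arm
        enroll_wk[n] = t
        traj[n] = _simulate_trajectory(truth, arm, rng)
        n += 1
        if n == config.burn_in_n:
            first = t
            if do_interim(first, adapt=True):
                break
            next_interim = first + config.adaptation_interval_weeks

    if stopped_early:
        duration = history[-1][0]
    else:
        duration = enroll_wk[n - 1] + final_week
        # end-of-trial analysis: complete follow-up, no masking, no imputation
        summary = summarize_arrays(
            arm_of[:n], traj[:n].copy(), config, int(rng.integers(2**31))
        )
        history.append((duration, summary, None))
        winner = check_success(summary, config.success_threshold)

    return TrialResult(
        success=winner is not None,
        winner=winner,
        stopped_early=stopped_early,
        n_enrolled=n,
        n_per_arm=np.bincount(arm_of[:n] - 1, minlength=A),
        duration_weeks=float(duration),
        losers=losers,
        interim_history=history,
        enroll_weeks=enroll_wk[:n].copy(),
        arms_assigned=arm_of[:n].copy(),
        seed=seed,
    )


@dataclass(frozen=True)
class OperatingCharacteristics:
    """Aggregated design properties over repeated simulated trials."""

    n_reps: int
    success_rate: float
    success_rate_se: float  # binomial Monte-Carlo standard error
    early_stop_rate: float
    mean_n: float
    sd_n: float
    mean_duration_weeks: float
    mean_allocation_share: np.ndarray  # (A,) mean of per-trial n_a / n
    loser_rate: np.ndarray  # (A,) fraction of trials declaring arm a a loser
    winner_rate: np.ndarray  # (A,) fraction of trials declaring arm a the winner

    def to_frame(self) -> pd.DataFrame:
        row: dict = {
            "n_reps": self.n_reps,
            "success_rate": self.success_rate,
            "success_rate_se": self.success_rate_se,
            "early_stop_rate": self.early_stop_rate,
            "mean_n": self.mean_n,
            "sd_n": self.sd_n,
            "mean_duration_weeks": self.mean_duration_weeks,
        }
        for a in range(len(self.mean_allocation_share)):
            row[f"share_arm{a + 1}"] = self.mean_allocation_share[a]
            row[f"loser_rate_arm{a + 1}"] = self.loser_rate[a]
            row[f"winner_rate_arm{a + 1}"] = self.winner_rate[a]
        return pd.DataFrame([row])


def operating_characteristics(
    truth: ScenarioTruth,
    config: TrialConfig,
    accrual_rate: float = 4.0,
    n_reps: int = 500,
    rng: np.random.Generator | int | None = None,
) -> OperatingCharacteristics:
    """Estimate operating characteristics from ``n_reps`` independent trials.

    Under a null truth (identical arms) the success rate estimates the
    design's Type I error; under an effect scenario it estimates power.
    """
    if n_reps < 1:
        raise InvalidInputError("n_reps must be >= 1")
    rng = np.random.default_rng(rng)
    A = config.n_arms
    results = [
        run_trial(truth, config, accrual_rate, int(rng.integers(2**31)))
        for _ in range(n_reps)
    ]
    succ = np.array([r.success for r in results], dtype=float)
    ns = np.array([r.n_enrolled for r in results], dtype=float)
    shares = np.array([r.n_per_arm / r.n_enrolled for r in results])
    loser = np.array(
        [[a in r.losers for a in range(1, A + 1)] for r in results], dtype=float
    )
    winner = np.array(
        [[r.winner == a for a in range(1, A + 1)] for r in results], dtype=float
    )
    p = succ.mean()
    return OperatingCharacteristics(
        n_reps=n_reps,
        success_rate=float(p),
        success_rate_se=float(np.sqrt(p * (1 - p) / n_reps)),
        early_stop_rate=float(np.mean([r.stopped_early for r in results])),
        mean_n=float(ns.mean()),
        sd_n=float(ns.std(ddof=1)) if n_reps > 1 else 0.0,
        mean_duration_weeks=float(np.mean([r.duration_weeks for r in results])),
        mean_allocation_share=shares.mean(axis=0),
        loser_rate=loser.mean(axis=0),
        winner_rate=winner.mean(axis=0),
    )
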