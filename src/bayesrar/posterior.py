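"""Dirichlet–multinomial posterior engine for the adaptive trial.

The 12-week response of a patient on arm ``a`` is multinomial over the
three outcome categories with probabilities ``theta_a``, given a weak
uniform Dirichlet(1/3, 1/3, 1/3) prior. Arms are scored by the utility

    U_a = w * theta_a[eff] + (1 - theta_a[quit]),      w = 0.75 by default,

which rewards efficacy and penalizes quitting; U ranges over [0, 1 + w].

At an interim analysis many patients have a 4- or 8-week outcome but no
12-week outcome yet. Their final outcome is imputed from conditional
transition models — one Dirichlet–multinomial per (arm, interim week),
fit separately for patients showing early efficacy (prior Dirichlet(1,7,2))
and early non-efficacy (prior Dirichlet(1,2,7)); each prior carries weight
equivalent to ten patients. A patient observed to have quit needs no model:
quitting is absorbing, so their 12-week outcome is quit with certainty.

The interim quantities — the posterior probability P_a^max that each arm
has the maximal utility, and the posterior mean and variance of U_a — are
computed by Monte Carlo, pooling utility draws over ``m`` multiple
imputations of the incomplete patients.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import TrialConfig
from .errors import InvalidInputError
from .outcomes import (
    DEFAULT_VISIT_WEEKS,
    OutcomeCategory,
    PatientRecord,
    records_to_arrays,
)

SIMPLEX_TOL = 1e-9


@dataclass(frozen=True)
class ArmPosterior:
    """Dirichlet concentrations over one arm's 12-week category probabilities."""

    arm: int
    concentration: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(c <= 0 for c in self.concentration):
            raise InvalidInputError("Dirichlet concentrations must be positive")

    @property
    def mean(self) -> np.ndarray:
        alpha = np.asarray(self.concentration, dtype=float)
        return alpha / alpha.sum()


@dataclass(frozen=True)
class TransitionModel:
    """Conditional 12-week outcome model for one (arm, interim week) pair.

    ``post_eff`` / ``post_noeff`` are the Dirichlet concentrations of the
    12-week category probabilities conditional on the interim visit showing
    efficacy / no efficacy. Prior-only instances sum to 10 in each branch.
    """

    arm: int
    interim_week: int
    post_eff: tuple[float, float, float]
    post_noeff: tuple[float, float, float]


@dataclass(frozen=True)
class PosteriorSummary:
    """Per-arm interim quantities from one Monte-Carlo posterior analysis."""

    p_max: np.ndarray  # (A,) posterior probability of being the best arm
    mean_utility: np.ndarray  # (A,) posterior mean of U_a
    var_utility: np.ndarray  # (A,) posterior variance of U_a
    n_enrolled: np.ndarray  # (A,) records contributing per arm
    n_draws: int
    m_imputations: int
    seed: int | None

    @property
    def n_arms(self) -> int:
        return len(self.p_max)

    def best_arm(self) -> int:
        """1-based arm index with the largest P_a^max."""
        return int(np.argmax(self.p_max)) + 1

    def to_frame(self, labels: Sequence[str] | None = None) -> pd.DataFrame:
        """Flat one-row-per-arm report (the numeric core of a DSMB report)."""
        if labels is None:
            labels = [str(a + 1) for a in range(self.n_arms)]
        return pd.DataFrame(
            {
                "arm": list(labels),
                "n": self.n_enrolled.astype(int),
                "p_max": self.p_max,
                "mean_utility": self.mean_utility,
                "var_utility": self.var_utility,
            }
        )


def update_dirichlet(prior: Sequence[float], counts: Sequence[float]) -> np.ndarray:
    """Conjugate update: posterior concentration = prior + observed counts."""
    prior = np.asarray(prior, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if prior.shape != counts.shape:
        raise InvalidInputError("prior and counts must have the same shape")
    if np.any(prior <= 0):
        raise InvalidInputError("prior concentrations must be positive")
    if np.any(counts < 0) or np.any(counts != np.floor(counts)):
        raise InvalidInputError("counts must be nonnegative integers")
    return prior + counts


def utility(theta: Sequence[float], weight: float = 0.75) -> float:
    """Arm utility ``weight * theta[eff] + (1 - theta[quit])``.

    ``theta`` must lie on the 3-simplex (tolerance 1e-9).
    """
    theta = np.asarray(theta, dtype=float)
    if weight < 0:
        raise InvalidInputError("weight must be nonnegative")
    if theta.shape != (3,) or np.any(theta < -SIMPLEX_TOL) or abs(theta.sum() - 1.0) > SIMPLEX_TOL:
        raise InvalidInputError(f"theta must lie on the 3-simplex, got {theta}")
    return float(weight * theta[1] + (1.0 - theta[0]))


def closed_form_utility_moments(
    concentration: Sequence[float], weight: float = 0.75
) -> tuple[float, float]:
    """Exact posterior mean and variance of U under a Dirichlet posterior.

    With alpha0 = sum(alpha):  E[U] = w*E[theta_2] + 1 - E[theta_1];
    Var(U) = w^2 Var(theta_2) + Var(theta_1) - 2w Cov(theta_1, theta_2),
    using the standard Dirichlet moments. Serves as the analytic
    counterpart of the Monte-Carlo summary.
    """
    alpha = np.asarray(concentration, dtype=float)
    a0 = alpha.sum()
    mean = alpha / a0
    denom = a0 * a0 * (a0 + 1.0)
    var = alpha * (a0 - alpha) / denom
    cov12 = -alpha[0] * alpha[1] / denom
    mean_u = weight * mean[1] + 1.0 - mean[0]
    var_u = weight**2 * var[1] + var[0] - 2.0 * weight * cov12
    return float(mean_u), float(var_u)


# ---------------------------------------------------------------------------
# transition models and imputation
# ---------------------------------------------------------------------------


def fit_transition_models(
    records: Iterable[PatientRecord],
    priors: tuple[Sequence[float], Sequence[float]] = ((1.0, 7.0, 2.0), (1.0, 2.0, 7.0)),
    schedule: tuple[int, ...] = DEFAULT_VISIT_WEEKS,
    n_arms: int = 4,
) -> dict[tuple[int, int], TransitionModel]:
    """Fit one conditional transition model per (arm, interim week).

    A patient contributes to the (arm, w) model iff their week-``w`` outcome
    is observed and not quit AND their final-week outcome is observed; the
    count lands in the efficacy or no-efficacy branch according to the
    interim status. Interim quitters contribute nowhere — their final
    outcome is already determined.
    """
    arms, codes = records_to_arrays(records, schedule)
    eff_conc, noeff_conc = _transition_concentrations(
        arms, codes, n_arms, np.asarray(priors[0], float), np.asarray(priors[1], float)
    )
    interim_weeks = schedule[:-1]
    return {
        (a + 1, w): TransitionModel(
            arm=a + 1,
            interim_week=w,
            post_eff=tuple(eff_conc[a, j]),
            post_noeff=tuple(noeff_conc[a, j]),
        )
        for a in range(n_arms)
        for j, w in enumerate(interim_weeks)
    }


def _transition_concentrations(
    arms: np.ndarray,
    codes: np.ndarray,
    n_arms: int,
    eff_prior: np.ndarray,
    noeff_prior: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized core: (A, n_interim, 3) concentration arrays per branch."""
    n_interim = codes.shape[1] - 1
    eff = np.tile(eff_prior, (n_arms, n_interim, 1))
    noeff = np.tile(noeff_prior, (n_arms, n_interim, 1))
    final = codes[:, -1]
    done = final >= 0
    arm0 = arms - 1
    for j in range(n_interim):
        yw = codes[:, j]
        for status, conc in ((1, eff), (2, noeff)):
            sel = (yw == status) & done
            if sel.any():
                flat = arm0[sel] * 3 + final[sel]
                conc[:, j, :] += np.bincount(flat, minlength=3 * n_arms).reshape(
                    n_arms, 3
                )
    return eff, noeff


def impute_final_counts(
    records: Iterable[PatientRecord],
    models: Mapping[tuple[int, int], TransitionModel],
    rng: np.random.Generator,
    n_arms: int = 4,
    schedule: tuple[int, ...] = DEFAULT_VISIT_WEEKS,
) -> np.ndarray:
    """One imputed completion: per-arm final-visit category counts.

    Observed final outcomes pass through unchanged. For each patient
    missing the final visit, the latest observed interim outcome decides:
    quit imputes quit with certainty; otherwise the category is drawn from
    the posterior predictive of the matching transition model (a Dirichlet
    draw of a probability triple, then a categorical draw).

    Returns an (n_arms, 3) integer array indexed by arm-1.
    """
    arms, codes = records_to_arrays(records, schedule)
    if np.any((codes < 0).all(axis=1)):
        raise InvalidInputError(
            "every record must have at least one observed visit outcome"
        )
    final_week = schedule[-1]
    counts = np.zeros((n_arms, 3), dtype=np.int64)
    for i in range(len(arms)):
        a = int(arms[i])
        if codes[i, -1] >= 0:
            counts[a - 1, codes[i, -1]] += 1
            continue
        j_latest = max(j for j in range(codes.shape[1] - 1) if codes[i, j] >= 0)
        status = int(codes[i, j_latest])
        if status == int(OutcomeCategory.QUIT):
            counts[a - 1, 0] += 1
            continue
        model = models[(a, schedule[j_latest])]
        alpha = model.post_eff if status == 1 else model.post_noeff
        theta = rng.dirichlet(alpha)
        counts[a - 1, rng.choice(3, p=theta)] += 1
    return counts


# ---------------------------------------------------------------------------
# interim summary
# ---------------------------------------------------------------------------


def posterior_summary(
    records: Iterable[PatientRecord],
    config: TrialConfig,
    seed: int | None = None,
) -> PosteriorSummary:
    """Run one Monte-Carlo interim analysis on the given records.

    Repeats ``config.m_imputations`` times: impute a completion, apply the
    conjugate update per arm, draw ``ceil(n_draws / m)`` probability triples
    per arm and score their utilities. Draws are pooled across completions;
    P_a^max is the fraction of pooled draw indices on which arm ``a``
    attains the maximum utility (exact ties split uniformly at random),
    and mean/variance of U_a are the pooled sample moments.

    An arm with no eligible records is summarized from its prior alone.
    """
    arms, codes = records_to_arrays(records, config.visit_weeks)
    return summarize_arrays(arms, codes, config, seed)


def summarize_arrays(
    arms: np.ndarray,
    codes: np.ndarray,
    config: TrialConfig,
    seed: int | None = None,
) -> PosteriorSummary:
    """Array-based core of :func:`posterior_summary`.

    ``arms`` holds 1-based arm indices; ``codes`` is (n, n_visits) with
    outcome codes and -1 for unobserved, columns ordered by
    ``config.visit_weeks``.
    """
    rng = np.random.default_rng(seed)
    A = config.n_arms
    w = config.utility_weight
    m = config.m_imputations
    k_draws = -(-config.n_draws // m)  # ceil

    if len(arms) and np.any((codes < 0).all(axis=1)):
        raise InvalidInputError(
            "records with no observed visit are ineligible for an interim analysis"
        )
    arm0 = arms - 1
    final = codes[:, -1] if len(arms) else np.empty(0, dtype=np.int8)

    eff_conc, noeff_conc = _transition_concentrations(
        arm0 + 1, codes, A, np.asarray(config.eff_prior, float),
        np.asarray(config.noeff_prior, float),
    )

    # fixed contributions: observed finals, plus deterministic quit imputations
    done = final >= 0
    base = np.zeros((A, 3), dtype=np.int64)
    if done.any():
        base += np.bincount(arm0[done] * 3 + final[done], minlength=3 * A).reshape(A, 3)
    inc = ~done
    n_interim = codes.shape[1] - 1
    # latest observed interim visit per incomplete patient
    groups: list[tuple[int, int, int, int]] = []  # (arm0, visit_idx, status, size)
    if inc.any():
        codes_inc = codes[inc][:, :n_interim]
        obs_interim = codes_inc >= 0
        # every incomplete record has >=1 observed interim (checked above)
        j_latest = n_interim - 1 - np.argmax(obs_interim[:, ::-1], axis=1)
        lat = codes_inc[np.arange(len(codes_inc)), j_latest]
        arm_inc = arm0[inc]
        det_quit = lat == 0
        if det_quit.any():
            base[:, 0] += np.bincount(arm_inc[det_quit], minlength=A)
        live = ~det_quit
        if live.any():
            key = (arm_inc[live] * n_interim + j_latest[live]) * 2 + (lat[live] - 1)
            sizes = np.bincount(key, minlength=A * n_interim * 2)
            for kk in np.nonzero(sizes)[0]:
                a, rem = divmod(int(kk), n_interim * 2)
                j, s = divmod(rem, 2)
                groups.append((a, j, s + 1, int(sizes[kk])))

    prior = np.asarray(config.outcome_prior, dtype=float)
    U = np.empty((m * k_draws, A))
    for rep in range(m):
        counts = base.copy()
        for a, j, status, size in groups:
            alpha = eff_conc[a, j] if status == 1 else noeff_conc[a, j]
            th = rng.gamma(alpha, size=(size, 3))
            th /= th.sum(axis=1, keepdims=True)
            u = rng.random(size)
            cat = (u[:, None] > np.cumsum(th, axis=1)[:, :2]).sum(axis=1)
            counts[a] += np.bincount(cat, minlength=3)
        alpha_post = prior + counts
        g = rng.gamma(alpha_post, size=(k_draws, A, 3))
        th = g / g.sum(axis=-1, keepdims=True)
        U[rep * k_draws : (rep + 1) * k_draws] = w * th[..., 1] + 1.0 - th[..., 0]

    win = _argmax_with_random_ties(U, rng)
    p_max = np.bincount(win, minlength=A) / len(U)
    return PosteriorSummary(
        p_max=p_max,
        mean_utility=U.mean(axis=0),
        var_utility=U.var(axis=0, ddof=1),
        n_enrolled=np.bincount(arm0, minlength=A) if len(arms) else np.zeros(A, dtype=np.int64),
        n_draws=len(U),
        m_imputations=m,
        seed=seed,
    )


def _argmax_with_random_ties(U: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Row-wise argmax; exact ties resolved uniformly at random."""
    win = U.argmax(axis=1)
    mx = U[np.arange(len(U)), win]
    ties = U == mx[:, None]
    tied_rows = ties.sum(axis=1) > 1
    if tied_rows.any():
        pert = rng.random((int(tied_rows.sum()), U.shape[1]))
        win = win.copy()
        win[tied_rows] = np.where(ties[tied_rows], pert, -1.0).argmax(axis=1)
    return win
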