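"""Independent numerical oracles used only by the tests.

These deliberately avoid the package's own Monte-Carlo machinery: the
utility distribution of a Dirichlet posterior is integrated on a dense
midpoint grid over the probability simplex, and moments come from
closed-form Dirichlet algebra or scipy.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln


def _simplex_grid(alpha: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Midpoint-cell discretization of Dirichlet(alpha) over (theta1, theta2).

    Returns utilities are left to the caller; here: theta grid (k, 2) and
    normalized cell weights (k,). Valid for alpha components >= 1 (no
    boundary singularities).
    """
    step = 1.0 / n
    centers = (np.arange(n) + 0.5) * step
    t1, t2 = np.meshgrid(centers, centers, indexing="ij")
    t1, t2 = t1.ravel(), t2.ravel()
    keep = t1 + t2 < 1.0
    t1, t2 = t1[keep], t2[keep]
    t3 = 1.0 - t1 - t2
    a = np.asarray(alpha, dtype=float)
    logpdf = (
        (a[0] - 1) * np.log(t1)
        + (a[1] - 1) * np.log(t2)
        + (a[2] - 1) * np.log(t3)
        + gammaln(a.sum())
        - gammaln(a).sum()
    )
    w = np.exp(logpdf) * step * step
    w /= w.sum()
    return np.column_stack([t1, t2]), w


def utility_distribution(alpha, weight: float = 0.75, n: int = 600):
    """Discretized distribution (values, weights) of U = w*t2 + 1 - t1."""
    theta, w = _simplex_grid(np.asarray(alpha, float), n)
    u = weight * theta[:, 1] + 1.0 - theta[:, 0]
    order = np.argsort(u)
    return u[order], w[order]


def prob_first_arm_best(alpha_a, alpha_b, weight: float = 0.75, n: int = 600) -> float:
    """P(U_A > U_B) for independent Dirichlet posteriors, by quadrature.

    Ties on the discretized grid get half weight; their mass vanishes as
    the grid refines.
    """
    ua, wa = utility_distribution(alpha_a, weight, n)
    ub, wb = utility_distribution(alpha_b, weight, n)
    cum_b = np.concatenate([[0.0], np.cumsum(wb)])
    lo = np.searchsorted(ub, ua, side="left")
    hi = np.searchsorted(ub, ua, side="right")
    p_below = cum_b[lo]
    p_tie = cum_b[hi] - cum_b[lo]
    return float(np.sum(wa * (p_below + 0.5 * p_tie)))


def mc_utility_fourth_moment(alpha, weight: float = 0.75, n: int = 100_000, seed: int = 0):
    """Monte-Carlo central fourth moment of U (for variance standard errors)."""
    rng = np.random.default_rng(seed)
    th = rng.dirichlet(np.asarray(alpha, float), size=n)
    u = weight * th[:, 1] + 1.0 - th[:, 0]
    return float(np.mean((u - u.mean()) ** 4))


def variance_se(alpha, weight: float = 0.75, n_draws: int = 100_000) -> float:
    """Approximate SE of a sample variance of n_draws utility draws."""
    mu4 = mc_utility_fourth_moment(alpha, weight)
    from bayesrar import closed_form_utility_moments

    _, var = closed_form_utility_moments(alpha, weight)
    return float(np.sqrt(max(mu4 - var**2, 0.0) / n_draws))
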