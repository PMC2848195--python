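"""Independent oracles used by the unit and acceptance tests.

These deliberately avoid the package's own solvers: the constrained
least-squares check uses an accelerated projected-gradient method (valid for
coordinate sign constraints, where projection is clipping), and the model
search check uses exhaustive subset enumeration.
"""

from __future__ import annotations

import itertools

import numpy as np


def projected_gradient_lsq(
    design: np.ndarray,
    response: np.ndarray,
    nonneg_cols: set[int],
    max_iter: int = 20000,
    tol: float = 1e-12,
) -> np.ndarray:
    """FISTA on ||X - Phi theta||^2 with theta_j >= 0 for j in nonneg_cols."""
    phi = np.asarray(design, float)
    x = np.asarray(response, float)
    g = phi.T @ phi
    c = phi.T @ x
    lip = 2.0 * np.linalg.norm(g, 2)
    idx = sorted(nonneg_cols)

    def project(v):
        if idx:
            v = v.copy()
            v[idx] = np.maximum(v[idx], 0.0)
        return v

    theta = project(np.zeros(phi.shape[1]))
    z = theta.copy()
    t_k = 1.0
    for _ in range(max_iter):
        grad = 2.0 * (g @ z - c)
        theta_new = project(z - grad / lip)
        t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_k * t_k))
        z = theta_new + ((t_k - 1.0) / t_next) * (theta_new - theta)
        if np.linalg.norm(theta_new - theta) <= tol * (1.0 + np.linalg.norm(theta_new)):
            theta = theta_new
            break
        theta, t_k = theta_new, t_next
    return theta


def lsq_objective(design, response, theta) -> float:
    r = np.asarray(response) - np.asarray(design) @ theta
    return float(r @ r)


def random_sign_constrained_problem(rng, n_rows=40, max_params=6, n_constraints=None):
    """A random LS problem with 1-2 coordinate non-negativity constraints.

    Returns (design, response, nonneg column indices).  The response is
    shifted so the constraints frequently bind at the optimum.
    """
    p = int(rng.integers(2, max_params + 1))
    design = rng.normal(size=(n_rows, p))
    beta = rng.normal(size=p)
    response = design @ beta + rng.normal(scale=0.5, size=n_rows)
    m = n_constraints if n_constraints is not None else int(rng.integers(1, 3))
    cols = rng.choice(p, size=min(m, p), replace=False)
    return design, response, {int(j) for j in cols}


def exhaustive_min_aic(prob, mandatory, fit_subset, max_candidates=8):
    """Minimum AIC over all candidate-column subsets (brute force).

    ``fit_subset(prob, labels)`` must return an object with an ``aic``
    attribute; enumeration is the oracle for the stepwise search strategy.
    """
    mand = set(mandatory)
    cands = [lab for lab in prob.column_labels if lab not in mand]
    if len(cands) > max_candidates:
        raise ValueError("exhaustive oracle limited to small candidate sets")
    best = np.inf
    for r in range(len(cands) + 1):
        for combo in itertools.combinations(cands, r):
            try:
                fit = fit_subset(prob, mand | set(combo))
            except Exception:
                continue
            best = min(best, fit.aic)
    return best
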