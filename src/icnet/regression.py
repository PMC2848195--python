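"""Constrained least squares, AIC stepwise selection, and coefficient tests.

Each target node of the dynamic model yields one regression problem

    minimize ||response - design @ theta||^2   s.t.   A @ theta <= b,

where the inequality rows encode non-negativity of basal (and translation)
terms.  The solver is a textbook primal active-set method for convex QP:
at each iterate the equality-constrained subproblem over the current working
set is solved through its KKT system; a blocking constraint is added when a
full step is infeasible, and the constraint with the most negative Lagrange
multiplier is dropped when the subproblem optimum is reached.

Model structure is chosen per target by bidirectional greedy AIC descent
over the candidate-edge columns (mandatory columns — retention, basal,
translation — are never searched).  Retained edge coefficients are then
tested by two-sided Student t-tests with Bonferroni adjustment over the
per-target candidate family.
"""

from __future__ import annotations

import dataclasses
import math
from collections.abc import Sequence

import numpy as np
import scipy.linalg
from scipy import optimize, stats

AIC_PERFECT_FIT = -math.inf
# Per-observation threshold below which a fit counts as numerically perfect.
# Kept near float round-off so that small-but-real residual signals are never
# mistaken for an exact fit.
_RSS_ZERO_TOL = 1e-20


class RankDeficientError(ValueError):
    """Design matrix is rank deficient over the selected columns."""

    def __init__(self, columns: Sequence[str]):
        self.columns = list(columns)
        super().__init__(f"rank-deficient design; offending columns: {self.columns}")


class InfeasibleError(ValueError):
    """The constraint system A @ theta <= b has no solution."""


@dataclasses.dataclass
class RegressionProblem:
    """One target node's regression form of the dynamic model.

    ``constraints`` is a tuple of (row, bound) pairs encoding row @ theta <= bound.
    ``meta`` carries bookkeeping such as the translation-merge flag.
    """

    response: np.ndarray
    design: np.ndarray
    column_labels: tuple[str, ...]
    constraints: tuple[tuple[np.ndarray, float], ...] = ()
    meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.response = np.asarray(self.response, dtype=float).ravel()
        self.design = np.asarray(self.design, dtype=float)
        self.column_labels = tuple(self.column_labels)
        if self.design.ndim != 2:
            raise ValueError("design must be 2-D")
        if self.design.shape[0] != self.response.size:
            raise ValueError("design row count must match response length")
        if len(self.column_labels) != self.design.shape[1]:
            raise ValueError("one label per design column required")
        if len(set(self.column_labels)) != len(self.column_labels):
            raise ValueError("column labels must be unique")
        self.constraints = tuple(
            (np.asarray(r, dtype=float).ravel(), float(bnd)) for r, bnd in self.constraints
        )
        for row, _ in self.constraints:
            if row.size != self.design.shape[1]:
                raise ValueError("constraint row length must equal parameter count")

    @property
    def n_obs(self) -> int:
        return self.response.size

    @property
    def n_params(self) -> int:
        return self.design.shape[1]

    def subproblem(self, labels: Sequence[str]) -> "RegressionProblem":
        """Restrict to a subset of columns (kept in original column order).

        Constraint rows may only involve retained columns; a constraint with a
        nonzero entry on a dropped column cannot be projected and is an error.
        """
        keep = [lab for lab in self.column_labels if lab in set(labels)]
        idx = [self.column_labels.index(lab) for lab in keep]
        dropped = [i for i in range(self.n_params) if i not in set(idx)]
        new_cons = []
        for row, bnd in self.constraints:
            if any(abs(row[j]) > 0 for j in dropped):
                raise ValueError("constraint involves a dropped column")
            new_cons.append((row[idx], bnd))
        return RegressionProblem(
            self.response, self.design[:, idx], tuple(keep), tuple(new_cons), dict(self.meta)
        )


# ---------------------------------------------------------------------------
# active-set constrained least squares
# ---------------------------------------------------------------------------

def _check_rank(design: np.ndarray, labels: tuple[str, ...]) -> None:
    n, p = design.shape
    if p == 0:
        return
    _, r, piv = scipy.linalg.qr(design, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    ref = diag[0] if diag.size and diag[0] > 0 else 0.0
    rank = int(np.sum(diag > max(n, p) * np.finfo(float).eps * ref)) if ref else 0
    if rank < p:
        raise RankDeficientError([labels[j] for j in piv[rank:]])


def constrained_least_squares(
    prob: RegressionProblem, tol: float = 1e-10, max_iter: int | None = None
) -> tuple[np.ndarray, tuple[int, ...]]:
    """Solve min ||X - Phi theta||^2 subject to A theta <= b.

    Returns the minimizer and the indices of constraint rows binding at the
    solution.  When the unconstrained optimum is feasible it is returned
    directly (all constraints inactive).
    """
    _check_rank(prob.design, prob.column_labels)
    phi, x = prob.design, prob.response
    g = phi.T @ phi
    c = phi.T @ x
    m = len(prob.constraints)
    if m == 0:
        return np.linalg.solve(g, c) if prob.n_params else np.empty(0), ()
    a = np.vstack([row for row, _ in prob.constraints])
    b = np.array([bnd for _, bnd in prob.constraints])

    # unconstrained optimum shortcut
    theta = np.linalg.solve(g, c)
    if np.all(a @ theta <= b + tol):
        active = tuple(i for i in range(m) if abs(a[i] @ theta - b[i]) <= 1e-8)
        return theta, active

    # feasible start (theta = 0 covers the pipeline's sign constraints)
    theta = np.zeros(prob.n_params)
    if not np.all(a @ theta <= b + tol):
        res = optimize.linprog(
            np.zeros(prob.n_params), A_ub=a, b_ub=b, bounds=[(None, None)] * prob.n_params,
            method="highs",
        )
        if not res.success:
            raise InfeasibleError("constraint system is infeasible")
        theta = res.x
    working = [i for i in range(m) if a[i] @ theta >= b[i] - 1e-12]

    if max_iter is None:
        max_iter = 50 * (prob.n_params + m + 1)
    for _ in range(max_iter):
        aw = a[working]
        if working:
            k = aw.shape[0]
            kkt = np.block([[g, aw.T], [aw, np.zeros((k, k))]])
            rhs = np.concatenate([c, b[working]])
            sol = np.linalg.lstsq(kkt, rhs, rcond=None)[0]
            theta_star, lam = sol[: prob.n_params], sol[prob.n_params:]
        else:
            theta_star, lam = np.linalg.solve(g, c), np.empty(0)
        step = theta_star - theta
        if np.linalg.norm(step) <= tol * (1.0 + np.linalg.norm(theta_star)):
            if lam.size == 0 or lam.min() >= -tol:
                theta = theta_star
                break
            working.pop(int(np.argmin(lam)))
            continue
        # ratio test against constraints outside the working set
        alpha, blocking = 1.0, None
        for i in range(m):
            if i in working:
                continue
            denom = a[i] @ step
            if denom > tol:
                ratio = (b[i] - a[i] @ theta) / denom
                if ratio < alpha - 1e-12:
                    alpha, blocking = max(ratio, 0.0), i
        theta = theta + alpha * step
        if blocking is not None:
            working.append(blocking)
            working.sort()
    else:
        raise RuntimeError("active-set iteration limit reached")

    if not np.all(a @ theta <= b + 1e-9):
        raise RuntimeError("active-set solver returned an infeasible point")
    active = tuple(i for i in range(m) if abs(a[i] @ theta - b[i]) <= 1e-8)
    return theta, active


def kkt_residual(prob: RegressionProblem, theta: np.ndarray) -> float:
    """Stationarity residual: distance of -grad from the cone of active normals.

    Zero (to tolerance) iff theta satisfies the KKT conditions of the
    inequality-constrained least-squares problem.
    """
    phi, x = prob.design, prob.response
    grad = 2.0 * (phi.T @ (phi @ theta - x))
    active_rows = [
        row for row, bnd in prob.constraints if abs(row @ theta - bnd) <= 1e-7
    ]
    if not active_rows:
        return float(np.linalg.norm(grad))
    basis = np.array(active_rows).T  # grad + basis @ lam = 0, lam >= 0
    lam, res = optimize.nnls(basis, -grad)
    return float(res)


# ---------------------------------------------------------------------------
# AIC
# ---------------------------------------------------------------------------

def aic_score(rss: float, n_obs: int, n_params: int) -> float:
    """Least-squares AIC: n * ln(rss/n) + 2p (additive constants dropped).

    A numerically perfect fit (rss ~ 0) maps to -inf so that model search
    terminates at a minimal perfect model.
    """
    if rss < 0:
        raise ValueError("rss must be non-negative")
    if n_obs <= n_params:
        raise ValueError(f"need n_obs > n_params (got {n_obs} <= {n_params})")
    if rss < _RSS_ZERO_TOL * n_obs:
        return AIC_PERFECT_FIT
    return n_obs * math.log(rss / n_obs) + 2.0 * n_params


# ---------------------------------------------------------------------------
# fits and stepwise structure selection
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class FitResult:
    """Constrained fit of one column subset, with inference annotations.

    ``se``/``p_raw``/``p_adjusted`` are aligned with ``selected`` and are NaN
    until :func:`coefficient_pvalues` / :func:`bonferroni_adjust` fill them
    (only candidate-edge coefficients are tested in the pipeline).
    """

    selected: tuple[str, ...]
    theta: np.ndarray
    residuals: np.ndarray
    rss: float
    aic: float
    active_constraints: tuple[int, ...]
    n_obs: int
    se: np.ndarray = dataclasses.field(default=None)  # type: ignore[assignment]
    p_raw: np.ndarray = dataclasses.field(default=None)  # type: ignore[assignment]
    p_adjusted: np.ndarray = dataclasses.field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        p = len(self.selected)
        for field in ("se", "p_raw", "p_adjusted"):
            if getattr(self, field) is None:
                setattr(self, field, np.full(p, np.nan))

    def coef(self, label: str) -> float:
        return float(self.theta[self.selected.index(label)])

    def __getitem__(self, label: str) -> float:
        return self.coef(label)


def _fit_subset(prob: RegressionProblem, labels: Sequence[str]) -> FitResult:
    sub = prob.subproblem(labels)
    theta, active = constrained_least_squares(sub)
    resid = sub.response - sub.design @ theta
    rss = float(resid @ resid)
    return FitResult(
        selected=sub.column_labels,
        theta=theta,
        residuals=resid,
        rss=rss,
        aic=aic_score(rss, sub.n_obs, sub.n_params),
        active_constraints=active,
        n_obs=sub.n_obs,
    )


def _move_key(aic: float, labels: frozenset) -> tuple:
    # deterministic ordering: AIC, then model size, then lexicographic labels
    return (aic, len(labels), tuple(sorted(labels)))


def _improves(move_aic: float, move_set: frozenset, cur_aic: float, cur_set: frozenset) -> bool:
    if move_aic < cur_aic:
        return True
    # at a perfect fit, shrinking while staying perfect is an improvement
    return (
        math.isinf(cur_aic) and math.isinf(move_aic)
        and cur_aic < 0 and move_aic < 0 and len(move_set) < len(cur_set)
    )


def stepwise_select(
    prob: RegressionProblem, mandatory: Sequence[str] = ()
) -> FitResult:
    """Bidirectional greedy AIC search over the candidate (non-mandatory) columns.

    From the current set, every single addition and single removal of a
    candidate column is evaluated by a constrained refit; the move with the
    lowest AIC is taken while it strictly improves.  The descent starts from
    the mandatory-only set; only if its endpoint scores worse than the full
    model does a second descent start from the full set, so the final AIC
    never exceeds either baseline while the search stays parsimonious.
    Ties are broken toward the smaller model, then lexicographically.
    """
    mand = frozenset(mandatory)
    if not mand <= set(prob.column_labels):
        raise ValueError("mandatory labels must be a subset of column labels")
    candidates = [lab for lab in prob.column_labels if lab not in mand]
    cache: dict[frozenset, FitResult | None] = {}

    def evaluate(subset: frozenset) -> FitResult | None:
        if subset not in cache:
            try:
                cache[subset] = _fit_subset(prob, subset)
            except RankDeficientError:
                cache[subset] = None  # unusable subset, never selected
        return cache[subset]

    def greedy(start: frozenset) -> tuple[frozenset, FitResult] | None:
        cur_fit = evaluate(start)
        if cur_fit is None:
            return None
        cur = start
        while True:
            best = None
            for col in candidates:
                cand_set = cur - {col} if col in cur else cur | {col}
                fit = evaluate(cand_set)
                if fit is None:
                    continue
                key = _move_key(fit.aic, cand_set)
                if best is None or key < best[0]:
                    best = (key, cand_set, fit)
            if best is None or not _improves(best[2].aic, best[1], cur_fit.aic, cur):
                return cur, cur_fit
            cur, cur_fit = best[1], best[2]

    full_set = frozenset(prob.column_labels)
    results = []
    primary = greedy(mand)
    if primary is not None:
        results.append(primary)
    full_fit = evaluate(full_set)
    needs_full_descent = primary is None or (
        full_fit is not None and full_fit.aic < primary[1].aic
    )
    if needs_full_descent:
        out = greedy(full_set)
        if out is not None:
            results.append(out)
    if not results:
        raise RankDeficientError(list(prob.column_labels))
    final_set, final_fit = min(results, key=lambda r: _move_key(r[1].aic, r[0]))
    return final_fit


# ---------------------------------------------------------------------------
# inference on retained coefficients
# ---------------------------------------------------------------------------

def coefficient_pvalues(
    prob: RegressionProblem, fit: FitResult
) -> FitResult:
    """Two-sided Student t p-values for the fitted coefficients (in place).

    Standard errors come from the unconstrained covariance formula on the
    selected columns, sigma^2 (Phi' Phi)^-1 with sigma^2 = rss / df,
    df = n_obs - p_selected.
    """
    sub = prob.subproblem(fit.selected)
    n, p = sub.n_obs, sub.n_params
    df = n - p
    if df < 1:
        raise ValueError(f"non-positive degrees of freedom ({n} obs, {p} params)")
    sigma2 = fit.rss / df
    cov = sigma2 * np.linalg.inv(sub.design.T @ sub.design)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, fit.theta / se, np.where(fit.theta == 0, 0.0, np.inf))
    p_raw = 2.0 * stats.t.sf(np.abs(t), df)
    fit.se = se
    fit.p_raw = p_raw
    return fit


def bonferroni_adjust(p_raw: np.ndarray | Sequence[float], family_size: int) -> np.ndarray:
    """Bonferroni adjustment: p_adj = min(1, family_size * p), order preserved."""
    p = np.asarray(p_raw, dtype=float)
    finite = p[np.isfinite(p)]
    if finite.size and (finite.min() < 0 or finite.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if family_size < p.size:
        raise ValueError("family size must be at least the number of p-values")
    return np.minimum(1.0, family_size * p)
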