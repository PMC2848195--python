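"""Transcription sub-network: per-gene dynamic model fitting and pruning.

Each target gene i follows the discrete-time model

    x_i[t+1] = sum_j a_ij z_j[t] + (1 - lambda_i) x_i[t] + k_i + eps_i[t],

where x_i is the (linear-scale) mRNA level, a_ij the signed regulatory
ability of TF j (positive = activation, negative = repression), lambda_i the
degradation effect, and k_i >= 0 the basal transcription level.  The
regulation function z_j is a logistic sigmoid of TF j's activity,

    z_j[t] = 1 / (1 + exp(-(y_j[t] - mu_j) / sigma_j)),

a saturable (Hill-type) binding effect; mu_j and sigma_j are the sample mean
and standard deviation of the TF's activity profile.  TF cooperativity is
deliberately not modeled.

Candidate regulators of each gene are screened by AIC stepwise selection and
Bonferroni-corrected t-tests; only significant regulations survive.
"""

from __future__ import annotations

import dataclasses
import logging
from collections.abc import Iterable, Sequence

import numpy as np
from scipy.special import expit

from .data_io import LINEAR, CandidateNetwork, ExpressionMatrix
from .regression import (
    FitResult,
    RegressionProblem,
    bonferroni_adjust,
    coefficient_pvalues,
    stepwise_select,
)

logger = logging.getLogger(__name__)

#: columns never subject to stepwise search in a gene problem
GENE_MANDATORY = ("retention", "basal")

EDGE_PREFIX = "a:"


@dataclasses.dataclass
class SigmoidParams:
    """Per-TF logistic parameters: activity mean ``mu`` and deviation ``sigma``."""

    mu: dict[str, float]
    sigma: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.mu) != set(self.sigma):
            raise ValueError("mu and sigma must cover the same TFs")
        for tf, s in self.sigma.items():
            if s < 0:
                raise ValueError(f"sigma for {tf!r} must be >= 0")


def sigmoid_activation(y, mu: float, sigma: float):
    """Regulation function z in (0, 1); sigma = 0 degenerates to 0.5."""
    y = np.asarray(y, dtype=float)
    if sigma == 0:
        out = np.full_like(y, 0.5)
        return float(out) if out.ndim == 0 else out
    z = expit((y - mu) / sigma)
    return float(z) if z.ndim == 0 else z


def estimate_sigmoid_params(expr: ExpressionMatrix, tf_ids: Iterable[str]) -> SigmoidParams:
    """Sample mean / sd (denominator L-1) of each TF profile on the fitting grid."""
    if expr.scale != LINEAR or not expr.is_complete:
        raise ValueError("sigmoid parameters require a complete linear-scale matrix")
    mu, sigma = {}, {}
    for tf in tf_ids:
        prof = expr.row(tf)  # KeyError names the TF if absent
        mu[tf] = float(np.mean(prof))
        sigma[tf] = float(np.std(prof, ddof=1)) if prof.size > 1 else 0.0
    return SigmoidParams(mu, sigma)


def build_gene_problem(
    target: str,
    tf_ids: Sequence[str],
    expr: ExpressionMatrix,
    sigmoid: SigmoidParams,
) -> RegressionProblem:
    """Regression form of the gene model over the (densified) grid.

    Response rows are x_i[t+1]; design columns are the TF regulation
    functions z_j[t], the retention term x_i[t] and a basal intercept, with
    parameter order (a_i1..a_iN, 1 - lambda_i, k_i).  One inequality row
    enforces k_i >= 0.
    """
    if expr.scale != LINEAR or not expr.is_complete:
        raise ValueError("gene problems require a complete linear-scale matrix")
    n_tf = len(tf_ids)
    big_l = expr.n_times
    if big_l < n_tf + 4:
        raise ValueError(
            f"target {target!r}: {big_l} time points insufficient for {n_tf} TFs"
        )
    x = expr.row(target)
    cols = [sigmoid_activation(expr.row(tf), sigmoid.mu[tf], sigmoid.sigma[tf])[:-1]
            for tf in tf_ids]
    cols.append(x[:-1])
    cols.append(np.ones(big_l - 1))
    design = np.column_stack(cols)
    labels = tuple(EDGE_PREFIX + tf for tf in tf_ids) + GENE_MANDATORY
    k_row = np.zeros(design.shape[1])
    k_row[-1] = -1.0  # -k_i <= 0
    return RegressionProblem(
        response=x[1:],
        design=design,
        column_labels=labels,
        constraints=((k_row, 0.0),),
        meta={"target": target, "kind": "gene"},
    )


@dataclasses.dataclass
class GeneModelFit:
    """Fitted gene model with the significance verdict per candidate regulator."""

    target: str
    candidates: tuple[str, ...]         # candidate TFs (the Bonferroni family)
    regulators: tuple[str, ...]         # TFs surviving selection + significance
    a: dict[str, float]                 # coefficients of stepwise-selected TFs
    lambda_: float                      # degradation effect = 1 - retention coef
    k: float                            # basal level (constrained >= 0)
    p_raw: dict[str, float]
    p_adj: dict[str, float]
    se: dict[str, float]
    fit: FitResult | None = None
    aic: float = float("nan")

    def __post_init__(self) -> None:
        if self.fit is not None:
            self.aic = self.fit.aic

    @property
    def selected(self) -> tuple[str, ...]:
        """TFs retained by the AIC search (before the significance test)."""
        return tuple(sorted(self.a))


@dataclasses.dataclass
class GeneNetworkResult:
    fits: list[GeneModelFit]
    pruned_edges: list[tuple[str, str]]  # (TF, gene) kept as significant
    n_candidate_edges: int
    failures: dict[str, str]

    @property
    def preserved_fraction(self) -> float:
        if self.n_candidate_edges == 0:
            return 0.0
        return len(self.pruned_edges) / self.n_candidate_edges

    @property
    def preserved_percent(self) -> float:
        return 100.0 * self.preserved_fraction


def fit_gene_model(
    target: str,
    tf_ids: Sequence[str],
    expr: ExpressionMatrix,
    sigmoid: SigmoidParams,
    alpha: float = 0.05,
) -> GeneModelFit:
    """Fit one gene: stepwise AIC over candidate TFs, then Bonferroni t-tests."""
    prob = build_gene_problem(target, tf_ids, expr, sigmoid)
    fit = stepwise_select(prob, GENE_MANDATORY)
    coefficient_pvalues(prob, fit)
    edge_labels = [lab for lab in fit.selected if lab.startswith(EDGE_PREFIX)]
    idx = [fit.selected.index(lab) for lab in edge_labels]
    p_raw_vec = fit.p_raw[idx]
    p_adj_vec = bonferroni_adjust(p_raw_vec, max(len(tf_ids), 1))
    for j, lab in zip(idx, edge_labels):
        fit.p_adjusted[j] = p_adj_vec[edge_labels.index(lab)]
    tf_of = {EDGE_PREFIX + tf: tf for tf in tf_ids}
    a = {tf_of[lab]: fit.coef(lab) for lab in edge_labels}
    p_raw = {tf_of[lab]: float(p) for lab, p in zip(edge_labels, p_raw_vec)}
    p_adj = {tf_of[lab]: float(p) for lab, p in zip(edge_labels, p_adj_vec)}
    se = {tf_of[lab]: float(fit.se[j]) for lab, j in zip(edge_labels, idx)}
    kept = tuple(sorted(tf for tf in p_adj if p_adj[tf] <= alpha))
    k_val = fit.coef("basal")
    return GeneModelFit(
        target=target,
        candidates=tuple(tf_ids),
        regulators=kept,
        a=a,
        lambda_=1.0 - fit.coef("retention"),
        k=max(k_val, 0.0) if k_val > -1e-9 else k_val,
        p_raw=p_raw,
        p_adj=p_adj,
        se=se,
        fit=fit,
    )


def fit_gene_network(
    candidates: CandidateNetwork,
    expr: ExpressionMatrix,
    alpha: float = 0.05,
    targets: Sequence[str] | None = None,
    sigmoid: SigmoidParams | None = None,
) -> GeneNetworkResult:
    """Fit every target gene in the candidate pool (gene-by-gene strategy).

    Per-gene failures are logged and skipped, never fatal.  The Bonferroni
    family for a gene is its own number of candidate regulators.
    """
    if targets is None:
        targets = sorted(candidates.target_ids)
    if sigmoid is None:
        tf_universe = sorted(candidates.tf_ids & set(expr.node_ids))
        sigmoid = estimate_sigmoid_params(expr, tf_universe)
    fits: list[GeneModelFit] = []
    pruned: list[tuple[str, str]] = []
    failures: dict[str, str] = {}
    for target in targets:
        tf_ids = [tf for tf in candidates.regulators_of(target) if tf in expr]
        if target not in expr:
            failures[target] = "target absent from expression matrix"
            logger.warning("skipping gene %s: not in expression matrix", target)
            continue
        try:
            gm = fit_gene_model(target, tf_ids, expr, sigmoid, alpha=alpha)
        except Exception as exc:  # per-gene robustness by contract
            failures[target] = str(exc)
            logger.warning("skipping gene %s: %s", target, exc)
            continue
        fits.append(gm)
        pruned.extend((tf, target) for tf in gm.regulators)
    return GeneNetworkResult(
        fits=fits,
        pruned_edges=pruned,
        n_candidate_edges=len(candidates.tf_gene_edges),
        failures=failures,
    )


_REPORT_COLS = (
    "target", "regulator", "a", "se", "p_raw", "p_adj", "selected", "kept",
    "lambda", "k", "aic",
)


def write_gene_report(result: GeneNetworkResult, path) -> None:
    """Fit report TSV: one row per candidate edge of every fitted gene."""
    with open(path, "w") as fh:
        fh.write("\t".join(_REPORT_COLS) + "\n")
        for gm in result.fits:
            for tf in gm.candidates:
                sel = tf in gm.a
                fh.write(
                    "\t".join([
                        gm.target, tf,
                        f"{gm.a.get(tf, 0.0):.10g}",
                        f"{gm.se.get(tf, float('nan')):.6g}",
                        f"{gm.p_raw.get(tf, float('nan')):.6g}",
                        f"{gm.p_adj.get(tf, float('nan')):.6g}",
                        str(int(sel)), str(int(tf in gm.regulators)),
                        f"{gm.lambda_:.10g}", f"{gm.k:.10g}", f"{gm.aic:.6g}",
                    ]) + "\n"
                )
            if not gm.candidates:  # gene with no candidate TFs: still report the fit
                fh.write(
                    "\t".join([
                        gm.target, ".", "0", "nan", "nan", "nan", "0", "0",
                        f"{gm.lambda_:.10g}", f"{gm.k:.10g}", f"{gm.aic:.6g}",
                    ]) + "\n"
                )


def write_sigmoid_params(sigmoid: SigmoidParams, path) -> None:
    with open(path, "w") as fh:
        fh.write("tf\tmu\tsigma\n")
        for tf in sorted(sigmoid.mu):
            fh.write(f"{tf}\t{sigmoid.mu[tf]:.10g}\t{sigmoid.sigma[tf]:.10g}\n")


def read_sigmoid_params(path) -> SigmoidParams:
    mu, sigma = {}, {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("tf\t"):
            raise ValueError(f"{path}: not a sigmoid parameter table")
        for line in fh:
            tf, m, s = line.rstrip("\n").split("\t")
            mu[tf], sigma[tf] = float(m), float(s)
    return SigmoidParams(mu, sigma)


def read_gene_report(path) -> GeneNetworkResult:
    """Rebuild a :class:`GeneNetworkResult` from a fit-report TSV."""
    rows: dict[str, list[dict]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != _REPORT_COLS:
            raise ValueError(f"{path}: unexpected gene report header")
        for line in fh:
            vals = dict(zip(_REPORT_COLS, line.rstrip("\n").split("\t")))
            rows.setdefault(vals["target"], []).append(vals)
    fits, pruned, n_cand = [], [], 0
    for target, recs in rows.items():
        cand = [r["regulator"] for r in recs if r["regulator"] != "."]
        n_cand += len(cand)
        sel = {r["regulator"]: float(r["a"]) for r in recs if r["selected"] == "1"}
        kept = tuple(sorted(r["regulator"] for r in recs if r["kept"] == "1"))
        fits.append(GeneModelFit(
            target=target, candidates=tuple(cand), regulators=kept, a=sel,
            lambda_=float(recs[0]["lambda"]), k=float(recs[0]["k"]),
            p_raw={r["regulator"]: float(r["p_raw"]) for r in recs if r["selected"] == "1"},
            p_adj={r["regulator"]: float(r["p_adj"]) for r in recs if r["selected"] == "1"},
            se={r["regulator"]: float(r["se"]) for r in recs if r["selected"] == "1"},
            aic=float(recs[0]["aic"]),
        ))
        pruned.extend((tf, target) for tf in kept)
    return GeneNetworkResult(
        fits=fits, pruned_edges=pruned, n_candidate_edges=n_cand, failures={}
    )
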