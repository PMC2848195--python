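"""Signaling sub-network: per-protein bilinear model fitting and pruning.

Each target protein n follows

    y_n[t+1] = sum_m b_nm y_n[t] y_m[t] + alpha_n x_n[t]
               + (1 - beta_n) y_n[t] + h_n + omega_n[t],

with y the protein activity, x_n the mRNA of the protein's gene, alpha_n >= 0
the translation effect, beta_n the degradation effect and h_n >= 0 the basal
activity.  The interaction regressor is the product y_n * y_m (mass-action
collision kinetics, e.g. kinase-substrate phosphorylation), and the sign of
b_nm carries no activation/repression meaning; preserved interactions are
undirected.

Because genome-wide activity measurements are rarely available, activity
profiles may be substituted by mRNA profiles (:func:`substitute_activity`).
Under that substitution the translation column x_n[t] and the retention
column y_n[t] are identical, so the builder merges them into a single
combined-retention column (coefficient alpha_n + 1 - beta_n); alpha and beta
are then not separately identifiable and are reported as ``None``.
"""

from __future__ import annotations

import dataclasses
import logging
from collections.abc import Sequence

import numpy as np

from .data_io import LINEAR, CandidateNetwork, ExpressionMatrix, canonical_pair
from .regression import (
    FitResult,
    RegressionProblem,
    bonferroni_adjust,
    coefficient_pvalues,
    stepwise_select,
)

logger = logging.getLogger(__name__)

EDGE_PREFIX = "b:"
PROTEIN_MANDATORY_FULL = ("translation", "retention", "basal")
PROTEIN_MANDATORY_MERGED = ("retention", "basal")

PRESERVATION_RULES = ("union", "intersection")


def substitute_activity(
    mrna: ExpressionMatrix, protein_ids: Sequence[str]
) -> tuple[ExpressionMatrix, list[tuple[str, str]]]:
    """Use each protein's mRNA profile as its activity profile.

    Returns the activity matrix and a provenance log of (protein, gene)
    substitutions (identity mapping here: one gene per protein id).
    """
    if mrna.scale != LINEAR or not mrna.is_complete:
        raise ValueError("substitution requires a complete linear-scale matrix")
    missing = [p for p in protein_ids if p not in mrna]
    if missing:
        raise KeyError(f"proteins with no mRNA profile: {missing}")
    activity = mrna.subset(list(protein_ids))
    provenance = [(p, p) for p in protein_ids]
    return activity, provenance


def build_protein_problem(
    target: str,
    partner_ids: Sequence[str],
    activity: ExpressionMatrix,
    mrna: ExpressionMatrix,
    merge_tol: float = 1e-12,
) -> RegressionProblem:
    """Regression form of the protein model over the (densified) grid.

    Response rows are y_n[t+1]; design columns are the bilinear products
    y_n[t]*y_m[t], the translation term x_n[t], the retention term y_n[t] and
    a basal intercept, parameter order (b_n1..b_nM, alpha_n, 1 - beta_n, h_n),
    with inequality rows alpha_n >= 0 and h_n >= 0.  If the target's activity
    and mRNA profiles coincide (mRNA substitution), the translation and
    retention columns are merged and only h_n >= 0 is enforced.
    """
    for mat, name in ((activity, "activity"), (mrna, "mRNA")):
        if mat.scale != LINEAR or not mat.is_complete:
            raise ValueError(f"protein problems require a complete linear {name} matrix")
    if target not in activity:
        raise KeyError(f"protein {target!r} absent from activity matrix")
    if target not in mrna:
        raise KeyError(f"protein {target!r} absent from mRNA matrix")
    y = activity.row(target)
    x = mrna.row(target)
    m = len(partner_ids)
    big_l = activity.n_times
    if big_l < m + 5:
        raise ValueError(
            f"target {target!r}: {big_l} time points insufficient for {m} partners"
        )
    cols = [y[:-1] * activity.row(p)[:-1] for p in partner_ids]
    merged = bool(np.max(np.abs(x - y), initial=0.0) <= merge_tol)
    if merged:
        cols.append(y[:-1])
        cols.append(np.ones(big_l - 1))
        labels = tuple(EDGE_PREFIX + p for p in partner_ids) + PROTEIN_MANDATORY_MERGED
        h_row = np.zeros(len(cols))
        h_row[-1] = -1.0
        constraints = ((h_row, 0.0),)
    else:
        cols.append(x[:-1])
        cols.append(y[:-1])
        cols.append(np.ones(big_l - 1))
        labels = tuple(EDGE_PREFIX + p for p in partner_ids) + PROTEIN_MANDATORY_FULL
        p_total = len(cols)
        alpha_row = np.zeros(p_total)
        alpha_row[-3] = -1.0
        h_row = np.zeros(p_total)
        h_row[-1] = -1.0
        constraints = ((alpha_row, 0.0), (h_row, 0.0))
    return RegressionProblem(
        response=y[1:],
        design=np.column_stack(cols),
        column_labels=labels,
        constraints=constraints,
        meta={"target": target, "kind": "protein", "translation_merged": merged},
    )


@dataclasses.dataclass
class ProteinModelFit:
    """Fitted protein model; ``alpha``/``beta`` are None when the translation
    column was merged into retention (mRNA-substitution mode)."""

    target: str
    candidates: tuple[str, ...]
    partners: tuple[str, ...]            # significant in THIS fit
    b: dict[str, float]                  # coefficients of selected partners
    alpha: float | None
    beta: float | None
    retention: float                     # 1 - beta, or alpha + 1 - beta when merged
    h: float
    merged: bool
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
        return tuple(sorted(self.b))


@dataclasses.dataclass
class ProteinNetworkResult:
    fits: list[ProteinModelFit]
    pruned_edges: list[tuple[str, str]]  # canonical undirected pairs preserved
    n_candidate_edges: int
    edge_verdicts: dict[tuple[str, str], dict[str, bool]]  # per-target significance
    failures: dict[str, str]

    @property
    def preserved_fraction(self) -> float:
        if self.n_candidate_edges == 0:
            return 0.0
        return len(self.pruned_edges) / self.n_candidate_edges

    @property
    def preserved_percent(self) -> float:
        return 100.0 * self.preserved_fraction


def fit_protein_model(
    target: str,
    partner_ids: Sequence[str],
    activity: ExpressionMatrix,
    mrna: ExpressionMatrix,
    alpha_level: float = 0.05,
) -> ProteinModelFit:
    """Fit one protein: stepwise AIC over partners, then Bonferroni t-tests."""
    prob = build_protein_problem(target, partner_ids, activity, mrna)
    merged = prob.meta["translation_merged"]
    mandatory = PROTEIN_MANDATORY_MERGED if merged else PROTEIN_MANDATORY_FULL
    fit = stepwise_select(prob, mandatory)
    coefficient_pvalues(prob, fit)
    edge_labels = [lab for lab in fit.selected if lab.startswith(EDGE_PREFIX)]
    idx = [fit.selected.index(lab) for lab in edge_labels]
    p_raw_vec = fit.p_raw[idx]
    p_adj_vec = bonferroni_adjust(p_raw_vec, max(len(partner_ids), 1))
    for j, padj in zip(idx, p_adj_vec):
        fit.p_adjusted[j] = padj
    partner_of = {EDGE_PREFIX + p: p for p in partner_ids}
    b = {partner_of[lab]: fit.coef(lab) for lab in edge_labels}
    p_raw = {partner_of[lab]: float(v) for lab, v in zip(edge_labels, p_raw_vec)}
    p_adj = {partner_of[lab]: float(v) for lab, v in zip(edge_labels, p_adj_vec)}
    se = {partner_of[lab]: float(fit.se[j]) for lab, j in zip(edge_labels, idx)}
    kept = tuple(sorted(p for p in p_adj if p_adj[p] <= alpha_level))
    h_val = fit.coef("basal")
    if merged:
        alpha_val, beta_val = None, None
    else:
        a = fit.coef("translation")
        alpha_val = max(a, 0.0) if a > -1e-9 else a
        beta_val = 1.0 - fit.coef("retention")
    return ProteinModelFit(
        target=target,
        candidates=tuple(partner_ids),
        partners=kept,
        b=b,
        alpha=alpha_val,
        beta=beta_val,
        retention=fit.coef("retention"),
        h=max(h_val, 0.0) if h_val > -1e-9 else h_val,
        merged=merged,
        p_raw=p_raw,
        p_adj=p_adj,
        se=se,
        fit=fit,
    )


def fit_protein_network(
    candidates: CandidateNetwork,
    activity: ExpressionMatrix,
    mrna: ExpressionMatrix,
    alpha: float = 0.05,
    rule: str = "union",
    targets: Sequence[str] | None = None,
) -> ProteinNetworkResult:
    """Fit every protein incident to a candidate interaction (protein-by-protein).

    Every candidate pair {n, m} appears as a regressor in both n's and m's
    problems.  Under the default "union" rule the undirected edge is preserved
    iff it is significant in at least one of the two fits; "intersection"
    requires both.  Per-protein failures are logged and skipped.
    """
    if rule not in PRESERVATION_RULES:
        raise ValueError(f"rule must be one of {PRESERVATION_RULES}")
    if targets is None:
        targets = sorted(candidates.protein_ids)
    fits: list[ProteinModelFit] = []
    failures: dict[str, str] = {}
    sig: dict[str, dict[str, bool]] = {}
    for target in targets:
        partner_ids = [p for p in candidates.partners_of(target) if p in activity]
        if target not in activity:
            failures[target] = "target absent from activity matrix"
            logger.warning("skipping protein %s: not in activity matrix", target)
            continue
        try:
            pm = fit_protein_model(target, partner_ids, activity, mrna, alpha_level=alpha)
        except Exception as exc:
            failures[target] = str(exc)
            logger.warning("skipping protein %s: %s", target, exc)
            continue
        fits.append(pm)
        sig[target] = {p: (p in pm.partners) for p in partner_ids}
    verdicts: dict[tuple[str, str], dict[str, bool]] = {}
    pruned: list[tuple[str, str]] = []
    for a, b_node in candidates.ppi_edges:
        pair = canonical_pair(a, b_node)
        v = {
            a: sig.get(a, {}).get(b_node, False),
            b_node: sig.get(b_node, {}).get(a, False),
        }
        verdicts[pair] = v
        preserved = any(v.values()) if rule == "union" else all(v.values())
        if preserved:
            pruned.append(pair)
    return ProteinNetworkResult(
        fits=fits,
        pruned_edges=pruned,
        n_candidate_edges=len(candidates.ppi_edges),
        edge_verdicts=verdicts,
        failures=failures,
    )


_REPORT_COLS = (
    "target", "partner", "b", "se", "p_raw", "p_adj", "selected",
    "kept_in_this_fit", "alpha", "beta", "retention", "h", "aic",
)


def write_protein_report(result: ProteinNetworkResult, path) -> None:
    """Fit report TSV: one row per candidate partner of every fitted protein."""
    def _opt(v):
        return "." if v is None else f"{v:.10g}"

    with open(path, "w") as fh:
        fh.write("\t".join(_REPORT_COLS) + "\n")
        for pm in result.fits:
            for p in pm.candidates:
                fh.write(
                    "\t".join([
                        pm.target, p,
                        f"{pm.b.get(p, 0.0):.10g}",
                        f"{pm.se.get(p, float('nan')):.6g}",
                        f"{pm.p_raw.get(p, float('nan')):.6g}",
                        f"{pm.p_adj.get(p, float('nan')):.6g}",
                        str(int(p in pm.b)), str(int(p in pm.partners)),
                        _opt(pm.alpha), _opt(pm.beta),
                        f"{pm.retention:.10g}", f"{pm.h:.10g}", f"{pm.aic:.6g}",
                    ]) + "\n"
                )


def write_ppi_summary(result: ProteinNetworkResult, path) -> None:
    """Undirected-edge summary TSV with the per-side verdicts and the outcome."""
    with open(path, "w") as fh:
        fh.write("node_a\tnode_b\tsig_in_a\tsig_in_b\tpreserved\n")
        preserved = set(result.pruned_edges)
        for (a, b), v in sorted(result.edge_verdicts.items()):
            fh.write(
                f"{a}\t{b}\t{int(v.get(a, False))}\t{int(v.get(b, False))}"
                f"\t{int((a, b) in preserved)}\n"
            )


def read_protein_report(report_path, summary_path) -> ProteinNetworkResult:
    """Rebuild a :class:`ProteinNetworkResult` from report + summary TSVs."""
    rows: dict[str, list[dict]] = {}
    with open(report_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != _REPORT_COLS:
            raise ValueError(f"{report_path}: unexpected protein report header")
        for line in fh:
            vals = dict(zip(_REPORT_COLS, line.rstrip("\n").split("\t")))
            rows.setdefault(vals["target"], []).append(vals)
    fits = []
    for target, recs in rows.items():
        merged = recs[0]["alpha"] == "."
        fits.append(ProteinModelFit(
            target=target,
            candidates=tuple(r["partner"] for r in recs),
            partners=tuple(sorted(r["partner"] for r in recs if r["kept_in_this_fit"] == "1")),
            b={r["partner"]: float(r["b"]) for r in recs if r["selected"] == "1"},
            alpha=None if merged else float(recs[0]["alpha"]),
            beta=None if merged else float(recs[0]["beta"]),
            retention=float(recs[0]["retention"]),
            h=float(recs[0]["h"]),
            merged=merged,
            p_raw={r["partner"]: float(r["p_raw"]) for r in recs if r["selected"] == "1"},
            p_adj={r["partner"]: float(r["p_adj"]) for r in recs if r["selected"] == "1"},
            se={r["partner"]: float(r["se"]) for r in recs if r["selected"] == "1"},
            aic=float(recs[0]["aic"]),
        ))
    verdicts: dict[tuple[str, str], dict[str, bool]] = {}
    pruned: list[tuple[str, str]] = []
    with open(summary_path) as fh:
        header = fh.readline().rstrip("\n")
        if header != "node_a\tnode_b\tsig_in_a\tsig_in_b\tpreserved":
            raise ValueError(f"{summary_path}: unexpected PPI summary header")
        for line in fh:
            a, b, sa, sb, pres = line.rstrip("\n").split("\t")
            pair = canonical_pair(a, b)
            verdicts[pair] = {a: sa == "1", b: sb == "1"}
            if pres == "1":
                pruned.append(pair)
    return ProteinNetworkResult(
        fits=fits, pruned_edges=pruned, n_candidate_edges=len(verdicts),
        edge_verdicts=verdicts, failures={},
    )
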