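"""Forward simulation, synthetic scenario generation, and knockout prediction.

The coupled system is stepped synchronously: gene mRNA levels x and protein
activity levels y are both read at time t and written at t+1,

    x_i[t+1] = sum_j a_ij f_j(y_j[t]) + r_i x_i[t] + k_i + eps_i[t]
    y_n[t+1] = sum_m b_nm y_n[t] y_m[t] + alpha_n x_n[t] + r_n y_n[t] + h_n + omega_n[t]

with r the retention coefficient (1 minus the degradation effect), additive
Gaussian noise on the linear scale, and negative states clipped at zero
(clipping events are counted).  TF activities feed the gene layer through the
sigmoid regulation functions, making TFs the interface between the two
layers.

The synthetic scenario generator emulates a stress-response experiment: a
transient relaxing from displaced initial states, simulated on a fine time
grid and observed on a coarser one, with decoy candidate edges added around
the true network.  Because the inference pipeline substitutes mRNA for
protein activity, the generated protein-layer ground truth uses the
identifiable merged dynamics (translation absorbed into retention); systems
with an explicit translation term can still be built and simulated directly.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import math
from collections.abc import Mapping, Sequence
from pathlib import Path

import numpy as np

from .data_io import (
    LINEAR,
    CandidateNetwork,
    ExpressionMatrix,
    canonical_pair,
    linear_to_log2,
    write_annotations,
    write_edge_list,
    write_expression,
)
from .gene_network import SigmoidParams, sigmoid_activation

KNOCKOUT_SEMANTICS = ("clamp", "hard_zero")

#: linear-scale floor applied before writing log2 expression files
LOG_FLOOR = 1e-6

# Scenario-generator kinetic defaults (rationale in docs/methods.md):
# slow protein turnover keeps the relaxation transient exciting over the
# whole course; the interaction budget (sum of |b| per target) sets the
# bilinear gain; the basal range positions the linear fixed point.
PROTEIN_RETENTION_RANGE = (0.4, 0.9)
TF_RETENTION_RANGE = (0.7, 0.95)
#: per-target sum of |b|, in units of the retention margin (1 - rho)
PROTEIN_INTERACTION_BUDGET = 3.0
PROTEIN_INTERACTION_MAG_RANGE = (0.7, 1.0)
PROTEIN_BASAL_LEVEL_RANGE = (0.4, 0.8)
#: activity ceiling for the stability rejection loop
ACTIVITY_CEILING = 10.0


@dataclasses.dataclass
class GeneDynamics:
    """x[t+1] = a . z(regulators) + retention * x + k."""

    regulators: tuple[str, ...]
    a: np.ndarray
    retention: float
    k: float


@dataclasses.dataclass
class ProteinDynamics:
    """y[t+1] = sum b_m y y_m + translation * x(mrna_source) + retention * y + h.

    ``mrna_source`` is None when the translation term is absorbed into the
    retention coefficient (the merged, substitution-identifiable form).
    """

    partners: tuple[str, ...]
    b: np.ndarray
    retention: float
    h: float
    translation: float = 0.0
    mrna_source: str | None = None


@dataclasses.dataclass
class CoupledSystem:
    """Parameterized dynamic equations of both layers plus the TF sigmoids."""

    gene: dict[str, GeneDynamics]
    protein: dict[str, ProteinDynamics]
    sigmoid: SigmoidParams

    @property
    def gene_ids(self) -> list[str]:
        return list(self.gene)

    @property
    def protein_ids(self) -> list[str]:
        return list(self.protein)

    @property
    def tf_ids(self) -> list[str]:
        return sorted(self.sigmoid.mu)


@dataclasses.dataclass
class SimulationResult:
    x: ExpressionMatrix          # gene-layer mRNA trajectories (linear)
    y: ExpressionMatrix          # protein-layer activity trajectories (linear)
    clip_events: int
    total_updates: int

    @property
    def clip_fraction(self) -> float:
        return self.clip_events / self.total_updates if self.total_updates else 0.0


def _as_sd_array(noise_sd, ids: Sequence[str]) -> np.ndarray:
    if isinstance(noise_sd, Mapping):
        return np.array([float(noise_sd[i]) for i in ids])
    return np.full(len(ids), float(noise_sd))


def simulate_coupled(
    system: CoupledSystem,
    x0: Mapping[str, float],
    y0: Mapping[str, float],
    steps: int,
    noise_sd_gene=0.0,
    noise_sd_protein=0.0,
    seed: int | np.random.Generator | None = None,
    dt: float = 1.0,
    clamped_tfs: Sequence[str] = (),
    knockout_semantics: str = "clamp",
    y_forced: np.ndarray | None = None,
) -> SimulationResult:
    """Exact synchronous forward iteration of the coupled difference equations.

    ``noise_sd_*`` may be scalars or per-node mappings; noise is additive
    Gaussian and negative states are clipped at zero.  ``clamped_tfs`` holds
    deleted TFs whose activity is pinned to 0 (see :func:`predict_knockout`).
    ``y_forced`` (steps+1 x n_proteins) replaces the protein-layer dynamics
    with a prescribed trajectory — used when layers are simulated separately.
    Deterministic for a given seed.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    if knockout_semantics not in KNOCKOUT_SEMANTICS:
        raise ValueError(f"knockout semantics must be one of {KNOCKOUT_SEMANTICS}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    gene_ids = system.gene_ids
    prot_ids = system.protein_ids
    gi = {g: j for j, g in enumerate(gene_ids)}
    pi = {p: j for j, p in enumerate(prot_ids)}
    unknown = set(clamped_tfs) - set(system.sigmoid.mu)
    if unknown:
        raise KeyError(f"unknown TF id(s) for knockout: {sorted(unknown)}")

    x = np.zeros((steps + 1, len(gene_ids)))
    y = np.zeros((steps + 1, len(prot_ids)))
    x[0] = [float(x0[g]) for g in gene_ids]
    if y_forced is not None:
        if y_forced.shape != (steps + 1, len(prot_ids)):
            raise ValueError("y_forced has the wrong shape")
        y[:] = y_forced
    else:
        y[0] = [float(y0[p]) for p in prot_ids]
    for tf in clamped_tfs:
        if tf in pi:
            y[:, pi[tf]] = 0.0

    sd_x = _as_sd_array(noise_sd_gene, gene_ids)
    sd_y = _as_sd_array(noise_sd_protein, prot_ids)
    clip_events = 0

    def z_value(tf: str, t: int) -> float:
        if tf in clamped_tfs:
            if knockout_semantics == "hard_zero":
                return 0.0
            return float(
                sigmoid_activation(0.0, system.sigmoid.mu[tf], system.sigmoid.sigma[tf])
            )
        ytf = y[t, pi[tf]] if tf in pi else 0.0
        return float(
            sigmoid_activation(ytf, system.sigmoid.mu[tf], system.sigmoid.sigma[tf])
        )

    # runaway parameter draws may overflow transiently; the caller's
    # stability checks handle non-finite trajectories
    with np.errstate(over="ignore", invalid="ignore"):
        for t in range(steps):
            zcache = {tf: z_value(tf, t) for tf in system.sigmoid.mu}
            for g, dyn in system.gene.items():
                drive = float(
                    np.dot(dyn.a, [zcache[tf] for tf in dyn.regulators])
                ) if dyn.regulators else 0.0
                nxt = drive + dyn.retention * x[t, gi[g]] + dyn.k
                if sd_x[gi[g]] > 0:
                    nxt += rng.normal(0.0, sd_x[gi[g]])
                if nxt < 0:
                    clip_events += 1
                    nxt = 0.0
                x[t + 1, gi[g]] = nxt
            if y_forced is None:
                for p, dyn in system.protein.items():
                    if p in clamped_tfs:
                        continue
                    yp = y[t, pi[p]]
                    inter = float(
                        np.dot(dyn.b, [yp * y[t, pi[m]] for m in dyn.partners])
                    ) if dyn.partners else 0.0
                    nxt = inter + dyn.retention * yp + dyn.h
                    if dyn.mrna_source is not None:
                        nxt += dyn.translation * x[t, gi[dyn.mrna_source]]
                    if sd_y[pi[p]] > 0:
                        nxt += rng.normal(0.0, sd_y[pi[p]])
                    if nxt < 0:
                        clip_events += 1
                        nxt = 0.0
                    y[t + 1, pi[p]] = nxt


    times = np.arange(steps + 1, dtype=float) * dt
    n_prot_updates = 0 if y_forced is not None else steps * len(prot_ids)
    return SimulationResult(
        x=ExpressionMatrix(gene_ids, times, x.T, LINEAR),
        y=ExpressionMatrix(prot_ids, times, y.T, LINEAR),
        clip_events=clip_events,
        total_updates=steps * len(gene_ids) + n_prot_updates,
    )


def predict_knockout(
    system: CoupledSystem,
    deleted_tf: str,
    x0: Mapping[str, float],
    y0: Mapping[str, float],
    steps: int,
    semantics: str = "clamp",
) -> SimulationResult:
    """Predict expression after deleting a TF (noise-free forward simulation).

    The deleted TF's activity is clamped to 0; under the default "clamp"
    semantics its regulation function becomes the deletion floor f_j(0) (the
    sigmoid never reaches exactly zero), while "hard_zero" forces z = 0.
    """
    if deleted_tf not in system.sigmoid.mu:
        raise KeyError(f"unknown TF id {deleted_tf!r}")
    return simulate_coupled(
        system, x0, y0, steps,
        clamped_tfs=(deleted_tf,), knockout_semantics=semantics,
    )


def system_from_fits(gene_result, protein_result, sigmoid: SigmoidParams) -> CoupledSystem:
    """Assemble the fitted dynamic system from per-target fit results.

    Uses the stepwise-selected coefficients (the fitted predictive model);
    merged protein fits yield translation-free dynamics.
    """
    gene = {}
    for gm in gene_result.fits:
        regs = tuple(sorted(gm.a))
        gene[gm.target] = GeneDynamics(
            regulators=regs,
            a=np.array([gm.a[tf] for tf in regs]),
            retention=1.0 - gm.lambda_,
            k=gm.k,
        )
    protein = {}
    for pm in protein_result.fits:
        partners = tuple(sorted(pm.b))
        protein[pm.target] = ProteinDynamics(
            partners=partners,
            b=np.array([pm.b[p] for p in partners]),
            retention=pm.retention,
            h=pm.h,
            translation=0.0 if pm.merged else (pm.alpha or 0.0),
            mrna_source=None if pm.merged else pm.target,
        )
    return CoupledSystem(gene=gene, protein=protein, sigmoid=sigmoid)


# ---------------------------------------------------------------------------
# synthetic scenarios
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SyntheticScenario:
    """A complete simulated experiment with known ground truth."""

    gene_ids: list[str]
    tf_ids: list[str]
    protein_ids: list[str]               # non-TF protein-layer nodes
    system: CoupledSystem                # ground-truth parameters
    true_network: CandidateNetwork
    candidates: CandidateNetwork         # true network plus decoys
    annotations: dict[str, frozenset[str]]
    expression: ExpressionMatrix         # observed log2 matrix (coarse grid)
    x0: dict[str, float]
    y0: dict[str, float]
    fine_x: ExpressionMatrix             # realized fine-grid linear trajectories
    fine_y: ExpressionMatrix
    noise_sd_gene: dict[str, float]
    noise_sd_protein: dict[str, float]
    clip_fraction: float
    seed: int
    config: dict

    @property
    def protein_layer_ids(self) -> list[str]:
        return self.tf_ids + self.protein_ids

    @property
    def decoy_tf_gene(self) -> set[tuple[str, str]]:
        return set(self.candidates.tf_gene_edges) - set(self.true_network.tf_gene_edges)

    @property
    def decoy_ppi(self) -> set[tuple[str, str]]:
        return set(self.candidates.ppi_edges) - set(self.true_network.ppi_edges)


def _balanced_signs(n: int, n_positive: int, rng) -> np.ndarray:
    signs = np.array([1.0] * n_positive + [-1.0] * (n - n_positive))
    rng.shuffle(signs)
    return signs


def _sample_decoys(true_pairs, pool, n_decoys, rng):
    spare = [p for p in pool if p not in set(true_pairs)]
    if n_decoys > len(spare):
        raise ValueError("not enough non-true pairs to sample decoys from")
    idx = rng.choice(len(spare), size=n_decoys, replace=False)
    return [spare[i] for i in sorted(idx)]


def generate_scenario(
    n_genes: int = 30,
    n_tfs: int = 8,
    n_proteins: int = 25,
    l0: int = 21,
    fine_factor: int = 2,
    tf_gene_density: float = 0.25,
    n_ppi_true: int = 60,
    decoy_factor: float = 2.5,
    noise_sd_gene: float = 0.02,
    noise_sd_protein: float = 0.02,
    missing_fraction: float = 0.0,
    observe_stride: int | None = None,
    seed: int = 0,
) -> SyntheticScenario:
    """Sample a ground-truth coupled system and simulate an observed experiment.

    Noise levels are fractions of each node's noise-free signal range.  The
    dynamics run on the fine grid ((l0-1)*fine_factor + 1 points); the written
    observation grid keeps every ``observe_stride``-th point (default:
    ``fine_factor``, so spline densification by the same factor recovers the
    simulation grid).  ``decoy_factor`` is the candidate:true edge-count
    ratio; 1 means candidate = true.  Deterministic for a given seed.
    """
    if not 0 < tf_gene_density <= 1:
        raise ValueError("tf_gene_density must be in (0, 1]")
    if decoy_factor < 1:
        raise ValueError("decoy_factor must be >= 1")
    if observe_stride is None:
        observe_stride = fine_factor
    rng = np.random.default_rng(seed)
    genes = [f"G{i + 1:03d}" for i in range(n_genes)]
    tfs = [f"TF{i + 1:02d}" for i in range(n_tfs)]
    prots = [f"P{i + 1:03d}" for i in range(n_proteins)]
    prot_layer = tfs + prots

    # --- true topology ---------------------------------------------------
    all_ppi = list(itertools.combinations(prot_layer, 2))
    if n_ppi_true > len(all_ppi):
        raise ValueError("n_ppi_true exceeds the number of possible pairs")
    idx = rng.choice(len(all_ppi), size=n_ppi_true, replace=False)
    true_ppi = [all_ppi[i] for i in sorted(idx)]
    true_tf_gene = []
    for g in genes:
        regs = [tf for tf in tfs if rng.random() < tf_gene_density]
        if not regs:
            regs = [tfs[int(rng.integers(n_tfs))]]
        true_tf_gene.extend((tf, g) for tf in regs)
    true_net = CandidateNetwork(list(true_tf_gene), list(true_ppi))

    # --- true parameters --------------------------------------------------
    # Protein kinetics are slow on the simulation grid (retention near 1) so
    # the stress transient remains exciting across the whole time course and
    # stays smooth at the observation stride.  Each undirected interaction
    # acts with opposite signs on its two endpoints (activator-inhibitor
    # pairing, as in kinase/phosphatase push-pull loops), which yields
    # damped-oscillatory rather than explosive coupling; the total
    # interaction weight per target is normalized to a fixed budget, and a
    # rejection loop below damps the b's if a draw still runs away.
    edge_sign = {
        canonical_pair(*e): (1.0 if rng.random() < 0.5 else -1.0) for e in true_ppi
    }
    protein_dyn: dict[str, ProteinDynamics] = {}
    for n in prot_layer:
        partners = tuple(true_net.partners_of(n))
        deg = len(partners)
        # TFs are long-lived regulatory proteins: slower turnover keeps their
        # activity curves smooth at the observation stride
        rng_lo, rng_hi = (TF_RETENTION_RANGE if n in tfs
                          else PROTEIN_RETENTION_RANGE)
        rho = float(rng.uniform(rng_lo, rng_hi))
        if deg:
            w = rng.uniform(*PROTEIN_INTERACTION_MAG_RANGE, size=deg)
            for j, m in enumerate(partners):
                s = edge_sign[canonical_pair(n, m)]
                w[j] *= s if n < m else -s
            b = w * (PROTEIN_INTERACTION_BUDGET * (1.0 - rho) / np.sum(np.abs(w)))
        else:
            b = np.empty(0)
        protein_dyn[n] = ProteinDynamics(
            partners=partners, b=b,
            retention=rho,
            h=float(rng.uniform(*PROTEIN_BASAL_LEVEL_RANGE)) * (1.0 - rho),
        )
    gene_dyn: dict[str, GeneDynamics] = {}
    for g in genes:
        regs = tuple(true_net.regulators_of(g))
        deg = len(regs)
        mags = rng.uniform(0.3, 1.0, size=deg)
        signs = _balanced_signs(deg, math.ceil((deg + 1) / 2), rng)
        gene_dyn[g] = GeneDynamics(
            regulators=regs, a=signs * mags,
            retention=float(rng.uniform(0.3, 0.9)),
            k=float(rng.uniform(0.0, 0.5)),
        )

    x0 = {g: float(rng.uniform(0.5, 2.0)) for g in genes}
    # The stress displaces a subset of "sensor" proteins far from baseline;
    # the rest start near their resting level.  Neighbor responses to these
    # sparse perturbations carry interaction-specific signatures.
    y0 = {
        p: float(rng.uniform(1.5, 3.5)) if rng.random() < 0.4
        else float(rng.uniform(0.4, 0.9))
        for p in prot_layer
    }
    steps = (l0 - 1) * fine_factor
    dt = 1.0 / fine_factor

    # --- protein layer (autonomous): noise scales, then realized run ------
    placeholder = SigmoidParams({}, {})
    proto = CoupledSystem(gene={}, protein=protein_dyn, sigmoid=placeholder)
    seed_y = int(rng.integers(2**31))
    for _attempt in range(10):  # stability rejection: damp b on runaway draws
        silent = simulate_coupled(proto, {}, y0, steps, seed=rng, dt=dt)
        sd_y = {
            p: noise_sd_protein * float(np.ptp(silent.y.row(p))) for p in prot_layer
        }
        noisy_y = simulate_coupled(
            proto, {}, y0, steps, noise_sd_protein=sd_y,
            seed=np.random.default_rng(seed_y), dt=dt,
        )
        worst = max(silent.y.values.max(), noisy_y.y.values.max())
        if np.isfinite(worst) and worst <= ACTIVITY_CEILING:
            break
        for dyn in protein_dyn.values():
            dyn.b = dyn.b * 0.7
    # the realized TF activity trajectories define the ground-truth sigmoids
    sigmoid = SigmoidParams(
        mu={tf: float(np.mean(noisy_y.y.row(tf))) for tf in tfs},
        sigma={tf: float(np.std(noisy_y.y.row(tf), ddof=1)) for tf in tfs},
    )
    system = CoupledSystem(gene=gene_dyn, protein=protein_dyn, sigmoid=sigmoid)

    # --- gene layer driven by the realized activities ----------------------
    y_mat = noisy_y.y.values.T  # (steps+1, n_prot)
    silent_x = simulate_coupled(
        system, x0, y0, steps, seed=rng, dt=dt, y_forced=y_mat
    )
    sd_x = {g: noise_sd_gene * float(np.ptp(silent_x.x.row(g))) for g in genes}
    rng_x = np.random.default_rng(rng.integers(2**31))
    noisy_x = simulate_coupled(
        system, x0, y0, steps, noise_sd_gene=sd_x, seed=rng_x, dt=dt, y_forced=y_mat
    )
    clip_events = noisy_y.clip_events + noisy_x.clip_events
    total_updates = noisy_y.total_updates + noisy_x.total_updates

    # --- observed matrix on the coarse grid --------------------------------
    obs_idx = np.arange(0, steps + 1, observe_stride)
    all_ids = genes + prot_layer
    fine_vals = np.vstack([noisy_x.x.values, noisy_y.y.values])
    coarse = ExpressionMatrix(
        all_ids, noisy_x.x.times[obs_idx], fine_vals[:, obs_idx], LINEAR
    )
    expression = linear_to_log2(coarse, floor=LOG_FLOOR)
    if missing_fraction > 0:
        rng_m = np.random.default_rng(rng.integers(2**31))
        mask = rng_m.random(expression.values.shape) < missing_fraction
        # keep at least 2 observed points per profile
        for i in range(mask.shape[0]):
            if (~mask[i]).sum() < 2:
                mask[i, :2] = False
        expression.values[mask] = np.nan

    # --- candidates = truth + decoys ---------------------------------------
    n_decoy_tg = int(round((decoy_factor - 1) * len(true_tf_gene)))
    n_decoy_pp = int(round((decoy_factor - 1) * len(true_ppi)))
    tg_pool = [(tf, g) for tf in tfs for g in genes]
    cand_tg = list(true_tf_gene) + _sample_decoys(true_tf_gene, tg_pool, n_decoy_tg, rng)
    cand_pp = list(true_ppi) + _sample_decoys(true_ppi, all_ppi, n_decoy_pp, rng)
    candidates = CandidateNetwork(cand_tg, cand_pp)

    annotations = {g: frozenset({"gene"}) for g in genes}
    annotations.update({tf: frozenset({"gene", "TF", "protein"}) for tf in tfs})
    annotations.update({p: frozenset({"protein"}) for p in prots})

    return SyntheticScenario(
        gene_ids=genes, tf_ids=tfs, protein_ids=prots,
        system=system, true_network=true_net, candidates=candidates,
        annotations=annotations, expression=expression,
        x0=x0, y0=y0, fine_x=noisy_x.x, fine_y=noisy_y.y,
        noise_sd_gene=sd_x, noise_sd_protein=sd_y,
        clip_fraction=clip_events / total_updates if total_updates else 0.0,
        seed=seed,
        config={
            "n_genes": n_genes, "n_tfs": n_tfs, "n_proteins": n_proteins,
            "l0": l0, "fine_factor": fine_factor,
            "tf_gene_density": tf_gene_density, "n_ppi_true": n_ppi_true,
            "decoy_factor": decoy_factor, "noise_sd_gene": noise_sd_gene,
            "noise_sd_protein": noise_sd_protein,
            "missing_fraction": missing_fraction,
            "observe_stride": observe_stride, "seed": seed,
        },
    )


def write_scenario(scenario: SyntheticScenario, outdir) -> dict[str, Path]:
    """Serialize the scenario's input files and ground truth to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "tf_gene_candidates": outdir / "tf_gene_candidates.tsv",
        "ppi_candidates": outdir / "ppi_candidates.tsv",
        "annotations": outdir / "annotations.tsv",
        "true_tf_gene": outdir / "true_tf_gene.tsv",
        "true_ppi": outdir / "true_ppi.tsv",
        "true_params": outdir / "true_params.tsv",
        "config": outdir / "scenario.json",
    }
    write_expression(scenario.expression, paths["expression"])
    write_edge_list(scenario.candidates.tf_gene_edges, paths["tf_gene_candidates"],
                    comment="candidate TF -> gene regulations")
    write_edge_list(scenario.candidates.ppi_edges, paths["ppi_candidates"],
                    comment="candidate protein-protein interactions")
    write_annotations(scenario.annotations, paths["annotations"])
    write_edge_list(scenario.true_network.tf_gene_edges, paths["true_tf_gene"],
                    comment="ground-truth TF -> gene regulations")
    write_edge_list(scenario.true_network.ppi_edges, paths["true_ppi"],
                    comment="ground-truth protein-protein interactions")
    with open(paths["true_params"], "w") as fh:
        fh.write("kind\ttarget\tsource\tvalue\n")
        for g, dyn in scenario.system.gene.items():
            for tf, a in zip(dyn.regulators, dyn.a):
                fh.write(f"a\t{g}\t{tf}\t{a:.10g}\n")
            fh.write(f"gene_retention\t{g}\t.\t{dyn.retention:.10g}\n")
            fh.write(f"k\t{g}\t.\t{dyn.k:.10g}\n")
        for p, dyn in scenario.system.protein.items():
            for m, b in zip(dyn.partners, dyn.b):
                fh.write(f"b\t{p}\t{m}\t{b:.10g}\n")
            fh.write(f"protein_retention\t{p}\t.\t{dyn.retention:.10g}\n")
            fh.write(f"h\t{p}\t.\t{dyn.h:.10g}\n")
        for tf in scenario.system.sigmoid.mu:
            fh.write(f"mu\t{tf}\t.\t{scenario.system.sigmoid.mu[tf]:.10g}\n")
            fh.write(f"sigma\t{tf}\t.\t{scenario.system.sigmoid.sigma[tf]:.10g}\n")
    with open(paths["config"], "w") as fh:
        json.dump(scenario.config, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


# ---------------------------------------------------------------------------
# scenario-based inference and evaluation helpers
# ---------------------------------------------------------------------------

def infer_from_scenario(
    scenario: SyntheticScenario,
    alpha: float = 0.05,
    rule: str = "union",
    densify_factor: int | None = None,
):
    """Run the standard pipeline on a scenario's observed matrix.

    impute -> linear -> densify -> fit genes -> fit proteins (mRNA-for-activity
    substitution).  Returns (gene_result, protein_result, densified matrix).
    """
    from .data_io import impute_missing, log2_to_linear, spline_densify
    from .gene_network import fit_gene_network
    from .protein_network import fit_protein_network, substitute_activity

    if densify_factor is None:
        densify_factor = scenario.config["observe_stride"]
    expr = impute_missing(scenario.expression)
    expr = log2_to_linear(expr)
    expr = spline_densify(expr, densify_factor)
    gene_result = fit_gene_network(scenario.candidates, expr, alpha=alpha)
    activity, _ = substitute_activity(expr, scenario.protein_layer_ids)
    protein_result = fit_protein_network(
        scenario.candidates, activity, expr, alpha=alpha, rule=rule
    )
    return gene_result, protein_result, expr


def evaluate_recovery(scenario: SyntheticScenario, gene_result, protein_result) -> dict:
    """True/false positive rates of edge recovery against the planted truth."""
    true_tg = set(scenario.true_network.tf_gene_edges)
    true_pp = set(scenario.true_network.ppi_edges)
    decoy_tg = scenario.decoy_tf_gene
    decoy_pp = scenario.decoy_ppi
    got_tg = set(gene_result.pruned_edges)
    got_pp = set(protein_result.pruned_edges)
    return {
        "tf_gene_tpr": len(got_tg & true_tg) / len(true_tg) if true_tg else math.nan,
        "tf_gene_fpr": len(got_tg & decoy_tg) / len(decoy_tg) if decoy_tg else 0.0,
        "ppi_tpr": len(got_pp & true_pp) / len(true_pp) if true_pp else math.nan,
        "ppi_fpr": len(got_pp & decoy_pp) / len(decoy_pp) if decoy_pp else 0.0,
    }
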