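"""Hand-designed small coupled systems for identifiability tests.

Trajectories are kept strictly positive (no clipping) and well-excited so
that zero-noise parameter recovery is exact up to floating point.
"""

import numpy as np

from icnet.data_io import ExpressionMatrix
from icnet.gene_network import SigmoidParams, estimate_sigmoid_params
from icnet.simulation import (
    CoupledSystem,
    GeneDynamics,
    ProteinDynamics,
    simulate_coupled,
)


def designed_gene_system(rng, n_genes=6, n_tfs=4, n_times=41):
    """Diverse multi-frequency TF activities; basal levels cover repression."""
    t = np.arange(float(n_times))
    tf_ids = [f"TF{i}" for i in range(n_tfs)]
    ys = np.vstack(
        [1.0 + 0.8 * np.sin(2 * np.pi * t / (8 + 5 * i) + i) for i in range(n_tfs)]
    )
    act = ExpressionMatrix(tf_ids, t, np.clip(ys, 0.05, None), scale="linear")
    sig = estimate_sigmoid_params(act, tf_ids)
    gene = {}
    for j in range(n_genes):
        regs = tuple(sorted(rng.choice(tf_ids, size=2, replace=False)))
        a = rng.uniform(0.3, 1.0, 2) * rng.choice([-1.0, 1.0], 2)
        k = float(np.sum(np.abs(a[a < 0]))) + float(rng.uniform(0.1, 0.5))
        gene[f"G{j}"] = GeneDynamics(regs, a, float(rng.uniform(0.3, 0.9)), k)
    system = CoupledSystem(
        gene=gene,
        protein={p: ProteinDynamics((), np.empty(0), 0.0, 0.0) for p in tf_ids},
        sigmoid=sig,
    )
    x0 = {g: float(rng.uniform(0.5, 2.0)) for g in gene}
    res = simulate_coupled(
        system, x0, {p: act.row(p)[0] for p in tf_ids}, n_times - 1,
        y_forced=act.values.T,
    )
    assert res.clip_events == 0
    expr = ExpressionMatrix(
        list(gene) + tf_ids, t, np.vstack([res.x.values, act.values]), scale="linear"
    )
    return system, expr, sig


def designed_protein_system(rng):
    """Ring of 5 proteins with explicit translation drive from 5 genes."""
    ids = [f"Q{i}" for i in range(5)]
    gene_ids = [f"g{i}" for i in range(5)]
    genes = {
        g: GeneDynamics((), np.empty(0), float(rng.uniform(0.4, 0.8)),
                        float(rng.uniform(0.2, 0.5)))
        for g in gene_ids
    }
    pairs = [("Q0", "Q1"), ("Q1", "Q2"), ("Q2", "Q3"), ("Q3", "Q4"), ("Q0", "Q4")]
    pdyn = {}
    for i, q in enumerate(ids):
        partners = tuple(sorted({a if b == q else b for a, b in pairs if q in (a, b)}))
        b = rng.uniform(0.03, 0.08, len(partners)) * rng.choice([-1.0, 1.0], len(partners))
        pdyn[q] = ProteinDynamics(
            partners, b, 0.6, 0.3, translation=0.2, mrna_source=gene_ids[i]
        )
    system = CoupledSystem(gene=genes, protein=pdyn, sigmoid=SigmoidParams({}, {}))
    x0 = {g: float(rng.uniform(0.8, 1.5)) for g in gene_ids}
    y0 = {q: float(rng.uniform(0.8, 1.5)) for q in ids}
    res = simulate_coupled(system, x0, y0, 20)
    assert res.clip_events == 0
    mrna = ExpressionMatrix(ids, res.x.times, res.x.values, scale="linear")
    return system, res.y, mrna
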