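"""Merging pruned sub-networks, hub ranking and cross-condition comparison.

The transcription sub-network (signed, directed TF->gene edges) and the
signaling sub-network (undirected protein-protein edges) are joined through
the TF nodes they share: a TF's activity variable drives the sigmoid
regulation functions of its target genes while obeying its own interaction
dynamics, so the merged equation sets form one coupled system.  TFs incident
to at least one edge of each kind are flagged as interface nodes.
"""

from __future__ import annotations

import dataclasses
import itertools
from collections.abc import Sequence

import pandas as pd

from .data_io import CandidateNetwork, canonical_pair, read_network_tsv
from .gene_network import GeneNetworkResult
from .protein_network import ProteinNetworkResult


@dataclasses.dataclass
class EdgeData:
    coefficient: float
    p_raw: float
    p_adj: float


@dataclasses.dataclass
class IntegratedNetwork:
    """Signed transcription edges + unsigned interaction edges over one node set."""

    nodes: dict[str, frozenset[str]]                       # id -> roles
    transcription_edges: dict[tuple[str, str], EdgeData]   # (TF, gene), directed
    interaction_edges: dict[tuple[str, str], EdgeData]     # canonical pair
    provenance: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        for (tf, _), _d in self.transcription_edges.items():
            if "TF" not in self.nodes.get(tf, frozenset()):
                raise ValueError(f"transcription edge source {tf!r} lacks the TF role")

    @property
    def interface_tfs(self) -> set[str]:
        """TFs incident to >= 1 transcription edge and >= 1 interaction edge."""
        in_trans = {tf for tf, _ in self.transcription_edges}
        in_inter = {n for e in self.interaction_edges for n in e}
        return {
            n for n, roles in self.nodes.items()
            if "TF" in roles and n in in_trans and n in in_inter
        }

    def nodes_with_role(self, role: str) -> set[str]:
        return {n for n, roles in self.nodes.items() if role in roles}

    @property
    def condition(self) -> str | None:
        return self.provenance.get("condition")


def merge_networks(
    gene_result: GeneNetworkResult,
    protein_result: ProteinNetworkResult,
    annotations: dict[str, frozenset[str]] | None = None,
    candidates: CandidateNetwork | None = None,
    condition: str | None = None,
    thresholds: dict | None = None,
) -> IntegratedNetwork:
    """Merge the pruned sub-networks into one integrated network.

    Node roles are inferred from edge incidence (sources are TFs, targets are
    genes, interaction endpoints are proteins) and unioned with any supplied
    annotations; a supplied annotation that excludes an inferred role is a
    contradiction and raises.  If the candidate network is given, preserved
    percentages per category are recorded in the provenance.
    """
    nodes: dict[str, set[str]] = {}

    def add_role(nid: str, role: str) -> None:
        nodes.setdefault(nid, set()).add(role)

    trans: dict[tuple[str, str], EdgeData] = {}
    for gm in gene_result.fits:
        add_role(gm.target, "gene")
        for tf in gm.regulators:
            add_role(tf, "TF")
            trans[(tf, gm.target)] = EdgeData(
                coefficient=gm.a[tf], p_raw=gm.p_raw[tf], p_adj=gm.p_adj[tf]
            )
    inter: dict[tuple[str, str], EdgeData] = {}
    by_target = {pm.target: pm for pm in protein_result.fits}
    for pair in protein_result.pruned_edges:
        a, b = pair
        add_role(a, "protein")
        add_role(b, "protein")
        # take coefficient/p from the side where the edge is significant
        # (smaller adjusted p wins when both sides agree)
        sides = []
        for tgt, other in ((a, b), (b, a)):
            pm = by_target.get(tgt)
            if pm is not None and other in pm.p_adj and other in pm.partners:
                sides.append((pm.p_adj[other], pm.b[other], pm.p_raw[other]))
        sides.sort()
        p_adj, coef, p_raw = sides[0] if sides else (float("nan"),) * 3
        inter[canonical_pair(a, b)] = EdgeData(coefficient=coef, p_raw=p_raw, p_adj=p_adj)
    # unfitted-but-annotated isolated nodes stay out; merge supplied annotations
    if annotations is not None:
        for nid, inferred in nodes.items():
            declared = annotations.get(nid)
            if declared is not None and not inferred <= declared:
                raise ValueError(
                    f"node {nid!r}: inferred roles {sorted(inferred)} contradict "
                    f"annotation {sorted(declared)}"
                )
        for nid in nodes:
            nodes[nid] |= set(annotations.get(nid, ()))
    provenance = {"condition": condition, "thresholds": dict(thresholds or {})}
    if candidates is not None:
        n_tg, n_pp = len(candidates.tf_gene_edges), len(candidates.ppi_edges)
        provenance["preserved"] = {
            "tf_gene_edges": len(trans),
            "tf_gene_candidates": n_tg,
            "tf_gene_percent": 100.0 * len(trans) / n_tg if n_tg else 0.0,
            "ppi_edges": len(inter),
            "ppi_candidates": n_pp,
            "ppi_percent": 100.0 * len(inter) / n_pp if n_pp else 0.0,
            "combined_percent": (
                100.0 * (len(trans) + len(inter)) / (n_tg + n_pp)
                if n_tg + n_pp else 0.0
            ),
        }
    return IntegratedNetwork(
        nodes={n: frozenset(r) for n, r in nodes.items()},
        transcription_edges=trans,
        interaction_edges=inter,
        provenance=provenance,
    )


def hub_degrees(net: IntegratedNetwork, top_k: int | None = None) -> list[tuple[str, int]]:
    """Nodes ranked by total degree (transcription in+out plus interaction).

    Descending by degree; ties broken lexicographically by id.
    """
    deg = {n: 0 for n in net.nodes}
    for tf, g in net.transcription_edges:
        deg[tf] += 1
        deg[g] += 1
    for a, b in net.interaction_edges:
        deg[a] += 1
        deg[b] += 1
    ranked = sorted(deg.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:top_k] if top_k is not None else ranked


_COMPARE_COLS = (
    "conditions", "n_genes", "n_tfs", "n_proteins", "n_tf_gene_edges", "n_ppi_edges",
)


def _category_sets(net: IntegratedNetwork):
    return {
        "n_genes": net.nodes_with_role("gene"),
        "n_tfs": net.nodes_with_role("TF"),
        "n_proteins": net.nodes_with_role("protein"),
        "n_tf_gene_edges": set(net.transcription_edges),
        "n_ppi_edges": set(net.interaction_edges),
    }


def compare_networks(
    nets: Sequence[IntegratedNetwork],
    labels: Sequence[str] | None = None,
    candidates: CandidateNetwork | None = None,
    exclusive: bool = False,
) -> pd.DataFrame:
    """Intersection table over every non-empty subset of conditions.

    Rows list, for each subset, the counts of genes, TFs, proteins, TF->gene
    edges and interaction edges shared by all conditions in the subset
    (inclusive intersections by default; ``exclusive=True`` additionally
    removes items present in any condition outside the subset).  If the
    candidate network is given, the all-conditions row also yields per-edge
    conservation fractions against the candidate counts.
    """
    if len(nets) < 2:
        raise ValueError("need at least two networks to compare")
    if labels is None:
        labels = [
            net.condition or f"condition{i + 1}" for i, net in enumerate(nets)
        ]
    if len(labels) != len(nets) or len(set(labels)) != len(labels):
        raise ValueError("labels must be unique, one per network")
    sets = [_category_sets(net) for net in nets]
    rows = []
    index = range(len(nets))
    for size in range(1, len(nets) + 1):
        for combo in itertools.combinations(index, size):
            row: dict = {"conditions": " & ".join(labels[i] for i in combo)}
            for cat in _COMPARE_COLS[1:]:
                shared = set.intersection(*(sets[i][cat] for i in combo))
                if exclusive:
                    for j in index:
                        if j not in combo:
                            shared -= sets[j][cat]
                row[cat] = len(shared)
            rows.append(row)
    table = pd.DataFrame(rows, columns=list(_COMPARE_COLS))
    if candidates is not None:
        all_row = table.iloc[-1]
        n_tg, n_pp = len(candidates.tf_gene_edges), len(candidates.ppi_edges)
        table.attrs["conservation"] = {
            "tf_gene_fraction": all_row["n_tf_gene_edges"] / n_tg if n_tg else 0.0,
            "ppi_fraction": all_row["n_ppi_edges"] / n_pp if n_pp else 0.0,
        }
    return table


def shared_core_edges(nets: Sequence[IntegratedNetwork]) -> tuple[set, set]:
    """Edges present in every condition: (TF->gene set, PPI set)."""
    trans = set.intersection(*(set(n.transcription_edges) for n in nets))
    inter = set.intersection(*(set(n.interaction_edges) for n in nets))
    return trans, inter


def recount_preserved(network_tsv_path, candidates: CandidateNetwork) -> dict:
    """Independent recount of preserved percentages from a serialized edge-TSV.

    Used to cross-check the pipeline's reported bookkeeping: the counts are
    recomputed from the file alone and compared against the candidate pool.
    """
    trans, inter = read_network_tsv(network_tsv_path)
    n_tg, n_pp = len(candidates.tf_gene_edges), len(candidates.ppi_edges)
    extr_t = set(trans) - set(candidates.tf_gene_edges)
    extr_p = set(inter) - {canonical_pair(*e) for e in candidates.ppi_edges}
    if extr_t or extr_p:
        raise ValueError(
            f"serialized network contains non-candidate edges: {sorted(extr_t | extr_p)}"
        )
    return {
        "tf_gene_edges": len(trans),
        "tf_gene_percent": 100.0 * len(trans) / n_tg if n_tg else 0.0,
        "ppi_edges": len(inter),
        "ppi_percent": 100.0 * len(inter) / n_pp if n_pp else 0.0,
        "combined_percent": (
            100.0 * (len(trans) + len(inter)) / (n_tg + n_pp) if n_tg + n_pp else 0.0
        ),
    }
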