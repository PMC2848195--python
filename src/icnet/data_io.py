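"""Expression-matrix and network file handling.

This module owns the on-disk formats (expression TSV, edge-list TSV, node
annotations, SIF / GraphML / edge-TSV network exports) and the preprocessing
steps applied before dynamic-model fitting:

1. responsive-node filter (fold-change on the log2 scale),
2. missing-fraction filter,
3. natural cubic-spline imputation of missing values,
4. log2 -> linear conversion,
5. spline densification of the time grid.

Imputation runs on the log2 scale (avoids positivity artifacts);
densification runs on the linear scale, with negative spline excursions
clipped to zero.
"""

from __future__ import annotations

import dataclasses
import math
from collections.abc import Iterable

import numpy as np
from scipy.interpolate import CubicSpline

LOG2_RATIO = "log2_ratio"
LINEAR = "linear"

#: cell contents interpreted as a missing measurement
MISSING_TOKENS = frozenset({"", "NA", "na", "NaN", "nan"})


class ExpressionError(ValueError):
    """Malformed expression matrix or file."""


@dataclasses.dataclass
class ExpressionMatrix:
    """Node x time matrix of expression (or activity) profiles.

    Parameters
    ----------
    node_ids : sequence of str
        Unique row identifiers.
    times : array-like
        Strictly increasing time stamps (arbitrary units).
    values : ndarray, shape (n_nodes, n_times)
        Measurements; ``NaN`` marks a missing entry.
    scale : str
        ``"log2_ratio"`` or ``"linear"``.
    """

    node_ids: list[str]
    times: np.ndarray
    values: np.ndarray
    scale: str = LOG2_RATIO

    def __post_init__(self) -> None:
        self.node_ids = list(self.node_ids)
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.node_ids)) != len(self.node_ids):
            dupes = sorted({i for i in self.node_ids if self.node_ids.count(i) > 1})
            raise ExpressionError(f"duplicate node ids: {dupes}")
        if self.times.ndim != 1 or np.any(np.diff(self.times) <= 0):
            raise ExpressionError("time stamps must be strictly increasing")
        if self.values.shape != (len(self.node_ids), self.times.size):
            raise ExpressionError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.node_ids)} nodes x {self.times.size} times"
            )
        if self.scale not in (LOG2_RATIO, LINEAR):
            raise ExpressionError(f"unknown scale {self.scale!r}")
        self._index = {n: i for i, n in enumerate(self.node_ids)}

    # -- basic access -------------------------------------------------

    @property
    def n_times(self) -> int:
        return self.times.size

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._index

    def row(self, node_id: str) -> np.ndarray:
        try:
            return self.values[self._index[node_id]]
        except KeyError:
            raise KeyError(f"node {node_id!r} not in expression matrix") from None

    def subset(self, node_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = list(node_ids)
        rows = np.array([self.row(n) for n in ids]) if ids else np.empty((0, self.n_times))
        return ExpressionMatrix(ids, self.times.copy(), rows, self.scale)

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            list(self.node_ids), self.times.copy(), self.values.copy(), self.scale
        )

    def missing_fraction(self, node_id: str) -> float:
        r = self.row(node_id)
        return float(np.isnan(r).sum()) / r.size

    @property
    def is_complete(self) -> bool:
        return not np.isnan(self.values).any()


# ---------------------------------------------------------------------------
# expression TSV
# ---------------------------------------------------------------------------

def read_expression(path, scale: str = LOG2_RATIO) -> ExpressionMatrix:
    """Read an expression TSV (header = "id" + time stamps, one row per node).

    Empty cells and "NA" (any case) are recorded as missing, never as zero.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise ExpressionError(f"{path}: empty expression file")
    header = lines[0].split("\t")
    try:
        times = np.array([float(t) for t in header[1:]], dtype=float)
    except ValueError as exc:
        raise ExpressionError(f"{path}: non-numeric time stamp in header") from exc
    node_ids: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        toks = line.split("\t")
        if len(toks) != times.size + 1:
            raise ExpressionError(
                f"{path}:{lineno}: expected {times.size + 1} columns, got {len(toks)}"
            )
        node_ids.append(toks[0])
        row = []
        for col, tok in enumerate(toks[1:], start=2):
            if tok.strip() in MISSING_TOKENS:
                row.append(math.nan)
            else:
                try:
                    row.append(float(tok))
                except ValueError:
                    raise ExpressionError(
                        f"{path}:{lineno}: non-numeric cell {tok!r} in column {col}"
                    ) from None
        rows.append(row)
    return ExpressionMatrix(node_ids, times, np.array(rows), scale)


def write_expression(expr: ExpressionMatrix, path, missing_token: str = "NA") -> None:
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(f"{t:g}" for t in expr.times) + "\n")
        for nid, row in zip(expr.node_ids, expr.values):
            cells = [missing_token if np.isnan(v) else f"{v:.10g}" for v in row]
            fh.write(nid + "\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def select_responsive(expr: ExpressionMatrix, fold: float = 3.0) -> set[str]:
    """Ids whose max |log2 value| over observed points reaches log2(fold)."""
    if expr.scale != LOG2_RATIO:
        raise ExpressionError("responsive filter requires a log2-ratio matrix")
    threshold = math.log2(fold)
    kept = set()
    for nid, row in zip(expr.node_ids, expr.values):
        obs = row[~np.isnan(row)]
        if obs.size and np.max(np.abs(obs)) >= threshold:
            kept.add(nid)
    return kept


def filter_missing(expr: ExpressionMatrix, max_fraction: float = 0.3) -> set[str]:
    """Ids whose missing fraction does not exceed ``max_fraction``."""
    return {
        nid
        for nid in expr.node_ids
        if expr.missing_fraction(nid) <= max_fraction + 1e-12
    }


def _natural_spline(x: np.ndarray, y: np.ndarray) -> CubicSpline:
    # natural boundary (zero second derivative); end pieces extrapolate as cubics
    return CubicSpline(x, y, bc_type="natural", extrapolate=True)


def impute_missing(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Fill missing entries by a natural cubic spline through the observed points.

    Observed values are left untouched (interpolation, never smoothing);
    missing leading/trailing points use the boundary cubic's extrapolation.
    """
    out = expr.copy()
    for i, nid in enumerate(out.node_ids):
        row = out.values[i]
        miss = np.isnan(row)
        if not miss.any():
            continue
        obs = ~miss
        if obs.sum() < 2:
            raise ExpressionError(f"node {nid!r}: fewer than 2 observed points")
        spline = _natural_spline(out.times[obs], row[obs])
        row[miss] = spline(out.times[miss])
    return out


def log2_to_linear(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Map every value v to 2**v; the result is on the positive linear scale."""
    if expr.scale != LOG2_RATIO:
        raise ExpressionError("matrix is already on the linear scale")
    return ExpressionMatrix(
        list(expr.node_ids), expr.times.copy(), np.exp2(expr.values), LINEAR
    )


def linear_to_log2(expr: ExpressionMatrix, floor: float = 0.0) -> ExpressionMatrix:
    """Inverse of :func:`log2_to_linear`; ``floor`` guards log2(0)."""
    if expr.scale != LINEAR:
        raise ExpressionError("matrix is not on the linear scale")
    vals = expr.values if floor <= 0 else np.maximum(expr.values, floor)
    return ExpressionMatrix(
        list(expr.node_ids), expr.times.copy(), np.log2(vals), LOG2_RATIO
    )


def spline_densify(expr: ExpressionMatrix, factor: int = 2) -> ExpressionMatrix:
    """Refine the time grid so each interval holds ``factor`` equal sub-intervals.

    Original points are preserved exactly; inserted points come from a natural
    cubic spline and are clipped at zero (linear-scale positivity).
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError("densification factor must be an integer >= 1")
    if expr.scale != LINEAR:
        raise ExpressionError("densification requires the linear scale")
    if not expr.is_complete:
        raise ExpressionError("densification requires a complete matrix")
    if factor == 1:
        return expr.copy()
    t = expr.times
    fine = [t[0]]
    for a, b in zip(t[:-1], t[1:]):
        fine.extend(np.linspace(a, b, factor + 1)[1:])
    fine = np.array(fine)
    orig_pos = np.arange(0, fine.size, factor)
    vals = np.empty((len(expr.node_ids), fine.size))
    for i in range(len(expr.node_ids)):
        spline = _natural_spline(t, expr.values[i])
        vals[i] = spline(fine)
        vals[i, orig_pos] = expr.values[i]  # exact at observed points
    np.clip(vals, 0.0, None, out=vals)
    return ExpressionMatrix(list(expr.node_ids), fine, vals, LINEAR)


def preprocess(
    expr: ExpressionMatrix,
    fold: float = 3.0,
    max_missing_fraction: float = 0.3,
    densify_factor: int = 2,
    responsive: bool = True,
) -> tuple[ExpressionMatrix, set[str]]:
    """Full pipeline: responsive filter -> missing filter -> impute -> linear -> densify.

    Returns the completed, linear, densified matrix over the kept nodes and
    the set of kept node ids.
    """
    kept = select_responsive(expr, fold) if responsive else set(expr.node_ids)
    kept &= filter_missing(expr, max_missing_fraction)
    sub = expr.subset([n for n in expr.node_ids if n in kept])
    sub = impute_missing(sub)
    sub = log2_to_linear(sub)
    sub = spline_densify(sub, densify_factor)
    return sub, kept


# ---------------------------------------------------------------------------
# candidate networks and annotations
# ---------------------------------------------------------------------------

class NetworkFormatError(ValueError):
    """Malformed edge list or annotation file."""


def read_edge_list(path) -> list[tuple[str, str]]:
    """Two-column TSV (or whitespace-separated); lines starting '#' ignored."""
    pairs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            toks = line.split("\t") if "\t" in line else line.split()
            if len(toks) < 2:
                raise NetworkFormatError(f"{path}:{lineno}: expected 2 columns")
            pairs.append((toks[0], toks[1]))
    return pairs


def write_edge_list(pairs: Iterable[tuple[str, str]], path, comment: str | None = None):
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        for a, b in pairs:
            fh.write(f"{a}\t{b}\n")


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Lexicographically ordered undirected pair."""
    return (a, b) if a <= b else (b, a)


@dataclasses.dataclass
class CandidateNetwork:
    """Candidate edge pools: directed TF->gene regulations and undirected PPIs.

    PPI pairs are stored canonically (lexicographic order) with duplicates
    removed; duplicate directed pairs and TF->gene self-pairs are rejected.
    """

    tf_gene_edges: list[tuple[str, str]]
    ppi_edges: list[tuple[str, str]]

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for tf, g in self.tf_gene_edges:
            if tf == g:
                raise NetworkFormatError(f"self-pair {tf!r} in TF->gene edges")
            if (tf, g) in seen:
                raise NetworkFormatError(f"duplicate TF->gene edge {(tf, g)}")
            seen.add((tf, g))
        canon = []
        seen_ppi: set[tuple[str, str]] = set()
        for a, b in self.ppi_edges:
            p = canonical_pair(a, b)
            if p not in seen_ppi:
                seen_ppi.add(p)
                canon.append(p)
        self.ppi_edges = canon

    @classmethod
    def from_files(cls, tf_gene_path, ppi_path) -> "CandidateNetwork":
        return cls(read_edge_list(tf_gene_path), read_edge_list(ppi_path))

    @property
    def tf_ids(self) -> set[str]:
        return {tf for tf, _ in self.tf_gene_edges}

    @property
    def target_ids(self) -> set[str]:
        return {g for _, g in self.tf_gene_edges}

    @property
    def protein_ids(self) -> set[str]:
        return {n for e in self.ppi_edges for n in e}

    def regulators_of(self, gene: str) -> list[str]:
        return sorted(tf for tf, g in self.tf_gene_edges if g == gene)

    def partners_of(self, protein: str) -> list[str]:
        out = set()
        for a, b in self.ppi_edges:
            if a == protein:
                out.add(b)
            elif b == protein:
                out.add(a)
        return sorted(out)

    def restrict(self, node_ids: set[str]) -> "CandidateNetwork":
        return CandidateNetwork(
            [(tf, g) for tf, g in self.tf_gene_edges if tf in node_ids and g in node_ids],
            [(a, b) for a, b in self.ppi_edges if a in node_ids and b in node_ids],
        )


def read_annotations(path) -> dict[str, frozenset[str]]:
    """Node role TSV: id <tab> comma-separated roles from {gene, TF, protein}."""
    roles: dict[str, frozenset[str]] = {}
    valid = {"gene", "TF", "protein"}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            toks = line.split("\t")
            if len(toks) != 2:
                raise NetworkFormatError(f"{path}:{lineno}: expected 2 columns")
            rset = frozenset(r.strip() for r in toks[1].split(","))
            if not rset <= valid:
                raise NetworkFormatError(
                    f"{path}:{lineno}: unknown roles {sorted(rset - valid)}"
                )
            if toks[0] in roles:
                raise NetworkFormatError(f"{path}:{lineno}: duplicate id {toks[0]!r}")
            roles[toks[0]] = rset
    return roles


def write_annotations(roles: dict[str, Iterable[str]], path) -> None:
    order = {"gene": 0, "TF": 1, "protein": 2}
    with open(path, "w") as fh:
        for nid in roles:
            fh.write(nid + "\t" + ",".join(sorted(roles[nid], key=order.get)) + "\n")


def check_annotations(candidates: CandidateNetwork, roles: dict[str, frozenset[str]]):
    """Every node referenced by any edge list must carry an annotation."""
    referenced = candidates.tf_ids | candidates.target_ids | candidates.protein_ids
    missing = sorted(referenced - roles.keys())
    if missing:
        raise NetworkFormatError(f"unannotated nodes referenced by edges: {missing}")


# ---------------------------------------------------------------------------
# integrated-network export (duck-typed on integration.IntegratedNetwork)
# ---------------------------------------------------------------------------

NETWORK_FORMATS = ("sif", "graphml", "edge-tsv")


def write_network(net, path, format: str = "edge-tsv") -> None:
    """Serialize an integrated network.

    SIF uses relation labels "activates"/"represses" (transcription edges, by
    coefficient sign) and "pp" (interaction edges). GraphML carries the
    coefficient and raw/adjusted p-values as edge attributes. The edge-TSV
    round-trips through :func:`read_network_tsv`.
    """
    if format == "sif":
        _write_sif(net, path)
    elif format == "graphml":
        _write_graphml(net, path)
    elif format == "edge-tsv":
        _write_edge_tsv(net, path)
    else:
        raise NetworkFormatError(
            f"unknown network format {format!r}; expected one of {NETWORK_FORMATS}"
        )


def _transcription_relation(data) -> str:
    return "activates" if data.coefficient >= 0 else "represses"


def _write_sif(net, path) -> None:
    touched = set()
    with open(path, "w") as fh:
        for (tf, g), data in sorted(net.transcription_edges.items()):
            fh.write(f"{tf}\t{_transcription_relation(data)}\t{g}\n")
            touched.update((tf, g))
        for (a, b), _ in sorted(net.interaction_edges.items()):
            fh.write(f"{a}\tpp\t{b}\n")
            touched.update((a, b))
        for nid in sorted(set(net.nodes) - touched):  # isolated nodes
            fh.write(f"{nid}\n")


def _write_graphml(net, path) -> None:
    import networkx as nx

    g = nx.DiGraph()
    for nid, roles in sorted(net.nodes.items()):
        g.add_node(nid, roles=",".join(sorted(roles)))
    for (tf, tgt), data in sorted(net.transcription_edges.items()):
        g.add_edge(
            tf, tgt, kind="transcription", sign=_transcription_relation(data),
            coefficient=float(data.coefficient),
            p_raw=float(data.p_raw), p_adj=float(data.p_adj),
        )
    for (a, b), data in sorted(net.interaction_edges.items()):
        g.add_edge(
            a, b, kind="pp", coefficient=float(data.coefficient),
            p_raw=float(data.p_raw), p_adj=float(data.p_adj), undirected=True,
        )
    nx.write_graphml(g, path)


_EDGE_TSV_COLS = ("source", "target", "kind", "sign", "coefficient", "p_raw", "p_adj")


def _write_edge_tsv(net, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_EDGE_TSV_COLS) + "\n")
        for (tf, g), d in sorted(net.transcription_edges.items()):
            fh.write(
                f"{tf}\t{g}\ttranscription\t{_transcription_relation(d)}"
                f"\t{d.coefficient:.10g}\t{d.p_raw:.6g}\t{d.p_adj:.6g}\n"
            )
        for (a, b), d in sorted(net.interaction_edges.items()):
            fh.write(
                f"{a}\t{b}\tpp\t.\t{d.coefficient:.10g}"
                f"\t{d.p_raw:.6g}\t{d.p_adj:.6g}\n"
            )


def read_network_tsv(path):
    """Read back an edge-TSV written by :func:`write_network`.

    Returns ``(transcription_edges, interaction_edges)`` as dicts keyed by the
    (source, target) pair, values = (sign, coefficient, p_raw, p_adj).
    """
    trans: dict[tuple[str, str], tuple] = {}
    inter: dict[tuple[str, str], tuple] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != _EDGE_TSV_COLS:
            raise NetworkFormatError(f"{path}: unexpected edge-TSV header {header}")
        for line in fh:
            s, t, kind, sign, coef, praw, padj = line.rstrip("\n").split("\t")
            rec = (sign, float(coef), float(praw), float(padj))
            if kind == "transcription":
                trans[(s, t)] = rec
            elif kind == "pp":
                inter[canonical_pair(s, t)] = rec
            else:
                raise NetworkFormatError(f"{path}: unknown edge kind {kind!r}")
    return trans, inter
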