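import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from icnet.data_io import (
    CandidateNetwork,
    ExpressionError,
    ExpressionMatrix,
    NetworkFormatError,
    canonical_pair,
    filter_missing,
    impute_missing,
    linear_to_log2,
    log2_to_linear,
    preprocess,
    read_expression,
    read_network_tsv,
    select_responsive,
    spline_densify,
    write_expression,
    write_network,
)
from icnet.integration import EdgeData, IntegratedNetwork


def _write(tmp_path, text, name="expr.tsv"):
    p = tmp_path / name
    p.write_text(text)
    return p


def _natural_spline_oracle(x, y, xq):
    """Evaluate the natural cubic interpolant at xq by solving the classic
    tridiagonal system for the knot second derivatives (moments)."""
    n = len(x)
    h = np.diff(x)
    a_mat = np.zeros((n, n))
    rhs = np.zeros(n)
    a_mat[0, 0] = a_mat[-1, -1] = 1.0  # natural: M_0 = M_{n-1} = 0
    for i in range(1, n - 1):
        a_mat[i, i - 1] = h[i - 1]
        a_mat[i, i] = 2 * (h[i - 1] + h[i])
        a_mat[i, i + 1] = h[i]
        rhs[i] = 6 * ((y[i + 1] - y[i]) / h[i] - (y[i] - y[i - 1]) / h[i - 1])
    m = np.linalg.solve(a_mat, rhs)
    i = np.searchsorted(x, xq) - 1
    i = min(max(i, 0), n - 2)
    d = xq - x[i]
    return (
        y[i]
        + d * ((y[i + 1] - y[i]) / h[i] - h[i] * (2 * m[i] + m[i + 1]) / 6)
        + d**2 * m[i] / 2
        + d**3 * (m[i + 1] - m[i]) / (6 * h[i])
    )


class TestReadExpression:
    def test_missing_cell_recorded_not_zero(self, tmp_path):
        p = _write(tmp_path, "id\t0\t5\t15\t30\nA\t1\t\t3\t4\nB\t0\t1\t2\t3\nC\tNA\t1\t2\t3\n")
        m = read_expression(p)
        assert np.isnan(m.row("A")[1]) and np.isnan(m.row("C")[0])
        assert np.isnan(m.values).sum() == 2

    def test_header_times(self, tmp_path):
        p = _write(tmp_path, "id\t0\t5\t15\t30\nA\t1\t2\t3\t4\n")
        assert read_expression(p).times.tolist() == [0, 5, 15, 30]

    @pytest.mark.parametrize(
        "body",
        [
            "A\t1\t2\nA\t3\t4\n",        # duplicate id
            "A\t1\t2\nB\t1\tbogus\n",    # non-numeric cell
        ],
    )
    def test_malformed_rows(self, tmp_path, body):
        p = _write(tmp_path, "id\t0\t5\n" + body)
        with pytest.raises(ExpressionError):
            read_expression(p)

    def test_non_increasing_times_rejected(self, tmp_path):
        p = _write(tmp_path, "id\t0\t5\t5\nA\t1\t2\t3\n")
        with pytest.raises(ExpressionError):
            read_expression(p)

    def test_round_trip(self, tmp_path, log2_matrix):
        p = tmp_path / "out.tsv"
        write_expression(log2_matrix, p)
        back = read_expression(p)
        np.testing.assert_allclose(back.values, log2_matrix.values, equal_nan=True)


class TestResponsiveFilter:
    def test_threshold_arithmetic(self, log2_matrix):
        kept = select_responsive(log2_matrix, fold=3)
        # 1.7 >= log2(3) ~ 1.585; |-2.0| >= 1.585; all-zero excluded
        assert "up" in kept and "down" in kept and "flat" not in kept

    def test_requires_log2_scale(self, log2_matrix):
        linear = log2_to_linear(impute_missing(log2_matrix))
        with pytest.raises(ExpressionError):
            select_responsive(linear)

    def test_monotone_in_fold(self, log2_matrix):
        for lo, hi in [(1.5, 2.0), (2.0, 3.0), (3.0, 4.0)]:
            assert select_responsive(log2_matrix, hi) <= select_responsive(log2_matrix, lo)


class TestMissingFilter:
    @pytest.mark.parametrize("n_missing,kept", [(7, False), (6, True), (0, True)])
    def test_boundary(self, n_missing, kept):
        row = np.arange(20.0)
        row[:n_missing] = np.nan
        m = ExpressionMatrix(["A"], np.arange(20), row[None, :])
        assert (("A" in filter_missing(m, 0.3)) is kept)

    def test_monotone_in_threshold(self, log2_matrix):
        assert filter_missing(log2_matrix, 0.1) <= filter_missing(log2_matrix, 0.5)


class TestImpute:
    def test_linear_data_interior(self):
        m = ExpressionMatrix(["A"], [0, 1, 2, 3], [[0.0, 1.0, np.nan, 3.0]])
        out = impute_missing(m)
        assert out.row("A")[2] == pytest.approx(2.0, abs=1e-9)

    def test_no_missing_is_identity(self, log2_matrix):
        complete = log2_matrix.subset(["up", "down", "flat"])
        np.testing.assert_array_equal(impute_missing(complete).values, complete.values)

    def test_matches_independent_natural_spline(self):
        # expected value derived from a hand-rolled natural-spline solve
        # (tridiagonal moment equations), independent of scipy
        t = np.array([0.0, 1, 2, 3, 4, 5])
        poly = lambda x: 0.3 * x**3 - x**2 + 2 * x - 1  # noqa: E731
        vals = poly(t)
        vals_missing = vals.copy()
        vals_missing[3] = np.nan
        out = impute_missing(ExpressionMatrix(["A"], t, vals_missing[None, :]))
        assert out.row("A")[3] == pytest.approx(
            _natural_spline_oracle(np.delete(t, 3), np.delete(vals, 3), 3.0), abs=1e-9
        )

    def test_observed_points_untouched(self, log2_matrix):
        out = impute_missing(log2_matrix)
        obs = ~np.isnan(log2_matrix.values)
        np.testing.assert_array_equal(out.values[obs], log2_matrix.values[obs])

    def test_too_few_observed(self):
        m = ExpressionMatrix(["A"], [0, 1, 2], [[1.0, np.nan, np.nan]])
        with pytest.raises(ExpressionError):
            impute_missing(m)


class TestScaleConversion:
    @pytest.mark.parametrize("v,expected", [(0.0, 1.0), (1.0, 2.0), (-1.0, 0.5)])
    def test_values(self, v, expected):
        m = ExpressionMatrix(["A"], [0, 1], [[v, v]])
        assert log2_to_linear(m).row("A")[0] == pytest.approx(expected)

    def test_round_trip(self, log2_matrix):
        complete = impute_missing(log2_matrix)
        back = linear_to_log2(log2_to_linear(complete))
        np.testing.assert_allclose(back.values, complete.values, atol=1e-12)

    def test_double_conversion_rejected(self, log2_matrix):
        lin = log2_to_linear(impute_missing(log2_matrix))
        with pytest.raises(ExpressionError):
            log2_to_linear(lin)

    @settings(max_examples=50, deadline=None)
    @given(st.floats(-10, 10))
    def test_bijection_positive(self, v):
        m = ExpressionMatrix(["A"], [0, 1], [[v, 0.0]])
        out = log2_to_linear(m)
        assert out.row("A")[0] > 0
        assert linear_to_log2(out).row("A")[0] == pytest.approx(v, abs=1e-12)


class TestDensify:
    def _linear_matrix(self):
        t = np.array([0.0, 2, 4, 6])
        return ExpressionMatrix(["A", "B"], t, np.vstack([2 * t + 1, 0.5 * t]), scale="linear")

    def test_dimensional_contract(self):
        out = spline_densify(self._linear_matrix(), factor=2)
        assert out.n_times == 7
        np.testing.assert_array_equal(out.values[:, ::2], self._linear_matrix().values)

    def test_factor_one_identity(self):
        m = self._linear_matrix()
        np.testing.assert_array_equal(spline_densify(m, 1).values, m.values)

    def test_linear_profile_on_line(self):
        out = spline_densify(self._linear_matrix(), factor=3)
        np.testing.assert_allclose(out.row("A"), 2 * out.times + 1, atol=1e-9)

    def test_factor_below_one_rejected(self):
        with pytest.raises(ValueError):
            spline_densify(self._linear_matrix(), 0)

    def test_negative_clipped(self):
        m = ExpressionMatrix(["A"], [0, 1, 2, 3], [[1.0, 0.0, 0.0, 1.0]], scale="linear")
        out = spline_densify(m, 4)
        assert out.values.min() >= 0.0


def test_preprocess_order_and_output(log2_matrix):
    dens, kept = preprocess(log2_matrix, fold=3, max_missing_fraction=0.3, densify_factor=2)
    assert kept == {"up", "down", "gappy"}
    assert dens.scale == "linear" and dens.is_complete
    assert dens.n_times == 2 * (log2_matrix.n_times - 1) + 1


class TestCandidateNetwork:
    def test_ppi_canonical_and_dedup(self):
        net = CandidateNetwork([], [("B", "A"), ("A", "B"), ("C", "A")])
        assert net.ppi_edges == [("A", "B"), ("A", "C")]

    def test_duplicate_directed_rejected(self):
        with pytest.raises(NetworkFormatError):
            CandidateNetwork([("T", "G"), ("T", "G")], [])

    def test_self_pair_rejected(self):
        with pytest.raises(NetworkFormatError):
            CandidateNetwork([("T", "T")], [])

    def test_neighbors(self):
        net = CandidateNetwork([("T1", "G1"), ("T2", "G1")], [("P1", "P2")])
        assert net.regulators_of("G1") == ["T1", "T2"]
        assert net.partners_of("P2") == ["P1"]


def _toy_network():
    return IntegratedNetwork(
        nodes={
            "TF1": frozenset({"TF", "protein"}),
            "G1": frozenset({"gene"}),
            "P1": frozenset({"protein"}),
            "LONER": frozenset({"gene"}),
        },
        transcription_edges={("TF1", "G1"): EdgeData(0.8, 1e-4, 2e-3)},
        interaction_edges={canonical_pair("TF1", "P1"): EdgeData(-0.1, 1e-3, 5e-3)},
    )


class TestNetworkExport:
    def test_sif_labels(self, tmp_path):
        p = tmp_path / "net.sif"
        write_network(_toy_network(), p, "sif")
        lines = p.read_text().splitlines()
        assert "TF1\tactivates\tG1" in lines
        assert "P1\tpp\tTF1" in lines
        assert "LONER" in lines  # isolated node still listed

    def test_repression_label(self, tmp_path):
        net = _toy_network()
        net.transcription_edges[("TF1", "G1")] = EdgeData(-0.8, 1e-4, 2e-3)
        p = tmp_path / "net.sif"
        write_network(net, p, "sif")
        assert "TF1\trepresses\tG1" in p.read_text()

    def test_graphml_carries_attributes(self, tmp_path):
        import networkx as nx

        p = tmp_path / "net.graphml"
        write_network(_toy_network(), p, "graphml")
        g = nx.read_graphml(p)
        assert set(g.nodes) == {"TF1", "G1", "P1", "LONER"}
        e = g.edges["TF1", "G1"]
        assert e["coefficient"] == pytest.approx(0.8)
        assert e["p_adj"] == pytest.approx(2e-3)

    def test_empty_network_graphml_lists_nodes(self, tmp_path):
        import networkx as nx

        net = IntegratedNetwork(
            nodes={"A": frozenset({"gene"})}, transcription_edges={}, interaction_edges={}
        )
        p = tmp_path / "empty.graphml"
        write_network(net, p, "graphml")
        g = nx.read_graphml(p)
        assert set(g.nodes) == {"A"} and g.number_of_edges() == 0

    def test_edge_tsv_round_trip(self, tmp_path):
        p = tmp_path / "net.tsv"
        net = _toy_network()
        write_network(net, p, "edge-tsv")
        trans, inter = read_network_tsv(p)
        assert set(trans) == set(net.transcription_edges)
        assert set(inter) == set(net.interaction_edges)
        assert trans[("TF1", "G1")][0] == "activates"

    def test_unknown_format(self, tmp_path):
        with pytest.raises(NetworkFormatError):
            write_network(_toy_network(), tmp_path / "x", "dot")
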