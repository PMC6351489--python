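"""Network construction, normalization and bi-colored assembly."""
import numpy as np
import pytest

from mprnmf import (
    EntityNetwork,
    ExpressionMatrix,
    ValidationError,
    assemble_bicolored,
    build_coexpression_network,
    build_disease_view,
    build_expression_view,
    jaccard,
    laplacian,
    largest_connected_component,
    normalize_adjacency,
)
from mprnmf.types import BipartiteView


def _expr(values, prefix="e"):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        ids=[f"{prefix}{i}" for i in range(values.shape[0])],
        samples=[f"s{j}" for j in range(values.shape[1])],
        values=values,
    )


class TestCoexpression:
    def test_perfect_linear_dependence_gives_unit_edge(self):
        net = build_coexpression_network(_expr([[1, 2, 3], [2, 4, 6]]), 1.0)
        assert net.W[0, 1] == pytest.approx(1.0)

    def test_negative_correlation_dropped(self):
        net = build_coexpression_network(_expr([[1, 2, 3], [3, 2, 1]]), 0.0)
        assert net.W[0, 1] == 0.0

    def test_absolute_correlation_option_keeps_negatives(self):
        net = build_coexpression_network(
            _expr([[1, 2, 3], [3, 2, 1]]), 0.5, use_absolute_correlation=True
        )
        assert net.W[0, 1] == pytest.approx(1.0)

    def test_zero_variance_entity_isolated(self):
        net = build_coexpression_network(_expr([[1, 1, 1], [1, 2, 3]]), 0.0)
        assert net.W[0, 1] == 0.0

    def test_single_sample_rejected(self):
        with pytest.raises(ValidationError):
            build_coexpression_network(_expr([[1], [2]]), 0.5)

    def test_matches_brute_force_pairwise_oracle(self, rng):
        V = rng.normal(size=(10, 15))
        net = build_coexpression_network(_expr(V), 0.5)
        for i in range(10):
            for j in range(10):
                r = np.corrcoef(V[i], V[j])[0, 1]
                expected = r if (i != j and r >= 0.5) else 0.0
                assert net.W[i, j] == pytest.approx(expected, abs=1e-12)


class TestExpressionView:
    def test_identical_profiles_give_unit_entry(self):
        l = _expr([[1.0, 2.0, 5.0]], "l")
        g = _expr([[1.0, 2.0, 5.0]], "g")
        assert build_expression_view(l, g, 0.5).Y[0, 0] == pytest.approx(1.0)

    def test_anticorrelated_thresholded_out(self):
        l = _expr([[1.0, 2.0, 3.0]], "l")
        g = _expr([[3.0, 2.0, 1.0]], "g")
        assert build_expression_view(l, g, 0.0).Y[0, 0] == 0.0

    def test_sample_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            build_expression_view(
                _expr([[1, 2, 3]], "l"), _expr([[1, 2]], "g"), 0.5
            )

    def test_matches_entrywise_oracle(self, rng):
        L, G = rng.normal(size=(5, 8)), rng.normal(size=(7, 8))
        Y = build_expression_view(_expr(L, "l"), _expr(G, "g"), 0.3).Y
        for i in range(5):
            for j in range(7):
                r = np.corrcoef(L[i], G[j])[0, 1]
                assert Y[i, j] == pytest.approx(r if r >= 0.3 else 0.0, abs=1e-12)


class TestDiseaseView:
    @pytest.mark.parametrize(
        "dl,dg,expected",
        [
            ({"d1", "d2"}, {"d1", "d2"}, 1.0),
            ({"d1"}, {"d2"}, 0.0),
            ({"d1", "d2", "d3"}, {"d2", "d3", "d4"}, 0.5),
            (set(), set(), 0.0),
        ],
    )
    def test_jaccard_formula(self, dl, dg, expected):
        view = build_disease_view({"l0": dl}, {"g0": dg})
        assert view.Y[0, 0] == expected

    def test_respects_explicit_id_order(self):
        view = build_disease_view(
            {"a": {"d"}, "b": set()}, {"g": {"d"}}, lnc_ids=["b", "a"], gene_ids=["g"]
        )
        np.testing.assert_array_equal(view.Y, [[0.0], [1.0]])


class TestLargestComponent:
    def test_connected_graph_identity(self):
        W = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0.0]])
        net = EntityNetwork(ids=["a", "b", "c"], W=W)
        sub, keep = largest_connected_component(net)
        assert sub.ids == net.ids and keep == [0, 1, 2]

    def test_keeps_largest_of_two_components(self):
        W = np.zeros((5, 5))
        W[0, 1] = W[1, 0] = 1
        W[2, 3] = W[3, 2] = 1
        W[3, 4] = W[4, 3] = 1
        sub, keep = largest_connected_component(
            EntityNetwork(ids=list("abcde"), W=W)
        )
        assert sub.ids == ["c", "d", "e"] and keep == [2, 3, 4]

    def test_empty_graph_rejected(self):
        with pytest.raises(ValidationError):
            largest_connected_component(EntityNetwork(ids=[], W=np.zeros((0, 0))))

    def test_matches_bfs_oracle(self, rng):
        n = 25
        W = np.triu((rng.random((n, n)) < 0.08).astype(float), 1)
        W = W + W.T
        net = EntityNetwork(ids=[f"n{i}" for i in range(n)], W=W)
        sub, keep = largest_connected_component(net)

        # plain breadth-first search over adjacency
        def bfs(start):
            seen, queue = {start}, [start]
            while queue:
                u = queue.pop()
                for v in np.nonzero(W[u])[0]:
                    if v not in seen:
                        seen.add(int(v))
                        queue.append(int(v))
            return seen

        remaining = set(range(n))
        comps = []
        while remaining:
            c = bfs(min(remaining))
            comps.append(sorted(c))
            remaining -= c
        comps.sort(key=lambda c: (-len(c), c[0]))
        assert keep == comps[0]


class TestNormalization:
    def test_single_unit_edge(self):
        net = EntityNetwork(ids=["a", "b"], W=np.array([[0, 1], [1, 0.0]]))
        np.testing.assert_allclose(normalize_adjacency(net), [[0, 1], [1, 0]])

    def test_triangle_halves(self):
        W = np.ones((3, 3)) - np.eye(3)
        net = EntityNetwork(ids=list("abc"), W=W)
        Wb = normalize_adjacency(net)
        np.testing.assert_allclose(Wb, W / 2)

    def test_isolated_vertex_zero_row(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 2.0
        Wb = normalize_adjacency(EntityNetwork(ids=list("abc"), W=W))
        assert (Wb[2] == 0).all() and (Wb[:, 2] == 0).all()

    def test_matches_explicit_formula_oracle(self, rng):
        n = 12
        W = np.triu(rng.random((n, n)) * (rng.random((n, n)) < 0.4), 1)
        W = W + W.T
        net = EntityNetwork(ids=[f"n{i}" for i in range(n)], W=W)
        d = W.sum(1)
        Dm = np.diag([1 / np.sqrt(x) if x > 0 else 0.0 for x in d])
        np.testing.assert_allclose(normalize_adjacency(net), Dm @ W @ Dm, atol=1e-12)

    def test_laplacian_trivial_cases(self):
        net = EntityNetwork(ids=["a", "b"], W=np.array([[0, 1], [1, 0.0]]))
        np.testing.assert_allclose(laplacian(net), [[1, -1], [-1, 1]])
        empty = EntityNetwork(ids=list("abc"), W=np.zeros((3, 3)))
        np.testing.assert_allclose(laplacian(empty), np.eye(3))

    def test_laplacian_psd_and_nullvector(self, rng):
        n = 10
        W = np.triu(rng.random((n, n)) * (rng.random((n, n)) < 0.6), 1)
        W = W + W.T
        net = EntityNetwork(ids=[f"n{i}" for i in range(n)], W=W)
        L = laplacian(net)
        eigs = np.linalg.eigvalsh(L)
        assert eigs.min() >= -1e-10
        d = net.degrees()
        if (d > 0).all():
            np.testing.assert_allclose(L @ np.sqrt(d), 0, atol=1e-8)

    def test_permutation_equivariance(self, rng):
        n = 9
        W = np.triu(rng.random((n, n)) * (rng.random((n, n)) < 0.5), 1)
        W = W + W.T
        net = EntityNetwork(ids=[f"n{i}" for i in range(n)], W=W)
        perm = rng.permutation(n)
        permuted = EntityNetwork(
            ids=[net.ids[i] for i in perm], W=W[np.ix_(perm, perm)]
        )
        for op in (normalize_adjacency, laplacian):
            M = op(net)
            np.testing.assert_allclose(op(permuted), M[np.ix_(perm, perm)], atol=1e-12)


class TestBicolored:
    def test_zero_view_gives_block_diagonal(self):
        W_l = EntityNetwork(ids=["l0"], W=np.zeros((1, 1)))
        W_g = EntityNetwork(ids=["g0"], W=np.zeros((1, 1)))
        view = BipartiteView("v", ["l0"], ["g0"], np.zeros((1, 1)))
        C = assemble_bicolored(W_l, W_g, view)
        np.testing.assert_array_equal(C.C, np.zeros((2, 2)))

    def test_minimal_cross_edge(self):
        W_l = EntityNetwork(ids=["l0"], W=np.zeros((1, 1)))
        W_g = EntityNetwork(ids=["g0"], W=np.zeros((1, 1)))
        view = BipartiteView("v", ["l0"], ["g0"], np.array([[0.5]]))
        C = assemble_bicolored(W_l, W_g, view)
        np.testing.assert_array_equal(C.C, [[0, 0.5], [0.5, 0]])

    def test_blocks_recoverable_by_slicing(self, rng):
        n_l, n_g = 4, 6
        A = np.triu(rng.random((n_l, n_l)), 1)
        B = np.triu(rng.random((n_g, n_g)), 1)
        W_l = EntityNetwork([f"l{i}" for i in range(n_l)], A + A.T)
        W_g = EntityNetwork([f"g{i}" for i in range(n_g)], B + B.T)
        Y = rng.random((n_l, n_g))
        view = BipartiteView("v", W_l.ids, W_g.ids, Y)
        C = assemble_bicolored(W_l, W_g, view)
        np.testing.assert_array_equal(C.W_l, W_l.W)
        np.testing.assert_array_equal(C.W_g, W_g.W)
        np.testing.assert_array_equal(C.Y, Y)
        np.testing.assert_array_equal(C.C, C.C.T)

    def test_dimension_mismatch_rejected(self):
        W_l = EntityNetwork(ids=["l0"], W=np.zeros((1, 1)))
        W_g = EntityNetwork(ids=["g0"], W=np.zeros((1, 1)))
        bad = BipartiteView("v", ["l0", "l1"], ["g0"], np.zeros((2, 1)))
        with pytest.raises(ValidationError):
            assemble_bicolored(W_l, W_g, bad)


def test_noise_free_views_block_structured(small_instance):
    """At noise=0 both association views vanish across planted modules."""
    from mprnmf import generate_instance

    inst = generate_instance(12, 24, 9, 3, noise=0.0, mask_fraction=0.0, seed=11)
    ev = build_expression_view(inst.expr_l, inst.expr_g, 0.5)
    dv = build_disease_view(
        inst.lnc_diseases, inst.gene_diseases, inst.expr_l.ids, inst.expr_g.ids
    )
    cross = inst.lnc_modules[:, None] != inst.gene_modules[None, :]
    assert (ev.Y[cross] == 0).all() and (dv.Y[cross] == 0).all()
    same = ~cross
    assert (ev.Y[same] > 0.99).all() and (dv.Y[same] == 1.0).all()
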