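"""Similarity-matrix construction against brute-force oracles and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import circgat as cg
from circgat.containers import DiseaseDAG, SimilarityMatrix

from conftest import random_association, random_symmetric_unit


# ---------------------------------------------------------------- oracles


def wang_values_oracle(edges: dict[str, list[str]], term: str, decay: float) -> dict[str, float]:
    """Exhaustive path-walk semantic values: S(t) is the max over all upward
    paths from ``term`` to t of decay^len(path)."""
    values = {}

    def walk(node, contrib):
        if contrib > values.get(node, 0.0):
            values[node] = contrib
            for parent in edges.get(node, []):
                walk(parent, contrib * decay)

    walk(term, 1.0)
    return values


def fs_oracle(ss: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Direct double-loop evaluation of the group best-match formula."""
    nc = y.shape[0]
    fs = np.eye(nc)
    for i in range(nc):
        for j in range(nc):
            if i == j:
                continue
            di = [d for d in range(y.shape[1]) if y[i, d] == 1]
            dj = [d for d in range(y.shape[1]) if y[j, d] == 1]
            if not di or not dj:
                continue
            total = sum(max(ss[dk, dl] for dl in di) for dk in dj)
            total += sum(max(ss[dl, dk] for dk in dj) for dl in di)
            fs[i, j] = total / (len(di) + len(dj))
    return fs


def chain_dag(decay_terms: list[tuple[str, str, list[str]]]) -> DiseaseDAG:
    terms = {tid: name for tid, name, _ in decay_terms}
    edges = [(tid, p) for tid, _, parents in decay_terms for p in parents]
    return DiseaseDAG.from_terms(terms, edges)


# ------------------------------------------------------- semantic similarity


class TestSemanticSimilarity:
    def test_same_term_gives_unit_similarity(self):
        dag = chain_dag([("T:r", "root", []), ("T:d", "flu", ["T:r"])])
        ss = cg.semantic_similarity(dag, ["flu"], decay=0.5)
        assert ss.values[0, 0] == 1.0

    def test_disjoint_dags_give_zero(self):
        dag = chain_dag(
            [
                ("T:r1", "root one", []),
                ("T:r2", "root two", []),
                ("T:d1", "flu", ["T:r1"]),
                ("T:d2", "gout", ["T:r2"]),
            ]
        )
        ss = cg.semantic_similarity(dag, ["flu", "gout"], decay=0.5)
        assert ss.values[0, 1] == 0.0

    def test_shared_chain_matches_path_walk_oracle(self):
        # root -> a -> {d1, d2}, decay 0.5
        dag = chain_dag(
            [
                ("T:r", "root", []),
                ("T:a", "mid", ["T:r"]),
                ("T:d1", "flu", ["T:a"]),
                ("T:d2", "gout", ["T:a"]),
            ]
        )
        edges = {"T:d1": ["T:a"], "T:d2": ["T:a"], "T:a": ["T:r"]}
        s1 = wang_values_oracle(edges, "T:d1", 0.5)
        s2 = wang_values_oracle(edges, "T:d2", 0.5)
        shared = s1.keys() & s2.keys()
        expected = sum(s1[t] + s2[t] for t in shared) / (sum(s1.values()) + sum(s2.values()))
        ss = cg.semantic_similarity(dag, ["flu", "gout"], decay=0.5)
        assert ss.values[0, 1] == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(1.5 / 3.5, abs=1e-12)

    def test_wang_values_match_oracle_on_random_dags(self, rng):
        # random layered DAGs with multiple parents exercise the max-over-paths
        for trial in range(25):
            n = int(rng.integers(4, 9))
            parents = {f"T:{0}": []}
            for i in range(1, n):
                k = int(rng.integers(1, min(i, 3) + 1))
                parents[f"T:{i}"] = [f"T:{j}" for j in rng.choice(i, size=k, replace=False)]
            dag = chain_dag([(t, f"name {t}", ps) for t, ps in parents.items()])
            term = f"T:{n - 1}"
            got = cg.wang_semantic_values(dag, term, 0.5)
            assert got == pytest.approx(wang_values_oracle(parents, term, 0.5), abs=1e-12)

    def test_unmapped_disease_row_is_zero(self):
        dag = chain_dag([("T:r", "root", []), ("T:d", "flu", ["T:r"])])
        ss = cg.semantic_similarity(dag, ["flu", "unseen disease"], decay=0.5)
        assert ss.values[1].sum() == 0.0 and ss.values[:, 1].sum() == 0.0

    def test_added_shared_ancestor_never_decreases_similarity(self):
        # enumerate 5-node configurations: two leaves under separate parents,
        # then insert a shared ancestor between the parents and the root
        for decay in (0.3, 0.5, 0.8):
            base = chain_dag(
                [
                    ("T:r", "root", []),
                    ("T:p1", "p one", ["T:r"]),
                    ("T:p2", "p two", ["T:r"]),
                    ("T:d1", "flu", ["T:p1"]),
                    ("T:d2", "gout", ["T:p2"]),
                ]
            )
            richer = chain_dag(
                [
                    ("T:r", "root", []),
                    ("T:s", "shared", ["T:r"]),
                    ("T:p1", "p one", ["T:s"]),
                    ("T:p2", "p two", ["T:s"]),
                    ("T:d1", "flu", ["T:p1"]),
                    ("T:d2", "gout", ["T:p2"]),
                ]
            )
            lo = cg.semantic_similarity(base, ["flu", "gout"], decay).values[0, 1]
            hi = cg.semantic_similarity(richer, ["flu", "gout"], decay).values[0, 1]
            assert hi >= lo

    def test_cyclic_ontology_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            chain_dag([("T:a", "a", ["T:b"]), ("T:b", "b", ["T:a"])])

    def test_empty_disease_list_rejected(self):
        dag = chain_dag([("T:r", "root", [])])
        with pytest.raises(ValueError, match="empty"):
            cg.semantic_similarity(dag, [], decay=0.5)

    @pytest.mark.parametrize("decay", [0.0, 1.0, -0.5])
    def test_decay_outside_open_interval_rejected(self, decay):
        dag = chain_dag([("T:r", "root", [])])
        with pytest.raises(ValueError, match="decay"):
            cg.semantic_similarity(dag, ["root"], decay=decay)


# ------------------------------------------------------ functional similarity


class TestFunctionalSimilarity:
    def test_shared_singleton_group_gives_one(self):
        y = cg.AssociationMatrix(np.array([[1.0], [1.0]]), ["c1", "c2"], ["d"])
        ss = SimilarityMatrix(np.eye(1), ["d"], "semantic")
        fs = cg.circ_functional_similarity(ss, y)
        assert fs.values[0, 1] == 1.0

    def test_disjoint_groups_under_identity_ss_give_zero(self):
        y = cg.AssociationMatrix(np.array([[1.0, 0.0], [0.0, 1.0]]), ["c1", "c2"], ["d1", "d2"])
        ss = SimilarityMatrix(np.eye(2), ["d1", "d2"], "semantic")
        fs = cg.circ_functional_similarity(ss, y)
        assert fs.values[0, 1] == 0.0

    def test_empty_group_gives_zero_offdiagonal_unit_diagonal(self):
        y = cg.AssociationMatrix(np.array([[0.0, 0.0], [1.0, 1.0]]), ["c1", "c2"], ["d1", "d2"])
        ss = SimilarityMatrix(np.eye(2), ["d1", "d2"], "semantic")
        fs = cg.circ_functional_similarity(ss, y)
        assert fs.values[0, 1] == 0.0
        assert fs.values[0, 0] == 1.0

    def test_matches_double_loop_oracle_on_random_instances(self, rng):
        for _ in range(100):
            nc = int(rng.integers(2, 11))
            nd = int(rng.integers(2, 9))
            y = random_association(rng, nc, nd)
            ss_vals = random_symmetric_unit(rng, nd)
            ss = SimilarityMatrix(ss_vals, y.disease_names, "semantic")
            got = cg.circ_functional_similarity(ss, y).values
            np.testing.assert_allclose(got, fs_oracle(ss_vals, y.values), atol=1e-12)

    def test_label_mismatch_rejected(self):
        y = cg.AssociationMatrix(np.array([[1.0]]), ["c1"], ["d1"])
        ss = SimilarityMatrix(np.eye(1), ["other"], "semantic")
        with pytest.raises(ValueError, match="mismatch"):
            cg.circ_functional_similarity(ss, y)


# ----------------------------------------------------------------- GIP kernel


class TestGipKernel:
    def test_bandwidth_one_when_single_association_per_row(self):
        y = cg.AssociationMatrix(np.eye(3), list("abc"), list("xyz"))
        assert cg.gip_bandwidth(y, "circ") == 1.0

    def test_bandwidth_all_ones_2x2_disease(self):
        y = cg.AssociationMatrix(np.ones((2, 2)), ["a", "b"], ["x", "y"])
        assert cg.gip_bandwidth(y, "disease") == 0.5

    def test_bandwidth_matches_direct_formula(self, rng):
        for _ in range(100):
            y = random_association(rng, 8, 5)
            for axis, profiles in (("circ", y.values), ("disease", y.values.T)):
                expected = 1.0 / np.mean([(p**2).sum() for p in profiles])
                assert cg.gip_bandwidth(y, axis) == pytest.approx(expected, rel=1e-12)

    def test_all_zero_matrix_rejected_with_axis_name(self):
        y = cg.AssociationMatrix(np.zeros((2, 2)), ["a", "b"], ["x", "y"])
        y.values[:] = 0.0
        with pytest.raises(ValueError, match="circ"):
            cg.gip_bandwidth(y, "circ")

    def test_orthogonal_unit_profiles(self):
        # profiles (1,0) and (0,1): gamma=1, similarity exp(-2)
        y = cg.AssociationMatrix(np.eye(2), ["a", "b"], ["x", "y"])
        gc = cg.gip_kernel(y, "circ")
        assert gc.values[0, 1] == pytest.approx(np.exp(-2.0), abs=1e-12)

    def test_kernel_matches_direct_formula(self, rng):
        for _ in range(100):
            y = random_association(rng, 6, 4)
            gamma = cg.gip_bandwidth(y, "circ")
            got = cg.gip_kernel(y, "circ").values
            for i in range(6):
                for j in range(6):
                    expected = np.exp(-gamma * ((y.values[i] - y.values[j]) ** 2).sum())
                    assert got[i, j] == pytest.approx(expected, abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_kernel_symmetric_unit_diagonal(self, seed):
        y = random_association(np.random.default_rng(seed), 7, 4)
        for axis in ("circ", "disease"):
            g = cg.gip_kernel(y, axis).values
            assert np.array_equal(g, g.T)
            assert np.array_equal(np.diag(g), np.ones(len(g)))
            assert (g > 0).all() and (g <= 1).all()


# ----------------------------------------------------------------- integrate


class TestIntegrate:
    @staticmethod
    def _pair(primary_vals, fallback_vals, labels):
        p = SimilarityMatrix(primary_vals, labels, "functional")
        f = SimilarityMatrix(fallback_vals, labels, "gip_circ")
        return p, f

    def test_all_zero_primary_returns_fallback(self, rng):
        fb = random_symmetric_unit(rng, 3)
        p, f = self._pair(np.zeros((3, 3)), fb, list("abc"))
        np.testing.assert_array_equal(cg.integrate(p, f).values, fb)

    def test_dense_primary_returns_primary(self, rng):
        pv = random_symmetric_unit(rng, 3) * 0.5 + 0.25
        p, f = self._pair(pv, random_symmetric_unit(rng, 3), list("abc"))
        np.testing.assert_array_equal(cg.integrate(p, f).values, pv)

    def test_mixed_case_matches_cellwise_oracle(self, rng):
        for _ in range(100):
            pv = random_symmetric_unit(rng, 3)
            pv[rng.random((3, 3)) < 0.5] = 0.0
            pv = np.triu(pv) + np.triu(pv, 1).T
            fb = random_symmetric_unit(rng, 3)
            p, f = self._pair(pv, fb, list("abc"))
            got = cg.integrate(p, f).values
            for i in range(3):
                for j in range(3):
                    assert got[i, j] == (pv[i, j] if pv[i, j] != 0 else fb[i, j])

    def test_never_zero_where_fallback_nonzero(self, rng):
        pv = np.zeros((4, 4))
        fb = random_symmetric_unit(rng, 4) * 0.9 + 0.05
        p, f = self._pair(pv, fb, list("abcd"))
        assert (cg.integrate(p, f).values != 0).all()

    def test_label_mismatch_rejected(self, rng):
        p = SimilarityMatrix(np.eye(2), ["a", "b"], "functional")
        f = SimilarityMatrix(np.eye(2), ["a", "c"], "gip_circ")
        with pytest.raises(ValueError, match="mismatch"):
            cg.integrate(p, f)


def test_all_six_matrices_symmetric_in_unit_interval(planted):
    for name, sim in planted["sims"].items():
        m = sim.values
        assert np.abs(m - m.T).max() <= 1e-9, name
        assert m.min() >= 0.0 and m.max() <= 1.0 + 1e-12, name
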