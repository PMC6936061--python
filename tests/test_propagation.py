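import dataclasses

import numpy as np
import pandas as pd
import pytest

from mecorank.graph import build_bipartite, prune_zero_vertices
from mecorank.io import PPINetwork
from mecorank.preprocess import PatientProfile
from mecorank.propagation import (
    Config,
    PatientRanking,
    fixed_point_oracle,
    propagate,
    rank_patient,
)

from conftest import random_patient_graph


class TestConfig:
    def test_lambda_coupling_both_ways(self):
        c = Config(lambda_v=0.25)
        assert c.lambda_u == 0.75
        c.lambda_u = 0.6
        assert c.lambda_v == pytest.approx(0.4)
        c.lambda_v = 0.3
        assert c.lambda_u == pytest.approx(0.7)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"lambda_u": 1.5},
            {"epsilon": 0.0},
            {"max_iter": 0},
            {"delta": -0.1},
            {"top_k": 0},
            {"init": "bogus"},
        ],
    )
    def test_validation(self, kwargs):
        with pytest.raises(ValueError):
            Config(**kwargs)

    def test_yaml_roundtrip(self, tmp_path):
        p = tmp_path / "c.yaml"
        p.write_text("lambda_u: 0.8\nepsilon: 1.0e-5\ndelta: 0.9\n")
        c = Config.from_yaml(p)
        assert c.lambda_u == 0.8 and c.epsilon == 1e-5 and c.delta == 0.9

    def test_coefficient_conservation(self):
        # the three damping coefficients of the update always sum to 1
        rng = np.random.default_rng(0)
        for lu in rng.uniform(0, 1, size=100):
            c = Config(lambda_u=float(lu))
            total = (1 - c.lambda_u) + c.lambda_u * (1 - c.lambda_v) + c.lambda_u * c.lambda_v
            assert total == pytest.approx(1.0, abs=1e-15)


class TestPropagate:
    def test_no_damping_returns_x0_exactly(self, path_graph):
        r = propagate(path_graph, Config(lambda_u=0.0))
        np.testing.assert_array_equal(r.scores, path_graph.x0)
        assert r.converged and r.iterations_used == 1

    def test_edgeless_graph_scales_x0(self):
        ppi = PPINetwork.from_edges([], extra_genes=["a", "b"])
        prof = PatientProfile(
            "P", pd.Series({"a": 2.0, "b": -1.0}), pd.Series({"a": 0.0, "b": 0.0}), {}
        )
        g = prune_zero_vertices(build_bipartite(prof, ppi))
        r = propagate(g)
        np.testing.assert_array_equal(r.scores, (1 - 0.9) * g.x0)

    def test_path_toy_matches_dense_solve(self, path_graph):
        r = propagate(path_graph, Config(epsilon=1e-10))
        expected = fixed_point_oracle(path_graph)
        np.testing.assert_allclose(r.scores, expected, atol=1e-6)
        assert r.converged

    def test_oracle_closed_form_when_linear_part_absent(self, path_graph):
        x = fixed_point_oracle(path_graph, Config(lambda_u=1.0))  # lambda_v = 0
        t2 = path_graph.W_vu @ (path_graph.y / np.sqrt(path_graph.d_v))
        np.testing.assert_allclose(x, t2)

    def test_oracle_agreement_on_random_graphs(self):
        # agreement is checked at a tolerance-matched epsilon (stopping at
        # eps leaves the iterate within ~rho*eps of the fixed point);
        # convergence speed is checked at the default epsilon
        rng = np.random.default_rng(42)
        for _ in range(50):
            g = random_patient_graph(rng)
            r = propagate(g, Config(epsilon=1e-8))
            x = fixed_point_oracle(g)
            np.testing.assert_allclose(r.scores, x, atol=1e-6)
            r_default = propagate(g)
            assert r_default.converged and r_default.iterations_used < 100

    def test_contraction_spectral_radius(self):
        # the linear part lambda_u*lambda_v*What_uu must be a contraction
        from mecorank.propagation import _inv_sqrt

        rng = np.random.default_rng(7)
        for _ in range(20):
            g = random_patient_graph(rng, max_u=30)
            A = (g.W_uu @ np.diag(_inv_sqrt(g.d_u))) * 0.9 * 0.1
            rho = max(abs(np.linalg.eigvals(A)))
            assert rho < 1

    def test_monotone_in_damage_coefficient(self):
        rng = np.random.default_rng(3)
        checked = 0
        for _ in range(30):
            g = random_patient_graph(rng, max_u=20, max_v=8)
            if g.n == 0:
                continue
            k = int(rng.integers(g.n))
            g2 = dataclasses.replace(g, y=g.y.copy())
            g2.y[k] *= 2.0
            x1 = fixed_point_oracle(g)
            x2 = fixed_point_oracle(g2)
            assert (x2 - x1 >= -1e-12).all()
            neighbors = g.W_vu[:, k].toarray().ravel() > 0
            assert (x2[neighbors] > x1[neighbors]).all()
            checked += 1
        assert checked >= 20

    def test_permutation_equivariance(self):
        # relabeling genes permutes the scores identically
        genes = ["a", "b", "c", "d"]
        relabel = {"a": "w", "b": "z", "c": "x", "d": "y"}
        edges = [("a", "b"), ("b", "c"), ("c", "d"), ("a", "d")]
        x0 = {"a": 0.3, "b": -1.0, "c": 2.0, "d": 0.0}
        mutated = {"b": 1.9, "d": 1.2}
        ppi1 = PPINetwork.from_edges(edges)
        ppi2 = PPINetwork.from_edges([(relabel[a], relabel[b]) for a, b in edges])
        p1 = PatientProfile("P", pd.Series(x0), pd.Series(x0), mutated)
        p2 = PatientProfile(
            "P",
            pd.Series({relabel[g]: v for g, v in x0.items()}),
            pd.Series({relabel[g]: v for g, v in x0.items()}),
            {relabel[g]: v for g, v in mutated.items()},
        )
        r1 = propagate(prune_zero_vertices(build_bipartite(p1, ppi1)), Config(epsilon=1e-12))
        r2 = propagate(prune_zero_vertices(build_bipartite(p2, ppi2)), Config(epsilon=1e-12))
        s1 = dict(zip(r1.genes, r1.scores))
        s2 = dict(zip(r2.genes, r2.scores))
        for g in genes:
            assert s2[relabel[g]] == pytest.approx(s1[g], abs=1e-12)

    def test_unpruned_graph_rejected(self):
        ppi = PPINetwork.from_edges([("a", "b")], extra_genes=["d"])
        prof = PatientProfile(
            "P", pd.Series({"a": 0.0, "b": 0.0}), pd.Series({"a": 0.0, "b": 0.0}), {"d": 1.0}
        )
        g = build_bipartite(prof, ppi)
        with pytest.raises(ValueError, match="prune"):
            propagate(g)

    def test_fixed_dx_variant_is_single_step_closed_form(self, path_graph):
        cfg = Config(fixed_dx=True)
        r = propagate(path_graph, cfg)
        assert r.converged and r.iterations_used == 1
        np.testing.assert_allclose(r.scores, fixed_point_oracle(path_graph, cfg))

    def test_init_does_not_change_fixed_point(self, path_graph):
        rs = [
            propagate(path_graph, Config(init=i, epsilon=1e-12)).scores
            for i in ("dx", "x0", "zeros")
        ]
        np.testing.assert_allclose(rs[0], rs[1], atol=1e-10)
        np.testing.assert_allclose(rs[0], rs[2], atol=1e-10)


class TestRankPatient:
    def test_affine_rescale(self):
        r = PatientRanking(
            "P", ["g1", "g2", "g3"], np.array([3.0, 1.0, 2.0]), 1, True,
            np.array([False, False, False]),
        )
        series = rank_patient(r)
        assert list(series.index) == ["g1", "g3", "g2"]
        np.testing.assert_allclose(series.to_numpy(), [1.0, 0.5, 0.0])

    def test_single_gene_normalizes_to_one(self):
        r = PatientRanking("P", ["g"], np.array([7.0]), 1, True, np.array([False]))
        with pytest.warns(UserWarning, match="all scores equal"):
            series = rank_patient(r)
        assert series["g"] == 1.0

    def test_all_equal_scores_warn_and_sort_lexicographically(self):
        r = PatientRanking(
            "P", ["b", "a"], np.array([1.0, 1.0]), 1, True, np.array([False, False])
        )
        with pytest.warns(UserWarning, match="all scores equal"):
            series = rank_patient(r)
        assert list(series.index) == ["a", "b"]
        assert (series == 1.0).all()

    def test_ties_break_lexicographically(self):
        r = PatientRanking(
            "P", ["z", "a", "m"], np.array([1.0, 1.0, 0.0]), 1, True,
            np.array([False] * 3),
        )
        series = rank_patient(r)
        assert list(series.index) == ["a", "z", "m"]
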