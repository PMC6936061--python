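import numpy as np
import pandas as pd
import pytest

from mecorank.graph import PatientBipartiteGraph, build_bipartite, prune_zero_vertices
from mecorank.io import ExpressionMatrix, MutationRecord, MutationTable, PPINetwork
from mecorank.preprocess import PatientProfile
from mecorank.propagation import PatientRanking


@pytest.fixture
def path_ppi():
    """The PPI path a - b - c."""
    return PPINetwork.from_edges([("a", "b"), ("b", "c")])


@pytest.fixture
def path_graph(path_ppi):
    """Patient over the path PPI: mutated {b} with y=2, x0 = dx = (1, 0, 1)."""
    profile = PatientProfile(
        sample="P1",
        x0=pd.Series({"a": 1.0, "b": 0.0, "c": 1.0}),
        dx=pd.Series({"a": 1.0, "b": 0.0, "c": 1.0}),
        mutated={"b": 2.0},
    )
    return build_bipartite(profile, path_ppi)


@pytest.fixture
def small_expr():
    values = pd.DataFrame(
        {
            "T1": [1.0, 5.0, 4.0],
            "T2": [3.0, 5.0, 6.0],
            "N1": [1.0, 5.0, 1.0],
            "N2": [3.0, 5.0, 3.0],
        },
        index=["g1", "g2", "g3"],
    )
    cond = pd.Series({"T1": "tumor", "T2": "tumor", "N1": "normal", "N2": "normal"})
    return ExpressionMatrix(values, cond)


@pytest.fixture
def small_mutations():
    return MutationTable(
        [
            MutationRecord("T1", "g2", "probably_damaging", 0.95, "tolerated", 0.6),
            MutationRecord("T1", "g2", "possibly_damaging", 0.80, None, None),
            MutationRecord("T2", "g3", "benign", 0.02, "tolerated", 0.9),
        ]
    )


def random_patient_graph(rng, max_u=50, max_v=20, sample="S"):
    """A random pruned bipartite patient graph for propagation tests.

    Genes are letters over a random PPI-like structure; edge probabilities
    are chosen so most graphs have both partitions populated.
    """
    m = int(rng.integers(2, max_u + 1))
    n = int(rng.integers(0, max_v + 1))
    genes_u = [f"u{i:03d}" for i in range(m)]
    genes_v = list(rng.choice(genes_u, size=min(n, m), replace=False)) if n else []
    edges = set()
    for i in range(m):
        for j in range(i + 1, m):
            if rng.random() < min(1.0, 4.0 / m):
                edges.add((genes_u[i], genes_u[j]))
    ppi = PPINetwork.from_edges(edges, extra_genes=genes_u)
    x0 = pd.Series(rng.normal(size=m), index=genes_u)
    dx = pd.Series(rng.normal(size=m), index=genes_u)
    mutated = {g: 1.0 + float(rng.uniform(0, 2)) for g in genes_v}
    profile = PatientProfile(sample=sample, x0=x0, dx=dx, mutated=mutated)
    return prune_zero_vertices(build_bipartite(profile, ppi))


def make_voter(sample, scores: dict, mutated: set) -> PatientRanking:
    """A hand-built voter with raw scores (normalization applied downstream)."""
    genes = sorted(scores)
    return PatientRanking(
        sample=sample,
        genes=genes,
        scores=np.array([scores[g] for g in genes], dtype=float),
        iterations_used=1,
        converged=True,
        mutated_flags=np.array([g in mutated for g in genes]),
    )
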