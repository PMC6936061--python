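"""Per-patient bipartite graph construction.

For each tumor sample a bipartite graph G = (U ∪ V, E) is built from the
PPI backbone: the left partition U holds the patient's expression genes,
the right partition V the patient's mutated genes, and an edge u–v is drawn
iff the two genes interact in the PPI. Binary weight matrices W_vu (m x n,
U–V edges) and W_uu (m x m, PPI edges within U) are stored sparse, together
with the degree vectors the propagation normalizes by. Mutated V-genes with
no U neighbor would make the d^(-1/2) factor blow up, so they are pruned.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .io import PPINetwork
from .preprocess import PatientProfile

logger = logging.getLogger(__name__)

__all__ = ["PatientBipartiteGraph", "build_bipartite", "prune_zero_vertices"]


@dataclass
class PatientBipartiteGraph:
    sample: str
    U: list                 # m expression-side genes, lexicographic
    V: list                 # n mutation-side genes, lexicographic
    W_vu: sp.csr_matrix     # m x n binary, (i, k) = 1 iff PPI edge U_i - V_k
    W_uu: sp.csr_matrix     # m x m binary symmetric, zero diagonal
    d_v: np.ndarray         # V-side degrees (column sums of W_vu)
    d_u: np.ndarray         # U-side degrees within W_uu (row sums)
    x0: np.ndarray          # standardized tumor expression over U
    dx: np.ndarray          # differential expression over U
    y: np.ndarray           # damage coefficients over V (each >= 1)
    mutated_u: np.ndarray   # bool over U: gene has >= 1 SNV in this patient

    @property
    def m(self) -> int:
        return len(self.U)

    @property
    def n(self) -> int:
        return len(self.V)


def build_bipartite(
    profile: PatientProfile, ppi: PPINetwork, self_edges: bool = False
) -> PatientBipartiteGraph:
    """Construct the (unpruned) bipartite graph for one patient.

    U is the full set of expression genes present in the PPI (no
    differential-expression filter); V is the set of genes with at least one
    SNV record in this patient, intersected with the PPI. By default a gene
    that sits on both sides gets no U–V edge with itself (the PPI has no
    self-loops); ``self_edges=True`` adds that edge for experimentation.
    """
    ppi_genes = ppi.genes
    U = sorted(set(profile.genes) & ppi_genes)
    if not U:
        raise ValueError(
            f"sample {profile.sample}: no expression gene overlaps the PPI network"
        )
    V = sorted(set(profile.mutated) & ppi_genes)
    u_index = {g: i for i, g in enumerate(U)}
    v_index = {g: k for k, g in enumerate(V)}
    m, n = len(U), len(V)

    vu_rows, vu_cols = [], []
    uu_rows, uu_cols = [], []
    for a, b in ppi.edges:
        ia, ib = u_index.get(a), u_index.get(b)
        ka, kb = v_index.get(a), v_index.get(b)
        if ia is not None and ib is not None:
            uu_rows.extend((ia, ib))
            uu_cols.extend((ib, ia))
        if ia is not None and kb is not None:
            vu_rows.append(ia)
            vu_cols.append(kb)
        if ib is not None and ka is not None:
            vu_rows.append(ib)
            vu_cols.append(ka)
    if self_edges:
        for g in V:
            if g in u_index:
                vu_rows.append(u_index[g])
                vu_cols.append(v_index[g])

    W_vu = sp.csr_matrix(
        (np.ones(len(vu_rows)), (vu_rows, vu_cols)), shape=(m, n), dtype=float
    )
    W_uu = sp.csr_matrix(
        (np.ones(len(uu_rows)), (uu_rows, uu_cols)), shape=(m, m), dtype=float
    )
    d_v = np.asarray(W_vu.sum(axis=0)).ravel()
    d_u = np.asarray(W_uu.sum(axis=1)).ravel()
    x0 = profile.x0.reindex(U).to_numpy(dtype=float)
    dx = profile.dx.reindex(U).to_numpy(dtype=float)
    y = np.array([profile.mutated[g] for g in V], dtype=float)
    mutated_u = np.array([g in profile.mutated for g in U], dtype=bool)
    return PatientBipartiteGraph(
        sample=profile.sample, U=U, V=V, W_vu=W_vu, W_uu=W_uu,
        d_v=d_v, d_u=d_u, x0=x0, dx=dx, y=y, mutated_u=mutated_u,
    )


def prune_zero_vertices(graph: PatientBipartiteGraph) -> PatientBipartiteGraph:
    """Drop V-vertices with no edge into U (degree 0).

    Such vertices contribute nothing to the left partition and would make
    the d_k^(-1/2) normalization divide by zero. U is never pruned: an
    isolated U-gene is still scored by the x0 term. Idempotent.
    """
    keep = graph.d_v > 0
    if keep.all():
        return graph
    n_removed = int((~keep).sum())
    logger.info("sample %s: pruned %d zero-degree mutation vertex(es)", graph.sample, n_removed)
    idx = np.flatnonzero(keep)
    return dataclasses.replace(
        graph,
        V=[graph.V[k] for k in idx],
        W_vu=graph.W_vu[:, idx],
        d_v=graph.d_v[idx],
        y=graph.y[idx],
    )
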