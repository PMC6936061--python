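"""Self-contained synthetic cohorts with the structure the method assumes.

The generator emulates the three real inputs — a scale-free PPI network, a
tumor/normal expression matrix, and a PolyPhen/SIFT-annotated somatic SNV
table — with a known ground truth: a handful of planted driver genes carry
recurrent damaging mutations, and in each tumor sample the PPI neighbors of
that sample's mutated drivers are shifted in expression. The driver signal
deliberately enters through the *neighbors'* expression rather than the
driver's own, because that is the geometry the propagation rewards: a
mutated gene has no edge to its own expression node and can only be seen
through its network neighborhood.

Planted drivers are drawn with probability proportional to PPI degree:
known cancer drivers are disproportionately high-degree in curated
interaction databases, and a degree-1 planted driver would be invisible to
a neighborhood-propagation method by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .io import (
    ExpressionMatrix,
    MutationRecord,
    MutationTable,
    PPINetwork,
    write_expression,
    write_gene_list,
    write_mutations,
    write_ppi,
)

logger = logging.getLogger(__name__)

__all__ = ["SyntheticParams", "SyntheticCohort", "generate_ppi", "generate_cohort"]


@dataclass(frozen=True)
class SyntheticParams:
    """Cohort generation parameters.

    The defaults give a strong but not degenerate planted signal at desk
    scale: 200 genes, 50 tumor / 20 normal samples, 5 drivers each mutated
    in 80% of tumor samples with PolyPhen probability 0.95, driver
    neighbors shifted by +2 expression SD, and a 2% per-gene benign
    passenger mutation rate on unit-variance background noise.
    """

    n_genes: int = 200
    edges_per_node: int = 2
    n_tumor: int = 50
    n_normal: int = 20
    n_drivers: int = 5
    driver_damage_prob: float = 0.95
    neighbor_shift: float = 2.0
    passenger_rate: float = 0.02
    noise_sd: float = 1.0
    driver_mutation_rate: float = 0.8

    def __post_init__(self):
        if self.n_drivers > self.n_genes:
            raise ValueError("n_drivers cannot exceed n_genes")
        if not 0.0 <= self.driver_damage_prob <= 1.0:
            raise ValueError("driver_damage_prob must be in [0, 1]")
        if not 0.0 <= self.passenger_rate <= 1.0:
            raise ValueError("passenger_rate must be in [0, 1]")
        if self.n_tumor < 2 or self.n_normal < 1:
            raise ValueError("need at least 2 tumor and 1 normal sample")


@dataclass
class SyntheticCohort:
    ppi: PPINetwork
    expr: ExpressionMatrix
    mutations: MutationTable
    planted_drivers: set
    passengers: set
    seed: int
    params: SyntheticParams = field(default_factory=SyntheticParams)

    def write(self, out_dir) -> dict:
        """Write ppi.tsv, expr_tumor.tsv, expr_normal.tsv, mutations.maf,
        truth_drivers.txt; returns the path map."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "ppi": out / "ppi.tsv",
            "expr_tumor": out / "expr_tumor.tsv",
            "expr_normal": out / "expr_normal.tsv",
            "mutations": out / "mutations.maf",
            "truth_drivers": out / "truth_drivers.txt",
        }
        write_ppi(self.ppi, paths["ppi"])
        write_expression(self.expr.tumor, paths["expr_tumor"])
        write_expression(self.expr.normal, paths["expr_normal"])
        write_mutations(self.mutations, paths["mutations"])
        write_gene_list(self.planted_drivers, paths["truth_drivers"])
        return paths


def _gene_name(i: int) -> str:
    return f"G{i + 1:04d}"


def generate_ppi(n_genes: int, edges_per_node: int = 2, seed: int = 0) -> PPINetwork:
    """Connected preferential-attachment (Barabási–Albert) gene network.

    Every new node attaches ``edges_per_node`` edges, giving
    (n - m) * m edges in total, a heavy-tailed degree distribution, and no
    self-loops. Gene symbols are "G0001", "G0002", ...
    """
    if n_genes < edges_per_node + 1:
        raise ValueError("n_genes must be at least edges_per_node + 1")
    g = nx.barabasi_albert_graph(n_genes, edges_per_node, seed=seed)
    pairs = [(_gene_name(a), _gene_name(b)) for a, b in g.edges()]
    return PPINetwork.from_edges(pairs, extra_genes=[_gene_name(i) for i in range(n_genes)])


def generate_cohort(
    ppi: PPINetwork, params: SyntheticParams | None = None, seed: int = 0
) -> SyntheticCohort:
    """Generate expression and mutations over an existing PPI.

    Normal samples are pure Normal(0, 1) noise per gene. Each tumor sample
    carries each planted driver mutated with probability
    ``driver_mutation_rate`` (one probably_damaging SNV with PolyPhen score
    ``driver_damage_prob``) and each passenger gene mutated at
    ``passenger_rate`` (one benign SNV); the PPI neighbors of the sample's
    mutated drivers have their mean expression shifted by
    ``neighbor_shift`` on top of Normal(0, noise_sd) noise. Bit-identical
    for a fixed seed.
    """
    params = params or SyntheticParams()
    rng = np.random.default_rng(seed)
    genes = sorted(ppi.genes)
    if params.n_drivers > len(genes):
        raise ValueError("n_drivers exceeds the number of PPI genes")
    deg = ppi.degree()
    weights = np.array([deg[g] for g in genes], dtype=float)
    if weights.sum() == 0:
        weights[:] = 1.0
    drivers = sorted(
        rng.choice(genes, size=params.n_drivers, replace=False, p=weights / weights.sum())
    )
    passengers = sorted(set(genes) - set(drivers))
    adjacency = ppi.adjacency()

    tumor_ids = [f"T{i + 1:03d}" for i in range(params.n_tumor)]
    normal_ids = [f"N{i + 1:03d}" for i in range(params.n_normal)]

    tumor = pd.DataFrame(
        rng.normal(0.0, params.noise_sd, size=(len(genes), params.n_tumor)),
        index=genes, columns=tumor_ids,
    )
    normal = pd.DataFrame(
        rng.normal(0.0, 1.0, size=(len(genes), params.n_normal)),
        index=genes, columns=normal_ids,
    )

    records = []
    for s in tumor_ids:
        mutated_drivers = [
            d for d in drivers if rng.random() < params.driver_mutation_rate
        ]
        for d in mutated_drivers:
            records.append(
                MutationRecord(
                    sample=s, gene=d,
                    polyphen_label="probably_damaging",
                    polyphen_score=params.driver_damage_prob,
                    sift_label="deleterious",
                    sift_score=round(1.0 - params.driver_damage_prob, 6),
                )
            )
        hit = rng.random(len(passengers)) < params.passenger_rate
        for g, h in zip(passengers, hit):
            if h:
                records.append(
                    MutationRecord(
                        sample=s, gene=g,
                        polyphen_label="benign",
                        polyphen_score=round(float(rng.uniform(0.0, 0.3)), 6),
                        sift_label="tolerated",
                        sift_score=round(float(rng.uniform(0.3, 1.0)), 6),
                    )
                )
        shifted = sorted(set().union(*(adjacency[d] for d in mutated_drivers))) if mutated_drivers else []
        if shifted and params.neighbor_shift != 0.0:
            tumor.loc[shifted, s] += params.neighbor_shift

    values = pd.concat([tumor, normal], axis=1)
    cond = pd.Series(
        {**{s: "tumor" for s in tumor_ids}, **{s: "normal" for s in normal_ids}}
    )
    expr = ExpressionMatrix(values, cond)
    return SyntheticCohort(
        ppi=ppi,
        expr=expr,
        mutations=MutationTable(records),
        planted_drivers=set(drivers),
        passengers=set(passengers),
        seed=seed,
        params=params,
    )
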