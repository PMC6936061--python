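"""Cohort-level rank aggregation by penalty-modified Condorcet voting.

Each patient is a voter; each gene a candidate. For an unordered pair of
genes (A, B) and one voter, the pairwise winner is

    A  if δ(A)·Rank(A) > δ(B)·Rank(B),  else B,

where Rank(·) is the voter's min-max normalized propagation score (0 for a
gene the voter does not rank) and δ(·) is 1 for a gene mutated in that
voter's sample and the penalty δ (default 0.85) otherwise — the penalty
lowers unmutated genes in each comparison. A gene beats another overall
when strictly more voters prefer it; the pairwise outcomes are completed
into a full ranking by the Copeland tally (pairs beaten minus pairs lost).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .propagation import Config, PatientRanking

logger = logging.getLogger(__name__)

__all__ = ["AggregateRanking", "pairwise_winner", "condorcet_aggregate", "select_top_k"]


@dataclass
class AggregateRanking:
    """Cohort-level ranking.

    ``table`` is ordered best-first with columns gene, copeland,
    aggregate_score (tally min-max rescaled to [0, 1]), rank (1 = best),
    n_patients_mutated and top_k (membership flag).
    """

    table: pd.DataFrame
    n_voters: int
    top_k: int

    @property
    def genes(self) -> list:
        return list(self.table["gene"])

    @property
    def top_k_set(self) -> list:
        return list(self.table.loc[self.table["top_k"], "gene"])

    def to_frame(self) -> pd.DataFrame:
        out = self.table[["rank", "gene", "aggregate_score", "n_patients_mutated"]].copy()
        out = out.rename(columns={"aggregate_score": "score"})
        return out


def pairwise_winner(gene_a: str, gene_b: str, voter: PatientRanking, delta: float) -> str:
    """Winner of one pairwise comparison for one voter.

    Ties fall to ``gene_b`` (the "otherwise" branch). Genes the voter does
    not rank get Rank 0; "mutated" means mutated in this voter's sample.
    """
    da = 1.0 if voter.is_mutated(gene_a) else delta
    db = 1.0 if voter.is_mutated(gene_b) else delta
    if da * voter.normalized_score(gene_a) > db * voter.normalized_score(gene_b):
        return gene_a
    return gene_b


def _candidate_genes(rankings, pool: int | None) -> list:
    """Union of each voter's top-``pool`` genes (all genes when pool is None)."""
    candidates = set()
    for r in rankings:
        if pool is None or pool >= len(r.genes):
            candidates.update(r.genes)
        else:
            series = pd.Series(r.normalized_scores())
            # per-patient order: score descending, gene name ascending
            top = sorted(series.index, key=lambda g: (-series[g], g))[:pool]
            candidates.update(top)
    return sorted(candidates)


def condorcet_aggregate(rankings: list, config: Config | None = None) -> AggregateRanking:
    """Aggregate per-patient rankings into one cohort-level driver ranking.

    All unordered candidate pairs are compared across all voters (the
    candidate set defaults to the union of each voter's top
    ``config.candidate_pool`` genes, for tractability on genome-scale
    inputs). Ties in the Copeland tally break by summed per-patient
    normalized score, then lexicographically. Deterministic and invariant
    to the order of the voters.
    """
    config = config or Config()
    if not rankings:
        raise ValueError("condorcet_aggregate requires at least one voter")
    genes = _candidate_genes(rankings, config.candidate_pool)
    P = len(genes)
    n_voters = len(rankings)
    gene_index = {g: i for i, g in enumerate(genes)}

    # S: delta-weighted normalized scores, R: raw normalized, M: mutation flags
    S = np.zeros((n_voters, P))
    R = np.zeros((n_voters, P))
    mut_count = np.zeros(P, dtype=int)
    for vi, r in enumerate(rankings):
        norm = r.normalized_scores()
        for g, s in norm.items():
            j = gene_index.get(g)
            if j is not None:
                R[vi, j] = s
                S[vi, j] = s if r.is_mutated(g) else config.delta * s
        for g in r.genes:
            j = gene_index.get(g)
            if j is not None and r.is_mutated(g):
                mut_count[j] += 1

    if P == 1:
        tally = np.zeros(1, dtype=int)
    else:
        # G[a, b] = number of voters with S[:, a] strictly greater than S[:, b]
        G = np.zeros((P, P), dtype=np.int64)
        for vi in range(n_voters):
            col = S[vi]
            G += col[:, None] > col[None, :]
        # For the unordered pair (a, b) with a lexicographically before b, a
        # per-voter tie falls to b; a beats b overall iff a's strict wins
        # exceed the remaining voters.
        iu = np.triu_indices(P, k=1)
        votes_a = G[iu]
        votes_b = n_voters - votes_a
        beats = np.zeros((P, P), dtype=bool)
        beats[iu] = votes_a > votes_b
        beats.T[iu] = votes_b > votes_a
        tally = beats.sum(axis=1).astype(int) - beats.sum(axis=0).astype(int)

    score_sum = R.sum(axis=0)
    order = sorted(range(P), key=lambda i: (-tally[i], -score_sum[i], genes[i]))
    lo, hi = tally.min(), tally.max()
    if hi == lo:
        agg_score = np.ones(P)
    else:
        agg_score = (tally - lo) / (hi - lo)
    k = min(config.top_k, P)
    table = pd.DataFrame(
        {
            "rank": np.arange(1, P + 1),
            "gene": [genes[i] for i in order],
            "copeland": tally[order],
            "aggregate_score": agg_score[order],
            "n_patients_mutated": mut_count[order],
            "top_k": np.arange(P) < k,
        }
    )
    return AggregateRanking(table=table, n_voters=n_voters, top_k=k)


def select_top_k(agg: AggregateRanking, k: int | None = None) -> list:
    """First min(k, number of genes) genes of the aggregate order."""
    if k is None:
        k = agg.top_k
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    return agg.genes[: min(k, len(agg.genes))]
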