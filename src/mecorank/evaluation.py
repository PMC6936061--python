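"""Evaluation against a known-driver gene list.

Provides the rank-cutoff curve (fraction of known drivers among the top-k
predictions for k = 10, 20, ..., 100), the average precision
P = mean(p_k) over k = 1..100, and a sub-sampling robustness test that
reruns the whole pipeline on random subsets of the tumor samples.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "EvaluationResult",
    "rank_cutoff_curve",
    "average_precision",
    "subsample_precision",
]

DEFAULT_KS = tuple(range(10, 101, 10))
DEFAULT_FRACTIONS = tuple(np.round(np.arange(0.1, 1.0, 0.1), 1))


@dataclass
class EvaluationResult:
    cutoff_curve: list              # (k, fraction of top-k in the known list)
    average_precision: float        # mean of p_k, k = 1..K
    subsample_curve: pd.DataFrame | None = None

    def cutoff_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.cutoff_curve, columns=["k", "precision"])


def _gene_order(ranking) -> list:
    """Accept an AggregateRanking, a pandas Series/Index, or a plain list."""
    if hasattr(ranking, "genes"):
        return list(ranking.genes)
    if isinstance(ranking, pd.Series):
        return list(ranking.index)
    return list(ranking)


def rank_cutoff_curve(ranking, known_drivers, ks=DEFAULT_KS) -> list:
    """Fraction of the top-k genes that are known drivers, per cutoff k.

    A cutoff larger than the ranking is computed over the available genes
    and flagged with a warning.
    """
    genes = _gene_order(ranking)
    if not genes:
        raise ValueError("empty ranking")
    known = set(known_drivers)
    curve = []
    for k in ks:
        k_eff = min(k, len(genes))
        if k_eff < k:
            logger.warning("cutoff k=%d exceeds ranking length %d; using %d", k, len(genes), k_eff)
        hits = sum(1 for g in genes[:k_eff] if g in known)
        curve.append((k, hits / k_eff))
    return curve


def average_precision(ranking, known_drivers, K: int = 100) -> float:
    """P = mean(p_k) for k = 1..K, p_k the known-driver fraction of the top k."""
    genes = _gene_order(ranking)
    if not genes:
        raise ValueError("empty ranking")
    known = set(known_drivers)
    hits = 0
    p = []
    for k in range(1, K + 1):
        k_eff = min(k, len(genes))
        if k <= len(genes):
            hits += genes[k - 1] in known
        p.append(hits / k_eff)
    return float(np.mean(p))


def subsample_precision(
    expr,
    mutations,
    ppi,
    known_drivers,
    fractions=DEFAULT_FRACTIONS,
    replicates: int = 10,
    seed: int = 0,
    config=None,
) -> pd.DataFrame:
    """Top-k precision when the pipeline is rerun on tumor-sample subsets.

    For each fraction f, ``replicates`` subsets of ceil(f * N) tumor samples
    are drawn without replacement (normal samples are always kept), the
    whole pipeline is rerun on the subset, and the precision of the top-k
    aggregate genes against the known-driver list is recorded. Fractions
    yielding fewer than 2 tumor samples are skipped with a warning.
    Deterministic for a fixed seed.
    """
    from .estimator import run_pipeline
    from .propagation import Config

    config = config or Config()
    known = set(known_drivers)
    tumor = expr.tumor_samples
    normal = expr.normal_samples
    N = len(tumor)
    rng = np.random.default_rng(seed)
    rows = []
    for f in fractions:
        n_sub = math.ceil(f * N)
        if n_sub < 2:
            logger.warning("fraction %.2f yields %d tumor sample(s); skipped", f, n_sub)
            continue
        for rep in range(replicates):
            chosen = sorted(rng.choice(tumor, size=min(n_sub, N), replace=False).tolist())
            sub = expr.subset_samples(chosen + normal)
            _, agg = run_pipeline(sub, mutations, ppi, config)
            k_eff = min(config.top_k, len(agg.genes))
            hits = sum(1 for g in agg.genes[:k_eff] if g in known)
            rows.append((float(f), rep, hits / k_eff))
    return pd.DataFrame(rows, columns=["fraction", "replicate", "precision"])
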