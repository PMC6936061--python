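"""Damped iterative score propagation on the patient bipartite graph.

The per-patient score vector x over the expression partition U is the fixed
point of

    x_i = (1 - λu) x0_i
        + λu (1 - λv) Σ_k  w_ik^vu d_k^(-1/2) y_k
        + λu λv       Σ_j  w_ij^uu d_j^(-1/2) x_j

with λu + λv = 1. The first term anchors each gene to its standardized
tumor expression, the second injects the (fixed) mutation-damage
coefficients y of the patient's mutated genes, and the third diffuses the
current scores through the PPI edges within U. The degree factors d^(-1/2)
(a one-sided Laplacian-style normalization, applied exactly as written;
``sym_norm`` switches to the symmetric d_i^(-1/2) w d_j^(-1/2) variant)
suppress high-degree hubs. Because the update is affine with linear part
λu·λv·Ŵ_uu and λu·λv is small at the defaults (0.09), the iteration is a
contraction on realistic graphs and the fixed point is unique — the
initialization (differential expression dx by default) only matters when
the iteration is stopped early.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .graph import PatientBipartiteGraph

logger = logging.getLogger(__name__)

__all__ = ["Config", "PatientRanking", "propagate", "fixed_point_oracle", "rank_patient"]

_INIT_CHOICES = ("dx", "x0", "zeros")


@dataclass
class Config:
    """Pipeline parameters and their defaults.

    λu = 0.9 weights the network terms over the expression anchor (the
    impact of mutation on the expression network is taken as the stronger
    signal); λv = 1 - λu splits the network weight between the mutation
    injection and the within-U diffusion. ε is the max-norm convergence
    threshold, δ the Condorcet penalty for unmutated genes, top_k the size
    of the final driver list.
    """

    lambda_u: float = 0.9
    epsilon: float = 1e-4
    max_iter: int = 100
    delta: float = 0.85
    top_k: int = 100
    init: str = "dx"
    sym_norm: bool = False
    self_edges: bool = False
    candidate_pool: int | None = 1000   # None means all genes
    missing_score_default: float = 1.0
    fixed_dx: bool = False              # third term uses dx held fixed (closed form)
    lambda_v: float | None = None       # complementary to lambda_u; see __setattr__

    def __setattr__(self, name, value):
        # λu + λv = 1 by definition: setting either one keeps both in sync.
        if name == "lambda_u" and value is not None:
            object.__setattr__(self, "lambda_u", value)
            object.__setattr__(self, "lambda_v", 1.0 - value)
        elif name == "lambda_v":
            if value is None:  # dataclass init placeholder; keep derived value
                return
            object.__setattr__(self, "lambda_v", value)
            object.__setattr__(self, "lambda_u", 1.0 - value)
        else:
            object.__setattr__(self, name, value)

    def __post_init__(self):
        if not 0.0 <= self.lambda_u <= 1.0:
            raise ValueError(f"lambda_u must be in [0, 1], got {self.lambda_u}")
        if self.epsilon <= 0:
            raise ValueError(f"epsilon must be > 0, got {self.epsilon}")
        if self.max_iter < 1:
            raise ValueError(f"max_iter must be >= 1, got {self.max_iter}")
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError(f"delta must be in [0, 1], got {self.delta}")
        if self.top_k < 1:
            raise ValueError(f"top_k must be >= 1, got {self.top_k}")
        if self.init not in _INIT_CHOICES:
            raise ValueError(f"init must be one of {_INIT_CHOICES}, got {self.init!r}")
        if self.candidate_pool is not None and self.candidate_pool < 1:
            raise ValueError(f"candidate_pool must be >= 1 or None, got {self.candidate_pool}")

    @classmethod
    def from_yaml(cls, path) -> "Config":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)} | {"lambda_v"}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys in {path}: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dataclasses.fields(self)}


@dataclass
class PatientRanking:
    """Converged scores over one patient's U genes."""

    sample: str
    genes: list
    scores: np.ndarray
    iterations_used: int
    converged: bool
    mutated_flags: np.ndarray  # bool, aligned with genes
    _norm: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.scores) != len(self.genes):
            raise ValueError("scores and genes length mismatch")
        if not np.isfinite(self.scores).all():
            raise ValueError(f"non-finite scores for sample {self.sample}")

    def normalized_scores(self) -> dict:
        """Gene -> min-max normalized score (used as Rank(·) in the vote)."""
        if self._norm is None:
            series = rank_patient(self)
            self._norm = dict(zip(series.index, series.to_numpy()))
        return self._norm

    def normalized_score(self, gene: str) -> float:
        """Normalized score, 0 for genes this patient does not rank."""
        return self.normalized_scores().get(gene, 0.0)

    def is_mutated(self, gene: str) -> bool:
        if not hasattr(self, "_mutset"):
            self._mutset = {g for g, m in zip(self.genes, self.mutated_flags) if m}
        return gene in self._mutset

    def to_frame(self) -> pd.DataFrame:
        series = rank_patient(self)
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(series) + 1),
                "gene": series.index,
                "score": series.to_numpy(),
                "mutated": [self.is_mutated(g) for g in series.index],
            }
        )


def _inv_sqrt(d: np.ndarray) -> np.ndarray:
    """Elementwise d^(-1/2) with the 0 -> 0 convention.

    A zero degree only ever multiplies a zero weight, so the convention
    never changes a product; it just avoids spurious infinities.
    """
    out = np.zeros_like(d, dtype=float)
    nz = d > 0
    out[nz] = 1.0 / np.sqrt(d[nz])
    return out


def _operators(graph: PatientBipartiteGraph, config: Config):
    """Constant term pieces and the normalized within-U operator.

    Returns (c0, t2, A) such that the update is x <- c0 + t2 + λuλv (A @ x).
    """
    lu, lv = config.lambda_u, config.lambda_v
    c0 = (1.0 - lu) * graph.x0
    if graph.n > 0:
        t2 = lu * (1.0 - lv) * (graph.W_vu @ (graph.y * _inv_sqrt(graph.d_v)))
    else:
        t2 = np.zeros(graph.m)
    A = graph.W_uu @ sp.diags(_inv_sqrt(graph.d_u))
    if config.sym_norm:
        A = sp.diags(_inv_sqrt(graph.d_u)) @ A
        if graph.n > 0:
            row_deg = np.asarray(graph.W_vu.sum(axis=1)).ravel()
            t2 = _inv_sqrt(row_deg) * t2
    return c0, t2, A.tocsr()


def _initial_vector(graph: PatientBipartiteGraph, config: Config) -> np.ndarray:
    if config.init == "dx":
        return graph.dx.copy()
    if config.init == "x0":
        return graph.x0.copy()
    return np.zeros(graph.m)


def propagate(graph: PatientBipartiteGraph, config: Config | None = None) -> PatientRanking:
    """Iterate the score update to convergence for one patient.

    Stops when the max-norm difference between successive iterates falls
    below ε, or after max_iter sweeps (``converged`` records which). A
    residual that keeps growing for 10 consecutive sweeps aborts with a
    diagnostic — it implies the linear part is not a contraction.
    """
    config = config or Config()
    if graph.n > 0 and not (graph.d_v > 0).all():
        raise ValueError(
            f"sample {graph.sample}: graph has zero-degree mutation vertices; prune first"
        )
    c0, t2, A = _operators(graph, config)
    lin = config.lambda_u * config.lambda_v
    if config.fixed_dx or lin == 0.0 or A.nnz == 0:
        # the update does not depend on x (with fixed_dx the third term keeps
        # the differential-expression vector as written): one application
        x = c0 + t2 + (lin * (A @ graph.dx) if config.fixed_dx and lin != 0.0 else 0.0)
        if not np.isfinite(x).all():
            raise FloatingPointError(f"sample {graph.sample}: non-finite scores")
        return PatientRanking(
            sample=graph.sample, genes=list(graph.U), scores=x,
            iterations_used=1, converged=True, mutated_flags=graph.mutated_u,
        )

    x = _initial_vector(graph, config)
    prev_residual = np.inf
    n_increasing = 0
    converged = False
    iterations = 0
    for iterations in range(1, config.max_iter + 1):
        x_new = c0 + t2 + lin * (A @ x)
        if not np.isfinite(x_new).all():
            raise FloatingPointError(
                f"sample {graph.sample}: non-finite value at iteration {iterations}"
            )
        residual = float(np.max(np.abs(x_new - x)))
        x = x_new
        logger.debug("sample %s: iteration %d residual %.3e", graph.sample, iterations, residual)
        if residual < config.epsilon:
            converged = True
            break
        if residual >= prev_residual:
            n_increasing += 1
            if n_increasing >= 10:
                raise FloatingPointError(
                    f"sample {graph.sample}: residual increased for 10 consecutive "
                    f"iterations (last {residual:.3e}); the update is not contracting"
                )
        else:
            n_increasing = 0
        prev_residual = residual
    if not converged:
        logger.warning(
            "sample %s: stopped at max_iter=%d without reaching epsilon=%g",
            graph.sample, config.max_iter, config.epsilon,
        )
    return PatientRanking(
        sample=graph.sample, genes=list(graph.U), scores=x,
        iterations_used=iterations, converged=converged, mutated_flags=graph.mutated_u,
    )


def fixed_point_oracle(graph: PatientBipartiteGraph, config: Config | None = None) -> np.ndarray:
    """Exact fixed point by a dense linear solve (test oracle).

    The update is affine, x = c + λuλv Ŵuu x, so the fixed point solves
    (I - λuλv Ŵuu) x = c. Intended for small graphs only (|U| <= 2000).
    """
    config = config or Config()
    if graph.m > 2000:
        raise ValueError("fixed_point_oracle is a dense solve; |U| must be <= 2000")
    c0, t2, A = _operators(graph, config)
    lin = config.lambda_u * config.lambda_v
    if lin == 0.0:
        return c0 + t2
    if config.fixed_dx:
        return c0 + t2 + lin * (A @ graph.dx)
    M = np.eye(graph.m) - lin * A.toarray()
    return np.linalg.solve(M, c0 + t2)


def rank_patient(ranking: PatientRanking) -> pd.Series:
    """Sort a patient's genes by score and min-max normalize to [0, 1].

    The best gene maps to exactly 1 and the worst to 0; ties in the sort
    break lexicographically. The normalized value serves as Rank(·) in the
    pairwise Condorcet comparison. If every score is equal the normalized
    scores are all 1 (with a warning) and the order is lexicographic.
    """
    order = sorted(range(len(ranking.genes)), key=lambda i: (-ranking.scores[i], ranking.genes[i]))
    genes = [ranking.genes[i] for i in order]
    scores = ranking.scores[order]
    lo, hi = scores[-1], scores[0]
    if hi == lo:
        warnings.warn(
            f"sample {ranking.sample}: all scores equal; normalized scores set to 1",
            stacklevel=2,
        )
        norm = np.ones_like(scores)
    else:
        norm = (scores - lo) / (hi - lo)
    return pd.Series(norm, index=pd.Index(genes, name="gene"), name=ranking.sample)
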