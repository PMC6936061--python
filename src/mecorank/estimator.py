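"""The MECoRank estimator: the full pipeline behind a scikit-learn surface."""

from __future__ import annotations

import logging

import numpy as np
from sklearn.base import BaseEstimator

from .aggregation import AggregateRanking, condorcet_aggregate, select_top_k
from .evaluation import (
    DEFAULT_KS,
    EvaluationResult,
    average_precision,
    rank_cutoff_curve,
)
from .graph import build_bipartite, prune_zero_vertices
from .io import ExpressionMatrix, MutationTable, PPINetwork
from .preprocess import build_profiles, damage_coefficients
from .propagation import Config, propagate

logger = logging.getLogger(__name__)

__all__ = ["MECoRank", "run_pipeline"]


def run_pipeline(
    expr: ExpressionMatrix,
    mutations: MutationTable,
    ppi: PPINetwork,
    config: Config | None = None,
    expression_reference: str = "tumor",
):
    """Run preprocessing, per-patient propagation and Condorcet aggregation.

    Returns (patient_rankings, aggregate_ranking). The pipeline is a pure
    function of its inputs and configuration: no randomness, no global
    state.
    """
    config = config or Config()
    damage = damage_coefficients(mutations, config.missing_score_default)
    profiles = build_profiles(expr, damage, reference=expression_reference)
    rankings = []
    for profile in profiles:
        g = prune_zero_vertices(build_bipartite(profile, ppi, self_edges=config.self_edges))
        rankings.append(propagate(g, config))
    aggregate = condorcet_aggregate(rankings, config)
    return rankings, aggregate


class MECoRank(BaseEstimator):
    """Patient-specific driver-gene prioritization over a tumor cohort.

    For every tumor sample a bipartite graph is built on the PPI backbone
    (expression genes on one side, that patient's mutated genes on the
    other), mutation-damage and expression signal is propagated to a
    converged per-patient score vector, and the per-patient rankings are
    aggregated by penalty-modified Condorcet voting into one cohort-level
    driver list.

    Parameters
    ----------
    lambda_u : float, default 0.9
        Damping weight of the network terms; 1 - lambda_u anchors each gene
        to its standardized tumor expression. lambda_v = 1 - lambda_u.
    epsilon : float, default 1e-4
        Max-norm convergence threshold of the per-patient iteration.
    max_iter : int, default 100
        Iteration cap per patient.
    delta : float, default 0.85
        Condorcet penalty multiplying the normalized score of a gene that
        is not mutated in a given voter's sample.
    top_k : int, default 100
        Size of the final driver list.
    candidate_pool : int or None, default 1000
        Candidate genes for the (quadratic) pairwise vote are the union of
        each patient's top ``candidate_pool`` genes; None uses all genes.
    init : {"dx", "x0", "zeros"}, default "dx"
        Initialization of the per-patient iterate (differential expression
        by default).
    sym_norm : bool, default False
        Use the symmetric two-sided degree normalization instead of the
        one-sided d^(-1/2) factor.
    self_edges : bool, default False
        Add a U-V edge between a mutated gene and its own expression node.
    fixed_dx : bool, default False
        Keep the differential-expression vector fixed in the within-U term
        (the closed-form, non-iterative variant of the update).
    missing_score_default : float, default 1.0
        Damage probability assumed for a damaging/deleterious label whose
        numeric score is missing.
    expression_reference : {"tumor", "normal"}, default "tumor"
        Cohort against which tumor expression is z-scored.

    Attributes
    ----------
    patient_rankings_ : list of PatientRanking
    aggregate_ : AggregateRanking
    ranking_ : pandas.DataFrame
        Aggregate table ordered best-first.
    top_genes_ : list of str
        The top-k driver list.
    n_iterations_ : ndarray
        Iterations used per patient.
    converged_ : ndarray of bool

    Examples
    --------
    >>> from mecorank import MECoRank, synthetic
    >>> ppi = synthetic.generate_ppi(200, 2, seed=7)
    >>> cohort = synthetic.generate_cohort(ppi, seed=7)
    >>> model = MECoRank().fit(cohort.expr, cohort.mutations, cohort.ppi)
    >>> model.top_genes_[:3]  # doctest: +SKIP
    ['G0002', 'G0011', 'G0001']
    """

    def __init__(
        self,
        lambda_u: float = 0.9,
        epsilon: float = 1e-4,
        max_iter: int = 100,
        delta: float = 0.85,
        top_k: int = 100,
        candidate_pool: int | None = 1000,
        init: str = "dx",
        sym_norm: bool = False,
        self_edges: bool = False,
        fixed_dx: bool = False,
        missing_score_default: float = 1.0,
        expression_reference: str = "tumor",
    ):
        self.lambda_u = lambda_u
        self.epsilon = epsilon
        self.max_iter = max_iter
        self.delta = delta
        self.top_k = top_k
        self.candidate_pool = candidate_pool
        self.init = init
        self.sym_norm = sym_norm
        self.self_edges = self_edges
        self.fixed_dx = fixed_dx
        self.missing_score_default = missing_score_default
        self.expression_reference = expression_reference

    def _config(self) -> Config:
        return Config(
            lambda_u=self.lambda_u,
            epsilon=self.epsilon,
            max_iter=self.max_iter,
            delta=self.delta,
            top_k=self.top_k,
            candidate_pool=self.candidate_pool,
            init=self.init,
            sym_norm=self.sym_norm,
            self_edges=self.self_edges,
            fixed_dx=self.fixed_dx,
            missing_score_default=self.missing_score_default,
        )

    def fit(self, expr: ExpressionMatrix, mutations: MutationTable, ppi: PPINetwork):
        """Run the full pipeline on a cohort.

        Parameters
        ----------
        expr : ExpressionMatrix
            Tumor and normal expression with condition labels.
        mutations : MutationTable
            Per-sample somatic SNVs with PolyPhen/SIFT annotation.
        ppi : PPINetwork
            Undirected protein-interaction backbone.
        """
        rankings, aggregate = run_pipeline(
            expr, mutations, ppi, self._config(),
            expression_reference=self.expression_reference,
        )
        self.patient_rankings_ = rankings
        self.aggregate_ = aggregate
        self.ranking_ = aggregate.table
        self.top_genes_ = select_top_k(aggregate)
        self.n_iterations_ = np.array([r.iterations_used for r in rankings])
        self.converged_ = np.array([r.converged for r in rankings])
        self.n_patients_ = len(rankings)
        return self

    def evaluate(self, known_drivers, ks=DEFAULT_KS, K: int | None = None) -> EvaluationResult:
        """Rank-cutoff curve and average precision against a known-driver list."""
        self._check_fitted()
        if K is None:
            K = self.top_k
        return EvaluationResult(
            cutoff_curve=rank_cutoff_curve(self.aggregate_, known_drivers, ks=ks),
            average_precision=average_precision(self.aggregate_, known_drivers, K=K),
        )

    def _check_fitted(self):
        if not hasattr(self, "aggregate_"):
            raise RuntimeError("this MECoRank instance is not fitted yet; call fit first")
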