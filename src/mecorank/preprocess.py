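"""Per-patient quantities consumed by the propagation step.

Three signals are derived from the raw inputs:

* mutation-damage coefficients ``y = 1 + p`` per (sample, gene), where ``p``
  sums the damaging probabilities of all SNVs the gene carries in that
  sample (PolyPhen "damaging" labels contribute their score, SIFT
  "deleterious" labels contribute 1 - score; a variant matching both
  contributes the maximum of the two, so a single variant is never counted
  twice);
* standardized tumor expression ``x0`` (per-gene z-score across the tumor
  cohort, population SD);
* differential expression ``dx`` (tumor value minus the mean over normal
  samples).

The +1 in ``y`` keeps a mutated gene informative in the network even when
none of its variants passes a damage filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, MutationTable

logger = logging.getLogger(__name__)

__all__ = [
    "DamageEntry",
    "DamageMatrix",
    "PatientProfile",
    "mutation_damage_probability",
    "damage_coefficients",
    "standardize_expression",
    "differential_expression",
    "build_profiles",
]


@dataclass(frozen=True)
class DamageEntry:
    p: float          # summed damaging probability, >= 0
    y: float          # 1 + p
    n_mutations: int  # >= 1

    def __post_init__(self):
        if self.p < 0 or self.n_mutations < 1:
            raise ValueError("invalid DamageEntry")
        if abs(self.y - (1.0 + self.p)) > 1e-12:
            raise ValueError("DamageEntry must satisfy y = 1 + p")


@dataclass
class DamageMatrix:
    """Map (sample ID, gene symbol) -> damage entry.

    A key exists iff the gene has at least one somatic SNV record in that
    sample, so key presence encodes "mutated" regardless of damage.
    """

    entries: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.entries)

    def get(self, sample: str, gene: str) -> DamageEntry | None:
        return self.entries.get((sample, gene))

    def samples(self) -> list:
        return sorted({s for s, _ in self.entries})

    def genes_for(self, sample: str) -> dict:
        """Gene -> y coefficient for one sample."""
        return {g: e.y for (s, g), e in self.entries.items() if s == sample}

    def merge(self, other: "DamageMatrix") -> "DamageMatrix":
        """Combine two matrices; p and mutation counts are additive."""
        out = dict(self.entries)
        for key, e in other.entries.items():
            if key in out:
                prev = out[key]
                p = prev.p + e.p
                out[key] = DamageEntry(p=p, y=1.0 + p, n_mutations=prev.n_mutations + e.n_mutations)
            else:
                out[key] = e
        return DamageMatrix(out)


def mutation_damage_probability(record, missing_score_default: float = 1.0) -> float:
    """Damaging probability a single SNV record contributes.

    PolyPhen labels containing "damaging" (probably_damaging,
    possibly_damaging) contribute the PolyPhen score; SIFT labels containing
    "deleterious" contribute 1 - SIFT score (low SIFT = more damaging). When
    both filters match, the maximum of the two contributions is taken.
    A matching label with no numeric score contributes
    ``missing_score_default`` (the label itself asserts damage).
    """
    contributions = []
    if record.polyphen_label and "damaging" in record.polyphen_label.lower():
        if record.polyphen_score is None:
            logger.warning(
                "PolyPhen label %r without score for (%s, %s): using default %.3g",
                record.polyphen_label, record.sample, record.gene, missing_score_default,
            )
            contributions.append(missing_score_default)
        else:
            contributions.append(record.polyphen_score)
    if record.sift_label and "deleterious" in record.sift_label.lower():
        if record.sift_score is None:
            logger.warning(
                "SIFT label %r without score for (%s, %s): using default %.3g",
                record.sift_label, record.sample, record.gene, missing_score_default,
            )
            contributions.append(missing_score_default)
        else:
            contributions.append(1.0 - record.sift_score)
    return max(contributions) if contributions else 0.0


def damage_coefficients(
    mutations: MutationTable, missing_score_default: float = 1.0
) -> DamageMatrix:
    """Aggregate per-mutation damaging probabilities into y = 1 + p.

    Multiple mutations of the same gene in the same sample have their
    probabilities summed.
    """
    acc: dict = {}
    counts: dict = {}
    for record in mutations:
        key = (record.sample, record.gene)
        acc[key] = acc.get(key, 0.0) + mutation_damage_probability(record, missing_score_default)
        counts[key] = counts.get(key, 0) + 1
    entries = {
        key: DamageEntry(p=p, y=1.0 + p, n_mutations=counts[key]) for key, p in acc.items()
    }
    return DamageMatrix(entries)


def standardize_expression(expr: ExpressionMatrix, reference: str = "tumor") -> pd.DataFrame:
    """Per-gene z-scores of tumor expression (genes x tumor samples).

    The mean and population SD (denominator n) are taken over the reference
    cohort — the tumor samples by default, switchable to the normal
    samples. Genes with zero variance get z = 0 everywhere.
    """
    if reference not in ("tumor", "normal"):
        raise ValueError(f"reference must be 'tumor' or 'normal', got {reference!r}")
    ref = expr.tumor if reference == "tumor" else expr.normal
    if ref.shape[1] < 2:
        raise ValueError(
            f"standardization requires at least 2 {reference} samples, got {ref.shape[1]}"
        )
    mu = ref.mean(axis=1)
    sd = ref.std(axis=1, ddof=0)
    tumor = expr.tumor
    z = tumor.sub(mu, axis=0).div(sd.where(sd > 0, np.inf), axis=0)
    return z


def differential_expression(expr: ExpressionMatrix) -> pd.DataFrame:
    """Tumor expression minus the mean of the normal samples (unpaired)."""
    normal = expr.normal
    if normal.shape[1] < 1:
        raise ValueError("differential expression requires at least 1 normal sample")
    return expr.tumor.sub(normal.mean(axis=1), axis=0)


@dataclass
class PatientProfile:
    """Everything the bipartite graph needs for one tumor sample."""

    sample: str
    x0: pd.Series        # gene -> standardized tumor expression
    dx: pd.Series        # gene -> differential expression
    mutated: dict        # gene -> y coefficient (>= 1)

    @property
    def genes(self) -> list:
        return list(self.x0.index)


def build_profiles(
    expr: ExpressionMatrix, damage: DamageMatrix, reference: str = "tumor"
) -> list:
    """One PatientProfile per tumor sample in the expression matrix.

    Samples present only in the mutation data are skipped with a warning;
    tumor samples with no mutation record at all are kept (empty mutated
    map) and logged.
    """
    x0 = standardize_expression(expr, reference=reference)
    dx = differential_expression(expr)
    tumor_samples = expr.tumor_samples
    orphan = set(damage.samples()) - set(tumor_samples)
    if orphan:
        logger.warning(
            "%d mutated sample(s) absent from the expression matrix were excluded: %s",
            len(orphan), sorted(orphan)[:5],
        )
    profiles = []
    for s in tumor_samples:
        mutated = damage.genes_for(s)
        if not mutated:
            logger.info("sample %s has no somatic SNV records", s)
        profiles.append(PatientProfile(sample=s, x0=x0[s], dx=dx[s], mutated=mutated))
    return profiles
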