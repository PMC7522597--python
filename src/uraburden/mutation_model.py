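"""Per-gene de novo mutation probabilities and the ultra-rare rescaling.

De novo mutation probabilities (per gene, per generation, as distributed
with sequence-context mutation models) are rescaled by a single global
multiplicative scaling factor SF chosen so that the expected number of
ultra-rare variants across the gene universe equals the observed total:

    SF = N_obs / (N_S * sum_g P_exp_g)

Constrained analyses first restrict the universe to genes under negative
selection (observed/expected ratio below a class-specific threshold) and
recompute SF within that universe.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Optional

from .containers import GeneSubjectMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "MutationProbabilityTable",
    "ConstraintTable",
    "RescaledModel",
    "CONSTRAINT_THRESHOLDS",
    "restrict_to_constrained",
    "compute_scaling_factor",
]

#: Default observed/expected constraint cut-offs (strict <) per variant class.
CONSTRAINT_THRESHOLDS = {"truncating": 0.35, "missense": 0.75}

_CLASS_INDEX = {"truncating": 0, "missense": 1}


@dataclass(frozen=True)
class MutationProbabilityTable:
    """Map gene -> (p_lof, p_mis); ``None`` means undefined for that class."""

    probabilities: Mapping[str, tuple[Optional[float], Optional[float]]]

    def __post_init__(self) -> None:
        if not self.probabilities:
            raise ValueError("probability table is empty")
        for gene, probs in self.probabilities.items():
            for p in probs:
                if p is not None and not 0.0 < p < 1.0:
                    raise ValueError(f"gene {gene}: probability {p} outside (0, 1)")

    def universe(self, variant_class: str) -> list[str]:
        """Genes with a defined probability for ``variant_class``, sorted."""
        i = _CLASS_INDEX[variant_class]
        return sorted(g for g, p in self.probabilities.items() if p[i] is not None)

    def probability(self, gene: str, variant_class: str) -> float:
        p = self.probabilities[gene][_CLASS_INDEX[variant_class]]
        if p is None:
            raise KeyError(f"gene {gene} has no defined {variant_class} probability")
        return p

    def __len__(self) -> int:
        return len(self.probabilities)

    @classmethod
    def from_table(cls, table: Mapping[str, tuple]) -> "MutationProbabilityTable":
        return cls(probabilities=dict(table))


@dataclass(frozen=True)
class ConstraintTable:
    """Map gene -> (oe_lof, oe_mis) observed/expected ratios."""

    ratios: Mapping[str, tuple[Optional[float], Optional[float]]]

    def __post_init__(self) -> None:
        for gene, oes in self.ratios.items():
            for oe in oes:
                if oe is not None and oe < 0:
                    raise ValueError(f"gene {gene}: negative o/e ratio {oe}")

    def ratio(self, gene: str, variant_class: str) -> Optional[float]:
        entry = self.ratios.get(gene)
        return None if entry is None else entry[_CLASS_INDEX[variant_class]]

    @classmethod
    def from_table(cls, table: Mapping[str, tuple]) -> "ConstraintTable":
        return cls(ratios=dict(table))


@dataclass(frozen=True)
class RescaledModel:
    """Rescaled per-gene carrier probabilities for one variant class.

    Invariant: sum_g p_success[g] * n_subjects == n_obs (to floating
    tolerance), i.e. the expected total equals the observed total within
    the analysis universe.
    """

    variant_class: str
    sf: float
    n_obs: int
    n_subjects: int
    p_success: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.sf <= 0:
            raise ValueError("scaling factor must be positive")
        if any(not 0.0 < p <= 1.0 for p in self.p_success.values()):
            raise ValueError("success probabilities must lie in (0, 1]")

    def check_conservation(self, rel_tol: float = 1e-9) -> None:
        """Assert sum_g p_success[g] * n_subjects == n_obs.

        Holds for any model produced by :func:`compute_scaling_factor`
        unless per-gene clamping at 1 was triggered by pathological inputs.
        """
        expected = sum(self.p_success.values()) * self.n_subjects
        if not math.isclose(expected, self.n_obs, rel_tol=rel_tol):
            if all(p < 1.0 for p in self.p_success.values()):
                raise ValueError(
                    f"conservation violated: expected {expected}, observed {self.n_obs}"
                )

    @property
    def universe(self) -> list[str]:
        return sorted(self.p_success)

    def probability(self, gene: str) -> float:
        return self.p_success[gene]

    def __contains__(self, gene: str) -> bool:
        return gene in self.p_success


def restrict_to_constrained(
    table: MutationProbabilityTable,
    constraint: ConstraintTable,
    variant_class: str,
    threshold: Optional[float] = None,
) -> MutationProbabilityTable:
    """Restrict the universe to genes with o/e strictly below the threshold.

    Genes absent from the constraint table (or with an undefined ratio for
    the class) are excluded.
    """
    if threshold is None:
        threshold = CONSTRAINT_THRESHOLDS[variant_class]
    i = _CLASS_INDEX[variant_class]
    kept = {}
    for gene, probs in table.probabilities.items():
        if probs[i] is None:
            continue
        oe = constraint.ratio(gene, variant_class)
        if oe is not None and oe < threshold:
            kept[gene] = probs
    if not kept:
        raise ValueError("no genes survive the constraint restriction")
    return MutationProbabilityTable(probabilities=kept)


def compute_scaling_factor(
    matrix: GeneSubjectMatrix,
    table: MutationProbabilityTable,
    n_subjects: Optional[int] = None,
    n_obs_scope: str = "universe",
) -> RescaledModel:
    """Compute SF and the rescaled per-gene success probabilities.

    ``n_obs_scope`` controls which observed variants anchor SF when the
    universe is restricted: ``"universe"`` (default) counts only variants in
    universe genes, preserving exact conservation within the analysis
    universe; ``"all"`` counts every observed variant of the class.
    """
    if n_obs_scope not in ("universe", "all"):
        raise ValueError(f"unknown n_obs_scope {n_obs_scope!r}")
    if n_subjects is None:
        n_subjects = matrix.n_subjects
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    universe = table.universe(matrix.variant_class)
    if n_obs_scope == "universe":
        n_obs = sum(matrix.gene_count(g) for g in universe)
    else:
        n_obs = matrix.total
    if n_obs == 0:
        raise ValueError("no observed variants; scaling factor undefined")
    total_p = sum(table.probability(g, matrix.variant_class) for g in universe)
    if total_p == 0:
        raise ValueError("summed mutation probability is zero")
    sf = n_obs / (n_subjects * total_p)
    p_success = {}
    for g in universe:
        p = table.probability(g, matrix.variant_class) * sf
        if p > 1.0:
            logger.warning("P_success for gene %s clamped from %g to 1", g, p)
            p = 1.0
        p_success[g] = p
    model = RescaledModel(
        variant_class=matrix.variant_class,
        sf=sf,
        n_obs=n_obs,
        n_subjects=n_subjects,
        p_success=p_success,
    )
    model.check_conservation()
    return model
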