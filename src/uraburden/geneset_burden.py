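"""Gene-set burden testing with de-correlation and resampling-based FDR.

A gene-set's carrier probability is the sum of its member genes' rescaled
probabilities, and its observed count is the number of subjects carrying at
least one qualifying variant in the set (at most one variant per set per
subject).  Because curated gene-sets overlap heavily, significant sets are
de-correlated by greedy step-down clustering: repeatedly select the most
significant remaining set and absorb every remaining set whose ultra-rare
variant content has Jaccard similarity > 0.5 with it.  The false discovery
rate of the surviving representatives is estimated by multinomial
resampling of the observed variants under the rescaled null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .containers import GeneSet, GeneSetCollection, GeneSubjectMatrix
from .mutation_model import MutationProbabilityTable, RescaledModel

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetBurdenResult",
    "ClusterSelection",
    "ResamplingFDRResult",
    "filter_genesets",
    "geneset_binomial_test",
    "run_geneset_tests",
    "jaccard_variant_similarity",
    "greedy_stepdown_select",
    "resample_counts",
    "resampling_fdr",
]

#: Size bounds for tested gene-sets (strict): more than 5, fewer than 100.
MIN_SET_SIZE_EXCLUSIVE = 5
MAX_SET_SIZE_EXCLUSIVE = 100

#: Jaccard similarity above which two gene-sets are clustered together.
JACCARD_CLUSTER_THRESHOLD = 0.5


@dataclass(frozen=True)
class GeneSetBurdenResult:
    name: str
    genes: frozenset[str]  # members after universe intersection
    p_success: float
    n_success: int
    n_trials: int
    p_value: float

    def __post_init__(self) -> None:
        if self.n_success > self.n_trials:
            raise ValueError("n_success exceeds n_trials")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")


@dataclass(frozen=True)
class Cluster:
    representative: GeneSetBurdenResult
    absorbed: tuple[str, ...]
    jaccard: Mapping[str, float]


@dataclass(frozen=True)
class ClusterSelection:
    """Greedy step-down output: ordered representatives with absorbed members."""

    clusters: tuple[Cluster, ...]

    @property
    def representatives(self) -> list[GeneSetBurdenResult]:
        return [c.representative for c in self.clusters]

    def all_set_names(self) -> list[str]:
        names = []
        for c in self.clusters:
            names.append(c.representative.name)
            names.extend(c.absorbed)
        return names


@dataclass(frozen=True)
class ResamplingFDRResult:
    thresholds: tuple[float, ...]  # representative p-values, most significant first
    names: tuple[str, ...]
    ngs_real: tuple[int, ...]
    mean_ngs_perm: tuple[float, ...]
    fdr: tuple[float, ...]  # clamped to [0, 1] and monotonized
    iterations: int
    seed: Optional[int]


def filter_genesets(
    collection: GeneSetCollection,
    universe: Iterable[str],
    constrained_universe: Optional[Iterable[str]] = None,
) -> GeneSetCollection:
    """Intersect sets with the probability universe and apply size bounds.

    Sets are retained iff 5 < |genes| < 100 after intersection; when a
    constrained universe is supplied, sets must additionally contain at
    least two constrained genes.
    """
    universe = frozenset(universe)
    constrained = None if constrained_universe is None else frozenset(constrained_universe)
    kept = []
    for s in collection.sets:
        genes = s.genes & universe
        if not MIN_SET_SIZE_EXCLUSIVE < len(genes) < MAX_SET_SIZE_EXCLUSIVE:
            continue
        if constrained is not None and len(genes & constrained) < 2:
            continue
        kept.append(GeneSet(name=s.name, description=s.description, genes=genes))
    return GeneSetCollection(sets=tuple(kept), source=collection.source)


def geneset_binomial_test(
    model: RescaledModel, matrix: GeneSubjectMatrix, geneset: GeneSet
) -> GeneSetBurdenResult:
    """One-sided binomial burden test of a gene-set.

    N_success counts subjects with >= 1 qualifying variant anywhere in the
    set (per-subject cap at one variant per set); P_success is the summed
    rescaled probability of the member genes, clamped at 1.
    """
    genes = frozenset(g for g in geneset.genes if g in model)
    if not genes:
        raise ValueError(f"gene-set {geneset.name!r} empty after universe intersection")
    p_success = sum(model.probability(g) for g in genes)
    if p_success > 1.0:
        logger.warning("gene-set %s P_success clamped from %g to 1", geneset.name, p_success)
        p_success = 1.0
    n_success = len(matrix.set_carriers(genes))
    p_value = float(stats.binom.sf(n_success - 1, model.n_subjects, p_success))
    return GeneSetBurdenResult(
        name=geneset.name,
        genes=genes,
        p_success=p_success,
        n_success=n_success,
        n_trials=model.n_subjects,
        p_value=min(p_value, 1.0),
    )


def run_geneset_tests(
    model: RescaledModel, matrix: GeneSubjectMatrix, collection: GeneSetCollection
) -> list[GeneSetBurdenResult]:
    return [geneset_binomial_test(model, matrix, s) for s in collection.sets]


def jaccard_variant_similarity(
    set_i: Iterable[str], set_j: Iterable[str], matrix: GeneSubjectMatrix
) -> float:
    """Jaccard similarity of two gene-sets' ultra-rare variant content.

    Similarity is computed on the (gene, subject) indicator entries of the
    member genes, not on the gene lists themselves, so two sets are only
    "correlated" when they share observed variants.  Empty union gives 0.
    """
    vi = matrix.variant_keys(set_i)
    vj = matrix.variant_keys(set_j)
    union = vi | vj
    if not union:
        return 0.0
    return len(vi & vj) / len(union)


def greedy_stepdown_select(
    results: Sequence[GeneSetBurdenResult], matrix: GeneSubjectMatrix
) -> ClusterSelection:
    """Greedy step-down clustering of overlapping gene-sets.

    Iteratively select the most significant remaining set (ties broken by
    name), absorb every remaining set with variant-Jaccard > 0.5 to it, and
    remove both from the pool.  Only representatives proceed to the FDR
    estimation.
    """
    pool = sorted(results, key=lambda r: (r.p_value, r.name))
    clusters = []
    while pool:
        selected = pool.pop(0)
        absorbed = []
        jaccards = {}
        remaining = []
        for r in pool:
            j = jaccard_variant_similarity(selected.genes, r.genes, matrix)
            if j > JACCARD_CLUSTER_THRESHOLD:
                absorbed.append(r.name)
                jaccards[r.name] = j
            else:
                remaining.append(r)
        pool = remaining
        clusters.append(
            Cluster(representative=selected, absorbed=tuple(absorbed), jaccard=jaccards)
        )
    return ClusterSelection(clusters=tuple(clusters))


def resample_counts(
    model: RescaledModel,
    n_subjects: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> GeneSubjectMatrix:
    """Resample gene counts under the rescaled null.

    The observed total N_obs is redistributed over genes by a multinomial
    with probabilities proportional to the rescaled per-gene probabilities;
    each resampled variant is assigned to a uniformly random subject.
    Multiplicities within (gene, subject) are retained and only capped at
    test time, so the total variant number is preserved exactly.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if n_subjects is None:
        n_subjects = model.n_subjects
    genes = model.universe
    probs = np.array([model.probability(g) for g in genes], dtype=float)
    probs = probs / probs.sum()
    gene_counts = rng.multinomial(model.n_obs, probs)
    subject_ids = tuple(f"S{i:04d}" for i in range(n_subjects))
    matrix = GeneSubjectMatrix(variant_class=model.variant_class, subject_ids=subject_ids)
    nonzero = np.nonzero(gene_counts)[0]
    for gi in nonzero:
        assignments = rng.integers(0, n_subjects, size=gene_counts[gi])
        for si in assignments:
            matrix.add(genes[gi], subject_ids[si])
    return matrix


def fdr_from_counts(mean_ngs_perm: np.ndarray, ngs_real: np.ndarray) -> np.ndarray:
    """FDR_p = mean permutation count / real count at each threshold,
    clamped to [0, 1] and monotonized (cumulative minimum from the least to
    the most significant threshold).  Thresholds are ordered most
    significant first."""
    raw = np.asarray(mean_ngs_perm, dtype=float) / np.asarray(ngs_real, dtype=float)
    clamped = np.clip(raw, 0.0, 1.0)
    return np.minimum.accumulate(clamped[::-1])[::-1]


def resampling_fdr(
    real: ClusterSelection,
    model: RescaledModel,
    collection: GeneSetCollection,
    n_subjects: Optional[int] = None,
    iterations: int = 1000,
    seed: Optional[int] = None,
    perm_selection: str = "rerun",
) -> ResamplingFDRResult:
    """Resampling-based FDR for the selected gene-set representatives.

    For each representative p-value threshold p, FDR_p is the mean (over
    resampling iterations) of the number of selected gene-sets with p-value
    <= p, divided by the real count of representatives with p-value <= p.
    With ``perm_selection="rerun"`` each iteration re-runs the full
    pipeline (gene-set tests then greedy selection) on the resampled
    counts; with ``"fixed"`` all filtered sets are counted without
    re-clustering.  The estimate is clamped to [0, 1] and monotonized
    (cumulative minimum from the least to the most significant threshold).
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if perm_selection not in ("rerun", "fixed"):
        raise ValueError(f"unknown perm_selection {perm_selection!r}")
    reps = sorted(real.representatives, key=lambda r: (r.p_value, r.name))
    if not reps:
        raise ValueError("empty cluster selection")
    thresholds = np.array([r.p_value for r in reps])
    ngs_real = np.array([int(np.sum(thresholds <= t)) for t in thresholds])

    rng = np.random.default_rng(seed)
    perm_counts = np.zeros((iterations, len(thresholds)))
    for it in range(iterations):
        perm_matrix = resample_counts(model, n_subjects=n_subjects, rng=rng)
        perm_results = run_geneset_tests(model, perm_matrix, collection)
        if perm_selection == "rerun":
            perm_sel = greedy_stepdown_select(perm_results, perm_matrix)
            perm_p = np.array([r.p_value for r in perm_sel.representatives])
        else:
            perm_p = np.array([r.p_value for r in perm_results])
        perm_counts[it] = [np.sum(perm_p <= t) for t in thresholds]

    mean_perm = perm_counts.mean(axis=0)
    fdr = fdr_from_counts(mean_perm, ngs_real)
    return ResamplingFDRResult(
        thresholds=tuple(float(t) for t in thresholds),
        names=tuple(r.name for r in reps),
        ngs_real=tuple(int(n) for n in ngs_real),
        mean_ngs_perm=tuple(float(m) for m in mean_perm),
        fdr=tuple(float(f) for f in fdr),
        iterations=iterations,
        seed=seed,
    )
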