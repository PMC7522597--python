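"""Gene-level burden tests and exact-test enrichment machinery.

The core test is a one-sided binomial test per gene: the number of distinct
carrier subjects is compared against Binomial(N_S, P_success_g) with
P_success_g the rescaled de novo mutation probability.  Multiple-test
correction follows the study design: Benjamini-Hochberg per variant class
over the full defined-probability universe, Bonferroni jointly across
classes.  Fisher exact tests (with conditional maximum-likelihood odds
ratios) support the reference-singleton comparison and the protein-region
and residue-class enrichment analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats
from scipy.stats.contingency import odds_ratio as _conditional_odds_ratio
from statsmodels.stats.multitest import multipletests

from .containers import GeneSubjectMatrix
from .mutation_model import RescaledModel

__all__ = [
    "GeneBurdenResult",
    "ContingencyTable2x2",
    "ExactTestResult",
    "ProteinAnnotation",
    "gene_binomial_test",
    "run_gene_tests",
    "correct_multiple_tests",
    "fisher_exact",
    "singleton_comparison_test",
    "singleton_comparison_all",
    "region_enrichment",
    "residue_class_enrichment",
    "carrier_fraction",
]


@dataclass(frozen=True)
class GeneBurdenResult:
    gene: str
    variant_class: str
    n_success: int
    n_trials: int
    p_success: float
    p_value: float
    bh_fdr: Optional[float] = None
    bonferroni: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")
        if self.n_success > self.n_trials:
            raise ValueError("n_success exceeds n_trials")


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b; c, d): rows cohort vs reference, or in- vs out-of-class."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(x < 0 for x in cells):
            raise ValueError("contingency cells must be non-negative")
        if sum(cells) == 0:
            raise ValueError("all-zero contingency table")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


@dataclass(frozen=True)
class ExactTestResult:
    p_one_sided_greater: float
    p_two_sided: float
    odds_ratio: float  # conditional MLE; may be +inf
    sample_odds_ratio: float
    bh_fdr: Optional[float] = None


@dataclass(frozen=True)
class ProteinAnnotation:
    """Protein length, named regions (closed aa intervals) and residue classes."""

    gene: str
    length: int
    regions: Mapping[str, tuple[int, int]] = field(default_factory=dict)
    residue_classes: Mapping[str, frozenset[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (start, end) in self.regions.items():
            if not 1 <= start <= end <= self.length:
                raise ValueError(f"region {name!r} interval outside [1, {self.length}]")
        for name, positions in self.residue_classes.items():
            if any(not 1 <= p <= self.length for p in positions):
                raise ValueError(f"residue class {name!r} has positions outside protein")

    def in_region(self, position: int, region: str) -> bool:
        start, end = self.regions[region]
        return start <= position <= end

    def in_residue_class(self, position: int, residue_class: str) -> bool:
        return position in self.residue_classes[residue_class]


def gene_binomial_test(
    model: RescaledModel, matrix: GeneSubjectMatrix, gene: str
) -> GeneBurdenResult:
    """One-sided binomial burden test for one gene.

    p = P(X >= n_success) for X ~ Binomial(N_S, P_success_g).  A gene with
    no observed carriers gets p = 1.
    """
    if gene not in model:
        raise KeyError(f"gene {gene} not in the model universe")
    p_success = model.probability(gene)
    n_success = matrix.gene_count(gene)
    p_value = float(stats.binom.sf(n_success - 1, model.n_subjects, p_success))
    return GeneBurdenResult(
        gene=gene,
        variant_class=model.variant_class,
        n_success=n_success,
        n_trials=model.n_subjects,
        p_success=p_success,
        p_value=min(p_value, 1.0),
    )


def run_gene_tests(
    model: RescaledModel, matrix: GeneSubjectMatrix, observed_only: bool = False
) -> list[GeneBurdenResult]:
    """Burden test every gene in the model universe.

    With ``observed_only`` only genes with at least one carrier are
    returned; unobserved genes (p = 1) still enter the multiple-test
    correction through the universe size.
    """
    genes = model.universe
    if observed_only:
        genes = [g for g in genes if matrix.gene_count(g) > 0]
    # Vectorised tail over the whole universe.
    n_success = np.array([matrix.gene_count(g) for g in genes])
    p_success = np.array([model.probability(g) for g in genes])
    p_values = stats.binom.sf(n_success - 1, model.n_subjects, p_success)
    return [
        GeneBurdenResult(
            gene=g,
            variant_class=model.variant_class,
            n_success=int(k),
            n_trials=model.n_subjects,
            p_success=float(p),
            p_value=float(min(pv, 1.0)),
        )
        for g, k, p, pv in zip(genes, n_success, p_success, p_values)
    ]


def correct_multiple_tests(
    results_by_class: Mapping[str, Sequence[GeneBurdenResult]],
    universe_sizes: Mapping[str, int],
    unobserved: str = "p1",
) -> dict[str, list[GeneBurdenResult]]:
    """Attach BH-FDR (per class) and Bonferroni (joint across classes).

    BH is computed per variant class over m = universe size of that class;
    with ``unobserved="p1"`` genes without observed variants enter as p = 1
    placeholders, with ``unobserved="omit"`` m is still the universe size
    but only supplied p-values are ranked (indistinguishable at top ranks).
    Bonferroni multiplies by the summed universe sizes of all classes.
    """
    if unobserved not in ("p1", "omit"):
        raise ValueError(f"unknown unobserved mode {unobserved!r}")
    m_joint = sum(universe_sizes[c] for c in results_by_class)
    corrected: dict[str, list[GeneBurdenResult]] = {}
    for variant_class, results in results_by_class.items():
        m = universe_sizes[variant_class]
        if len(results) > m:
            raise ValueError("more results than universe size")
        pvals = [r.p_value for r in results]
        if unobserved == "p1":
            padded = np.concatenate([pvals, np.ones(m - len(pvals))])
        else:
            padded = np.asarray(pvals, dtype=float)
        if len(padded):
            bh_all = _bh_adjust(padded, m)
        else:
            bh_all = padded
        corrected[variant_class] = [
            replace(
                r,
                bh_fdr=float(bh_all[i]),
                bonferroni=float(min(1.0, r.p_value * m_joint)),
            )
            for i, r in enumerate(results)
        ]
    return corrected


def _bh_adjust(pvals: np.ndarray, m: int) -> np.ndarray:
    """Benjamini-Hochberg step-up with total test count m >= len(pvals)."""
    n = len(pvals)
    order = np.argsort(pvals, kind="stable")
    ranked = pvals[order] * m / np.arange(1, n + 1)
    # enforce monotonicity from the largest p downwards
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def fisher_exact(
    table: ContingencyTable2x2, alternative: str = "two_sided"
) -> ExactTestResult:
    """Fisher exact test with conditional-MLE odds ratio.

    The two-sided p-value uses the minimum-likelihood rule (sum of all
    hypergeometric table probabilities no larger than the observed one).
    The reported odds ratio is the conditional maximum-likelihood estimate
    of the noncentral hypergeometric odds parameter (+inf when b or c is
    zero with a positive diagonal); the simple sample estimate ad/bc is
    also provided.
    """
    if alternative not in ("greater", "two_sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    arr = table.as_array()
    _, p_greater = stats.fisher_exact(arr, alternative="greater")
    _, p_two = stats.fisher_exact(arr, alternative="two-sided")
    cmle = float(_conditional_odds_ratio(arr, kind="conditional").statistic)
    a, b, c, d = table.a, table.b, table.c, table.d
    if b * c == 0:
        sample = math.inf if a * d > 0 else math.nan
    else:
        sample = a * d / (b * c)
    return ExactTestResult(
        p_one_sided_greater=float(p_greater),
        p_two_sided=float(p_two),
        odds_ratio=cmle,
        sample_odds_ratio=sample,
    )


def _singleton_universe(singletons: Mapping[str, tuple[int, int]]) -> list[str]:
    """Genes with >= 1 reference truncating AND >= 1 reference missense singleton."""
    return sorted(g for g, (n_lof, n_mis) in singletons.items() if n_lof >= 1 and n_mis >= 1)


def singleton_comparison_test(
    matrix: GeneSubjectMatrix,
    singletons: Mapping[str, tuple[int, int]],
    gene: str,
    variant_class: Optional[str] = None,
) -> ExactTestResult:
    """Compare the cohort's ultra-rare burden in ``gene`` to reference singletons.

    2x2 cells: (a) cohort ultra-rare variants in the gene, (b) cohort
    variants in other universe genes, (c) reference singletons in the gene,
    (d) reference singletons in other genes.  Two-sided exact test.
    """
    variant_class = variant_class or matrix.variant_class
    universe = _singleton_universe(singletons)
    if gene not in universe:
        raise KeyError(f"gene {gene} outside the reference-singleton universe")
    i = 0 if variant_class == "truncating" else 1
    a = matrix.gene_count(gene)
    b = sum(matrix.gene_count(g) for g in universe) - a
    c = singletons[gene][i]
    d = sum(singletons[g][i] for g in universe) - c
    return fisher_exact(ContingencyTable2x2(a, b, c, d), alternative="two_sided")


def singleton_comparison_all(
    matrix: GeneSubjectMatrix,
    singletons: Mapping[str, tuple[int, int]],
    variant_class: Optional[str] = None,
) -> dict[str, ExactTestResult]:
    """Singleton comparison for every universe gene with observed carriers,
    with BH-FDR across the tested genes."""
    variant_class = variant_class or matrix.variant_class
    universe = _singleton_universe(singletons)
    tested = [g for g in universe if matrix.gene_count(g) > 0]
    results = {
        g: singleton_comparison_test(matrix, singletons, g, variant_class) for g in tested
    }
    if results:
        pvals = np.array([results[g].p_two_sided for g in tested])
        _, bh, _, _ = multipletests(pvals, method="fdr_bh")
        results = {g: replace(results[g], bh_fdr=float(q)) for g, q in zip(tested, bh)}
    return results


def _positions_table(
    cohort_positions: Sequence[int],
    reference_positions: Sequence[int],
    member,
) -> ContingencyTable2x2:
    if len(cohort_positions) == 0:
        raise ValueError("no cohort positions; cannot build a table")
    a = sum(1 for p in cohort_positions if member(p))
    b = len(cohort_positions) - a
    c = sum(1 for p in reference_positions if member(p))
    d = len(reference_positions) - c
    if a + c == 0:
        raise ValueError("no in-class positions in cohort or reference; degenerate margin")
    return ContingencyTable2x2(a, b, c, d)


def region_enrichment(
    cohort_positions: Sequence[int],
    reference_positions: Sequence[int],
    annotation: ProteinAnnotation,
    region: str,
) -> ExactTestResult:
    """One-sided enrichment of cohort variant positions within a protein region."""
    if region not in annotation.regions:
        raise KeyError(f"unknown region {region!r} for {annotation.gene}")
    for p in list(cohort_positions) + list(reference_positions):
        if not 1 <= p <= annotation.length:
            raise ValueError(f"position {p} outside protein of length {annotation.length}")
    table = _positions_table(
        cohort_positions, reference_positions, lambda p: annotation.in_region(p, region)
    )
    return fisher_exact(table, alternative="greater")


def residue_class_enrichment(
    cohort_positions: Sequence[int],
    reference_positions: Sequence[int],
    annotation: ProteinAnnotation,
    residue_class: str,
) -> ExactTestResult:
    """One-sided enrichment of cohort variants hitting a residue class
    (e.g. disulfide-bond cysteines)."""
    if residue_class not in annotation.residue_classes:
        raise KeyError(f"unknown residue class {residue_class!r} for {annotation.gene}")
    table = _positions_table(
        cohort_positions,
        reference_positions,
        lambda p: annotation.in_residue_class(p, residue_class),
    )
    return fisher_exact(table, alternative="greater")


def carrier_fraction(
    matrices: Iterable[GeneSubjectMatrix],
    genes: Iterable[str],
    subjects: Iterable[str],
) -> float:
    """Fraction of ``subjects`` carrying >= 1 qualifying variant in >= 1 gene.

    Carriers are counted distinctly: a subject with variants in several
    listed genes (or in both variant classes) contributes once.
    """
    subjects = list(subjects)
    if not subjects:
        raise ValueError("empty subject subset")
    genes = list(genes)
    carriers: set[str] = set()
    for matrix in matrices:
        carriers.update(matrix.set_carriers(genes))
    return len(carriers & set(subjects)) / len(subjects)
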