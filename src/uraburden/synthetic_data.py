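"""Synthetic cohorts, reference singleton tables and gene-set collections.

The generator emulates the inputs of the burden pipeline under an explicit
multinomial null: per-gene mutation probabilities are drawn log-uniformly
over the dynamic range of published per-gene tables, the stated number of
ultra-rare variants per class is distributed over genes proportionally to
those probabilities, and each variant is assigned to a uniformly random
subject.  Per-gene burden can be injected as extra distinct carriers, and
filter-violating records (low depth, low alt fraction, population-reference
hits, non-principal transcripts, frame-restoring indel pairs) can be
planted at chosen rates.  Ground-truth labels travel in a side channel,
never inside the variant table, so the pipeline cannot peek.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .containers import CohortTable, GeneSet, GeneSetCollection, VariantRecord
from .mutation_model import MutationProbabilityTable

__all__ = [
    "SyntheticCohortSpec",
    "simulate_probability_table",
    "simulate_cohort",
    "simulate_singletons",
    "simulate_genesets",
]

#: Log-uniform range of synthetic per-gene mutation probabilities, matching
#: the dynamic range of published per-gene de novo tables.
PROBABILITY_RANGE = (1e-7, 1e-4)

#: Study-scale defaults: cohort size and final per-class ultra-rare totals.
DEFAULT_N_SUBJECTS = 231
DEFAULT_CLASS_TOTALS = {"truncating": 642, "missense": 3293}

_CLASS_EFFECT = {"truncating": "stopgain", "missense": "missense"}


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Parameters of one synthetic cohort.

    ``burden_injections`` maps gene -> number of extra distinct carrier
    subjects per class label, e.g. ``{"G0001": ("truncating", 7)}``.
    ``qc_violation_rates`` gives, per violation type, the number of planted
    bad records as a fraction of the clean records.
    """

    n_subjects: int = DEFAULT_N_SUBJECTS
    n_genes: int = 1000
    class_totals: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_TOTALS)
    )
    burden_injections: Mapping[str, tuple[str, int]] = field(default_factory=dict)
    qc_violation_rates: Mapping[str, float] = field(default_factory=dict)
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_genes < 1:
            raise ValueError("n_subjects and n_genes must be >= 1")
        for rate in self.qc_violation_rates.values():
            if not 0.0 <= rate <= 1.0:
                raise ValueError("violation rates must be in [0, 1]")
        for gene, (_, extra) in self.burden_injections.items():
            if extra > self.n_subjects:
                raise ValueError(
                    f"injection of {extra} carriers in {gene} exceeds cohort size"
                )


def simulate_probability_table(
    n_genes: int,
    rng: np.random.Generator,
    prob_range: tuple[float, float] = PROBABILITY_RANGE,
) -> MutationProbabilityTable:
    """Log-uniform synthetic per-gene probability table (both classes)."""
    lo, hi = np.log(prob_range[0]), np.log(prob_range[1])
    p_lof = np.exp(rng.uniform(lo, hi, size=n_genes))
    p_mis = np.exp(rng.uniform(lo, hi, size=n_genes))
    genes = [f"G{i:04d}" for i in range(n_genes)]
    return MutationProbabilityTable(
        probabilities={g: (float(a), float(b)) for g, a, b in zip(genes, p_lof, p_mis)}
    )


def _clean_record(
    subject: str,
    gene: str,
    variant_class: str,
    pos: int,
    **overrides,
) -> VariantRecord:
    base = dict(
        subject_id=subject,
        chrom="chr1",
        pos=pos,
        ref="A",
        alt="C",
        gene=gene,
        transcript=f"TX_{gene}",
        effect=_CLASS_EFFECT[variant_class],
        zygosity="het",
        dp=40,
        gq=99,
        alt_fraction=0.5,
        af_1000g=None,
        af_exac=None,
        af_gnomad=None,
        cohort_allele_count=1,
    )
    base.update(overrides)
    return VariantRecord(**base)


def simulate_cohort(
    spec: SyntheticCohortSpec,
    table: Optional[MutationProbabilityTable] = None,
) -> tuple[CohortTable, dict[str, str], dict]:
    """Draw a synthetic cohort under the multinomial null.

    Returns ``(cohort, principal_map, truth)``; ``truth`` records injected
    burden carriers and planted filter violations by record position.
    All clean records pass every filter of the cascade.
    """
    rng = np.random.default_rng(spec.seed)
    if table is None:
        table = simulate_probability_table(spec.n_genes, rng)
    subjects = [f"S{i:04d}" for i in range(spec.n_subjects)]
    principal_map = {g: f"TX_{g}" for g in table.probabilities}
    truth: dict = {"injections": {}, "violations": []}
    records: list[VariantRecord] = []
    pos_counter = 1

    for variant_class, total in spec.class_totals.items():
        universe = table.universe(variant_class)
        probs = np.array([table.probability(g, variant_class) for g in universe])
        probs = probs / probs.sum()
        gene_counts = rng.multinomial(total, probs)
        for gi in np.nonzero(gene_counts)[0]:
            for _ in range(gene_counts[gi]):
                subject = subjects[rng.integers(0, spec.n_subjects)]
                records.append(
                    _clean_record(subject, universe[gi], variant_class, pos_counter)
                )
                pos_counter += 1

    # Injected burden: extra distinct carriers where possible.
    for gene, (variant_class, extra) in spec.burden_injections.items():
        existing = {r.subject_id for r in records if r.gene == gene}
        available = [s for s in subjects if s not in existing]
        rng.shuffle(available)
        chosen = available[:extra]
        if len(chosen) < extra:
            raise ValueError(f"cannot inject {extra} distinct carriers in {gene}")
        for subject in chosen:
            records.append(_clean_record(subject, gene, variant_class, pos_counter))
            pos_counter += 1
        truth["injections"][gene] = {"class": variant_class, "carriers": chosen}

    n_clean = len(records)
    genes_all = list(table.probabilities)
    for kind, rate in spec.qc_violation_rates.items():
        n_bad = int(round(rate * n_clean))
        for _ in range(n_bad):
            subject = subjects[rng.integers(0, spec.n_subjects)]
            gene = genes_all[rng.integers(0, len(genes_all))]
            vclass = "truncating" if rng.random() < 0.5 else "missense"
            if kind == "low_dp":
                rec = _clean_record(subject, gene, vclass, pos_counter, dp=5)
                records.append(rec)
            elif kind == "low_alt_fraction":
                rec = _clean_record(subject, gene, vclass, pos_counter, alt_fraction=0.1)
                records.append(rec)
            elif kind == "reference_hit":
                rec = _clean_record(subject, gene, vclass, pos_counter, af_gnomad=1e-5)
                records.append(rec)
            elif kind == "non_principal":
                rec = _clean_record(
                    subject, gene, vclass, pos_counter, transcript=f"ALT_{gene}"
                )
                records.append(rec)
            elif kind == "multi_indel":
                # frame-restoring pair (+1 then +2): both must be removed
                records.append(
                    _clean_record(
                        subject, gene, "truncating", pos_counter,
                        ref="A", alt="AC", effect="frameshift_insertion",
                    )
                )
                pos_counter += 1
                records.append(
                    _clean_record(
                        subject, gene, "truncating", pos_counter,
                        ref="A", alt="ACC", effect="frameshift_insertion",
                    )
                )
            else:
                raise ValueError(f"unknown violation kind {kind!r}")
            truth["violations"].append({"kind": kind, "gene": gene, "subject": subject})
            pos_counter += 1

    cohort = CohortTable.from_records(records, subject_ids=subjects)
    return cohort, principal_map, truth


def simulate_singletons(
    table: MutationProbabilityTable,
    totals: Mapping[str, int],
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> dict[str, tuple[int, int]]:
    """Multinomial per-gene reference singleton counts.

    Every gene is guaranteed at least one singleton of each class (the
    reference-comparison universe requires it), so each class total must be
    at least the number of genes.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    counts = {}
    for variant_class in ("truncating", "missense"):
        universe = table.universe(variant_class)
        total = totals[variant_class]
        if total < len(universe):
            raise ValueError(
                f"{variant_class} total {total} < {len(universe)} genes; "
                "cannot guarantee one singleton per gene"
            )
        probs = np.array([table.probability(g, variant_class) for g in universe])
        probs = probs / probs.sum()
        extra = rng.multinomial(total - len(universe), probs)
        counts[variant_class] = {g: 1 + int(e) for g, e in zip(universe, extra)}
    genes = sorted(set(counts["truncating"]) | set(counts["missense"]))
    return {
        g: (counts["truncating"].get(g, 0), counts["missense"].get(g, 0)) for g in genes
    }


def simulate_genesets(
    universe: Sequence[str],
    n_sets: int,
    size_range: tuple[int, int] = (6, 99),
    overlap: str = "planted",
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
    n_clusters: int = 2,
    cluster_size: int = 3,
    shared_fraction: float = 0.75,
) -> tuple[GeneSetCollection, dict[str, int]]:
    """Random gene-sets with optional planted overlapping clusters.

    With ``overlap="planted"``, ``n_clusters`` groups of ``cluster_size``
    sets share ``shared_fraction`` of their members (above the 0.5 Jaccard
    clustering threshold under full carriage); the remaining sets are
    sampled independently.  Returns the collection and the ground-truth
    cluster label per set name (-1 for independent sets).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if overlap not in ("planted", "none"):
        raise ValueError(f"unknown overlap design {overlap!r}")
    lo, hi = size_range
    if hi > len(universe):
        raise ValueError(f"universe of {len(universe)} genes smaller than max size {hi}")
    universe = list(universe)
    sets: list[GeneSet] = []
    labels: dict[str, int] = {}
    set_idx = 0

    def random_size() -> int:
        return int(rng.integers(lo, hi + 1))

    if overlap == "planted":
        for cluster in range(n_clusters):
            if n_sets - set_idx < cluster_size:
                break
            size = random_size()
            core_n = max(1, int(round(shared_fraction * size)))
            core = list(rng.choice(universe, size=core_n, replace=False))
            for _ in range(cluster_size):
                rest = [g for g in universe if g not in core]
                extra = list(rng.choice(rest, size=size - core_n, replace=False))
                name = f"SET{set_idx:03d}"
                sets.append(
                    GeneSet(
                        name=name,
                        description=f"planted cluster {cluster}",
                        genes=frozenset(core + extra),
                    )
                )
                labels[name] = cluster
                set_idx += 1
    while set_idx < n_sets:
        size = random_size()
        members = list(rng.choice(universe, size=size, replace=False))
        name = f"SET{set_idx:03d}"
        sets.append(GeneSet(name=name, description="independent", genes=frozenset(members)))
        labels[name] = -1
        set_idx += 1
    return GeneSetCollection(sets=tuple(sets), source="synthetic"), labels
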