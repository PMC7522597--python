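"""Core in-memory containers shared across the pipeline.

The pipeline operates on three kinds of objects: per-subject annotated
variant calls (:class:`VariantRecord` collected in a :class:`CohortTable`),
named gene collections (:class:`GeneSetCollection`), and the per-gene,
per-subject carrier indicator matrix (:class:`GeneSubjectMatrix`) that the
burden tests consume.  Everything downstream of the readers works only on
these types.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional

__all__ = [
    "VariantRecord",
    "CohortTable",
    "GeneSet",
    "GeneSetCollection",
    "GeneSubjectMatrix",
    "TRUNCATING_EFFECTS",
    "EFFECT_VOCABULARY",
    "classify_effect",
]

#: Controlled effect vocabulary.  Annotation-tool labels are mapped onto
#: these by the alias table shipped under ``uraburden/data``.
EFFECT_VOCABULARY = frozenset(
    {
        "stopgain",
        "frameshift_insertion",
        "frameshift_deletion",
        "nonframeshift_insertion",
        "nonframeshift_deletion",
        "splice_donor",
        "splice_acceptor",
        "missense",
        "synonymous",
        "other",
    }
)

#: Effects counted as protein-truncating (loss of function): premature stop
#: codons, frameshifting indels and disruption of the canonical intronic
#: splice dinucleotides.
TRUNCATING_EFFECTS = frozenset(
    {
        "stopgain",
        "frameshift_insertion",
        "frameshift_deletion",
        "splice_donor",
        "splice_acceptor",
    }
)


def classify_effect(effect: str) -> str:
    """Map a controlled-vocabulary effect label to its variant class.

    Returns one of ``"truncating"``, ``"missense"`` or ``"other"``.
    """
    if effect in TRUNCATING_EFFECTS:
        return "truncating"
    if effect == "missense":
        return "missense"
    return "other"


@dataclass(frozen=True)
class VariantRecord:
    """One annotated variant call in one subject.

    Allele frequencies of ``None`` mean the allele is absent from that
    reference panel; coordinates are 1-based VCF-style.
    """

    subject_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    transcript: str
    effect: str
    zygosity: str  # "het" | "hom"
    dp: int
    gq: int
    alt_fraction: float
    af_1000g: Optional[float] = None
    af_exac: Optional[float] = None
    af_gnomad: Optional[float] = None
    cohort_allele_count: int = 1

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt are identical at {self.chrom}:{self.pos}")
        if not 0.0 <= self.alt_fraction <= 1.0:
            raise ValueError(f"alt_fraction {self.alt_fraction} outside [0, 1]")
        if self.dp < 0:
            raise ValueError(f"DP must be >= 0, got {self.dp}")
        if self.cohort_allele_count < 1:
            raise ValueError(
                f"cohort_allele_count must be >= 1, got {self.cohort_allele_count}"
            )
        if self.zygosity not in ("het", "hom"):
            raise ValueError(f"unknown zygosity {self.zygosity!r}")
        if self.effect not in EFFECT_VOCABULARY:
            raise ValueError(f"unknown effect label {self.effect!r}")

    @property
    def variant_class(self) -> str:
        return classify_effect(self.effect)

    @property
    def indel_size(self) -> int:
        """Signed indel size: insertions positive, deletions negative."""
        return len(self.alt) - len(self.ref)

    def with_effect(self, effect: str) -> "VariantRecord":
        return replace(self, effect=effect)


@dataclass(frozen=True)
class CohortTable:
    """A cohort of variant calls plus its subject roster.

    ``subject_ids`` may contain subjects without any surviving variant;
    the roster, not the records, defines the number of binomial trials.
    """

    records: tuple[VariantRecord, ...]
    subject_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.subject_ids) == 0:
            raise ValueError("cohort must contain at least one subject")
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise ValueError("subject_ids must be unique")
        roster = set(self.subject_ids)
        for rec in self.records:
            if rec.subject_id not in roster:
                raise ValueError(
                    f"record subject {rec.subject_id!r} not in subject roster"
                )

    @classmethod
    def from_records(
        cls,
        records: Iterable[VariantRecord],
        subject_ids: Optional[Iterable[str]] = None,
    ) -> "CohortTable":
        records = tuple(records)
        if subject_ids is None:
            seen: dict[str, None] = {}
            for rec in records:
                seen.setdefault(rec.subject_id, None)
            subject_ids = tuple(seen)
        else:
            subject_ids = tuple(subject_ids)
        return cls(records=records, subject_ids=subject_ids)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def __len__(self) -> int:
        return len(self.records)

    def filter(self, predicate) -> "CohortTable":
        """New table with records satisfying ``predicate``; roster kept."""
        return CohortTable(
            records=tuple(r for r in self.records if predicate(r)),
            subject_ids=self.subject_ids,
        )

    def subset_subjects(self, subjects: Iterable[str]) -> "CohortTable":
        keep = [s for s in self.subject_ids if s in set(subjects)]
        if not keep:
            raise ValueError("subject subset is empty or disjoint from roster")
        keep_set = set(keep)
        return CohortTable(
            records=tuple(r for r in self.records if r.subject_id in keep_set),
            subject_ids=tuple(keep),
        )


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene-set {self.name!r} is empty")


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene-sets (GO/pathways or mouse-phenotype collections)."""

    sets: tuple[GeneSet, ...]
    source: str = ""

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate gene-set names: {dup}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def get(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)


@dataclass
class GeneSubjectMatrix:
    """Per-gene, per-subject ultra-rare variant counts for one variant class.

    The burden tests use the capped (0/1 indicator) view: a gene's count is
    its number of distinct carrier subjects.  Raw multiplicities are kept so
    that multinomial resampling can preserve the total variant number while
    the per-subject cap is still applied at test time.
    """

    variant_class: str
    counts: dict[str, dict[str, int]] = field(default_factory=dict)
    subject_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.variant_class not in ("truncating", "missense"):
            raise ValueError(f"unknown variant class {self.variant_class!r}")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def genes(self) -> list[str]:
        return sorted(g for g, subj in self.counts.items() if subj)

    def add(self, gene: str, subject_id: str, count: int = 1) -> None:
        self.counts.setdefault(gene, {})
        self.counts[gene][subject_id] = self.counts[gene].get(subject_id, 0) + count

    def carriers(self, gene: str) -> frozenset[str]:
        return frozenset(self.counts.get(gene, {}))

    def gene_count(self, gene: str) -> int:
        """Distinct carrier subjects for ``gene`` (the capped count)."""
        return len(self.counts.get(gene, {}))

    @property
    def total(self) -> int:
        """Total capped count: sum over genes of distinct carriers."""
        return sum(len(subj) for subj in self.counts.values())

    @property
    def raw_total(self) -> int:
        """Total variant multiplicity before per-gene-per-subject capping."""
        return sum(sum(c.values()) for c in self.counts.values())

    def variant_keys(self, genes: Iterable[str]) -> frozenset[tuple[str, str]]:
        """(gene, subject) indicator entries for genes in ``genes``."""
        out = set()
        for g in genes:
            for s in self.counts.get(g, {}):
                out.add((g, s))
        return frozenset(out)

    def set_carriers(self, genes: Iterable[str]) -> frozenset[str]:
        """Distinct subjects carrying >=1 variant in any of ``genes``."""
        out: set[str] = set()
        for g in genes:
            out.update(self.counts.get(g, {}))
        return frozenset(out)

    @classmethod
    def from_cohort(cls, cohort: CohortTable, variant_class: str) -> "GeneSubjectMatrix":
        m = cls(variant_class=variant_class, subject_ids=cohort.subject_ids)
        for rec in cohort.records:
            if rec.variant_class == variant_class:
                m.add(rec.gene, rec.subject_id)
        return m
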