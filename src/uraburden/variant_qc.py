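"""Filter cascade turning raw cohort calls into ultra-rare carrier counts.

The cascade retains only ultra-rare variants (cohort singletons absent from
all population references), removes low-quality calls, collapses multiple
frameshift indels per gene per subject, restricts to effects on the
principal transcript, rescues splice-site insertions that re-encode the
canonical intronic dinucleotide, and finally caps counts at one variant per
gene per subject so that a gene's count equals its number of distinct
carrier subjects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from .containers import CohortTable, GeneSubjectMatrix, VariantRecord, classify_effect

logger = logging.getLogger(__name__)

__all__ = [
    "QCThresholds",
    "SpliceSite",
    "StageReport",
    "select_ultra_rare",
    "filter_low_quality",
    "collapse_frameshift_indels",
    "filter_splice_insertions",
    "filter_principal_transcript",
    "collapse_per_gene_per_subject",
    "run_filter_cascade",
]


@dataclass(frozen=True)
class QCThresholds:
    """Call-quality cut-offs.

    A call is removed if DP <= ``max_dp`` or, for heterozygous calls, if
    alt_fraction < ``het_min_alt_fraction`` or GQ < ``het_min_gq``; for
    homozygous calls, if alt_fraction < ``hom_min_alt_fraction`` or
    GQ <= ``hom_max_gq_removed``.  The het genotype-quality rule keeps only
    calls at the common GQ cap of 99; a literal "remove GQ <= 99" would
    remove every capped het call.
    """

    max_dp: int = 10
    het_min_alt_fraction: float = 0.3
    het_min_gq: int = 99
    hom_min_alt_fraction: float = 0.8
    hom_max_gq_removed: int = 25


@dataclass(frozen=True)
class SpliceSite:
    """Annotated canonical splice dinucleotide with local reference context.

    ``context`` is the reference sequence window (about +/-10 bp) around the
    dinucleotide; ``context_start`` is the 1-based genomic position of its
    first base; ``dinucleotide_offset`` is the 0-based offset of the first
    dinucleotide base within ``context``.  ``strand`` gives the annotated
    transcript strand; on '-', the canonical motif appears reverse
    complemented in the reference-forward ``context``.
    """

    transcript: str
    role: str  # "donor" | "acceptor"
    strand: str  # "+" | "-"
    context: str
    context_start: int
    dinucleotide_offset: int

    def __post_init__(self) -> None:
        if self.role not in ("donor", "acceptor"):
            raise ValueError(f"unknown splice role {self.role!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand {self.strand!r}")
        if not 0 <= self.dinucleotide_offset <= len(self.context) - 2:
            raise ValueError("dinucleotide offset outside context window")

    @property
    def canonical(self) -> str:
        motif = "GT" if self.role == "donor" else "AG"
        if self.strand == "-":
            comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
            motif = "".join(comp[b] for b in reversed(motif))
        return motif


@dataclass
class StageReport:
    """Per-stage surviving record counts from the cascade."""

    stages: list[tuple[str, int]] = field(default_factory=list)

    def log(self, stage: str, count: int) -> None:
        self.stages.append((stage, count))
        logger.info("stage %-24s %d records", stage, count)

    def counts(self) -> list[int]:
        return [c for _, c in self.stages]


def _is_absent(af: Optional[float]) -> bool:
    # Missing annotation and a literal zero frequency both mean "absent".
    return af is None or af == 0.0


def select_ultra_rare(cohort: CohortTable) -> CohortTable:
    """Keep cohort singletons never seen in 1000G, ExAC or gnomAD."""
    return cohort.filter(
        lambda r: r.cohort_allele_count == 1
        and _is_absent(r.af_1000g)
        and _is_absent(r.af_exac)
        and _is_absent(r.af_gnomad)
    )


def filter_low_quality(
    cohort: CohortTable, thresholds: QCThresholds = QCThresholds()
) -> CohortTable:
    """Remove calls with low depth, low alt-read fraction or low GQ."""

    def keep(r: VariantRecord) -> bool:
        if r.dp <= thresholds.max_dp:
            return False
        if r.zygosity == "het":
            return (
                r.alt_fraction >= thresholds.het_min_alt_fraction
                and r.gq >= thresholds.het_min_gq
            )
        if r.zygosity == "hom":
            return (
                r.alt_fraction >= thresholds.hom_min_alt_fraction
                and r.gq > thresholds.hom_max_gq_removed
            )
        raise ValueError(f"unknown zygosity {r.zygosity!r}")

    return cohort.filter(keep)


_FRAMESHIFT = ("frameshift_insertion", "frameshift_deletion")


def collapse_frameshift_indels(
    cohort: CohortTable, size_mode: str = "signed"
) -> CohortTable:
    """Collapse multiple frameshift indels per (subject, gene).

    If a subject carries >= 2 frameshift indels in one gene and their
    cumulative size is a multiple of 3 the frame is restored and all are
    removed; otherwise one representative (smallest (chrom, pos)) is kept.
    ``size_mode`` selects signed (insertions +, deletions -) or absolute
    cumulative size.
    """
    if size_mode not in ("signed", "absolute"):
        raise ValueError(f"unknown size_mode {size_mode!r}")

    groups: dict[tuple[str, str], list[VariantRecord]] = {}
    for r in cohort.records:
        if r.effect in _FRAMESHIFT:
            groups.setdefault((r.subject_id, r.gene), []).append(r)

    drop: set[int] = set()
    for recs in groups.values():
        if len(recs) < 2:
            continue
        sizes = [r.indel_size if size_mode == "signed" else abs(r.indel_size) for r in recs]
        if sum(sizes) % 3 == 0:
            drop.update(id(r) for r in recs)
        else:
            representative = min(recs, key=lambda r: (r.chrom, r.pos))
            drop.update(id(r) for r in recs if r is not representative)

    return cohort.filter(lambda r: id(r) not in drop)


def filter_splice_insertions(
    cohort: CohortTable,
    splice_annotation: Optional[Mapping[str, list[SpliceSite]]] = None,
) -> CohortTable:
    """Reclassify splice-site insertions that still encode the canonical motif.

    For insertion records labelled splice_donor/splice_acceptor, the local
    alternate sequence is reconstructed by splicing the inserted bases into
    the annotated reference context.  If the canonical GT/AG dinucleotide
    (strand-adjusted) is still present at the annotated offset, the variant
    does not disrupt splicing and is reclassified to effect "other".  A
    flagged record without an annotated site is conservatively retained.
    """
    annotation = splice_annotation or {}
    out: list[VariantRecord] = []
    for r in cohort.records:
        if r.effect not in ("splice_donor", "splice_acceptor") or r.indel_size <= 0:
            out.append(r)
            continue
        site = _find_site(annotation.get(r.transcript, []), r)
        if site is None:
            logger.warning(
                "no splice annotation for %s %s:%d; record retained",
                r.transcript,
                r.chrom,
                r.pos,
            )
            out.append(r)
            continue
        alt_context = _apply_insertion(site, r)
        at_offset = alt_context[site.dinucleotide_offset : site.dinucleotide_offset + 2]
        if at_offset == site.canonical:
            out.append(r.with_effect("other"))
        else:
            out.append(r)
    return CohortTable(records=tuple(out), subject_ids=cohort.subject_ids)


def _find_site(sites: Iterable[SpliceSite], record: VariantRecord) -> Optional[SpliceSite]:
    for site in sites:
        if site.context_start <= record.pos < site.context_start + len(site.context):
            return site
    return None


def _apply_insertion(site: SpliceSite, record: VariantRecord) -> str:
    """Splice a VCF-style insertion into the reference context window."""
    # VCF insertion: ref is the anchor base at pos, alt = anchor + inserted.
    anchor_index = record.pos - site.context_start
    inserted = record.alt[len(record.ref) :]
    return site.context[: anchor_index + 1] + inserted + site.context[anchor_index + 1 :]


def filter_principal_transcript(
    cohort: CohortTable, principal_map: Mapping[str, str]
) -> CohortTable:
    """Retain only records whose effect is on the gene's principal transcript."""
    n_unmapped = sum(1 for r in cohort.records if r.gene not in principal_map)
    if n_unmapped:
        logger.info("%d record(s) in genes without a principal transcript removed", n_unmapped)
    return cohort.filter(lambda r: principal_map.get(r.gene) == r.transcript)


def collapse_per_gene_per_subject(
    cohort: CohortTable, variant_class: str
) -> GeneSubjectMatrix:
    """Cap at one variant per gene per subject; counts = distinct carriers."""
    if variant_class not in ("truncating", "missense"):
        raise ValueError(f"variant_class must be truncating or missense, got {variant_class!r}")
    matrix = GeneSubjectMatrix(variant_class=variant_class, subject_ids=cohort.subject_ids)
    for r in cohort.records:
        if r.variant_class == variant_class:
            matrix.counts.setdefault(r.gene, {})
            matrix.counts[r.gene][r.subject_id] = 1
    return matrix


def run_filter_cascade(
    cohort: CohortTable,
    variant_class: str,
    principal_map: Mapping[str, str],
    splice_annotation: Optional[Mapping[str, list[SpliceSite]]] = None,
    thresholds: QCThresholds = QCThresholds(),
    size_mode: str = "signed",
) -> tuple[GeneSubjectMatrix, StageReport]:
    """Run the full cascade for one variant class.

    Order: ultra-rare selection -> low-quality -> frameshift-indel collapse
    (truncating only) -> principal transcript -> splice-insertion rescue
    (truncating only) -> per-gene-per-subject collapse.  The missense path
    has no indel or splice stage.
    """
    report = StageReport()
    stage = select_ultra_rare(cohort)
    # Restrict to the class of interest up-front so stage counts are per class.
    stage = stage.filter(lambda r: classify_effect(r.effect) == variant_class)
    report.log("ultra_rare", len(stage))
    stage = filter_low_quality(stage, thresholds)
    report.log("low_quality", len(stage))
    if variant_class == "truncating":
        stage = collapse_frameshift_indels(stage, size_mode=size_mode)
        report.log("frameshift_indel", len(stage))
    stage = filter_principal_transcript(stage, principal_map)
    report.log("principal_transcript", len(stage))
    if variant_class == "truncating":
        stage = filter_splice_insertions(stage, splice_annotation)
        stage = stage.filter(lambda r: classify_effect(r.effect) == variant_class)
        report.log("splice_site", len(stage))
    matrix = collapse_per_gene_per_subject(stage, variant_class)
    report.log("per_gene_per_subject", matrix.total)
    return matrix, report
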