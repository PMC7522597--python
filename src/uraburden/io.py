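"""Readers and writers for the tabular formats the pipeline consumes.

All files are UTF-8, tab-separated, with ``#``-prefixed comment lines
ignored.  Readers return the in-memory containers; nothing downstream
touches files.  An optional multi-sample VCF ingestion path is provided for
cohorts that have not yet been flattened to the per-subject variant table.
"""

from __future__ import annotations

import csv
import logging

import numpy as np
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

from .containers import (
    EFFECT_VOCABULARY,
    CohortTable,
    GeneSet,
    GeneSetCollection,
    VariantRecord,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

VARIANT_COLUMNS = [
    "subject_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "transcript",
    "effect",
    "zygosity",
    "DP",
    "GQ",
    "alt_fraction",
    "af_1000g",
    "af_exac",
    "af_gnomad",
    "cohort_allele_count",
]


class FormatError(ValueError):
    """A file does not follow the documented column/field contract."""


def _load_effect_aliases() -> dict[str, str]:
    text = resources.files("uraburden").joinpath("data/effect_aliases.tsv").read_text()
    aliases: dict[str, str] = {}
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        alias, effect = line.split("\t")
        aliases[alias] = effect
    return aliases


EFFECT_ALIASES = _load_effect_aliases()


def map_effect(label: str) -> str:
    """Map an annotation label to the controlled effect vocabulary."""
    label = label.strip()
    if label in EFFECT_ALIASES:
        return EFFECT_ALIASES[label]
    if label in EFFECT_VOCABULARY:
        return label
    return "other"


def _data_lines(path: PathLike):
    """Yield (line_number, line) skipping comments and blank lines."""
    with open(path, "r", encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            stripped = line.rstrip("\n")
            if not stripped.strip() or stripped.startswith("#"):
                continue
            yield i, stripped


def _parse_optional_af(value: str, column: str, lineno: int) -> Optional[float]:
    value = value.strip()
    if value in ("", "NA", "nan", "."):
        return None
    try:
        return float(value)
    except ValueError:
        raise FormatError(f"line {lineno}: non-numeric {column} value {value!r}")


def read_variant_table(path: PathLike) -> CohortTable:
    """Read a per-subject annotated variant TSV into a :class:`CohortTable`.

    The header must contain exactly the documented columns.  Missing allele
    frequency fields (empty, ``NA`` or ``.``) are read as "absent from that
    reference".
    """
    lines = _data_lines(path)
    try:
        _, header_line = next(lines)
    except StopIteration:
        raise FormatError(f"{path}: empty file")
    header = header_line.split("\t")
    missing = [c for c in VARIANT_COLUMNS if c not in header]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    unknown = [c for c in header if c not in VARIANT_COLUMNS]
    if unknown:
        raise FormatError(f"{path}: unknown column(s) {unknown}")
    idx = {c: header.index(c) for c in VARIANT_COLUMNS}

    records = []
    for lineno, line in lines:
        fields = line.split("\t")
        if len(fields) != len(header):
            raise FormatError(
                f"{path}: line {lineno}: expected {len(header)} fields, got {len(fields)}"
            )
        row = {c: fields[idx[c]] for c in VARIANT_COLUMNS}
        try:
            dp = int(row["DP"])
            gq = int(row["GQ"])
            alt_fraction = float(row["alt_fraction"])
        except ValueError as exc:
            raise FormatError(f"{path}: line {lineno}: {exc}")
        records.append(
            VariantRecord(
                subject_id=row["subject_id"],
                chrom=row["chrom"],
                pos=int(row["pos"]),
                ref=row["ref"],
                alt=row["alt"],
                gene=row["gene"],
                transcript=row["transcript"],
                effect=map_effect(row["effect"]),
                zygosity=row["zygosity"],
                dp=dp,
                gq=gq,
                alt_fraction=alt_fraction,
                af_1000g=_parse_optional_af(row["af_1000g"], "af_1000g", lineno),
                af_exac=_parse_optional_af(row["af_exac"], "af_exac", lineno),
                af_gnomad=_parse_optional_af(row["af_gnomad"], "af_gnomad", lineno),
                cohort_allele_count=int(row["cohort_allele_count"]),
            )
        )
    return CohortTable.from_records(records)


def write_variant_table(cohort: CohortTable, path: PathLike) -> None:
    """Write a :class:`CohortTable` back to the canonical TSV layout."""

    def fmt_af(v: Optional[float]) -> str:
        return "" if v is None else repr(v)

    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("\t".join(VARIANT_COLUMNS) + "\n")
        for r in cohort.records:
            fh.write(
                "\t".join(
                    [
                        r.subject_id,
                        r.chrom,
                        str(r.pos),
                        r.ref,
                        r.alt,
                        r.gene,
                        r.transcript,
                        r.effect,
                        r.zygosity,
                        str(r.dp),
                        str(r.gq),
                        repr(r.alt_fraction),
                        fmt_af(r.af_1000g),
                        fmt_af(r.af_exac),
                        fmt_af(r.af_gnomad),
                        str(r.cohort_allele_count),
                    ]
                )
                + "\n"
            )


def read_gmt(path: PathLike, source: str = "") -> GeneSetCollection:
    """Read gene-sets in the standard GMT dialect.

    Each line is ``name<TAB>description<TAB>gene1<TAB>gene2...``; duplicate
    genes within a line are stored once.
    """
    sets = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}: line {lineno}: GMT line with <3 fields")
        name, description = fields[0], fields[1]
        genes = frozenset(g for g in fields[2:] if g)
        sets.append(GeneSet(name=name, description=description, genes=genes))
    return GeneSetCollection(sets=tuple(sets), source=source)


def write_gmt(collection: GeneSetCollection, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for s in collection.sets:
            fh.write("\t".join([s.name, s.description, *sorted(s.genes)]) + "\n")


def _read_gene_keyed_table(
    path: PathLike,
    columns: list[str],
    parsers: list,
) -> dict[str, tuple]:
    lines = _data_lines(path)
    try:
        _, header_line = next(lines)
    except StopIteration:
        raise FormatError(f"{path}: empty file")
    header = header_line.split("\t")
    expected = ["gene", *columns]
    if header != expected:
        raise FormatError(f"{path}: header {header} != expected {expected}")
    out: dict[str, tuple] = {}
    for lineno, line in lines:
        fields = line.split("\t")
        if len(fields) != len(expected):
            raise FormatError(f"{path}: line {lineno}: wrong field count")
        gene = fields[0]
        if gene in out:
            raise FormatError(f"{path}: line {lineno}: duplicate gene {gene!r}")
        out[gene] = tuple(parse(v) for parse, v in zip(parsers, fields[1:]))
    return out


def _parse_optional_float(value: str) -> Optional[float]:
    return None if value.strip() in ("", "NA", ".") else float(value)


def read_probability_table(path: PathLike) -> dict[str, tuple]:
    """Per-gene de novo mutation probabilities; columns gene, p_lof, p_mis.

    Probabilities must lie in (0, 1); an empty/NA field means the gene has
    no defined probability for that class.
    """
    table = _read_gene_keyed_table(
        path, ["p_lof", "p_mis"], [_parse_optional_float, _parse_optional_float]
    )
    for gene, (p_lof, p_mis) in table.items():
        for label, p in (("p_lof", p_lof), ("p_mis", p_mis)):
            if p is not None and not 0.0 < p < 1.0:
                raise ValueError(f"gene {gene}: {label} = {p} outside (0, 1)")
    return table


def read_constraint_table(path: PathLike) -> dict[str, tuple]:
    """Per-gene observed/expected constraint ratios; columns gene, oe_lof, oe_mis."""
    table = _read_gene_keyed_table(
        path, ["oe_lof", "oe_mis"], [_parse_optional_float, _parse_optional_float]
    )
    for gene, (oe_lof, oe_mis) in table.items():
        for label, oe in (("oe_lof", oe_lof), ("oe_mis", oe_mis)):
            if oe is not None and oe < 0:
                raise ValueError(f"gene {gene}: {label} = {oe} is negative")
    return table


def read_singleton_table(path: PathLike) -> dict[str, tuple]:
    """Per-gene reference singleton counts; columns gene, n_singleton_lof, n_singleton_mis."""
    table = _read_gene_keyed_table(path, ["n_singleton_lof", "n_singleton_mis"], [int, int])
    for gene, (n_lof, n_mis) in table.items():
        if n_lof < 0 or n_mis < 0:
            raise ValueError(f"gene {gene}: negative singleton count")
    return table


def read_principal_map(path: PathLike) -> dict[str, str]:
    """Principal-transcript map; columns gene, principal_transcript."""
    table = _read_gene_keyed_table(path, ["principal_transcript"], [str])
    return {gene: tx for gene, (tx,) in table.items()}


def write_tsv(rows: Iterable[Mapping], path: PathLike, columns: list[str]) -> None:
    """Write an iterable of mappings as a TSV with the given column order."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=columns, delimiter="\t")
        writer.writeheader()
        for row in rows:
            writer.writerow({c: row.get(c, "") for c in columns})


def write_matrix(matrix, path: PathLike) -> None:
    """Write a gene-by-subject count matrix as a long TSV."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# variant_class={matrix.variant_class}\n")
        fh.write(f"# subjects={','.join(matrix.subject_ids)}\n")
        fh.write("gene\tsubject_id\tcount\n")
        for gene in sorted(matrix.counts):
            for subject in sorted(matrix.counts[gene]):
                fh.write(f"{gene}\t{subject}\t{matrix.counts[gene][subject]}\n")


def read_matrix(path: PathLike):
    """Read a long-format gene-by-subject count matrix TSV."""
    from .containers import GeneSubjectMatrix

    variant_class = None
    subjects: tuple[str, ...] = ()
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    for line in lines:
        if line.startswith("# variant_class="):
            variant_class = line.split("=", 1)[1]
        elif line.startswith("# subjects="):
            subjects = tuple(line.split("=", 1)[1].split(","))
    if variant_class is None:
        raise FormatError(f"{path}: missing '# variant_class=' header")
    matrix = GeneSubjectMatrix(variant_class=variant_class, subject_ids=subjects)
    body = [l for l in lines if l and not l.startswith("#")]
    if not body or body[0].split("\t") != ["gene", "subject_id", "count"]:
        raise FormatError(f"{path}: bad matrix header")
    for line in body[1:]:
        gene, subject, count = line.split("\t")
        matrix.add(gene, subject, int(count))
    return matrix


def write_model(model, path: PathLike) -> None:
    """Write a rescaled model (SF plus per-gene success probabilities)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# variant_class={model.variant_class}\n")
        fh.write(f"# sf={model.sf!r}\n")
        fh.write(f"# n_obs={model.n_obs}\n")
        fh.write(f"# n_subjects={model.n_subjects}\n")
        fh.write("gene\tp_success\n")
        for gene in model.universe:
            fh.write(f"{gene}\t{model.p_success[gene]!r}\n")


def read_model(path: PathLike):
    """Read a rescaled model TSV written by :func:`write_model`."""
    from .mutation_model import RescaledModel

    meta: dict[str, str] = {}
    p_success: dict[str, float] = {}
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    body = []
    for line in lines:
        if line.startswith("# ") and "=" in line:
            key, value = line[2:].split("=", 1)
            meta[key] = value
        elif line and not line.startswith("#"):
            body.append(line)
    if body[0].split("\t") != ["gene", "p_success"]:
        raise FormatError(f"{path}: bad model header")
    for line in body[1:]:
        gene, p = line.split("\t")
        p_success[gene] = float(p)
    return RescaledModel(
        variant_class=meta["variant_class"],
        sf=float(meta["sf"]),
        n_obs=int(meta["n_obs"]),
        n_subjects=int(meta["n_subjects"]),
        p_success=p_success,
    )


def ingest_vcf(
    path: PathLike,
    annotation: Mapping[tuple[str, int, str, str], tuple[str, str, str]],
) -> CohortTable:
    """Ingest a multi-sample VCF into a :class:`CohortTable`.

    ``annotation`` maps ``(chrom, pos, ref, alt)`` to
    ``(gene, transcript, effect_label)`` since consequence calling is out of
    scope here.  One record is emitted per non-reference genotype per sample;
    ``alt_fraction`` is the alternate-read fraction from AD.  Sites whose
    FORMAT lacks GT/DP/GQ/AD are dropped with a warning.
    """
    import cyvcf2  # deferred: only needed for VCF input

    vcf = cyvcf2.VCF(str(path))
    samples = list(vcf.samples)
    records = []
    n_dropped = 0
    for site in vcf:
        for alt_index, alt in enumerate(site.ALT):
            key = (site.CHROM, site.POS, site.REF, alt)
            if key not in annotation:
                continue
            gene, transcript, effect_label = annotation[key]
            try:
                depths = site.format("AD")
                gqs = site.format("GQ")
                dps = site.format("DP")
            except KeyError:
                logger.warning("site %s:%s lacks FORMAT fields; dropped", site.CHROM, site.POS)
                n_dropped += 1
                continue
            if depths is None or gqs is None or dps is None:
                logger.warning("site %s:%s lacks FORMAT fields; dropped", site.CHROM, site.POS)
                n_dropped += 1
                continue
            gts = site.genotypes  # [allele1, allele2, phased]
            allele_counts = 0
            carriers = []
            for s_i, sample in enumerate(samples):
                alleles = [a for a in gts[s_i][:-1] if a >= 0]
                n_alt = sum(1 for a in alleles if a == alt_index + 1)
                allele_counts += n_alt
                if n_alt == 0:
                    continue
                zygosity = "hom" if n_alt == len(alleles) and len(alleles) > 1 else "het"
                ad = depths[s_i]
                total_ad = int(sum(max(int(x), 0) for x in ad))
                alt_ad = int(max(int(ad[alt_index + 1]), 0)) if len(ad) > alt_index + 1 else 0
                alt_fraction = alt_ad / total_ad if total_ad > 0 else 0.0
                dp = int(np.ravel(dps[s_i])[0])
                gq = int(np.ravel(gqs[s_i])[0])
                carriers.append((sample, zygosity, dp, gq, alt_fraction))
            for sample, zygosity, dp, gq, alt_fraction in carriers:
                records.append(
                    VariantRecord(
                        subject_id=sample,
                        chrom=site.CHROM,
                        pos=site.POS,
                        ref=site.REF,
                        alt=alt,
                        gene=gene,
                        transcript=transcript,
                        effect=map_effect(effect_label),
                        zygosity=zygosity,
                        dp=dp,
                        gq=gq,
                        alt_fraction=alt_fraction,
                        cohort_allele_count=max(allele_counts, 1),
                    )
                )
    if n_dropped:
        logger.warning("dropped %d site(s) lacking FORMAT fields", n_dropped)
    return CohortTable.from_records(records, subject_ids=samples)
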