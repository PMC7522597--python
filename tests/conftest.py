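import pytest

from uraburden.containers import CohortTable, VariantRecord


def make_record(**overrides) -> VariantRecord:
    """A clean ultra-rare het call that passes every filter; override freely."""
    base = dict(
        subject_id="S01",
        chrom="chr1",
        pos=100,
        ref="A",
        alt="C",
        gene="FLT4",
        transcript="TX_FLT4",
        effect="stopgain",
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


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture
def small_cohort():
    """Three records, two subjects, two genes."""
    records = [
        make_record(subject_id="S01", gene="FLT4", pos=100),
        make_record(subject_id="S01", gene="KDR", pos=200, effect="missense"),
        make_record(subject_id="S02", gene="FLT4", pos=300),
    ]
    return CohortTable.from_records(records, subject_ids=("S01", "S02"))
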