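"""Shared fixtures: small hand-built cohorts and catalogs."""

from __future__ import annotations

import pytest

from dpmload import (
    Cohort,
    PopulationCatalog,
    SampleMeta,
    SampleVariantSet,
    VariantRecord,
)


def make_variant(
    pos=100,
    effect="missense",
    gene="TP53",
    polyphen2=None,
    sift=None,
    alt_reads=10,
    total_reads=40,
    chrom="1",
    ref="A",
    alt="G",
):
    return VariantRecord(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        gene=gene,
        effect=effect,
        polyphen2=polyphen2,
        sift=sift,
        alt_reads=alt_reads,
        total_reads=total_reads,
    )


@pytest.fixture
def nt_meta():
    return SampleMeta(sample_id="S1", patient_id="P1", tissue="non_tumour")


@pytest.fixture
def five_variant_sample(nt_meta):
    variants = [
        make_variant(pos=100, effect="missense", polyphen2=0.9, gene="TP53"),
        make_variant(pos=200, effect="missense", polyphen2=0.1, gene="CTNNB1"),
        make_variant(pos=300, effect="synonymous", gene="ALB"),
        make_variant(pos=400, effect="stop_gain", gene="AXIN1"),
        make_variant(pos=500, effect="nonframeshift_indel", gene="ARID1A", ref="A", alt="ACCC"),
    ]
    return SampleVariantSet(meta=nt_meta, variants=variants)


@pytest.fixture
def small_catalog():
    return PopulationCatalog(
        sites={("1", 100, "A", "G"), ("1", 200, "A", "G"), ("2", 999, "C", "T")},
        release_tag="test",
    )


@pytest.fixture
def paired_cohort():
    """Two patients, paired NT/T, simple class structure."""
    samples = []
    pairs = {}
    for i, patient in enumerate(("P1", "P2"), start=1):
        for tissue, tag in (("non_tumour", "NT"), ("tumour", "T")):
            sid = f"{patient}-{tag}"
            variants = [
                make_variant(pos=1000 * i + j, effect="missense", polyphen2=0.9, gene=f"GENE{j}")
                for j in range(3)
            ] + [
                make_variant(pos=1000 * i + 10 + j, effect="synonymous", gene=f"GENE{10 + j}")
                for j in range(2)
            ]
            samples.append(
                SampleVariantSet(
                    meta=SampleMeta(sample_id=sid, patient_id=patient, tissue=tissue),
                    variants=variants,
                )
            )
        pairs[patient] = (f"{patient}-NT", f"{patient}-T")
    return Cohort(dataset_id="toy", samples=samples, pairs=pairs)
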