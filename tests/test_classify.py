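"""Variant classification rules and per-sample normalization."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dpmload import (
    GeneList,
    SampleMeta,
    SampleVariantSet,
    classify_sample,
    classify_variant,
    restrict_to_genes,
    summarize_sample,
)
from dpmload.classify import MODES, POLYPHEN2_DAMAGING_MIN, SIFT_DAMAGING_MAX
from tests.conftest import make_variant


def oracle_classify(effect, pp2, sift, mode):
    """Independent brute-force rule table over effect x score-band x mode."""
    if effect in ("stop_gain", "stop_loss", "frameshift_indel"):
        return "dpm"
    if effect == "nonframeshift_indel":
        return "excluded_nonframeshift"
    if effect == "synonymous":
        return "synonymous"
    pp2_band = None if pp2 is None else ("damaging" if pp2 >= 0.453 else "benign")
    sift_band = None if sift is None else ("damaging" if sift <= 0.05 else "benign")
    if mode == "polyphen2":
        band = pp2_band
    elif mode == "sift":
        band = sift_band
    else:
        if pp2_band is None and sift_band is None:
            band = None
        elif "damaging" in (pp2_band, sift_band):
            band = "damaging"
        else:
            band = "benign"
    if band is None:
        return "unscored_missense"
    return "dpm" if band == "damaging" else "benign_missense"


@pytest.mark.parametrize(
    "effect,pp2,sift,mode,expected",
    [
        ("missense", 0.46, None, "polyphen2", "dpm"),
        ("stop_gain", None, None, "polyphen2", "dpm"),
        ("missense", 0.453, None, "polyphen2", "dpm"),  # boundary inclusive
        ("missense", 0.4529, None, "polyphen2", "benign_missense"),
        ("missense", None, 0.05, "sift", "dpm"),  # boundary inclusive
        ("missense", None, 0.0501, "sift", "benign_missense"),
        ("nonframeshift_indel", None, None, "polyphen2", "excluded_nonframeshift"),
        ("missense", None, None, "polyphen2", "unscored_missense"),
        ("missense", 0.1, 0.01, "either", "dpm"),
        ("missense", 0.1, 0.9, "either", "benign_missense"),
        ("frameshift_indel", None, None, "sift", "dpm"),
        ("synonymous", None, None, "either", "synonymous"),
    ],
)
def test_classification_rule_table(effect, pp2, sift, mode, expected):
    ref, alt = ("A", "AT") if "indel" in effect else ("A", "G")
    v = make_variant(effect=effect, polyphen2=pp2, sift=sift, ref=ref, alt=alt)
    assert classify_variant(v, mode) == expected
    assert oracle_classify(effect, pp2, sift, mode) == expected


def test_randomized_agreement_with_oracle():
    """100% agreement with the rule-table oracle on randomized variants,
    including the exact score boundaries."""
    rng = np.random.default_rng(7)
    effects = ["missense", "synonymous", "stop_gain", "stop_loss", "frameshift_indel", "nonframeshift_indel"]
    boundary = [None, 0.0, 0.05, 0.0501, 0.4529, 0.453, 1.0]
    n = 0
    for _ in range(1200):
        effect = effects[rng.integers(len(effects))]
        pp2 = boundary[rng.integers(len(boundary))] if rng.random() < 0.5 else float(rng.random())
        sift = boundary[rng.integers(len(boundary))] if rng.random() < 0.5 else float(rng.random())
        ref, alt = ("A", "AT") if "indel" in effect else ("A", "G")
        v = make_variant(effect=effect, polyphen2=pp2, sift=sift, ref=ref, alt=alt)
        for mode in MODES:
            assert classify_variant(v, mode) == oracle_classify(effect, pp2, sift, mode)
            n += 1
    assert n >= 3000


def test_either_mode_dpm_superset(nt_meta):
    variants = [
        make_variant(pos=i + 1, effect="missense", polyphen2=float(p), sift=float(s))
        for i, (p, s) in enumerate([(0.9, 0.5), (0.1, 0.01), (0.2, 0.9), (0.5, 0.04)])
    ]
    sample = SampleVariantSet(meta=nt_meta, variants=variants)
    dpm_pp2 = {cv.variant.pos for cv in classify_sample(sample, "polyphen2") if cv.klass == "dpm"}
    dpm_either = {cv.variant.pos for cv in classify_sample(sample, "either") if cv.klass == "dpm"}
    assert dpm_pp2 <= dpm_either


def test_classify_sample_order_preserving(five_variant_sample):
    classified = classify_sample(five_variant_sample)
    assert [cv.variant.pos for cv in classified] == [100, 200, 300, 400, 500]
    assert [cv.klass for cv in classified] == [
        "dpm",
        "benign_missense",
        "synonymous",
        "dpm",
        "excluded_nonframeshift",
    ]


def test_unscored_policies(nt_meta):
    sample = SampleVariantSet(
        meta=nt_meta,
        variants=[make_variant(pos=1, effect="missense"), make_variant(pos=2, effect="synonymous")],
    )
    assert classify_sample(sample, unscored_as="own-class")[0].klass == "unscored_missense"
    assert classify_sample(sample, unscored_as="benign")[0].klass == "benign_missense"
    dropped = classify_sample(sample, unscored_as="drop")
    assert len(dropped) == 1 and dropped[0].klass == "synonymous"


def test_summary_percentages(five_variant_sample, nt_meta):
    summary = summarize_sample(classify_sample(five_variant_sample), nt_meta)
    assert summary.n_total_exonic == 5
    assert summary.n_dpm == 2 and summary.pct_dpm == 40.0
    assert summary.pct_benign == 20.0
    total = (
        summary.n_dpm
        + summary.n_benign
        + summary.n_synonymous
        + summary.n_excluded_nonframeshift
        + summary.n_unscored
    )
    assert total == summary.n_total_exonic


def test_summary_all_synonymous(nt_meta):
    sample = SampleVariantSet(
        meta=nt_meta, variants=[make_variant(pos=i + 1, effect="synonymous") for i in range(4)]
    )
    summary = summarize_sample(classify_sample(sample), nt_meta)
    assert summary.pct_dpm == 0.0 and summary.pct_benign == 0.0


def test_denominator_classified_only(five_variant_sample, nt_meta):
    summary = summarize_sample(
        classify_sample(five_variant_sample), nt_meta, denominator="classified-only"
    )
    # the non-frameshift indel leaves the denominator
    assert summary.n_total_exonic == 4
    assert summary.pct_dpm == 50.0


def test_summarize_empty_is_error(nt_meta):
    with pytest.raises(ValueError):
        summarize_sample([], nt_meta)


@settings(max_examples=60, derandomize=True)
@given(
    st.lists(
        st.tuples(
            st.sampled_from(
                ["missense", "synonymous", "stop_gain", "frameshift_indel", "nonframeshift_indel"]
            ),
            st.one_of(st.none(), st.floats(0, 1, allow_nan=False)),
        ),
        min_size=1,
        max_size=40,
    )
)
def test_percentages_sum_to_100(spec):
    meta = SampleMeta(sample_id="H", patient_id="H", tissue="tumour")
    variants = [
        make_variant(
            pos=i + 1,
            effect=eff,
            polyphen2=pp2,
            ref="A",
            alt="AT" if "indel" in eff else "G",
        )
        for i, (eff, pp2) in enumerate(spec)
    ]
    sample = SampleVariantSet(meta=meta, variants=variants)
    s = summarize_sample(classify_sample(sample), meta)
    assert (
        abs(
            s.pct_dpm + s.pct_benign + s.pct_synonymous + s.pct_excluded_nonframeshift + s.pct_unscored
            - 100.0
        )
        < 1e-9
    )
    # counts agree with an independent tally
    tally = {}
    for cv in classify_sample(sample):
        tally[cv.klass] = tally.get(cv.klass, 0) + 1
    assert s.n_dpm == tally.get("dpm", 0)
    assert s.n_total_exonic == len(variants)


def test_restrict_to_genes(five_variant_sample):
    restricted = restrict_to_genes(five_variant_sample, GeneList(name="x", genes={"TP53", "ALB"}))
    assert {v.gene for v in restricted} == {"TP53", "ALB"}
    everything = restrict_to_genes(
        five_variant_sample, GeneList(name="all", genes={v.gene for v in five_variant_sample})
    )
    assert len(everything) == len(five_variant_sample)


def test_restriction_commutes_with_classification(five_variant_sample):
    genes = GeneList(name="x", genes={"TP53", "AXIN1", "ARID1A"})
    first = [
        (cv.variant.key, cv.klass)
        for cv in classify_sample(restrict_to_genes(five_variant_sample, genes))
    ]
    second = [
        (cv.variant.key, cv.klass)
        for cv in classify_sample(five_variant_sample)
        if cv.variant.gene in genes
    ]
    assert first == second
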