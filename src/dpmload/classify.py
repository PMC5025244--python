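"""Classification of somatic exonic variants into DPM / benign classes.

A deleterious passenger mutation (DPM) is a non-driver somatic mutation
predicted to damage protein function: a missense SNV judged damaging by
PolyPhen-2 (score >= 0.453) or by SIFT (score <= 0.05), a stop-gain or
stop-loss mutation, or a frameshift indel.  Benign missense SNVs are
those whose score falls outside the damaging criterion.  Non-frameshift
indels are classed neither as DPMs nor benign and excluded from the two
headline classes.  Missense variants lacking the required score form an
explicit ``unscored_missense`` class rather than silently counting as
benign (configurable).

Per-sample class counts are normalized to the total somatic exonic
variants in the sample (percentages), the cross-sample comparable
statistic used throughout the downstream comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .germline import allelic_frequency
from .records import GeneList, SampleMeta, SampleVariantSet, VariantRecord

#: Boundary-inclusive damaging thresholds, exactly as printed by the scorers.
POLYPHEN2_DAMAGING_MIN = 0.453
SIFT_DAMAGING_MAX = 0.05

MODES = ("polyphen2", "sift", "either")
KLASSES = ("dpm", "benign_missense", "synonymous", "excluded_nonframeshift", "unscored_missense")
UNSCORED_POLICIES = ("own-class", "benign", "drop")
DENOMINATORS = ("all-retained", "classified-only")


@dataclass(frozen=True)
class ClassifiedVariant:
    variant: VariantRecord
    klass: str
    af: float


@dataclass(frozen=True)
class SampleSummary:
    """Per-sample class counts and normalized percentages."""

    sample_id: str
    patient_id: str
    tissue: str
    n_total_exonic: int
    n_dpm: int
    n_benign: int
    n_synonymous: int
    n_excluded_nonframeshift: int
    n_unscored: int
    pct_dpm: float
    pct_benign: float
    pct_synonymous: float
    pct_excluded_nonframeshift: float
    pct_unscored: float


def _missense_damaging(variant: VariantRecord, mode: str) -> str:
    """Classify a missense SNV under the given scorer mode."""
    pp2, sift = variant.polyphen2, variant.sift
    if mode == "polyphen2":
        if pp2 is None:
            return "unscored_missense"
        return "dpm" if pp2 >= POLYPHEN2_DAMAGING_MIN else "benign_missense"
    if mode == "sift":
        if sift is None:
            return "unscored_missense"
        return "dpm" if sift <= SIFT_DAMAGING_MAX else "benign_missense"
    # mode == "either": damaging if at least one available score says so
    if pp2 is None and sift is None:
        return "unscored_missense"
    if (pp2 is not None and pp2 >= POLYPHEN2_DAMAGING_MIN) or (
        sift is not None and sift <= SIFT_DAMAGING_MAX
    ):
        return "dpm"
    return "benign_missense"


def classify_variant(variant: VariantRecord, mode: str = "polyphen2") -> str:
    """Assign a variant to one of the five mutation classes.

    Stop-gain/-loss and frameshift indels are DPMs regardless of scores;
    non-frameshift indels are excluded from the DPM/benign classes;
    synonymous SNVs are their own class; missense SNVs are judged by the
    selected scorer(s) with boundary-inclusive thresholds.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    effect = variant.effect
    if effect in ("stop_gain", "stop_loss", "frameshift_indel"):
        return "dpm"
    if effect == "nonframeshift_indel":
        return "excluded_nonframeshift"
    if effect == "synonymous":
        return "synonymous"
    return _missense_damaging(variant, mode)


def classify_sample(
    sample: SampleVariantSet,
    mode: str = "polyphen2",
    unscored_as: str = "own-class",
) -> list[ClassifiedVariant]:
    """Classify every variant of a (germline-filtered) sample, in order.

    ``unscored_as`` controls score-less missense SNVs: keep them as
    their own class, fold them into benign, or drop them entirely.
    """
    if unscored_as not in UNSCORED_POLICIES:
        raise ValueError(f"unscored_as must be one of {UNSCORED_POLICIES}")
    out = []
    for variant in sample:
        klass = classify_variant(variant, mode)
        if klass == "unscored_missense":
            if unscored_as == "drop":
                continue
            if unscored_as == "benign":
                klass = "benign_missense"
        out.append(ClassifiedVariant(variant=variant, klass=klass, af=allelic_frequency(variant)))
    return out


def summarize_sample(
    classified: Iterable[ClassifiedVariant],
    meta: SampleMeta,
    denominator: str = "all-retained",
) -> SampleSummary:
    """Count classes and normalize to the sample's total exonic variants.

    ``all-retained`` (default) normalizes to everything retained after
    germline filtering — including synonymous variants, non-frameshift
    indels and unscored missense; ``classified-only`` restricts the
    denominator to the DPM + benign + synonymous classes.
    """
    if denominator not in DENOMINATORS:
        raise ValueError(f"denominator must be one of {DENOMINATORS}")
    classified = list(classified)
    if not classified:
        raise ValueError(f"cannot summarize empty classification for {meta.sample_id!r}")
    counts = {k: 0 for k in KLASSES}
    for cv in classified:
        counts[cv.klass] += 1
    if denominator == "all-retained":
        total = len(classified)
    else:
        total = counts["dpm"] + counts["benign_missense"] + counts["synonymous"]
        if total == 0:
            raise ValueError("classified-only denominator is zero")
    pct = lambda k: 100.0 * counts[k] / total  # noqa: E731
    return SampleSummary(
        sample_id=meta.sample_id,
        patient_id=meta.patient_id,
        tissue=meta.tissue,
        n_total_exonic=total,
        n_dpm=counts["dpm"],
        n_benign=counts["benign_missense"],
        n_synonymous=counts["synonymous"],
        n_excluded_nonframeshift=counts["excluded_nonframeshift"],
        n_unscored=counts["unscored_missense"],
        pct_dpm=pct("dpm"),
        pct_benign=pct("benign_missense"),
        pct_synonymous=pct("synonymous"),
        pct_excluded_nonframeshift=pct("excluded_nonframeshift"),
        pct_unscored=pct("unscored_missense"),
    )


def restrict_to_genes(sample: SampleVariantSet, genes: GeneList) -> SampleVariantSet:
    """Keep only variants in the listed genes (e.g. liver-expressed).

    Variants with an empty gene symbol never match.  Downstream
    summaries are recomputed on the restricted set, so the restricted
    denominator is the restricted total.
    """
    if len(genes) == 0:
        raise ValueError("gene restriction list is empty")
    return sample.replace_variants(v for v in sample if v.gene and v.gene in genes)


def classified_to_frame(
    classified: Iterable[ClassifiedVariant], meta: SampleMeta
) -> pd.DataFrame:
    rows = [
        {
            "sample_id": meta.sample_id,
            "tissue": meta.tissue,
            "chrom": cv.variant.chrom,
            "pos": cv.variant.pos,
            "ref": cv.variant.ref,
            "alt": cv.variant.alt,
            "gene": cv.variant.gene,
            "effect": cv.variant.effect,
            "klass": cv.klass,
            "af": cv.af,
        }
        for cv in classified
    ]
    return pd.DataFrame(
        rows,
        columns=["sample_id", "tissue", "chrom", "pos", "ref", "alt", "gene", "effect", "klass", "af"],
    )


def summaries_to_frame(summaries: Iterable[SampleSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries])


def summarize_cohort(
    cohort,
    mode: str = "polyphen2",
    unscored_as: str = "own-class",
    denominator: str = "all-retained",
    genes: Optional[GeneList] = None,
) -> tuple[dict[str, list[ClassifiedVariant]], list[SampleSummary]]:
    """Classify and summarize every sample of a cohort.

    Returns (per-sample classifications keyed by sample_id, summaries).
    Samples left empty by gene restriction are skipped.
    """
    classifications: dict[str, list[ClassifiedVariant]] = {}
    summaries: list[SampleSummary] = []
    for sample in cohort:
        if genes is not None:
            sample = restrict_to_genes(sample, genes)
        classified = classify_sample(sample, mode=mode, unscored_as=unscored_as)
        if not classified:
            continue
        classifications[sample.meta.sample_id] = classified
        summaries.append(summarize_sample(classified, sample.meta, denominator=denominator))
    return classifications, summaries
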