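"""Putative-germline exclusion and allelic-frequency quantities.

Somatic calls from a tumour/non-tumour exome without a matched germline
control retain inherited variants.  Following common practice, putative
germline variants are excluded by membership in a population site
catalog (e.g. a 1000 Genomes release); matching is allele-exact by
default, with position-only matching as an option.  The fraction of
retained variants at allelic frequency exactly 1.0 is the standard
diagnostic that homozygous germline variants have been removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .records import PopulationCatalog, SampleVariantSet, VariantRecord

log = logging.getLogger(__name__)

MATCH_MODES = ("allele_exact", "position_only")


@dataclass(frozen=True)
class FilterReport:
    """Bookkeeping for one sample's germline filtering pass."""

    sample_id: str
    n_input: int
    n_removed: int
    n_retained: int
    af_one_fraction: float

    def __post_init__(self) -> None:
        assert self.n_input == self.n_removed + self.n_retained


def allelic_frequency(variant: VariantRecord) -> float:
    """Fraction of reads at the site carrying the alternate allele."""
    if variant.total_reads < 1:
        raise ValueError("total_reads must be >= 1")
    return variant.alt_reads / variant.total_reads


def af_one_fraction(sample: SampleVariantSet) -> float:
    """Fraction of variants with every read carrying the variant.

    Uses exact integer equality alt_reads == total_reads, not a
    tolerance: the statement concerns reads all carrying the variant.
    """
    if len(sample) == 0:
        raise ValueError(f"sample {sample.meta.sample_id!r} is empty")
    n_one = sum(1 for v in sample if v.alt_reads == v.total_reads)
    return n_one / len(sample)


def filter_germline(
    sample: SampleVariantSet,
    catalog: PopulationCatalog,
    match_mode: str = "allele_exact",
) -> tuple[SampleVariantSet, FilterReport]:
    """Remove variants present in the population catalog.

    ``allele_exact`` requires the same (chrom, pos, ref, alt) key;
    ``position_only`` removes any variant at a catalogued (chrom, pos).
    The input sample is not modified.
    """
    if match_mode not in MATCH_MODES:
        raise ValueError(f"match_mode must be one of {MATCH_MODES}, got {match_mode!r}")
    if len(catalog) == 0:
        log.warning("germline filter running against an empty catalog")

    if match_mode == "allele_exact":
        hit = lambda v: v.key in catalog.sites  # noqa: E731
    else:
        positions = catalog.positions
        hit = lambda v: (v.chrom, v.pos) in positions  # noqa: E731

    retained = [v for v in sample if not hit(v)]
    filtered = sample.replace_variants(retained)
    report = FilterReport(
        sample_id=sample.meta.sample_id,
        n_input=len(sample),
        n_removed=len(sample) - len(retained),
        n_retained=len(retained),
        af_one_fraction=af_one_fraction(filtered) if retained else 0.0,
    )
    return filtered, report


def af_distribution(
    sample: SampleVariantSet,
    selector: Optional[Callable[[VariantRecord], bool]] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Empirical cumulative distribution of allelic frequencies.

    Returns ``(af, cumulative_fraction)`` over the selected variants:
    sorted unique allelic frequencies with the fraction of variants at
    or below each, monotone non-decreasing and ending at 1.0.  Raises on
    an empty selection.
    """
    values = sorted(
        allelic_frequency(v) for v in sample if selector is None or selector(v)
    )
    if not values:
        raise ValueError("allelic-frequency distribution of an empty selection")
    af = np.unique(values)
    counts = np.searchsorted(values, af, side="right")
    return af, counts / len(values)
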