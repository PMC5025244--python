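"""Core domain types for somatic-variant cohorts.

The pipeline's unit of data is one called somatic variant
(:class:`VariantRecord`), grouped per sample
(:class:`SampleVariantSet`) and per dataset (:class:`Cohort`), with a
population site catalog (:class:`PopulationCatalog`) used for germline
exclusion and plain gene lists (:class:`GeneList`) for restriction and
driver analyses.

Coordinates are 1-based, fully closed, VCF-style.  Indels are taken as
given (assumed left-aligned upstream).  Gene symbols are matched
case-insensitively after uppercasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

#: Closed vocabulary of coding-effect classes.
EFFECTS = frozenset(
    {
        "synonymous",
        "missense",
        "stop_gain",
        "stop_loss",
        "frameshift_indel",
        "nonframeshift_indel",
    }
)

#: Closed vocabulary of tissue labels (NC / C / NT / T plus blood).
TISSUES = frozenset({"non_cirrhotic", "cirrhotic", "non_tumour", "tumour", "pbmc"})

VariantKey = tuple[str, int, str, str]


class ValidationError(ValueError):
    """A record violates a domain-type invariant."""


class FormatError(ValueError):
    """An input file does not conform to its declared dialect."""


def normalize_gene(symbol: str) -> str:
    """Case-normalize a gene symbol (uppercase, stripped)."""
    return symbol.strip().upper()


@dataclass(frozen=True)
class VariantRecord:
    """One somatic variant call.

    ``polyphen2``/``sift`` are the precomputed deleteriousness scores
    consumed as annotations (``None`` when the annotator produced no
    score, e.g. for indels).  ``alt_reads``/``total_reads`` are the
    per-sample read counts from which allelic frequency is derived.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    effect: str
    alt_reads: int
    total_reads: int
    polyphen2: Optional[float] = None
    sift: Optional[float] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValidationError("ref and alt must be non-empty")
        if self.ref == self.alt:
            raise ValidationError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        if self.effect not in EFFECTS:
            raise ValidationError(f"unknown effect {self.effect!r}")
        if self.total_reads < 1:
            raise ValidationError("total_reads must be >= 1")
        if not 0 <= self.alt_reads <= self.total_reads:
            raise ValidationError(
                f"alt_reads ({self.alt_reads}) must lie in [0, total_reads={self.total_reads}]"
            )
        for name, score in (("polyphen2", self.polyphen2), ("sift", self.sift)):
            if score is not None and not 0.0 <= score <= 1.0:
                raise ValidationError(f"{name} score {score} outside [0, 1]")
        object.__setattr__(self, "gene", normalize_gene(self.gene))

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample clinical metadata."""

    sample_id: str
    patient_id: str
    tissue: str
    age: Optional[float] = None
    sex: Optional[str] = None
    aetiology: Optional[str] = None

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise ValidationError(
                f"unknown tissue {self.tissue!r} for sample {self.sample_id!r}; "
                f"expected one of {sorted(TISSUES)}"
            )
        if self.sex is not None and self.sex not in {"M", "F"}:
            raise ValidationError(f"sex must be M or F, got {self.sex!r}")


@dataclass
class SampleVariantSet:
    """A sample's variants plus metadata.

    Variant keys (chrom, pos, ref, alt) must be unique within a sample.
    """

    meta: SampleMeta
    variants: list[VariantRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [v.key for v in self.variants]
        if len(keys) != len(set(keys)):
            seen: set[VariantKey] = set()
            for k in keys:
                if k in seen:
                    raise ValidationError(
                        f"duplicate variant {k} in sample {self.meta.sample_id!r}"
                    )
                seen.add(k)

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self):
        return iter(self.variants)

    def keys(self) -> set[VariantKey]:
        return {v.key for v in self.variants}

    def replace_variants(self, variants: Iterable[VariantRecord]) -> "SampleVariantSet":
        """New set with the same metadata and the given variants."""
        return SampleVariantSet(meta=self.meta, variants=list(variants))


@dataclass
class Cohort:
    """A dataset of samples with optional patient-level NT/T pairing.

    ``pairs`` maps patient_id -> (non_tumour sample_id, tumour
    sample_id) for paired designs.
    """

    dataset_id: str
    samples: list[SampleVariantSet] = field(default_factory=list)
    pairs: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.meta.sample_id for s in self.samples]
        if len(ids) != len(set(ids)):
            raise ValidationError(f"duplicate sample_id in cohort {self.dataset_id!r}")
        by_id = {s.meta.sample_id: s for s in self.samples}
        for patient, (nt_id, t_id) in self.pairs.items():
            for sid, tissue in ((nt_id, "non_tumour"), (t_id, "tumour")):
                if sid not in by_id:
                    raise ValidationError(
                        f"pair for patient {patient!r} references unknown sample {sid!r}"
                    )
                s = by_id[sid]
                if s.meta.tissue != tissue:
                    raise ValidationError(
                        f"sample {sid!r} in pair for {patient!r} has tissue "
                        f"{s.meta.tissue!r}, expected {tissue!r}"
                    )
                if s.meta.patient_id != patient:
                    raise ValidationError(
                        f"sample {sid!r} belongs to patient {s.meta.patient_id!r}, "
                        f"not {patient!r}"
                    )

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    def sample(self, sample_id: str) -> SampleVariantSet:
        for s in self.samples:
            if s.meta.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def by_tissue(self, tissue: str) -> list[SampleVariantSet]:
        return [s for s in self.samples if s.meta.tissue == tissue]


@dataclass
class PopulationCatalog:
    """Known germline sites/alleles used for exclusion.

    Emulates a population release such as the 1000 Genomes Project
    site catalog (``release_tag`` records which).
    """

    sites: set[VariantKey] = field(default_factory=set)
    release_tag: str = "synthetic"

    def __post_init__(self) -> None:
        for key in self.sites:
            if key[1] < 1:
                raise ValidationError(f"catalog position must be >= 1: {key}")

    def __len__(self) -> int:
        return len(self.sites)

    def __contains__(self, key: VariantKey) -> bool:
        return key in self.sites

    @property
    def positions(self) -> set[tuple[str, int]]:
        """(chrom, pos) projection, for position-only matching."""
        return {(c, p) for c, p, _, _ in self.sites}


@dataclass
class GeneList:
    """A named set of case-normalized gene symbols."""

    name: str
    genes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        normalized = {normalize_gene(g) for g in self.genes if g.strip()}
        if len(normalized) != len(self.genes):
            self.genes = normalized
        else:
            self.genes = normalized

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, symbol: str) -> bool:
        return normalize_gene(symbol) in self.genes
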