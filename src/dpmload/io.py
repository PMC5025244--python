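"""Readers and writers for variant tables, site catalogs and gene lists.

The canonical interchange format is a tab-separated variant table with
header columns::

    sample_id patient_id tissue chrom pos ref alt gene effect
    polyphen2 sift alt_reads total_reads

Missing scores are encoded as an empty field or ``NA``.  VCF ingestion
(via cyvcf2) maps annotation keys through a small configuration object
rather than hard-coding any annotator's key names, because ANNOVAR-style
INFO dialects vary in the wild.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from .records import (
    Cohort,
    FormatError,
    GeneList,
    PopulationCatalog,
    SampleMeta,
    SampleVariantSet,
    ValidationError,
    VariantKey,
    VariantRecord,
    EFFECTS,
)

log = logging.getLogger(__name__)

TSV_COLUMNS = [
    "sample_id",
    "patient_id",
    "tissue",
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "effect",
    "polyphen2",
    "sift",
    "alt_reads",
    "total_reads",
]


@dataclass
class VcfAnnotationConfig:
    """How to pull annotations out of a VCF's INFO field.

    ``effect_map`` translates the annotator's effect vocabulary into the
    pipeline's closed vocabulary; unmapped values are rejected.
    """

    gene_key: str = "GENE"
    effect_key: str = "EFFECT"
    polyphen2_key: str = "PP2"
    sift_key: str = "SIFT"
    effect_map: dict[str, str] = field(default_factory=dict)

    def map_effect(self, raw: str) -> Optional[str]:
        value = self.effect_map.get(raw, raw)
        return value if value in EFFECTS else None


def _parse_score(value) -> Optional[float]:
    if value is None:
        return None
    if isinstance(value, float):
        if math.isnan(value):
            return None
        # VCF floats arrive as float32; recover the printed precision
        return float(f"{value:.6g}")
    text = str(value).strip()
    if text in ("", "NA", "NaN", "nan", "."):
        return None
    return float(text)


def _infer_pairs(samples: list[SampleVariantSet]) -> dict[str, tuple[str, str]]:
    """Patients with exactly one NT and one T sample form a pair."""
    by_patient: dict[str, dict[str, list[str]]] = {}
    for s in samples:
        by_patient.setdefault(s.meta.patient_id, {}).setdefault(
            s.meta.tissue, []
        ).append(s.meta.sample_id)
    pairs = {}
    for patient, tissues in by_patient.items():
        nt = tissues.get("non_tumour", [])
        t = tissues.get("tumour", [])
        if len(nt) == 1 and len(t) == 1:
            pairs[patient] = (nt[0], t[0])
    return pairs


def read_variant_table(
    path: Union[str, Path],
    dialect: str = "tsv",
    dataset_id: Optional[str] = None,
    vcf_config: Optional[VcfAnnotationConfig] = None,
    sample_meta: Optional[dict[str, SampleMeta]] = None,
) -> Cohort:
    """Read a per-sample somatic variant table into a :class:`Cohort`.

    Parameters
    ----------
    path
        Input file.
    dialect
        ``"tsv"`` for the canonical tab-separated table, ``"vcf"`` for a
        multi-sample VCF with per-sample AD/DP fields.
    dataset_id
        Cohort label; defaults to the file stem.
    vcf_config
        Annotation-key mapping, required for the VCF dialect.
    sample_meta
        Optional sample_id -> :class:`SampleMeta` mapping for dialects
        (VCF) that carry no clinical metadata.  Unlisted VCF samples
        default to tissue ``"tumour"`` with patient_id = sample_id.

    Rows whose effect value is outside the closed vocabulary are
    rejected; their count is logged and stored on the returned cohort as
    ``n_rejected_effects``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    dataset_id = dataset_id or path.stem
    if dialect == "tsv":
        cohort, n_rejected = _read_tsv(path, dataset_id)
    elif dialect == "vcf":
        cohort, n_rejected = _read_vcf(
            path, dataset_id, vcf_config or VcfAnnotationConfig(), sample_meta or {}
        )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    cohort.n_rejected_effects = n_rejected  # type: ignore[attr-defined]
    if n_rejected:
        log.warning("%s: rejected %d rows with unknown effect values", path, n_rejected)
    return cohort


def _read_tsv(path: Path, dataset_id: str) -> tuple[Cohort, int]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in TSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")

    metas: dict[str, SampleMeta] = {}
    variants: dict[str, list[VariantRecord]] = {}
    n_rejected = 0
    for idx, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        effect = row.effect.strip()
        if effect not in EFFECTS:
            n_rejected += 1
            continue
        sid = row.sample_id
        if sid not in metas:
            metas[sid] = SampleMeta(
                sample_id=sid, patient_id=row.patient_id, tissue=row.tissue
            )
        try:
            rec = VariantRecord(
                chrom=row.chrom,
                pos=int(row.pos),
                ref=row.ref,
                alt=row.alt,
                gene=row.gene,
                effect=effect,
                polyphen2=_parse_score(row.polyphen2),
                sift=_parse_score(row.sift),
                alt_reads=int(row.alt_reads),
                total_reads=int(row.total_reads),
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path} line {idx}: {exc}") from exc
        variants.setdefault(sid, []).append(rec)

    samples = [
        SampleVariantSet(meta=metas[sid], variants=variants.get(sid, []))
        for sid in metas
    ]
    return Cohort(dataset_id=dataset_id, samples=samples, pairs=_infer_pairs(samples)), n_rejected


def _read_vcf(
    path: Path,
    dataset_id: str,
    config: VcfAnnotationConfig,
    sample_meta: dict[str, SampleMeta],
) -> tuple[Cohort, int]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    metas = {
        sid: sample_meta.get(
            sid, SampleMeta(sample_id=sid, patient_id=sid, tissue="tumour")
        )
        for sid in sample_ids
    }
    variants: dict[str, list[VariantRecord]] = {sid: [] for sid in sample_ids}
    n_rejected = 0
    for record in vcf:
        raw_effect = record.INFO.get(config.effect_key)
        effect = config.map_effect(str(raw_effect)) if raw_effect is not None else None
        if effect is None:
            n_rejected += 1
            continue
        gene = str(record.INFO.get(config.gene_key) or "")
        pp2 = _parse_score(record.INFO.get(config.polyphen2_key))
        sift = _parse_score(record.INFO.get(config.sift_key))
        ad = record.format("AD")
        dp = record.format("DP")
        for alt_index, alt in enumerate(record.ALT, start=1):
            for s_index, sid in enumerate(sample_ids):
                alt_reads = int(ad[s_index][alt_index]) if ad is not None else 0
                if alt_reads < 0:  # missing AD encoded as negative
                    continue
                total = int(dp[s_index][0]) if dp is not None else 0
                if total < 1:
                    continue
                variants[sid].append(
                    VariantRecord(
                        chrom=record.CHROM,
                        pos=record.POS,
                        ref=record.REF,
                        alt=alt,
                        gene=gene,
                        effect=effect,
                        polyphen2=pp2,
                        sift=sift,
                        alt_reads=alt_reads,
                        total_reads=total,
                    )
                )
    samples = [SampleVariantSet(meta=metas[sid], variants=variants[sid]) for sid in sample_ids]
    return Cohort(dataset_id=dataset_id, samples=samples, pairs=_infer_pairs(samples)), n_rejected


def read_site_catalog(
    path: Union[str, Path], dialect: str = "site_list", release_tag: Optional[str] = None
) -> PopulationCatalog:
    """Read a population germline site catalog.

    ``site_list`` is one whitespace-separated ``chrom pos ref alt`` per
    line; ``vcf`` expands multi-allelic records to one key per alternate
    allele.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sites: set[VariantKey] = set()
    if dialect == "site_list":
        with open(path) as handle:
            for lineno, line in enumerate(handle, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split()
                if len(fields) != 4:
                    raise FormatError(
                        f"{path} line {lineno}: expected 'chrom pos ref alt', got {line!r}"
                    )
                chrom, pos_s, ref, alt = fields
                try:
                    pos = int(pos_s)
                except ValueError as exc:
                    raise FormatError(f"{path} line {lineno}: malformed position {pos_s!r}") from exc
                if pos < 1:
                    raise FormatError(f"{path} line {lineno}: position must be >= 1")
                sites.add((chrom, pos, ref, alt))
    elif dialect == "vcf":
        from cyvcf2 import VCF

        for record in VCF(str(path)):
            for alt in record.ALT:
                sites.add((record.CHROM, record.POS, record.REF, alt))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if not sites:
        log.warning("%s: empty site catalog", path)
    return PopulationCatalog(sites=sites, release_tag=release_tag or path.stem)


def read_gene_list(path: Union[str, Path], name: Optional[str] = None) -> GeneList:
    """Read a one-symbol-per-line gene list (``#`` comments ignored).

    An empty result is an error: an empty restriction list is almost
    surely a mistake.  The count of duplicates dropped is logged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    symbols: list[str] = []
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if line and not line.startswith("#"):
                symbols.append(line)
    gene_list = GeneList(name=name or path.stem, genes=set(symbols))
    if not gene_list.genes:
        raise FormatError(f"{path}: gene list is empty")
    n_dup = len(symbols) - len({s.strip().upper() for s in symbols})
    if n_dup:
        log.info("%s: dropped %d duplicate gene symbols", path, n_dup)
    return gene_list


def cohort_to_frame(cohort: Cohort) -> pd.DataFrame:
    """Flatten a cohort to the canonical TSV column layout."""
    rows = []
    for sample in cohort:
        m = sample.meta
        for v in sample:
            rows.append(
                {
                    "sample_id": m.sample_id,
                    "patient_id": m.patient_id,
                    "tissue": m.tissue,
                    "chrom": v.chrom,
                    "pos": v.pos,
                    "ref": v.ref,
                    "alt": v.alt,
                    "gene": v.gene,
                    "effect": v.effect,
                    "polyphen2": "" if v.polyphen2 is None else repr(v.polyphen2),
                    "sift": "" if v.sift is None else repr(v.sift),
                    "alt_reads": v.alt_reads,
                    "total_reads": v.total_reads,
                }
            )
    return pd.DataFrame(rows, columns=TSV_COLUMNS)


def write_cohort(cohort: Cohort, path: Union[str, Path]) -> None:
    """Serialize a cohort as the canonical TSV (round-trips losslessly)."""
    cohort_to_frame(cohort).to_csv(path, sep="\t", index=False)


def write_site_catalog(catalog: PopulationCatalog, path: Union[str, Path]) -> None:
    with open(path, "w") as handle:
        for chrom, pos, ref, alt in sorted(catalog.sites):
            handle.write(f"{chrom}\t{pos}\t{ref}\t{alt}\n")


def write_results(
    tables: dict[str, pd.DataFrame], out_dir: Union[str, Path]
) -> list[Path]:
    """Write named result tables as TSV files under ``out_dir``.

    Deterministic column order (as given in each frame); returns the
    written paths.  Empty frames produce header-only files with a
    warning.
    """
    out_dir = Path(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    written = []
    for name, frame in tables.items():
        target = out_dir / f"{name}.tsv"
        if frame.empty:
            log.warning("result table %r is empty; writing header only", name)
        frame.to_csv(target, sep="\t", index=False)
        written.append(target)
    return written
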