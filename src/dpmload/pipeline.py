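"""End-to-end orchestration: ingest/simulate -> filter -> classify ->
summarize -> compare -> drivers/recurrence -> enrich.

A :class:`RunConfig` fully determines a run; outputs are a deterministic
set of TSV tables plus a JSON manifest recording the config hash, seed
and per-stage record counts, so re-running an identical config
reproduces identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import classify as _classify
from . import drivers as _drivers
from . import enrichment as _enrichment
from . import germline as _germline
from . import io as _io
from . import simulate as _simulate
from . import stats as _stats
from .records import Cohort, GeneList, PopulationCatalog

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a pipeline run depends on."""

    out_dir: str = "dpmload-run"
    # input: either a variant table + catalog, or a simulation
    input_table: Optional[str] = None
    input_dialect: str = "tsv"
    catalog_path: Optional[str] = None
    catalog_dialect: str = "site_list"
    simulate: bool = False
    n_patients: int = 6
    tumour_extra_sweeps: int = 2
    # analysis settings
    match_mode: str = "allele_exact"
    mode: str = "polyphen2"
    unscored_as: str = "own-class"
    denominator: str = "all-retained"
    expressed_genes: Optional[str] = None
    driver_genes: Optional[str] = None
    damaging_only: bool = True
    control_reps: int = 10
    control_k: int = 20
    gmt: Optional[str] = None
    alpha: float = 0.01
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class PipelineResult:
    out_dir: Path
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def _load_inputs(config: RunConfig) -> tuple[Cohort, PopulationCatalog]:
    if config.simulate:
        cohort, catalog = _simulate.generate_paired_cohort(
            _simulate.SimulationParams(seed=config.seed),
            _simulate.SeqParams(private_germline_fraction=0.03),
            n_patients=config.n_patients,
            tumour_extra_sweeps=config.tumour_extra_sweeps,
            seed=config.seed,
        )
        return cohort, catalog
    if config.input_table is None:
        raise ValueError("config needs input_table or simulate=True")
    cohort = _io.read_variant_table(config.input_table, dialect=config.input_dialect)
    if config.catalog_path:
        catalog = _io.read_site_catalog(config.catalog_path, dialect=config.catalog_dialect)
    else:
        catalog = PopulationCatalog(sites=set(), release_tag="none")
    return cohort, catalog


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute every enabled stage and write the artifact set."""
    out_dir = Path(config.out_dir)
    stage = "load"
    try:
        cohort, catalog = _load_inputs(config)
        counts = {"input_samples": len(cohort), "input_variants": sum(len(s) for s in cohort)}

        stage = "germline_filter"
        filtered_samples = []
        reports = []
        for sample in cohort:
            filtered, report = _germline.filter_germline(sample, catalog, config.match_mode)
            filtered_samples.append(filtered)
            reports.append(report.__dict__)
        filtered_cohort = Cohort(
            dataset_id=cohort.dataset_id, samples=filtered_samples, pairs=cohort.pairs
        )
        counts["removed_germline"] = sum(r["n_removed"] for r in reports)
        counts["retained_variants"] = sum(r["n_retained"] for r in reports)

        stage = "classify"
        genes = (
            _io.read_gene_list(config.expressed_genes) if config.expressed_genes else None
        )
        classifications, summaries = _classify.summarize_cohort(
            filtered_cohort,
            mode=config.mode,
            unscored_as=config.unscored_as,
            denominator=config.denominator,
            genes=genes,
        )
        counts["summarized_samples"] = len(summaries)

        classified_frames = [
            _classify.classified_to_frame(cvs, filtered_cohort.sample(sid).meta)
            for sid, cvs in classifications.items()
        ]
        tables: dict[str, pd.DataFrame] = {
            "filter_reports": pd.DataFrame(reports),
            "classified_variants": (
                pd.concat(classified_frames, ignore_index=True)
                if classified_frames
                else pd.DataFrame()
            ),
            "sample_summaries": _classify.summaries_to_frame(summaries),
        }

        stage = "compare"
        groups, tests = _stats.summarize_groups(
            {cohort.dataset_id: (summaries, filtered_cohort.pairs)}
        )
        tables["group_summaries"] = groups
        tables["statistics"] = tests

        stage = "drivers"
        if config.driver_genes:
            driver_list = _io.read_gene_list(config.driver_genes, name="drivers")
            assoc_rows = []
            for tissue in ("non_tumour", "tumour"):
                if sum(s.tissue == tissue for s in summaries) < 3:
                    continue
                table, results = _drivers.driver_dpm_association(
                    summaries, classifications, driver_list, tissue, config.damaging_only
                )
                table["dataset_id"] = cohort.dataset_id
                assoc_rows.append(table)
                for metric, res in results.items():
                    if res is not None:
                        tables["statistics"].loc[len(tables["statistics"])] = {
                            "comparison": f"driver count vs {metric} ({tissue})",
                            "test": res.test_name,
                            "statistic": res.statistic,
                            "p_value": res.p_value,
                            "n": str(res.n),
                            "method_note": res.method_note,
                        }
            if assoc_rows:
                tables["driver_association"] = pd.concat(assoc_rows, ignore_index=True)

        stage = "recurrence"
        patient_of_sample = {
            s.meta.sample_id: s.meta.patient_id for s in filtered_cohort
        }
        recurrence_frames = []
        for tissue in ("non_tumour", "tumour"):
            stratum = {
                sid: cvs
                for sid, cvs in classifications.items()
                if filtered_cohort.sample(sid).meta.tissue == tissue
            }
            if not stratum:
                continue
            try:
                hist = _drivers.recurrence_histogram(
                    stratum, patient_of_sample, dataset_id=f"{cohort.dataset_id}/{tissue}"
                )
            except ValueError:
                continue
            frame = _drivers.recurrence_to_frame(hist)
            frame["uniqueness_fraction"] = _drivers.uniqueness_fraction(hist)
            recurrence_frames.append(frame)
        if recurrence_frames:
            tables["recurrence"] = pd.concat(recurrence_frames, ignore_index=True)

        stage = "enrich"
        if config.gmt:
            sets = _enrichment.read_gmt(config.gmt)
            dpm_genes = _drivers.dpm_bearing_genes(classifications)
            background = {
                v.gene for s in filtered_cohort for v in s if v.gene
            }
            results = _enrichment.enrich(
                dpm_genes & background, background, sets, alpha=config.alpha
            )
            tables["enrichment"] = _enrichment.enrichment_to_frame(results)

        stage = "write"
        written = _io.write_results(tables, out_dir)
        manifest = {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "stage_counts": counts,
            "tables": sorted(p.name for p in written),
        }
        with open(out_dir / "manifest.json", "w") as handle:
            json.dump(manifest, handle, indent=2, sort_keys=True)
        return PipelineResult(out_dir=out_dir, tables=tables, manifest=manifest)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
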