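"""Driver-gene counting, DPM-vs-driver association, and recurrence.

Driver mutations are operationalized as mutations falling in a
configurable list of recurrently mutated genes (e.g. the most frequently
mutated genes in the tumour type).  The association analysis asks
whether the normalized DPM percentage of a sample rises with its count
of driver mutations (Spearman on raw counts; {0, 1, 2+} bins are for
display only), with a matched random-gene control: the same analysis
repeated over random draws of k genes among DPM-bearing genes.

Recurrence asks, for each gene carrying at least one DPM, in how many
patients it does so; the fraction of genes private to a single patient
is the headline "non-recurrent" summary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .classify import ClassifiedVariant, SampleSummary
from .records import GeneList, normalize_gene
from .stats import TestResult, spearman_rho


def default_driver_list_path():
    """Path of the shipped, user-editable driver-gene list."""
    from pathlib import Path

    return Path(__file__).parent / "data" / "driver_genes.txt"


@dataclass
class RecurrenceHistogram:
    """gene -> number of patients in which the gene carries >= 1 DPM."""

    dataset_id: str
    counts: dict[str, int]

    def __len__(self) -> int:
        return len(self.counts)


def driver_mutation_count(
    classified: Iterable[ClassifiedVariant],
    drivers: GeneList,
    damaging_only: bool,
) -> int:
    """Number of a sample's variants falling in driver genes.

    ``damaging_only`` counts only DPM-class variants; otherwise every
    non-synonymous variant in a driver gene counts.
    """
    if len(drivers) == 0:
        raise ValueError("driver gene list is empty")
    n = 0
    for cv in classified:
        if not cv.variant.gene or cv.variant.gene not in drivers:
            continue
        if damaging_only:
            n += cv.klass == "dpm"
        else:
            n += cv.variant.effect != "synonymous"
    return n


def driver_dpm_association(
    summaries: list[SampleSummary],
    classifications: dict[str, list[ClassifiedVariant]],
    drivers: GeneList,
    tissue: str,
    damaging_only: bool = True,
) -> tuple[pd.DataFrame, dict[str, Optional[TestResult]]]:
    """Join per-sample driver counts to pct_dpm / pct_benign and correlate.

    Returns the per-sample table (with display bins {0, 1, 2+}) and
    Spearman results for (count, pct_dpm) and (count, pct_benign).
    If every sample has the same driver count the correlation is
    undefined and reported as None.
    """
    selected = [s for s in summaries if s.tissue == tissue]
    if len(selected) < 3:
        raise ValueError(f"need >= 3 samples with tissue {tissue!r}")
    rows = []
    for s in selected:
        count = driver_mutation_count(classifications[s.sample_id], drivers, damaging_only)
        rows.append(
            {
                "sample_id": s.sample_id,
                "tissue": s.tissue,
                "n_driver_mutations": count,
                "driver_bin": "2+" if count >= 2 else str(count),
                "pct_dpm": s.pct_dpm,
                "pct_benign": s.pct_benign,
            }
        )
    table = pd.DataFrame(rows)
    counts = table["n_driver_mutations"].to_numpy()
    results: dict[str, Optional[TestResult]] = {}
    for metric in ("pct_dpm", "pct_benign"):
        vals = table[metric].to_numpy()
        if np.unique(counts).size == 1 or np.unique(vals).size == 1:
            results[metric] = None
        else:
            results[metric] = spearman_rho(counts, vals)
    return table, results


def dpm_bearing_genes(classifications: dict[str, list[ClassifiedVariant]]) -> set[str]:
    return {
        cv.variant.gene
        for cvs in classifications.values()
        for cv in cvs
        if cv.klass == "dpm" and cv.variant.gene
    }


def random_gene_control(
    summaries: list[SampleSummary],
    classifications: dict[str, list[ClassifiedVariant]],
    tissue: str,
    k: int = 20,
    reps: int = 10,
    seed: int = 0,
    damaging_only: bool = True,
) -> pd.DataFrame:
    """Repeat the driver association with random DPM-bearing gene draws.

    ``reps`` independent draws of ``k`` genes, uniform without
    replacement among genes carrying at least one DPM anywhere in the
    cohort; deterministic under a fixed seed.  Returns one row per draw
    with the Spearman rho/p on pct_dpm.
    """
    eligible = sorted(dpm_bearing_genes(classifications))
    if len(eligible) < k:
        raise ValueError(f"only {len(eligible)} DPM-bearing genes; need >= {k}")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(reps):
        drawn = rng.choice(eligible, size=k, replace=False)
        gene_list = GeneList(name=f"random_{rep}", genes=set(drawn))
        _, results = driver_dpm_association(
            summaries, classifications, gene_list, tissue, damaging_only=damaging_only
        )
        res = results["pct_dpm"]
        rows.append(
            {
                "rep": rep,
                "genes": ",".join(sorted(normalize_gene(g) for g in drawn)),
                "rho": res.statistic if res else np.nan,
                "p_value": res.p_value if res else np.nan,
            }
        )
    return pd.DataFrame(rows)


def recurrence_histogram(
    classifications: dict[str, list[ClassifiedVariant]],
    patient_of_sample: dict[str, str],
    dataset_id: str = "",
    klass: str = "dpm",
) -> RecurrenceHistogram:
    """Per-gene count of patients carrying >= 1 variant of ``klass``.

    Deduplication is patient-level: multiple qualifying variants of one
    gene in one patient count once.  Callers stratify by tissue by
    passing only that stratum's classifications.
    """
    gene_patients: dict[str, set[str]] = {}
    for sample_id, cvs in classifications.items():
        patient = patient_of_sample[sample_id]
        for cv in cvs:
            if cv.klass == klass and cv.variant.gene:
                gene_patients.setdefault(cv.variant.gene, set()).add(patient)
    if not gene_patients:
        raise ValueError(f"no variants of class {klass!r} in the cohort")
    return RecurrenceHistogram(
        dataset_id=dataset_id,
        counts={gene: len(p) for gene, p in gene_patients.items()},
    )


def uniqueness_fraction(hist: RecurrenceHistogram) -> float:
    """Fraction of DPM-bearing genes seen in exactly one patient."""
    if len(hist) == 0:
        raise ValueError("empty recurrence histogram")
    return sum(1 for c in hist.counts.values() if c == 1) / len(hist)


def recurrence_to_frame(hist: RecurrenceHistogram) -> pd.DataFrame:
    rows = sorted(hist.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(rows, columns=["gene", "n_patients"]).assign(dataset_id=hist.dataset_id)
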