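"""Synthetic cohorts: clonal-evolution simulator and direct generators.

Three generators feed the pipeline's tests and calibrations:

1. A forward-time Wright-Fisher simulator of the driver-sweep model of
   DPM accumulation in regenerating tissue: a fixed-size population of
   cells acquires driver, deleterious-passenger (DPM), benign and
   synonymous mutations at per-cell per-generation probabilities;
   fitness is multiplicative, ``(1+s_driver)^drivers * (1-s_dpm)^dpms``;
   a driver sweep amplifies one cell's genotype, carrying its
   (otherwise selected-against) DPMs to detectable frequency by
   hitchhiking.  Tumours are modelled as additional driver sweeps on
   top of the non-tumour epoch of the same patient.
2. A bulk-sequencing emulator turning a clone state into called
   variants (binomial read sampling at a detection threshold), with
   germline heterozygous/homozygous spike-ins that may or may not be
   present in the population catalog.
3. A fast direct generator of per-sample summary statistics with
   specified moments (means, SDs, within-patient correlation), used for
   type-I-error and power calibration of the paired tests.

The underlying biology gives no mutation rates or selection
coefficients; every numeric default here is an invented but
field-plausible choice targeting the regimes the pipeline is built
for - drivers occurring 0-2 times per sampled tissue, a DPM class near
one third of somatic exonic variants, and a missense-dominated effect
mix.  See docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .records import (
    Cohort,
    PopulationCatalog,
    SampleMeta,
    SampleVariantSet,
    VariantRecord,
)

# Reserved position ranges keep somatic, catalog and private-germline
# sites disjoint by construction (single synthetic "chromosome 1").
_CATALOG_POS_MAX = 5_000_000
_PRIVATE_GERMLINE_BASE = 6_000_000
_SOMATIC_BASE = 10_000_000

_BASES = np.array(["A", "C", "G", "T"])


@dataclass
class SimulationParams:
    """Wright-Fisher driver/passenger simulation parameters.

    Mutation probabilities are per cell per generation; at most one new
    mutation per cell per generation is drawn (adequate for the small
    rates used).  All defaults are invented: the modelled biology is
    qualitative.
    """

    n_cells: int = 300
    generations: int = 120
    mu_driver: float = 0.0
    mu_dpm: float = 0.020
    mu_benign: float = 0.012
    mu_synonymous: float = 0.016
    s_driver: float = 0.5
    s_dpm: float = 0.03
    n_genes: int = 2000
    driver_genes: tuple[str, ...] = ("TP53", "CTNNB1")
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mu_driver", "mu_dpm", "mu_benign", "mu_synonymous"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.s_driver < 0 or not 0.0 <= self.s_dpm < 1.0:
            raise ValueError("s_driver >= 0 and s_dpm in [0, 1) required")


@dataclass
class CloneState:
    """Subclone composition at one generation.

    ``clones`` maps a genotype (sorted tuple of mutation ids) to its
    cell count; ``mutations`` maps id -> (class, gene).  Cell counts
    always sum to the population size.
    """

    generation: int
    clones: dict[tuple[int, ...], int]
    mutations: dict[int, tuple[str, str]]

    @property
    def n_cells(self) -> int:
        return sum(self.clones.values())

    def mutation_frequencies(self) -> dict[int, float]:
        """Fraction of cells carrying each segregating mutation."""
        n = self.n_cells
        freq: dict[int, float] = {}
        for genotype, count in self.clones.items():
            for m in genotype:
                freq[m] = freq.get(m, 0.0) + count
        return {m: c / n for m, c in freq.items()}

    def class_load(self) -> dict[str, float]:
        """Mean per-cell mutation count by class."""
        n = self.n_cells
        load: dict[str, float] = {}
        for genotype, count in self.clones.items():
            for m in genotype:
                klass = self.mutations[m][0]
                load[klass] = load.get(klass, 0.0) + count / n
        return load


@dataclass
class SeqParams:
    """Bulk-exome sequencing emulation parameters (artifact plumbing)."""

    cells_sampled: Optional[int] = None
    detection_fraction: float = 0.05
    mean_depth: float = 80.0
    depth_law: str = "poisson"  # or "fixed"
    germline_het: int = 30
    germline_hom: int = 10
    private_germline_fraction: float = 0.0
    #: stream key making per-mutation annotations (effect, scores,
    #: alleles) identical across samples sharing a simulation
    annotation_seed: int = 0
    # effect mix within the simulator's mutation classes
    dpm_effect_mix: dict = field(
        default_factory=lambda: {
            "missense": 0.80,
            "stop_gain": 0.10,
            "stop_loss": 0.02,
            "frameshift_indel": 0.08,
        }
    )
    benign_nonframeshift_fraction: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.detection_fraction <= 1.0:
            raise ValueError("detection_fraction must lie in (0, 1]")
        if self.mean_depth < 1:
            raise ValueError("mean_depth must be >= 1")
        if not 0.0 <= self.private_germline_fraction <= 1.0:
            raise ValueError("private_germline_fraction must lie in [0, 1]")


@dataclass
class DirectCohortParams:
    """Moments for the direct per-sample summary generator.

    Defaults emulate a realistic paired liver-exome regime: non-tumour
    pct_dpm near 34 with SD ~4, a tumour shift of +2.4 percentage
    points, and strong within-patient correlation.
    """

    n_patients: int = 24
    nt_mean: float = 34.3
    nt_sd: float = 4.1
    delta: float = 2.4
    t_sd: Optional[float] = 3.2
    within_patient_corr: float = 0.7
    mean_total_exonic: float = 600.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nt_sd < 0 or (self.t_sd is not None and self.t_sd < 0):
            raise ValueError("standard deviations must be >= 0")
        if not -1.0 <= self.within_patient_corr <= 1.0:
            raise ValueError("within_patient_corr must lie in [-1, 1]")
        if not 0 < self.nt_mean < 100 or not 0 < self.nt_mean + self.delta < 100:
            raise ValueError("mean percentages must lie in (0, 100)")


class _WrightFisher:
    """Mutable simulation engine behind the public functions."""

    def __init__(self, params: SimulationParams, rng: np.random.Generator):
        self.params = params
        self.rng = rng
        self.clones: dict[tuple[int, ...], int] = {(): params.n_cells}
        self.fitness: dict[tuple[int, ...], float] = {(): 1.0}
        self.mutations: dict[int, tuple[str, str]] = {}
        self.generation = 0
        self._next_id = 0
        p = params
        self._class_names = ("driver", "dpm", "benign", "synonymous")
        self._mus = np.array([p.mu_driver, p.mu_dpm, p.mu_benign, p.mu_synonymous])

    def _new_mutation(self, klass: str) -> int:
        mid = self._next_id
        self._next_id += 1
        if klass == "driver":
            gene = self.params.driver_genes[
                int(self.rng.integers(len(self.params.driver_genes)))
            ]
        else:
            gene = f"G{int(self.rng.integers(self.params.n_genes)):05d}"
        self.mutations[mid] = (klass, gene)
        return mid

    def _fitness_factor(self, klass: str) -> float:
        if klass == "driver":
            return 1.0 + self.params.s_driver
        if klass == "dpm":
            return 1.0 - self.params.s_dpm
        return 1.0

    def _add_cell(self, parent: tuple[int, ...], klass: str) -> None:
        mid = self._new_mutation(klass)
        child = tuple(sorted(parent + (mid,)))
        self.clones[child] = self.clones.get(child, 0) + 1
        self.fitness[child] = self.fitness[parent] * self._fitness_factor(klass)

    def inject_driver(self) -> None:
        """Place one driver mutation in a uniformly chosen cell."""
        genotypes = list(self.clones)
        counts = np.array([self.clones[g] for g in genotypes], dtype=float)
        idx = int(self.rng.choice(len(genotypes), p=counts / counts.sum()))
        parent = genotypes[idx]
        self.clones[parent] -= 1
        if self.clones[parent] == 0:
            del self.clones[parent]
        self._add_cell(parent, "driver")

    def step(self) -> None:
        mu_total = float(self._mus.sum())
        # mutation phase: at most one new mutation per cell per generation
        if mu_total > 0:
            rel = self._mus / mu_total
            for genotype in list(self.clones):
                count = self.clones[genotype]
                n_mut = int(self.rng.binomial(count, mu_total))
                if n_mut == 0:
                    continue
                self.clones[genotype] = count - n_mut
                classes = self.rng.choice(4, size=n_mut, p=rel)
                for c in classes:
                    self._add_cell(genotype, self._class_names[c])
                if self.clones[genotype] == 0:
                    del self.clones[genotype]
        # selection + resampling (Wright-Fisher multinomial)
        genotypes = list(self.clones)
        weights = np.array(
            [self.clones[g] * self.fitness[g] for g in genotypes], dtype=float
        )
        counts = self.rng.multinomial(self.params.n_cells, weights / weights.sum())
        self.clones = {g: int(c) for g, c in zip(genotypes, counts) if c > 0}
        self.generation += 1

    def run(self, generations: int) -> None:
        for _ in range(generations):
            self.step()

    def snapshot(self) -> CloneState:
        return CloneState(
            generation=self.generation,
            clones=dict(self.clones),
            mutations=dict(self.mutations),
        )


def simulate_clonal_tissue(
    params: SimulationParams,
    record_every: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> list[CloneState]:
    """Run the Wright-Fisher simulation, returning recorded clone states.

    ``record_every`` keeps a snapshot every that many generations (plus
    the final state); by default only initial and final states are kept.
    Deterministic under ``params.seed`` when no generator is supplied.
    """
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    engine = _WrightFisher(params, rng)
    trajectory = [engine.snapshot()]
    for g in range(1, params.generations + 1):
        engine.step()
        if (record_every and g % record_every == 0) or g == params.generations:
            trajectory.append(engine.snapshot())
    return trajectory


def _draw_depth(seq: SeqParams, rng: np.random.Generator) -> int:
    if seq.depth_law == "fixed":
        return max(1, int(round(seq.mean_depth)))
    return max(1, int(rng.poisson(seq.mean_depth)))


def _somatic_site(mutation_id: int) -> tuple[str, int]:
    return "1", _SOMATIC_BASE + mutation_id


def _alleles_for(effect: str, rng: np.random.Generator) -> tuple[str, str]:
    if effect in ("frameshift_indel", "nonframeshift_indel"):
        ins = "".join(rng.choice(_BASES, size=1 if effect == "frameshift_indel" else 3))
        ref = str(rng.choice(_BASES))
        return ref, ref + ins
    ref, alt = rng.choice(4, size=2, replace=False)
    return str(_BASES[ref]), str(_BASES[alt])


def _assign_effect_and_scores(
    klass: str, seq: SeqParams, rng: np.random.Generator
) -> tuple[str, Optional[float], Optional[float]]:
    """Map a simulator mutation class to an annotated effect + scores.

    DPM-class mutations draw damaging scores (PolyPhen-2 >= 0.453,
    SIFT <= 0.05) when missense; benign-class draw benign scores;
    indels and stop variants carry no scores, as annotators emit.
    """
    if klass == "synonymous":
        return "synonymous", None, None
    if klass == "benign":
        if rng.random() < seq.benign_nonframeshift_fraction:
            return "nonframeshift_indel", None, None
        return "missense", float(rng.uniform(0.0, 0.4529)), float(rng.uniform(0.051, 1.0))
    # dpm and driver classes are damaging
    mix = seq.dpm_effect_mix
    effects = list(mix)
    effect = str(rng.choice(effects, p=np.array([mix[e] for e in effects])))
    if klass == "driver":
        effect = "missense"
    if effect == "missense":
        return "missense", float(rng.uniform(0.453, 1.0)), float(rng.uniform(0.0, 0.05))
    return effect, None, None


@dataclass(frozen=True)
class GermlineSpike:
    """One spiked germline variant, shared between a patient's samples."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    effect: str
    polyphen2: Optional[float]
    sift: Optional[float]
    homozygous: bool
    in_catalog: bool


def make_germline_spikes(
    seq: SeqParams,
    catalog: PopulationCatalog,
    rng: np.random.Generator,
    private_site_offset: int = 0,
) -> list[GermlineSpike]:
    """Draw a patient's germline spike-in variants.

    Each spike is private (absent from the catalog) independently with
    probability ``private_germline_fraction``; catalogued spikes are
    sampled from the catalog's own sites, private ones from a reserved
    position range disjoint from catalog and somatic sites.
    """
    spikes: list[GermlineSpike] = []
    catalog_sites = sorted(catalog.sites)
    used: set[tuple[str, int, str, str]] = set()
    n_private = 0
    for i in range(seq.germline_het + seq.germline_hom):
        homozygous = i >= seq.germline_het
        private = bool(rng.random() < seq.private_germline_fraction)
        if private or not catalog_sites:
            pos = _PRIVATE_GERMLINE_BASE + private_site_offset + n_private
            n_private += 1
            ref, alt = _alleles_for("missense", rng)
            chrom = "1"
        else:
            while True:  # distinct catalog sites within one patient
                chrom, pos, ref, alt = catalog_sites[int(rng.integers(len(catalog_sites)))]
                if (chrom, pos, ref, alt) not in used:
                    break
        used.add((chrom, int(pos), ref, alt))
        # germline background: mostly benign missense / synonymous
        if rng.random() < 0.4:
            effect, pp2, sift = "synonymous", None, None
        else:
            effect, pp2, sift = (
                "missense",
                float(rng.uniform(0.0, 0.4529)),
                float(rng.uniform(0.051, 1.0)),
            )
        spikes.append(
            GermlineSpike(
                chrom=chrom,
                pos=int(pos),
                ref=ref,
                alt=alt,
                gene=f"G{int(rng.integers(2000)):05d}",
                effect=effect,
                polyphen2=pp2,
                sift=sift,
                homozygous=homozygous,
                in_catalog=not private and bool(catalog_sites),
            )
        )
    return spikes


def sequence_tissue(
    state: CloneState,
    seq: SeqParams,
    catalog: PopulationCatalog,
    meta: SampleMeta,
    rng: Optional[np.random.Generator] = None,
    germline: Optional[list[GermlineSpike]] = None,
) -> SampleVariantSet:
    """Emulate bulk exome calling on a simulated tissue.

    Somatic mutations at cell fraction >= ``detection_fraction`` become
    heterozygous calls: total reads from the depth law, alt reads
    binomial at half the cell fraction (floored at one read, since the
    variant was called).  Germline heterozygous spikes sample at allele
    fraction 1/2; homozygous at 1.  Catalog membership of spikes is
    taken from the spike list (see :func:`make_germline_spikes`).
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    freq = state.mutation_frequencies()
    if seq.cells_sampled is not None and seq.cells_sampled < state.n_cells:
        genotypes = list(state.clones)
        counts = np.array([state.clones[g] for g in genotypes], dtype=float)
        sampled = rng.multinomial(seq.cells_sampled, counts / counts.sum())
        freq = {}
        for genotype, c in zip(genotypes, sampled):
            if c:
                for m in genotype:
                    freq[m] = freq.get(m, 0.0) + c / seq.cells_sampled

    variants: list[VariantRecord] = []
    for mid in sorted(freq):
        f = freq[mid]
        if f < seq.detection_fraction:
            continue
        klass, gene = state.mutations[mid]
        # annotation keyed to the mutation, not the sample, so a clonal
        # mutation shared by a patient's NT and T gets one identity
        annot_rng = np.random.default_rng([seq.annotation_seed, mid])
        effect, pp2, sift = _assign_effect_and_scores(klass, seq, annot_rng)
        chrom, pos = _somatic_site(mid)
        ref, alt = _alleles_for(effect, annot_rng)
        total = _draw_depth(seq, rng)
        alt_reads = max(1, int(rng.binomial(total, min(1.0, f / 2.0))))
        variants.append(
            VariantRecord(
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                gene=gene,
                effect=effect,
                polyphen2=pp2,
                sift=sift,
                alt_reads=alt_reads,
                total_reads=total,
            )
        )
    for spike in germline or []:
        total = _draw_depth(seq, rng)
        if spike.homozygous:
            alt_reads = total
        else:
            alt_reads = max(1, int(rng.binomial(total, 0.5)))
        variants.append(
            VariantRecord(
                chrom=spike.chrom,
                pos=spike.pos,
                ref=spike.ref,
                alt=spike.alt,
                gene=spike.gene,
                effect=spike.effect,
                polyphen2=spike.polyphen2,
                sift=spike.sift,
                alt_reads=alt_reads,
                total_reads=total,
            )
        )
    return SampleVariantSet(meta=meta, variants=variants)


def make_population_catalog(
    n_sites: int, genome_model: Optional[dict] = None, seed: int = 0
) -> PopulationCatalog:
    """Deterministic synthetic population site catalog.

    Sites are unique by construction and confined to a reserved
    position range disjoint from the simulator's somatic and
    private-germline site allocators.
    """
    if n_sites < 0:
        raise ValueError("n_sites must be >= 0")
    rng = np.random.default_rng(seed)
    chroms = [str(c) for c in range(1, 23)]
    positions = rng.choice(_CATALOG_POS_MAX - 1, size=n_sites, replace=False) + 1
    sites = set()
    for pos in positions:
        chrom = chroms[int(rng.integers(len(chroms)))]
        r, a = rng.choice(4, size=2, replace=False)
        sites.add((chrom, int(pos), str(_BASES[r]), str(_BASES[a])))
    return PopulationCatalog(sites=sites, release_tag=f"synthetic-{seed}")


def generate_paired_cohort(
    params: SimulationParams,
    seq: SeqParams,
    n_patients: int,
    tumour_extra_sweeps: int = 2,
    sweep_generations: int = 30,
    seed: int = 0,
    catalog: Optional[PopulationCatalog] = None,
    dataset_id: str = "synthetic",
) -> tuple[Cohort, PopulationCatalog]:
    """Paired NT/T cohort from per-patient clonal simulations.

    Each patient's non-tumour sample is sequenced at the end of the
    baseline epoch; the tumour continues the same simulation through
    ``tumour_extra_sweeps`` injected driver sweeps (each followed by
    ``sweep_generations`` generations).  With zero extra sweeps the
    tumour is sequenced from the same epoch (a null cohort).  Germline
    spikes are drawn once per patient and shared between NT and T.
    Fully deterministic under ``seed``.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    root = np.random.SeedSequence(seed)
    if catalog is None:
        catalog = make_population_catalog(2000, seed=int(root.spawn(1)[0].generate_state(1)[0] % 2**31))
    samples: list[SampleVariantSet] = []
    pairs: dict[str, tuple[str, str]] = {}
    for i, child in enumerate(root.spawn(n_patients)):
        rng = np.random.default_rng(child)
        patient = f"P{i + 1:03d}"
        patient_seq = replace(seq, annotation_seed=(seed * 100_003 + i) % 2**31)
        engine = _WrightFisher(params, rng)
        engine.run(params.generations)
        nt_state = engine.snapshot()
        spikes = make_germline_spikes(patient_seq, catalog, rng, private_site_offset=i * 10_000)
        nt_meta = SampleMeta(sample_id=f"{patient}-NT", patient_id=patient, tissue="non_tumour")
        samples.append(sequence_tissue(nt_state, patient_seq, catalog, nt_meta, rng, spikes))
        for _ in range(tumour_extra_sweeps):
            engine.inject_driver()
            engine.run(sweep_generations)
        t_state = engine.snapshot()
        t_meta = SampleMeta(sample_id=f"{patient}-T", patient_id=patient, tissue="tumour")
        samples.append(sequence_tissue(t_state, patient_seq, catalog, t_meta, rng, spikes))
        pairs[patient] = (f"{patient}-NT", f"{patient}-T")
    return Cohort(dataset_id=dataset_id, samples=samples, pairs=pairs), catalog


def generate_direct_cohort(
    params: DirectCohortParams, expand: bool = False
) -> pd.DataFrame | tuple[pd.DataFrame, Cohort]:
    """Correlated per-patient (NT, T) pct_dpm draws with given moments.

    Returns a per-sample summary table; with ``expand=True`` also
    materializes a variant-level :class:`Cohort` whose classification
    reproduces the summarized counts exactly (percentages rounded to
    achievable counts).
    """
    p = params
    rng = np.random.default_rng(p.seed)
    t_sd = p.nt_sd if p.t_sd is None else p.t_sd
    rho = p.within_patient_corr
    cov = np.array(
        [[p.nt_sd**2, rho * p.nt_sd * t_sd], [rho * p.nt_sd * t_sd, t_sd**2]]
    )
    draws = rng.multivariate_normal([p.nt_mean, p.nt_mean + p.delta], cov, size=p.n_patients)
    draws = np.clip(draws, 0.0, 100.0)

    rows = []
    cohort_samples: list[SampleVariantSet] = []
    pairs: dict[str, tuple[str, str]] = {}
    pos_counter = [0]
    for i in range(p.n_patients):
        patient = f"D{i + 1:03d}"
        for tissue, pct in (("non_tumour", draws[i, 0]), ("tumour", draws[i, 1])):
            sid = f"{patient}-{'NT' if tissue == 'non_tumour' else 'T'}"
            total = max(50, int(rng.poisson(p.mean_total_exonic)))
            n_dpm = int(round(pct / 100.0 * total))
            achieved = 100.0 * n_dpm / total
            n_benign = int(round((total - n_dpm) * 0.45))
            n_syn = total - n_dpm - n_benign
            rows.append(
                {
                    "sample_id": sid,
                    "patient_id": patient,
                    "tissue": tissue,
                    "n_total_exonic": total,
                    "n_dpm": n_dpm,
                    "n_benign": n_benign,
                    "n_synonymous": n_syn,
                    "drawn_pct_dpm": float(pct),
                    "pct_dpm": achieved,
                    "pct_benign": 100.0 * n_benign / total,
                }
            )
            if expand:
                cohort_samples.append(
                    _expand_sample(sid, patient, tissue, n_dpm, n_benign, n_syn, rng, pos_counter)
                )
        pairs[patient] = (f"{patient}-NT", f"{patient}-T")
    frame = pd.DataFrame(rows)
    if expand:
        cohort = Cohort(dataset_id=f"direct-{p.seed}", samples=cohort_samples, pairs=pairs)
        return frame, cohort
    return frame


def _expand_sample(
    sample_id: str,
    patient_id: str,
    tissue: str,
    n_dpm: int,
    n_benign: int,
    n_syn: int,
    rng: np.random.Generator,
    pos_counter: list[int],
) -> SampleVariantSet:
    meta = SampleMeta(sample_id=sample_id, patient_id=patient_id, tissue=tissue)
    variants = []
    specs = [("missense", 0.9, n_dpm), ("missense", 0.1, n_benign), ("synonymous", None, n_syn)]
    for effect, pp2, count in specs:
        for _ in range(count):
            pos_counter[0] += 1
            total = max(1, int(rng.poisson(80)))
            alt = max(1, int(rng.binomial(total, 0.35)))
            variants.append(
                VariantRecord(
                    chrom="1",
                    pos=_SOMATIC_BASE + pos_counter[0],
                    ref="A",
                    alt="G",
                    gene=f"G{int(rng.integers(2000)):05d}",
                    effect=effect,
                    polyphen2=pp2,
                    sift=None,
                    alt_reads=alt,
                    total_reads=total,
                )
            )
    return SampleVariantSet(meta=meta, variants=variants)
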