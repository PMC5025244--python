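# Methods

## Scope and data model

`dpmload` starts where variant calling and annotation end: its unit of
input is an annotated somatic variant call (coordinates, alleles, gene,
coding effect, PolyPhen-2/SIFT scores, alt/total read counts), grouped
into samples and patient-paired cohorts. Coordinates are 1-based,
VCF-style; indels are taken as the caller left them (an upstream
left-alignment is assumed, not enforced). Gene symbols are uppercased
before any comparison, since annotation sources disagree on case.
Variants with an empty gene symbol stay in all totals but are invisible
to gene-based operations (exome kits capture near-gene sequence).

## Germline exclusion

Without a matched germline control, inherited variants are removed by
membership in a population site catalog. Matching is **allele-exact**
(`chrom, pos, ref, alt`) by default — "present in the database" most
naturally means the same allele, and allele-exact is the conservative
choice for somatic retention — with `position_only` available because
annotation-driven exclusion in the wild is sometimes position-based.
Both modes are reported side by side in the filter report. Population
allele-frequency thresholds are deliberately out of scope: exclusion is
presence/absence.

The residual-germline diagnostic is the fraction of retained variants
with allelic frequency exactly 1.0, using integer equality
`alt_reads == total_reads` (no tolerance: the statement is about every
read carrying the variant). Peripheral-blood samples are supported as
ordinary samples (tissue `pbmc`) but never used as a subtraction
control: blood mutational profiles shift with inflammatory disease and
carry their own age-acquired somatic variants, so all samples are
filtered identically against the catalog instead.

## Classification and normalization

Classification is a fixed rule table. Stop-gain/-loss and frameshift
indels are DPMs regardless of scores. Non-frameshift indels are neither
DPM nor benign and form their own excluded class. Missense SNVs are
judged by the configured scorer: `polyphen2` (damaging iff score
≥ 0.453), `sift` (damaging iff score ≤ 0.05) or `either` (damaging if
at least one available score says so). Both thresholds are boundary
inclusive, exactly as the scorers print them. Missense variants lacking
the needed score are an explicit `unscored_missense` class rather than
silently benign; a policy flag folds them into benign or drops them.

Per-sample counts are normalized to the total somatic exonic variants,
`pct = 100 · count / n_total_exonic`, to damp inter-sample and
inter-dataset depth differences. The default denominator is everything
retained after germline filtering (synonymous, excluded indels and
unscored missense included); a `classified-only` denominator (DPM +
benign + synonymous) is available because the boundary of "excluded"
classes is genuinely ambiguous in practice. A gene-restriction pass
(e.g. to liver-expressed genes) recomputes both numerator and
denominator on the restricted set.

## Statistics

Cohorts in this setting are tens of pairs, so exactness matters:

* **Wilcoxon signed-rank** (paired NT/T): zeros dropped (Wilcoxon's
  original rule), tied |differences| mid-ranked. Exact null by dynamic
  programming over doubled midranks (counts of all 2^n sign
  assignments) for ≤ 25 non-zero differences; beyond that, a normal
  approximation with tie and continuity corrections. Two-sided p is
  `2·min(P(W⁺≤w), P(W⁺≥w))`, capped at 1.
* **Mann–Whitney U** (unpaired): exact distribution by the standard
  count recurrence when `n_x·n_y ≤ 400` and the pooled data are
  tie-free; tie-corrected normal approximation otherwise. `U + U' =
  n_x·n_y` holds by construction.
* **Spearman** on mid-ranked data; exact permutation enumeration for
  n ≤ 8, t-approximation otherwise.
* **Fisher exact, right tail**: the hypergeometric survival function
  (scipy), used both for enrichment and as a standalone test.

Two-sided p-values are reported throughout (sidedness is an argument).
No multiple-testing correction is applied to the headline comparisons;
enrichment uses a fixed significance gate (default α = 0.01, with an
optional Benjamini–Hochberg flag, off by default). Enumeration limits
are configurable; the defaults keep exact computation at desk scale.
The exact and approximate branches agree within 0.02 in p wherever both
apply (property-tested).

Covariate checks use ordinary least-squares R² (the square of the
Pearson correlation for a single covariate) — deliberately simple;
mixed or multivariable modelling is out of scope.

## Drivers, recurrence, enrichment

Driver mutations are operationalized as mutations in a user-supplied
gene list (the shipped default carries only the two genes that are
uncontroversial for liver cancer, TP53 and CTNNB1, plus user slots —
inventing the rest of a "top 20" list would be worse than requiring
one). The association analysis correlates per-sample driver counts with
`pct_dpm` using raw counts (Spearman); the {0, 1, 2+} bins exist only
for display. `damaging_only` is an explicit flag with no silent
default in the CLI, because "mutations in driver genes" and "damaging
mutations in driver genes" are both defensible readings. The matched
control repeats the analysis over seeded random draws of k genes
(default k = 20, 10 repetitions) from the cohort's DPM-bearing genes.

Recurrence counts, per gene, the number of patients carrying ≥ 1 DPM in
that gene (patient-level deduplication via `patient_id`; histograms are
computed per tissue stratum). The headline summary is the fraction of
DPM-bearing genes private to one patient. For uniform random placement
this fraction has a closed-form occupancy expectation — with m genes, P
patients and k placements each, `q = 1−(1−1/m)^k` and the expected
fraction is `P·q·(1−q)^(P−1) / (1−(1−q)^P)` — used as the analytic
oracle in tests.

Enrichment is a generic right-tailed Fisher over-representation test of
DPM-bearing genes against gene sets (GMT input), replacing proprietary
pathway tooling. The background universe defaults to all genes bearing
≥ 1 retained variant in the cohort, configurable to an explicit list,
since commercial tools rarely document their reference set. The
`contributing_fraction` summary reports the percentage of DPM variants
whose gene falls in ≥ 1 significant set.

## The synthetic-cohort generators

**Wright–Fisher simulator.** Non-overlapping generations, constant
population of `N` cells, multinomial resampling proportional to fitness
`w = (1+s_driver)^drivers · (1−s_dpm)^DPMs` (multiplicative; epistasis
out of scope). Each cell gains at most one new mutation per generation,
drawn per class with probabilities `mu_driver, mu_dpm, mu_benign,
mu_synonymous`. Wright–Fisher was chosen over Moran as the simpler
standard model, adequate for the qualitative sweep/hitchhiking claims
the simulator exists to express. **Every numeric default is invented**:
the modelled biology is qualitative and supplies no rates. The shipped
regime — `N = 300`, 120 generations, `mu_dpm = 0.02`, `mu_benign =
0.012`, `mu_synonymous = 0.016`, `s_driver = 0.5`, `s_dpm = 0.03` — was
chosen once to land in the regimes the pipeline targets: drivers
occurring 0–2 times per sampled tissue, a DPM class near one third of
somatic exonic variants, and a missense-dominated effect mix. Tumours
are modelled as `tumour_extra_sweeps` injected driver mutations (each
followed by a fixed number of generations) on the continuation of the
patient's own simulation; zero sweeps yields a null cohort sequenced
from the same epoch.

**Sequencing emulation.** Somatic mutations at cell fraction ≥
`detection_fraction` (default 0.05, emulating bulk-exome sensitivity)
become heterozygous calls: depth Poisson around `mean_depth` (default
80×), alt reads binomial at half the cell fraction, floored at one read
because the variant was, by construction, called. `cells_sampled`
subsamples the tissue multinomially before detection, emulating biopsy
sampling noise — this is what makes same-epoch NT/T pairs a non-
degenerate null. Germline spike-ins are drawn once per patient and
shared between that patient's samples: heterozygous at allele fraction
1/2, homozygous at 1; each spike is private (absent from the catalog)
with probability `private_germline_fraction`. Per-mutation annotations
(effect, scores, alleles) are keyed to the mutation identity, not the
sample, so clonal mutations shared by NT and T carry one identity.
Site disjointness between catalog, private-germline and somatic
variants is by reserved position ranges — a deliberate, documented
artifice that makes filtering truth exact.

**Direct generator.** For statistical calibration, per-patient
(NT, T) `pct_dpm` pairs are drawn from a bivariate normal with
configurable means, SDs and within-patient correlation (defaults:
NT 34.3 ± 4.1, shift +2.4, T SD 3.2, ρ = 0.7, a realistic paired
liver-exome regime), truncated to [0, 100] and rounded to achievable
counts given a Poisson total (mean 600 exonic variants). The optional
expansion materializes variant rows whose classification reproduces the
drawn counts exactly, closing the loop through the real pipeline.

**Determinism.** A single top-level seed governs everything; per-patient
and per-stage streams derive from it via `SeedSequence` spawning, so
cohorts are byte-identical across re-runs.

## What the synthetic data does and does not show

The generators emulate class composition, allelic-frequency structure,
germline contamination and paired effect sizes — not real exome
tri-nucleotide mutation spectra, gene-length biases, copy-number events,
subclonal phylogenies beyond the simulated sweeps, or caller artefacts.
Green tests therefore demonstrate that the pipeline's arithmetic,
filtering and inference behave correctly under known truth at realistic
magnitudes; they do not re-establish any biological claim about real
tumours.

## Problem sizes and numerical choices

Calibration runs use 1,000 direct replicates for type-I error, 200 for
power, 50 simulated patients for the sweep contrast and 30 cohorts of 8
patients for the simulator null — sizes chosen to give stable rates at
desk scale. Exact-test oracles enumerate up to 2^10 sign vectors,
C(10,5) labelings and 6! permutations. Degenerate inputs are explicit:
all-zero differences give p = 1 with a warning; constant vectors make
rho/R² an error; an empty sample cannot be summarized (a zero
denominator is meaningless); an empty gene-restriction list is an
error, while an empty population catalog is allowed with a warning.

## Known limitations

* The simulator's quantitative behaviour (how much excess, how fast) is
  a property of invented parameters; only directions and calibrations
  are meaningful.
* VCF ingestion expects per-sample AD/DP; callers that encode depth
  differently need a pre-pass.
* Germline exclusion by catalog membership cannot remove private
  germline variants — exactly the residue the AF = 1.0 diagnostic
  watches.
* `mean_relative_increase` on group means and on per-patient ratios
  differ in general; both are provided, group means being the default
  basis.
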