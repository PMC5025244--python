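"""Germline-filter, classify and summarize a synthetic paired cohort.

Builds a small simulated tumour/non-tumour cohort with germline
contamination, removes putative germline variants by catalog membership,
classifies each retained variant (DPM / benign missense / synonymous /
excluded non-frameshift / unscored) and prints the per-sample normalized
percentages — the pipeline's core statistic.
"""

import dpmload as d

cohort, catalog = d.generate_paired_cohort(
    d.SimulationParams(seed=11),
    d.SeqParams(private_germline_fraction=0.03),
    n_patients=3,
    seed=11,
)

print(f"catalog: {len(catalog)} germline sites ({catalog.release_tag})")
print("sample      tissue       input  removed  retained  pct_dpm  pct_benign  AF=1.0")
for sample in cohort:
    filtered, report = d.filter_germline(sample, catalog, match_mode="allele_exact")
    summary = d.summarize_sample(d.classify_sample(filtered, mode="polyphen2"), filtered.meta)
    print(
        f"{summary.sample_id:<11} {summary.tissue:<12} {report.n_input:>5}"
        f"  {report.n_removed:>7}  {report.n_retained:>8}"
        f"  {summary.pct_dpm:>7.1f}  {summary.pct_benign:>10.1f}"
        f"  {report.af_one_fraction:>6.3f}"
    )

print(
    "\npct_dpm is the percentage of retained somatic exonic variants classified\n"
    "as deleterious passengers; the AF=1.0 column is the fraction of retained\n"
    "variants where every read carries the alternate allele (a residual-germline\n"
    "diagnostic: it stays small once catalogued germline has been excluded)."
)
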