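"""Gene-set over-representation of DPM-bearing genes.

A generic replacement for proprietary pathway tools: for each gene set,
the overlap with the cohort's DPM-bearing genes is tested against a
background universe by the right-tailed Fisher exact test
(hypergeometric tail).  The background defaults to all genes bearing at
least one retained variant in the cohort.  No multiple-testing
correction is applied by default (fixed significance gate, alpha 0.01),
with optional Benjamini-Hochberg for modern use.

Gene-set input is GMT: one set per line, tab-separated
``name<TAB>description<TAB>member1<TAB>member2...``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd

from .classify import ClassifiedVariant
from .records import FormatError, normalize_gene

log = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.01


@dataclass
class GeneSetCollection:
    name: str
    sets: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        normalized = {}
        for set_name, genes in self.sets.items():
            members = {normalize_gene(g) for g in genes if g.strip()}
            if not members:
                raise ValueError(f"gene set {set_name!r} is empty")
            normalized[set_name] = members
        self.sets = normalized

    def __len__(self) -> int:
        return len(self.sets)


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    k: int  # DPM genes in the set
    K: int  # background genes in the set
    n: int  # DPM genes total
    N: int  # background genes total
    p_value: float
    significant: bool

    def __post_init__(self) -> None:
        assert self.k <= min(self.K, self.n)


def read_gmt(path: Union[str, Path], name: Optional[str] = None) -> GeneSetCollection:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sets: dict[str, set[str]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path} line {lineno}: GMT needs name, description and >= 1 member"
                )
            sets[fields[0]] = {g for g in fields[2:] if g.strip()}
    if not sets:
        raise FormatError(f"{path}: no gene sets found")
    return GeneSetCollection(name=name or path.stem, sets=sets)


def enrich(
    dpm_genes: Iterable[str],
    background: Iterable[str],
    sets: GeneSetCollection,
    alpha: float = DEFAULT_ALPHA,
    bh_correct: bool = False,
) -> list[EnrichmentResult]:
    """Right-tailed Fisher over-representation test per gene set.

    ``dpm_genes`` must be a subset of ``background``; each set is
    intersected with the background before testing, and sets with an
    empty background intersection are skipped with a note.  Results are
    sorted by p-value; ``significant`` applies the fixed alpha gate to
    raw p-values, or to Benjamini-Hochberg-adjusted ones when
    ``bh_correct`` is set.
    """
    from .stats import fisher_exact_right

    dpm = {normalize_gene(g) for g in dpm_genes}
    universe = {normalize_gene(g) for g in background}
    if not universe:
        raise ValueError("empty background universe")
    if not dpm <= universe:
        raise ValueError("dpm_genes must be a subset of the background")

    results = []
    for set_name, members in sets.sets.items():
        in_background = members & universe
        if not in_background:
            log.info("set %r has no background overlap; skipped", set_name)
            continue
        k = len(dpm & in_background)
        K = len(in_background)
        n = len(dpm)
        N = len(universe)
        # rows: in set / not in set; columns: DPM / non-DPM
        p = fisher_exact_right([[k, K - k], [n - k, N - K - (n - k)]]).p_value
        results.append((set_name, k, K, n, N, p))

    results.sort(key=lambda r: (r[5], r[0]))
    if bh_correct and results:
        from statsmodels.stats.multitest import multipletests

        flags = multipletests([r[5] for r in results], alpha=alpha, method="fdr_bh")[0]
    else:
        flags = [r[5] <= alpha for r in results]
    return [
        EnrichmentResult(set_name=r[0], k=r[1], K=r[2], n=r[3], N=r[4], p_value=r[5], significant=bool(f))
        for r, f in zip(results, flags)
    ]


def contributing_fraction(
    classifications: dict[str, list[ClassifiedVariant]],
    significant: Iterable[EnrichmentResult],
    sets: GeneSetCollection,
) -> float:
    """Percent of DPM variants whose gene lies in >= 1 significant set.

    Computed over the supplied (tissue-stratified) classifications;
    counts variants, not genes, so recurrently hit pathway genes weigh
    more.  Raises when the stratum carries no DPMs.
    """
    pathway_genes: set[str] = set()
    for res in significant:
        if res.significant:
            pathway_genes |= sets.sets[res.set_name]
    n_dpm = 0
    n_in = 0
    for cvs in classifications.values():
        for cv in cvs:
            if cv.klass == "dpm":
                n_dpm += 1
                n_in += cv.variant.gene in pathway_genes
    if n_dpm == 0:
        raise ValueError("no DPM variants in the selected stratum")
    return 100.0 * n_in / n_dpm


def enrichment_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [r.__dict__ for r in results],
        columns=["set_name", "k", "K", "n", "N", "p_value", "significant"],
    )
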