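"""Numeric summaries of mutation and copy-number landscapes, pairwise
mutual-exclusivity testing, and protein-interaction based classification of
candidate regulators.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .containers import validate_cnv


@dataclass
class MutationSummary:
    """Per-gene counts/frequencies, per-sample burden, panel-level rate."""

    per_gene: pd.DataFrame       # mutated_samples, frequency_pct, n_mutations
    tmb: pd.Series               # mutations per sample (samples absent: 0)
    panel_mutated_samples: int
    panel_mutation_events: int
    panel_alteration_frequency_pct: float
    n_samples_total: int

    def top_genes(self, n: int = 10) -> pd.DataFrame:
        return self.per_gene.head(n)


def mutation_summary(maf: pd.DataFrame, panel, n_samples_total: int
                     ) -> MutationSummary:
    """Summarise a MAF against a gene panel.

    ``n_samples_total`` is the cohort denominator; samples absent from the
    MAF count as unmutated. The panel alteration frequency is the
    percentage of samples carrying ≥1 mutation in any panel gene, rounded
    to 2 decimals; mutation events are counted separately since one sample
    can carry several. Gene ranking ties break alphabetically.
    """
    panel = list(panel)
    if not panel:
        raise ValueError("empty panel")
    n_distinct = maf["Tumor_Sample_Barcode"].nunique()
    if n_samples_total < n_distinct:
        raise ValueError(
            f"n_samples_total={n_samples_total} below the {n_distinct} "
            "distinct samples in the MAF"
        )
    rows = []
    for gene in panel:
        hits = maf[maf["Hugo_Symbol"] == gene]
        mutated = hits["Tumor_Sample_Barcode"].nunique()
        rows.append((gene, mutated, len(hits),
                     round(100.0 * mutated / n_samples_total, 2)))
    per_gene = pd.DataFrame(rows, columns=["gene", "mutated_samples",
                                           "n_mutations", "frequency_pct"])
    per_gene = per_gene.sort_values(
        ["mutated_samples", "gene"], ascending=[False, True]
    ).set_index("gene")

    panel_maf = maf[maf["Hugo_Symbol"].isin(panel)]
    mutated_samples = panel_maf["Tumor_Sample_Barcode"].nunique()
    tmb = maf.groupby("Tumor_Sample_Barcode").size().astype(float)
    return MutationSummary(
        per_gene=per_gene,
        tmb=tmb,
        panel_mutated_samples=int(mutated_samples),
        panel_mutation_events=int(len(panel_maf)),
        panel_alteration_frequency_pct=round(
            100.0 * mutated_samples / n_samples_total, 2),
        n_samples_total=int(n_samples_total),
    )


def cnv_frequency(cnv_calls: pd.DataFrame) -> pd.DataFrame:
    """Per-gene amplification / deletion frequency (% of samples)."""
    cnv = validate_cnv(cnv_calls)
    n = cnv.shape[1]
    amp = 100.0 * (cnv == 1).sum(axis=1) / n
    dele = 100.0 * (cnv == -1).sum(axis=1) / n
    return pd.DataFrame({"amplification_pct": amp, "deletion_pct": dele})


def mutual_exclusivity(maf: pd.DataFrame, genes, n_samples_total: int
                       ) -> pd.DataFrame:
    """Pairwise Fisher tests on mutated/unmutated 2×2 tables.

    Odds ratio < 1 is labelled exclusive, > 1 co-occurring; an infinite
    sample odds ratio (a zero off-diagonal cell) is reported as inf and
    flagged. p-values are two-sided and BH-adjusted across pairs.
    """
    genes = list(genes)
    if len(genes) < 2:
        raise ValueError("need at least 2 genes")
    mutated = {g: set(maf.loc[maf["Hugo_Symbol"] == g,
                              "Tumor_Sample_Barcode"]) for g in genes}
    rows = []
    for a, b in combinations(genes, 2):
        both = len(mutated[a] & mutated[b])
        only_a = len(mutated[a]) - both
        only_b = len(mutated[b]) - both
        neither = n_samples_total - both - only_a - only_b
        table = np.array([[both, only_a], [only_b, neither]])
        odds, p = fisher_exact(table, alternative="two-sided")
        rows.append((a, b, both, only_a, only_b, neither, odds, p))
    out = pd.DataFrame(rows, columns=[
        "gene_a", "gene_b", "both", "only_a", "only_b", "neither",
        "odds_ratio", "p"])
    out["adj_p"] = multipletests(out["p"], method="fdr_bh")[1]
    out["direction"] = np.select(
        [out["odds_ratio"] < 1.0, out["odds_ratio"] > 1.0],
        ["exclusive", "co-occurring"], default="independent")
    out["or_infinite"] = ~np.isfinite(out["odds_ratio"])
    return out


@dataclass
class PpiClassification:
    """Seed / direct / indirect partition of an interaction neighbourhood."""

    seeds: set
    direct: set
    indirect: set


def ppi_classify(edges: pd.DataFrame, seeds) -> PpiClassification:
    """Two-hop neighbourhood classification in a confidence-filtered graph.

    Non-seed one-hop neighbours of seeds are *direct* candidate regulators;
    non-seed, non-direct neighbours of direct genes are *indirect*. Direct
    takes precedence when both apply, so the three sets partition.
    """
    seeds = set(seeds)
    if not seeds:
        raise ValueError("seeds must be non-empty")
    adj: dict[str, set] = {}
    for a, b in edges[["gene_a", "gene_b"]].itertuples(index=False):
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    direct = set()
    for s in seeds:
        direct |= adj.get(s, set())
    direct -= seeds
    indirect = set()
    for d in direct:
        indirect |= adj.get(d, set())
    indirect -= seeds | direct
    return PpiClassification(seeds=seeds, direct=direct, indirect=indirect)
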