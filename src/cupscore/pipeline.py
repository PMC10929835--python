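"""End-to-end cuproptosis-pattern pipeline.

Chains the stages on one cohort: batch correction → consensus clustering
on the regulator panel → pairwise pattern DEGs → overlap-DEG extraction →
univariate Cox prognostic filter → optional LASSO sparsification →
CupScore fit and scoring → cutpoint-based low/high grouping with log-rank
comparison. Every stochastic stage draws its own stream from one master
seed, so a run is reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cluster import ConsensusResult, cluster_survival_table, consensus_cluster
from .containers import ExpressionMatrix, REGULATOR_PANEL
from .diffexpr import overlap_degs, pattern_degs
from .io import write_manifest
from .preprocess import batch_correct
from .signature import CupScoreSignature, assign_groups, lasso_select
from .survival import CutpointResult, LogRankResult, logrank, prognostic_filter


@dataclass
class PipelineResult:
    """Everything one pipeline run produced."""

    matrix: ExpressionMatrix
    consensus: ConsensusResult
    assignment: pd.Series
    cluster_sizes: pd.Series
    pair_tables: dict
    overlap_genes: list
    prognostic_genes: list
    selected_genes: list
    model: CupScoreSignature
    scores: pd.Series
    groups: pd.DataFrame
    cutoff: float
    group_logrank: LogRankResult | None
    params: dict = field(default_factory=dict)

    @property
    def group_sizes(self) -> pd.Series:
        return self.groups["group"].value_counts().sort_index()


def run_pipeline(expr: ExpressionMatrix, clinical: pd.DataFrame, *,
                 panel=REGULATOR_PANEL, k_range=(2, 6),
                 n_resamples: int = 1000, lfc_cut: float = 0.7,
                 p_cut: float = 0.05, adj_p_cut: float = 0.001,
                 overlap_mode: str = "intersection",
                 prognostic_p: float = 0.05, use_lasso: bool = True,
                 lasso_folds: int = 10, cutoff="auto", n_perm: int = 1000,
                 correct_batches: bool = True,
                 seed: int | None = 0) -> PipelineResult:
    """Run the full pattern-discovery / scoring pipeline on one cohort."""
    ss = np.random.SeedSequence(seed)
    seed_cluster, seed_lasso, seed_cut = [
        int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(3)]

    matrix = expr
    if correct_batches and expr.batch is not None \
            and expr.batch.nunique() > 1:
        matrix = batch_correct(expr)

    consensus = consensus_cluster(matrix, panel, k_range=k_range,
                                  n_resamples=n_resamples, seed=seed_cluster)
    assignment = consensus.assignment
    cluster_sizes, _ = cluster_survival_table(assignment, clinical)

    pair_tables, _union = pattern_degs(matrix, assignment,
                                       lfc_cut=lfc_cut, p_cut=p_cut)
    overlap = overlap_degs(pair_tables, adj_p_cut=adj_p_cut,
                           mode=overlap_mode)
    if len(overlap) < 2:
        raise RuntimeError(
            "fewer than 2 overlap DEGs; cannot build a score signature"
        )

    prognostic, _cox_table = prognostic_filter(
        matrix.subset_genes(overlap), clinical, p_cut=prognostic_p)
    if len(prognostic) < 2:
        raise RuntimeError("fewer than 2 prognostic genes after Cox filter")

    selected = prognostic
    if use_lasso:
        selected = lasso_select(matrix.subset_genes(prognostic), clinical,
                                n_folds=lasso_folds, seed=seed_lasso)
        if len(selected) < 2:
            selected = prognostic

    model = CupScoreSignature(genes=selected, orient_panel=list(panel))
    model.fit(matrix.to_samples_by_genes())
    scores = model.training_scores_

    clin_idx = clinical.set_index("sample_id")
    common = scores.index.intersection(clin_idx.index)
    groups, used_cutoff = assign_groups(
        scores.loc[common], cutoff,
        clinical=clinical, n_perm=n_perm, seed=seed_cut)

    surv = clin_idx.loc[common, ["time", "event"]]
    lr = None
    by_group = {g: surv.loc[groups.index[groups["group"] == g]]
                for g in groups["group"].unique()}
    if len(by_group) == 2:
        lr = logrank(by_group)

    params = {
        "panel": list(panel), "k_range": list(k_range),
        "n_resamples": n_resamples, "lfc_cut": lfc_cut, "p_cut": p_cut,
        "adj_p_cut": adj_p_cut, "overlap_mode": overlap_mode,
        "prognostic_p": prognostic_p, "use_lasso": use_lasso,
        "cutoff": used_cutoff, "seed": seed,
    }
    return PipelineResult(
        matrix=matrix, consensus=consensus, assignment=assignment,
        cluster_sizes=cluster_sizes, pair_tables=pair_tables,
        overlap_genes=overlap, prognostic_genes=prognostic,
        selected_genes=selected, model=model, scores=scores, groups=groups,
        cutoff=used_cutoff, group_logrank=lr, params=params,
    )


def save_results(result: PipelineResult, out_dir, seed=None) -> None:
    """Write assignment, scores, groups, model and manifest as text files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.assignment.rename("cluster").to_csv(out / "assignment.tsv",
                                               sep="\t")
    result.scores.rename("cupscore").to_csv(out / "scores.tsv", sep="\t")
    result.groups.to_csv(out / "groups.tsv", sep="\t")
    result.model.save(out / "model.json")
    result.consensus.pac.to_csv(out / "pac.tsv", sep="\t")
    write_manifest(
        out / "manifest.json",
        inputs={"n_genes": result.matrix.n_genes,
                "n_samples": result.matrix.n_samples},
        parameters=result.params,
        seed=seed,
        substitutions=(
            "immune/stromal composite via ssGSEA signature scoring",
            "pathway activity via ssGSEA over pathway sets",
        ),
    )
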