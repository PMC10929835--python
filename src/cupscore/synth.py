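"""Seeded synthetic multi-omic cohorts with planted cuproptosis-pattern
structure.

The generator emulates the statistical skeleton of a multi-cohort GBM
expression study: ``n_clusters`` regulator-driven sample subtypes whose mean
expression patterns differ on a 13-gene regulator panel, cluster-associated
differentially expressed gene blocks, cluster-dependent exponential survival,
per-sample clinical covariates, gene-level batch effects, and toy somatic
mutation (MAF) and discrete copy-number tables. Every random draw flows from
a single integer seed, so equal seeds give bit-identical cohorts.

Regulator shift design
----------------------
The base clustering distance downstream is 1 − Pearson correlation between
sample profiles, which is blind to a constant offset added to every panel
gene. Cluster shifts are therefore *sign patterns* over the panel, not flat
offsets: the panel is split into contiguous functional blocks (one per
cluster) and each cluster carries ±shift signs arranged so that (a) every
pair of clusters differs in a non-constant way, and (b) the panel-mean
expression is strictly ordered across clusters, so the convention
"last cluster = highest regulator expression" is well defined.

DEG design
----------
``n_deg`` genes are split into ``n_clusters`` cluster-private blocks (each
up-regulated in exactly one cluster) plus one *graded* block whose expression
rises monotonically across the cluster order. Private blocks make pairwise
differential expression non-trivial; the graded block is the only set
significant in *every* pairwise comparison, so the all-pairs intersection
("overlap DEGs") has a well-defined planted answer, and its monotone
association with the planted hazard ordering gives the score signature a
recoverable prognostic axis.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .containers import ExpressionMatrix, REGULATOR_PANEL


def cluster_letters(n: int) -> list[str]:
    """Cluster labels "A", "B", ... ordered by planted panel expression."""
    if n > 26:
        raise ValueError("at most 26 clusters supported")
    return list(string.ascii_uppercase[:n])


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic cohort.

    Shifts and effects are in log2-expression units; survival is in days.
    """

    n_samples: int = 450
    n_genes: int = 3000
    n_clusters: int = 3
    mixing: tuple[float, ...] | None = None  # defaults to equal proportions
    regulator_panel: tuple[str, ...] = REGULATOR_PANEL
    regulator_shift: float = 1.5
    n_deg: int = 300
    deg_effect_mean: float = 0.8
    deg_effect_sd: float = 0.2
    sigma: float = 1.0
    n_batches: int = 2
    batch_sd: float = 0.5
    baseline_hazard: float = 1.0 / 600.0  # per day; median OS ~14 months
    log_hazard: tuple[float, ...] = (0.0, 0.4, 0.9)
    censoring_rate: float = 0.3
    weibull_shape: float = 1.0  # 1.0 = exponential survival
    age_mean: float = 60.0
    age_sd: float = 10.0
    idh_mutant_prob: tuple[float, ...] = (0.30, 0.15, 0.05)
    tmz_prob: float = 0.6
    mutation_rates: dict[str, float] | None = None
    cnv_amp_rate: float = 0.10
    cnv_del_rate: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        errors = []
        if self.mixing is None:
            self.mixing = tuple([1.0 / self.n_clusters] * self.n_clusters)
        if len(self.mixing) != self.n_clusters:
            errors.append("mixing must have n_clusters entries")
        elif abs(sum(self.mixing) - 1.0) > 1e-8:
            errors.append("mixing proportions must sum to 1")
        if len(self.log_hazard) != self.n_clusters:
            errors.append("log_hazard must have n_clusters entries")
        if len(self.idh_mutant_prob) != self.n_clusters:
            errors.append("idh_mutant_prob must have n_clusters entries")
        if self.n_deg + len(self.regulator_panel) > self.n_genes:
            errors.append("n_deg + panel size exceeds n_genes")
        if not 0.0 <= self.censoring_rate < 1.0:
            errors.append("censoring_rate must be in [0, 1)")
        for name in ("tmz_prob", "cnv_amp_rate", "cnv_del_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                errors.append(f"{name} must be in [0, 1]")
        if any(not 0.0 <= p <= 1.0 for p in self.idh_mutant_prob):
            errors.append("idh_mutant_prob entries must be in [0, 1]")
        if self.sigma <= 0:
            errors.append("sigma must be positive")
        if errors:
            raise ValueError("invalid config: " + "; ".join(errors))
        if self.mutation_rates is None:
            rates = {g: 0.01 for g in self.regulator_panel}
            self.mutation_rates = rates
        if any(not 0.0 <= r <= 1.0 for r in self.mutation_rates.values()):
            raise ValueError("invalid config: mutation rates must be in [0,1]")


@dataclass
class SyntheticTruth:
    """Ground truth planted by :func:`generate_cohort` (the test oracle)."""

    labels: pd.Series  # sample -> cluster letter, ordered A < B < ... by panel mean
    batch: pd.Series
    deg_table: pd.DataFrame  # gene, kind {private, graded}, cluster, effect
    regulator_shifts: pd.DataFrame  # panel gene x cluster shift matrix
    log_hazard: dict[str, float]
    censoring_horizon: float

    @property
    def deg_genes(self) -> list[str]:
        return self.deg_table["gene"].tolist()

    @property
    def graded_genes(self) -> list[str]:
        t = self.deg_table
        return t.loc[t["kind"] == "graded", "gene"].tolist()

    def private_genes(self, cluster: str) -> list[str]:
        t = self.deg_table
        keep = (t["kind"] == "private") & (t["cluster"] == cluster)
        return t.loc[keep, "gene"].tolist()


def _panel_shift_patterns(n_clusters: int, n_panel: int,
                          shift: float) -> np.ndarray:
    """(n_clusters × n_panel) shift matrix; rows ordered by ascending mean.

    Panel genes are split into ``n_clusters`` contiguous blocks; cluster c
    over-expresses its own block (+shift) and under-expresses the others
    (−shift), plus a small cluster-ordering offset (linspace(−0.5, 0.5, K)
    × shift). The block patterns put the cluster centroids at balanced,
    mutually negative correlations *after* both gene-centering and the
    per-profile centering implicit in the downstream Pearson distance —
    constant offsets are invisible there, which is also why the ordering
    offset (the "cluster C expresses regulators highest" convention) can be
    layered on freely. Balanced separation additionally makes
    under-clustering unstable: below the true k the merged pair varies
    between subsamples, inflating PAC away from the truth. Rows are
    returned sorted by ascending panel mean.
    """
    if n_clusters == 1:
        return np.zeros((1, n_panel))
    blocks = np.array([j * n_clusters // n_panel for j in range(n_panel)])
    pat = np.full((n_clusters, n_panel), -1.0)
    for c in range(n_clusters):
        pat[c, blocks == c] = 1.0
    pat = pat * shift
    pat += shift * np.linspace(-0.5, 0.5, n_clusters)[:, None]
    order = np.argsort(pat.mean(axis=1), kind="stable")
    return pat[order]


def _censoring_horizon(config: SyntheticConfig) -> float:
    """Uniform-censoring horizon hitting the configured censoring rate.

    With event time T ~ Exp(lam) and censoring C ~ U(0, H), the censoring
    probability is (1 − exp(−lam·H)) / (lam·H); the horizon solving the
    mixture over clusters is found by bisection.
    """
    if config.censoring_rate == 0.0:
        return np.inf
    lams = config.baseline_hazard * np.exp(np.asarray(config.log_hazard))
    w = np.asarray(config.mixing)

    def cens_prob(h: float) -> float:
        return float(w @ ((1.0 - np.exp(-lams * h)) / (lams * h)))

    target = config.censoring_rate
    lo, hi = 1e-6, 1e9
    return brentq(lambda h: cens_prob(h) - target, lo, hi, xtol=1e-6)


def generate_cohort(config: SyntheticConfig | None = None, seed: int | None = None):
    """Generate one synthetic cohort.

    Returns
    -------
    (ExpressionMatrix, clinical DataFrame, MAF DataFrame, CNV DataFrame,
    SyntheticTruth). ``seed`` overrides ``config.seed`` when given.
    """
    config = config or SyntheticConfig()
    if seed is not None:
        config = SyntheticConfig(**{**config.__dict__, "seed": seed})
    ss = np.random.SeedSequence(config.seed)
    (rng_labels, rng_effects, rng_expr, rng_surv,
     rng_clin, rng_mut, rng_cnv) = map(np.random.default_rng, ss.spawn(7))

    n, g, k = config.n_samples, config.n_genes, config.n_clusters
    letters = cluster_letters(k)
    samples = [f"S{i + 1:04d}" for i in range(n)]

    panel = list(config.regulator_panel)
    n_private = config.n_deg // (k + 1) if k > 1 else 0
    n_graded = config.n_deg - k * n_private if k > 1 else 0
    deg_names = [f"DEG{i + 1:04d}" for i in range(config.n_deg)]
    n_bg = g - len(panel) - config.n_deg
    bg_names = [f"G{i + 1:05d}" for i in range(n_bg)]
    genes = panel + deg_names + bg_names

    # --- truth structure (deterministic given config) -----------------------
    private_blocks = {letters[c]: deg_names[c * n_private:(c + 1) * n_private]
                      for c in range(k)} if k > 1 else {}
    graded = deg_names[k * n_private:] if k > 1 else []

    # --- cluster labels and batches ----------------------------------------
    labels_idx = rng_labels.choice(k, size=n, p=np.asarray(config.mixing))
    labels = pd.Series([letters[c] for c in labels_idx], index=samples,
                       name="cluster")
    batch = pd.Series([f"batch{(i % config.n_batches) + 1}" for i in range(n)],
                      index=samples, name="batch")

    # --- expression ---------------------------------------------------------
    base_mean = rng_effects.normal(5.0, 2.0, size=g)
    X = np.tile(base_mean[:, None], (1, n))

    shifts = _panel_shift_patterns(k, len(panel), config.regulator_shift)
    if k > 1:
        for c in range(k):
            X[: len(panel), labels_idx == c] += shifts[c][:, None]

    effects = rng_effects.normal(config.deg_effect_mean, config.deg_effect_sd,
                                 size=config.n_deg)
    effects = np.abs(effects)
    gene_pos = {name: i for i, name in enumerate(genes)}
    deg_rows = []
    if k > 1:
        for c, letter in enumerate(letters):
            for j, gene in enumerate(private_blocks[letter]):
                e = effects[c * n_private + j]
                X[gene_pos[gene], labels_idx == c] += e
                deg_rows.append((gene, "private", letter, e))
        grades = np.linspace(-1.0, 1.0, k)
        for j, gene in enumerate(graded):
            e = effects[k * n_private + j]
            X[gene_pos[gene], :] += grades[labels_idx] * e
            deg_rows.append((gene, "graded", "", e))
    deg_table = pd.DataFrame(deg_rows,
                             columns=["gene", "kind", "cluster", "effect"])

    if config.n_batches > 1:
        batch_codes = np.array([i % config.n_batches for i in range(n)])
        batch_fx = rng_expr.normal(0.0, config.batch_sd,
                                   size=(g, config.n_batches))
        X += batch_fx[:, batch_codes]
    X += rng_expr.normal(0.0, config.sigma, size=(g, n))

    expr = ExpressionMatrix(pd.DataFrame(X, index=genes, columns=samples),
                            batch=batch)

    # --- survival and clinical ----------------------------------------------
    lam = config.baseline_hazard * np.exp(
        np.asarray(config.log_hazard)[labels_idx])
    u = rng_surv.uniform(size=n)
    # inverse-CDF Weibull; shape 1 reduces to exponential
    t_event = (-np.log(u)) ** (1.0 / config.weibull_shape) / lam
    horizon = _censoring_horizon(config)
    if np.isfinite(horizon):
        c_time = rng_surv.uniform(0.0, horizon, size=n)
    else:
        c_time = np.full(n, np.inf)
    time = np.minimum(t_event, c_time)
    event = (t_event <= c_time).astype(int)

    age = rng_clin.normal(config.age_mean, config.age_sd, size=n)
    sex = np.where(rng_clin.uniform(size=n) < 0.6, "male", "female")
    idh_p = np.asarray(config.idh_mutant_prob)[labels_idx]
    idh = np.where(rng_clin.uniform(size=n) < idh_p, "mutant", "wildtype")
    subtype_by_cluster = {0: "proneural", 1: "classical", 2: "mesenchymal"}
    subtype = [subtype_by_cluster.get(min(c, 2), "classical")
               for c in labels_idx]
    tmz = np.where(rng_clin.uniform(size=n) < config.tmz_prob, "yes", "no")
    clinical = pd.DataFrame({
        "sample_id": samples,
        "time": np.round(time, 2),
        "event": event,
        "age": np.round(age, 1),
        "sex": sex,
        "idh_status": idh,
        "subtype": subtype,
        "tmz": tmz,
    })

    # --- toy MAF and CNV -----------------------------------------------------
    maf_records = []
    for gene, rate in config.mutation_rates.items():
        hits = rng_mut.uniform(size=n) < rate
        for s in np.asarray(samples)[hits]:
            maf_records.append((gene, s, "Missense_Mutation"))
    maf = pd.DataFrame(maf_records, columns=[
        "Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification"])

    cnv_draw = rng_cnv.uniform(size=(len(panel), n))
    cnv = np.zeros((len(panel), n), dtype=int)
    cnv[cnv_draw < config.cnv_amp_rate] = 1
    cnv[cnv_draw > 1.0 - config.cnv_del_rate] = -1
    cnv = pd.DataFrame(cnv, index=panel, columns=samples)

    truth = SyntheticTruth(
        labels=labels,
        batch=batch,
        deg_table=deg_table,
        regulator_shifts=pd.DataFrame(shifts.T, index=panel, columns=letters),
        log_hazard=dict(zip(letters, config.log_hazard)),
        censoring_horizon=horizon,
    )
    return expr, clinical, maf, cnv, truth


def worked_mutation_fixture() -> pd.DataFrame:
    """Fixed toy MAF reproducing the published regulator mutation landscape.

    390 distinct tumour samples of which exactly 9 carry one mutation each in
    the 13-regulator panel (panel alteration frequency 9/390 = 2.31%). ATP7A
    is the most frequently mutated regulator, and FDX1, LIAS and GCSH carry
    none. Every sample appears in the table (unmutated samples carry a
    Silent passenger record in a non-panel gene) so the table itself
    witnesses the 390-sample denominator.
    """
    samples = [f"T{i + 1:03d}" for i in range(390)]
    panel_hits = [
        ("ATP7A", samples[0]), ("ATP7A", samples[1]), ("ATP7A", samples[2]),
        ("ATP7B", samples[3]), ("ATP7B", samples[4]),
        ("DLD", samples[5]), ("DLAT", samples[6]),
        ("PDHA1", samples[7]), ("SLC31A1", samples[8]),
    ]
    records = [(g, s, "Missense_Mutation") for g, s in panel_hits]
    records += [("TTN", s, "Silent") for s in samples[9:]]
    return pd.DataFrame(records, columns=[
        "Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification"])
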