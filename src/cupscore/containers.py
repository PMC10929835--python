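"""Core in-memory containers shared across the pipeline.

The on-disk and in-memory convention throughout the package is a
genes × samples expression matrix (rows = gene symbols, columns = sample
ids), log2(TPM+1) scale unless explicitly flagged as raw FPKM.
Estimator classes that follow the scikit-learn API transpose to
samples × features at their boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REGULATOR_PANEL: tuple[str, ...] = (
    "FDX1", "LIPT1", "LIAS", "DLD", "DLAT", "PDHA1", "PDHB",
    "DBT", "GCSH", "DLST", "SLC31A1", "ATP7A", "ATP7B",
)
"""The 13 cuproptosis regulators used for pattern discovery."""

MAF_VARIANT_CLASSES = frozenset({
    "Missense_Mutation", "Nonsense_Mutation", "Silent", "Splice_Site",
    "Frame_Shift_Del", "Frame_Shift_Ins", "In_Frame_Del", "In_Frame_Ins",
    "Translation_Start_Site", "Nonstop_Mutation", "3'UTR", "5'UTR",
    "3'Flank", "5'Flank", "Intron", "IGR", "RNA", "Targeted_Region",
})


@dataclass
class ExpressionMatrix:
    """Genes × samples expression matrix with optional per-sample batch labels.

    Parameters
    ----------
    values : pandas.DataFrame
        Numeric matrix, rows indexed by gene symbol, columns by sample id.
    batch : pandas.Series, optional
        Per-sample categorical batch label, indexed like ``values.columns``.
    log_scale : bool
        True when values are log2(TPM+1); False for raw FPKM.
    """

    values: pd.DataFrame
    batch: pd.Series | None = None
    log_scale: bool = True

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if v.columns.has_duplicates:
            dups = v.columns[v.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise TypeError("expression values must be numeric")
        if not np.all(np.isfinite(arr)):
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(
                f"non-finite value at gene {v.index[bad[0]]!r}, "
                f"sample {v.columns[bad[1]]!r}"
            )
        if self.batch is not None:
            self.batch = self.batch.reindex(v.columns)
            if self.batch.isna().any():
                missing = self.batch.index[self.batch.isna()].tolist()
                raise ValueError(f"samples without batch label: {missing[:5]}")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing}")
        return ExpressionMatrix(
            self.values.loc[list(genes)], batch=self.batch,
            log_scale=self.log_scale,
        )

    def to_samples_by_genes(self) -> pd.DataFrame:
        """Samples × genes view for scikit-learn style estimators."""
        return self.values.T


@dataclass
class GeneSetCollection:
    """Named, non-empty gene sets (GMT semantics)."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(members) == 0:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)


def validate_clinical(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a clinical table: unique sample ids, time >= 0, event in {0,1}.

    Required columns: sample_id, time, event. Optional covariates (age, sex,
    idh_status, subtype, tmz) are kept as-is; missing values stay NA and are
    excluded per-analysis downstream, never imputed.
    """
    required = {"sample_id", "time", "event"}
    missing = sorted(required - set(df.columns))
    if missing:
        raise ValueError(f"clinical table missing columns: {missing}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids in clinical table: {dups[:5]}")
    if (df["time"] < 0).any():
        raise ValueError("negative survival times present")
    if not df["event"].isin([0, 1]).all():
        raise ValueError("event indicator must be 0 or 1")
    return df.reset_index(drop=True)


def validate_cnv(df: pd.DataFrame) -> pd.DataFrame:
    """Validate discrete CNV calls: values in {-1, 0, +1}."""
    arr = df.to_numpy()
    if not np.isin(arr, (-1, 0, 1)).all():
        raise ValueError("CNV calls must be in {-1, 0, +1}")
    return df
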