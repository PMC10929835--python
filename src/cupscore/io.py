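"""Readers and writers for the pipeline's external formats.

Expression TSV (genes × samples), GMT, clinical TSV, MAF (minimum columns
Hugo_Symbol / Tumor_Sample_Barcode / Variant_Classification), discrete CNV
TSV and protein-interaction edge TSV. All writers emit headered TSV so that
read/write round-trips are bit-identical for well-formed files.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    ExpressionMatrix,
    GeneSetCollection,
    MAF_VARIANT_CLASSES,
    validate_clinical,
    validate_cnv,
)

logger = logging.getLogger(__name__)

MAF_REQUIRED_COLUMNS = ("Hugo_Symbol", "Tumor_Sample_Barcode",
                        "Variant_Classification")


def _read_table(path, **kw) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    try:
        df = pd.read_csv(path, sep=sep, **kw)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty file") from exc
    return df


def read_expression(path, orientation: str = "genes_by_samples",
                    batch: pd.Series | None = None) -> ExpressionMatrix:
    """Read an expression matrix from TSV/CSV.

    First column holds gene ids (or sample ids when
    ``orientation='samples_by_genes'``). Duplicate gene symbols are collapsed
    to the row with the highest mean expression; the collapsed count is
    logged. Non-numeric body cells raise a parse error naming the offending
    coordinate.
    """
    if orientation not in ("genes_by_samples", "samples_by_genes"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = _read_table(path, index_col=0)
    if orientation == "samples_by_genes":
        df = df.T
    # locate non-numeric cells precisely before coercing
    coerced = df.apply(pd.to_numeric, errors="coerce")
    bad = coerced.isna() & ~df.isna()
    if bad.to_numpy().any():
        g, s = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric value {df.iat[g, s]!r} at "
            f"gene {df.index[g]!r}, sample {df.columns[s]!r}"
        )
    if coerced.isna().to_numpy().any():
        g, s = np.argwhere(coerced.isna().to_numpy())[0]
        raise ValueError(
            f"{path}: missing value at gene {df.index[g]!r}, "
            f"sample {df.columns[s]!r}"
        )
    df = coerced
    if df.index.has_duplicates:
        n_before = len(df)
        means = df.mean(axis=1)
        # keep, per symbol, the row with the largest mean expression
        order = np.argsort(-means.to_numpy(), kind="stable")
        df = df.iloc[order]
        df = df[~df.index.duplicated(keep="first")]
        df = df.sort_index()
        logger.info("collapsed %d duplicate gene rows", n_before - len(df))
    return ExpressionMatrix(df.rename_axis(None), batch=batch)


def write_expression(matrix: ExpressionMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene")


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: one set per line, fields name, description, members."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, "
                    "need at least name, description and one member"
                )
            name, desc, *members = fields
            members = [m for m in members if m]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = members
            descriptions[name] = desc
    if not sets:
        raise ValueError(f"{path}: no gene sets found")
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_clinical(path) -> pd.DataFrame:
    df = _read_table(path)
    return validate_clinical(df)


def write_clinical(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_maf(path) -> pd.DataFrame:
    """Read a MAF; unknown variant classifications are preserved but flagged."""
    df = _read_table(path, comment="#")
    missing = [c for c in MAF_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: MAF missing required columns: {missing}")
    if df[list(MAF_REQUIRED_COLUMNS)].isna().any().any():
        raise ValueError(f"{path}: MAF contains empty required fields")
    unknown = set(df["Variant_Classification"]) - MAF_VARIANT_CLASSES
    if unknown:
        warnings.warn(
            f"MAF contains non-standard variant classifications: "
            f"{sorted(unknown)}", stacklevel=2,
        )
    return df


def write_maf(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_cnv(path) -> pd.DataFrame:
    """Read discrete gene × sample CNV calls in {-1, 0, +1}."""
    df = _read_table(path, index_col=0)
    return validate_cnv(df.astype(int).rename_axis(None))


def write_cnv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="gene")


def read_edges(path, min_score: float = 0.7) -> pd.DataFrame:
    """Read a protein-interaction edge list (gene_a, gene_b, score).

    Self-edges are dropped, the edge (a, b) is canonicalised with a < b and
    deduplicated keeping the maximum score, and only edges with
    score > ``min_score`` (strict, default 0.7) are retained.
    """
    df = _read_table(path)
    cols = list(df.columns[:3])
    df = df[cols].copy()
    df.columns = ["gene_a", "gene_b", "score"]
    df["score"] = pd.to_numeric(df["score"])
    if ((df["score"] < 0) | (df["score"] > 1)).any():
        raise ValueError(f"{path}: edge scores must lie in [0, 1]")
    df = df[df["gene_a"] != df["gene_b"]]
    a = df[["gene_a", "gene_b"]].min(axis=1)
    b = df[["gene_a", "gene_b"]].max(axis=1)
    df = pd.DataFrame({"gene_a": a, "gene_b": b, "score": df["score"]})
    df = (df.sort_values("score", ascending=False)
            .drop_duplicates(["gene_a", "gene_b"], keep="first"))
    df = df[df["score"] > min_score]
    return df.sort_values(["gene_a", "gene_b"]).reset_index(drop=True)


def write_edges(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_manifest(path, *, inputs: dict, parameters: dict, seed=None,
                   substitutions: tuple[str, ...] = ()) -> None:
    """Write a JSON run manifest recording inputs, parameters and versions."""
    import sklearn

    manifest = {
        "inputs": inputs,
        "parameters": parameters,
        "seed": seed,
        "substitutions": list(substitutions),
        "versions": {
            "cupscore": _package_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "sklearn": sklearn.__version__,
        },
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)


def _package_version() -> str:
    from importlib.metadata import PackageNotFoundError, version

    try:
        return version("cupscore")
    except PackageNotFoundError:  # editable/dev tree
        return "0.0.0.dev"
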