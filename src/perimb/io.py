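"""Readers and writers for the on-disk formats (TSV, Newick, JSON).

All pairs are lossless round trips on the fields they carry.  The feature
table is written features-as-rows / samples-as-columns (the common QIIME
export dialect); the reader accepts either orientation via an explicit flag.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    DistanceMatrix,
    FeatureTable,
    FormatError,
    RootedTree,
    SampleMetadata,
    Taxonomy,
)

__all__ = [
    "read_feature_table",
    "write_feature_table",
    "read_metadata",
    "write_metadata",
    "read_tree",
    "write_tree",
    "read_taxonomy",
    "write_taxonomy",
    "read_distance_matrix",
    "write_distance_matrix",
]

_ORIENTATIONS = ("samples_as_rows", "samples_as_columns")


def read_feature_table(path, orientation="samples_as_columns") -> FeatureTable:
    """Read a TSV count table; ``orientation`` names where samples live on disk."""
    if orientation not in _ORIENTATIONS:
        raise ValueError(f"orientation must be one of {_ORIENTATIONS}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    seen = set()
    for col in header:  # pandas would silently mangle duplicate columns
        if col in seen:
            raise FormatError(f"duplicate identifier in header: {col!r}")
        seen.add(col)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, comment=None)
    df.index = df.index.astype(str)
    try:
        body = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"non-numeric cell in feature table {path}: {exc}") from exc
    if orientation == "samples_as_columns":
        body = body.T
    arr = body.to_numpy()
    if arr.size and np.any(arr != np.floor(arr)):
        r, c = np.argwhere(arr != np.floor(arr))[0]
        raise FormatError(
            f"non-integer count at sample {body.index[r]!r}, feature {body.columns[c]!r}"
        )
    return FeatureTable(tuple(body.index), tuple(body.columns), arr.astype(np.int64))


def write_feature_table(table: FeatureTable, path, orientation="samples_as_columns"):
    if orientation not in _ORIENTATIONS:
        raise ValueError(f"orientation must be one of {_ORIENTATIONS}")
    df = table.to_dataframe()
    if orientation == "samples_as_columns":
        df = df.T
        df.index.name = "feature_id"
    else:
        df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_metadata(path, validate_twins=True) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.columns[0] in ("#SampleID", "sample_id", "sample-id", "#Sample ID"):
        df = df.rename(columns={df.columns[0]: "sample_id"})
    else:
        raise FormatError(
            f"first metadata column must be a sample-id column, got {df.columns[0]!r}"
        )
    if (df["sample_id"] == "").any():
        raise FormatError("metadata row without sample id")
    df = df.set_index("sample_id")
    df = df.replace({"": np.nan})
    for col in ("dna_concentration",):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col])
    for col in df.columns:
        if col in ("site", "subject_id", "family_id", "role", "batch",
                   "twin_pair_id", "chorionicity"):
            continue
        converted = pd.to_numeric(df[col], errors="coerce")
        if converted.notna().equals(df[col].notna()):
            df[col] = converted
    if "is_negative_control" in df.columns:
        df["is_negative_control"] = df["is_negative_control"].astype(float) > 0
    return SampleMetadata(df, validate_twins=validate_twins)


def write_metadata(metadata: SampleMetadata, path):
    df = metadata.df.copy()
    for col in df.columns:
        if df[col].dtype == bool:
            df[col] = df[col].astype(int)
    out = df.reset_index().rename(columns={"sample_id": "#SampleID"})
    out.to_csv(path, sep="\t", index=False)


def read_tree(path) -> RootedTree:
    text = Path(path).read_text()
    return RootedTree.from_newick(text)


def write_tree(tree: RootedTree, path):
    Path(path).write_text(tree.to_newick())


def read_taxonomy(path) -> Taxonomy:
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower().replace(" ", "_"): c for c in df.columns}
    fid_col = cols.get("feature_id") or cols.get("feature id") or df.columns[0]
    tax_col = cols.get("taxon") or cols.get("lineage") or df.columns[1]
    conf_col = cols.get("confidence")
    lineages = dict(zip(df[fid_col].astype(str), df[tax_col].astype(str)))
    confidences = {}
    if conf_col is not None:
        conf = pd.to_numeric(df[conf_col], errors="coerce")
        confidences = {
            str(f): (None if pd.isna(c) else float(c))
            for f, c in zip(df[fid_col], conf)
        }
    return Taxonomy(lineages, confidences)


def write_taxonomy(taxonomy: Taxonomy, path):
    rows = []
    for fid, lineage in taxonomy.items():
        conf = taxonomy.confidence(fid)
        rows.append({"Feature ID": fid, "Taxon": lineage,
                     "Confidence": "" if conf is None else conf})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_distance_matrix(path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if list(df.index) != list(df.columns):
        raise FormatError("distance matrix row and column labels disagree")
    return DistanceMatrix(tuple(df.index), df.to_numpy(dtype=float))


def write_distance_matrix(dm: DistanceMatrix, path):
    df = dm.to_dataframe()
    df.index.name = "sample_id"
    # repr-round-trip precision so read(write(dm)) == dm exactly
    df.to_csv(path, sep="\t", float_format="%.17g")


def write_json(obj, path):
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, tuple)):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
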