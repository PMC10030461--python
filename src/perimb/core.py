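"""Domain types for ASV-table analysis.

The objects here are deliberately thin: a validated integer count matrix
(:class:`FeatureTable`), per-sample metadata (:class:`SampleMetadata`), a
rooted phylogeny over features (:class:`RootedTree`), taxonomy lineage
assignments (:class:`Taxonomy`) and a symmetric :class:`DistanceMatrix`.
Every analysis stage consumes and produces these types; file formats live in
:mod:`perimb.io`.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

__all__ = [
    "FeatureTable",
    "SampleMetadata",
    "RootedTree",
    "Taxonomy",
    "DistanceMatrix",
    "FormatError",
    "SITES",
    "RANK_PREFIXES",
    "collapse_taxa",
]

#: Recognized body-site codes; ``NC`` marks negative controls.
SITES = ("VD", "AF", "CB", "GL", "M", "NC")

RANK_PREFIXES = ("d__", "p__", "c__", "o__", "f__", "g__", "s__")


class FormatError(ValueError):
    """Raised when an on-disk artifact violates its format contract."""


def _check_unique(ids, what):
    seen = set()
    for i in ids:
        if i in seen:
            raise FormatError(f"duplicate {what} identifier: {i!r}")
        seen.add(i)


@dataclass(frozen=True)
class FeatureTable:
    """Samples x features matrix of non-negative integer read counts."""

    sample_ids: tuple
    feature_ids: tuple
    counts: np.ndarray

    def __init__(self, sample_ids, feature_ids, counts):
        sample_ids = tuple(str(s) for s in sample_ids)
        feature_ids = tuple(str(f) for f in feature_ids)
        _check_unique(sample_ids, "sample")
        _check_unique(feature_ids, "feature")
        counts = np.asarray(counts)
        if counts.shape != (len(sample_ids), len(feature_ids)):
            raise FormatError(
                f"count matrix shape {counts.shape} does not match "
                f"{len(sample_ids)} samples x {len(feature_ids)} features"
            )
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.isfinite(counts)) or np.any(counts != np.floor(counts)):
                raise FormatError("counts must be integral")
            counts = counts.astype(np.int64)
        counts = counts.astype(np.int64, copy=False)
        if counts.size and counts.min() < 0:
            s, f = np.unravel_index(int(np.argmin(counts)), counts.shape)
            raise FormatError(
                f"negative count at sample {sample_ids[s]!r}, "
                f"feature {feature_ids[f]!r}"
            )
        counts = counts.copy()
        counts.setflags(write=False)
        object.__setattr__(self, "sample_ids", sample_ids)
        object.__setattr__(self, "feature_ids", feature_ids)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "_sidx", {s: i for i, s in enumerate(sample_ids)})
        object.__setattr__(self, "_fidx", {f: i for i, f in enumerate(feature_ids)})

    # -- lookups ----------------------------------------------------------
    @property
    def n_samples(self):
        return len(self.sample_ids)

    @property
    def n_features(self):
        return len(self.feature_ids)

    def sample_index(self, sample_id):
        try:
            return self._sidx[sample_id]
        except KeyError:
            raise KeyError(f"unknown sample id: {sample_id!r}") from None

    def feature_index(self, feature_id):
        try:
            return self._fidx[feature_id]
        except KeyError:
            raise KeyError(f"unknown feature id: {feature_id!r}") from None

    def sample_counts(self, sample_id):
        return self.counts[self.sample_index(sample_id)]

    def feature_counts(self, feature_id):
        return self.counts[:, self.feature_index(feature_id)]

    def totals(self):
        """Per-sample read totals, ordered like ``sample_ids``."""
        return self.counts.sum(axis=1)

    # -- subsetting -------------------------------------------------------
    def select_samples(self, sample_ids):
        idx = [self.sample_index(s) for s in sample_ids]
        return FeatureTable(tuple(sample_ids), self.feature_ids, self.counts[idx])

    def select_features(self, feature_ids):
        idx = [self.feature_index(f) for f in feature_ids]
        return FeatureTable(self.sample_ids, tuple(feature_ids), self.counts[:, idx])

    def drop_features(self, feature_ids):
        drop = set(feature_ids)
        keep = [f for f in self.feature_ids if f not in drop]
        return self.select_features(keep)

    def drop_empty_features(self):
        keep = [f for f, c in zip(self.feature_ids, self.counts.sum(axis=0)) if c > 0]
        return self.select_features(keep)

    def to_dataframe(self):
        return pd.DataFrame(
            self.counts, index=list(self.sample_ids), columns=list(self.feature_ids)
        )

    @classmethod
    def from_dataframe(cls, df):
        return cls(tuple(df.index), tuple(df.columns), df.to_numpy())

    def __eq__(self, other):
        if not isinstance(other, FeatureTable):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.feature_ids == other.feature_ids
            and np.array_equal(self.counts, other.counts)
        )


class SampleMetadata:
    """Per-sample metadata table (QIIME-style), indexed by sample id.

    Required column: ``site``.  Well-known optional columns: ``subject_id``,
    ``family_id``, ``role`` ({mother, neonate, control}), ``batch``,
    ``dna_concentration``, ``is_negative_control``, ``twin_pair_id``,
    ``chorionicity`` ({mono, di, none}).  Any further columns are treated as
    clinical covariates.
    """

    REQUIRED_COLUMNS = ("site",)

    def __init__(self, df: pd.DataFrame, validate_twins: bool = True):
        df = df.copy()
        df.index = df.index.astype(str)
        df.index.name = "sample_id"
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise FormatError(f"duplicate sample identifier: {dup!r}")
        for col in self.REQUIRED_COLUMNS:
            if col not in df.columns:
                raise FormatError(f"metadata is missing required column {col!r}")
        bad = set(df["site"]) - set(SITES)
        if bad:
            raise FormatError(f"unknown site value(s): {sorted(bad)}")
        if "is_negative_control" not in df.columns:
            df["is_negative_control"] = df["site"] == "NC"
        else:
            df["is_negative_control"] = df["is_negative_control"].astype(bool)
            mism = df["is_negative_control"] != (df["site"] == "NC")
            if mism.any():
                raise FormatError(
                    "is_negative_control must be true exactly for site NC; "
                    f"violated by sample {df.index[mism][0]!r}"
                )
        if "dna_concentration" in df.columns:
            df["dna_concentration"] = pd.to_numeric(df["dna_concentration"])
            if (df["dna_concentration"] <= 0).any():
                bad_id = df.index[df["dna_concentration"] <= 0][0]
                raise FormatError(
                    f"dna_concentration must be > 0 or missing (sample {bad_id!r})"
                )
        if validate_twins and {"twin_pair_id", "role", "subject_id"} <= set(df.columns):
            neo = df[(df["role"] == "neonate") & df["twin_pair_id"].notna()]
            neo = neo[neo["twin_pair_id"] != ""]
            for pair, grp in neo.groupby("twin_pair_id"):
                n = grp["subject_id"].nunique()
                if n != 2:
                    raise FormatError(
                        f"twin_pair_id {pair!r} has {n} neonate subjects, expected 2"
                    )
        self._df = df

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def sample_ids(self):
        return tuple(self._df.index)

    def __len__(self):
        return len(self._df)

    def __contains__(self, sample_id):
        return sample_id in self._df.index

    def for_samples(self, sample_ids) -> pd.DataFrame:
        """Rows for ``sample_ids`` in order; missing ids are an error."""
        missing = [s for s in sample_ids if s not in self._df.index]
        if missing:
            raise KeyError(f"samples without metadata: {missing[:5]}")
        return self._df.loc[list(sample_ids)]

    def __eq__(self, other):
        if not isinstance(other, SampleMetadata):
            return NotImplemented
        return self._df.equals(other._df)


class RootedTree:
    """Rooted phylogeny with branch lengths; leaf labels are feature ids."""

    def __init__(self, root: TreeNode):
        if root.parent is not None:
            raise FormatError("tree root must not have a parent")
        names = [t.name for t in root.tips()]
        if any(n is None for n in names):
            raise FormatError("every leaf must be labeled")
        _check_unique(names, "leaf")
        for node in root.traverse(include_self=False):
            if node.length is not None and node.length < 0:
                raise FormatError(f"negative branch length at node {node.name!r}")
        self._root = root

    @property
    def root(self) -> TreeNode:
        return self._root

    @property
    def leaf_names(self):
        return tuple(t.name for t in self._root.tips())

    @property
    def n_leaves(self):
        return len(self.leaf_names)

    def total_branch_length(self):
        return sum(
            n.length or 0.0 for n in self._root.traverse(include_self=False)
        )

    @classmethod
    def from_newick(cls, newick: str) -> "RootedTree":
        import warnings

        try:
            with warnings.catch_warnings():
                # suppress skbio's format-sniffing chatter on bad input;
                # the error below is the real signal
                warnings.simplefilter("ignore")
                root = TreeNode.read(_io.StringIO(newick), format="newick")
        except Exception as exc:  # skbio raises its own parse errors
            raise FormatError(f"malformed Newick: {exc}") from exc
        return cls(root)

    def to_newick(self) -> str:
        buf = _io.StringIO()
        self._root.write(buf, format="newick")
        return buf.getvalue()


class Taxonomy:
    """Mapping feature id -> (lineage string, optional confidence)."""

    def __init__(self, lineages: dict, confidences: dict | None = None):
        self._lineages = {}
        self._confidences = {}
        confidences = confidences or {}
        for fid, lineage in lineages.items():
            self._lineages[str(fid)] = self._validate_lineage(str(fid), lineage)
            conf = confidences.get(fid)
            if conf is not None and not (np.isnan(conf) or 0.0 <= conf <= 1.0):
                raise FormatError(f"confidence for {fid!r} outside [0, 1]: {conf}")
            self._confidences[str(fid)] = conf

    @staticmethod
    def _validate_lineage(fid, lineage):
        tokens = [t.strip() for t in str(lineage).split(";")]
        if len(tokens) > 7:
            raise FormatError(f"lineage for {fid!r} has more than 7 ranks")
        # rank prefixes, where present, must appear in canonical order
        for i, tok in enumerate(tokens):
            for j, pref in enumerate(RANK_PREFIXES):
                if tok.startswith(pref) and j != i:
                    raise FormatError(
                        f"lineage for {fid!r}: prefix {pref!r} at position {i}"
                    )
        return ";".join(tokens)

    def lineage(self, feature_id):
        try:
            return self._lineages[feature_id]
        except KeyError:
            raise KeyError(f"no taxonomy for feature {feature_id!r}") from None

    def confidence(self, feature_id):
        return self._confidences.get(feature_id)

    def tokens(self, feature_id):
        return self.lineage(feature_id).split(";")

    @property
    def feature_ids(self):
        return tuple(self._lineages)

    def __len__(self):
        return len(self._lineages)

    def __contains__(self, feature_id):
        return feature_id in self._lineages

    def items(self):
        return self._lineages.items()

    def __eq__(self, other):
        if not isinstance(other, Taxonomy):
            return NotImplemented
        return self._lineages == other._lineages


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric non-negative dissimilarity matrix with zero diagonal."""

    sample_ids: tuple
    data: np.ndarray
    _sidx: dict = field(repr=False, compare=False, default=None)

    def __init__(self, sample_ids, data):
        sample_ids = tuple(str(s) for s in sample_ids)
        _check_unique(sample_ids, "sample")
        data = np.asarray(data, dtype=float)
        n = len(sample_ids)
        if data.shape != (n, n):
            raise FormatError(f"distance matrix shape {data.shape}, expected ({n},{n})")
        if not np.allclose(data, data.T, atol=1e-12):
            raise FormatError("distance matrix is not symmetric")
        if not np.allclose(np.diag(data), 0.0, atol=1e-12):
            raise FormatError("distance matrix diagonal is not zero")
        if data.size and data.min() < -1e-12:
            raise FormatError("distance matrix has negative entries")
        data = np.clip((data + data.T) / 2.0, 0.0, None)
        np.fill_diagonal(data, 0.0)
        data.setflags(write=False)
        object.__setattr__(self, "sample_ids", sample_ids)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "_sidx", {s: i for i, s in enumerate(sample_ids)})

    @property
    def n_samples(self):
        return len(self.sample_ids)

    def between(self, a, b):
        try:
            return self.data[self._sidx[a], self._sidx[b]]
        except KeyError as exc:
            raise KeyError(f"unknown sample id: {exc.args[0]!r}") from None

    def submatrix(self, sample_ids):
        idx = [self._sidx[s] for s in sample_ids]
        return DistanceMatrix(tuple(sample_ids), self.data[np.ix_(idx, idx)])

    def condensed(self):
        """Upper-triangle distances as a flat vector (``pdist`` order)."""
        iu = np.triu_indices(self.n_samples, k=1)
        return self.data[iu]

    def to_dataframe(self):
        return pd.DataFrame(
            self.data, index=list(self.sample_ids), columns=list(self.sample_ids)
        )


def collapse_taxa(table: FeatureTable, taxonomy: Taxonomy, rank: int) -> FeatureTable:
    """Sum features whose lineages agree up to ``rank`` (1=domain .. 7=species).

    Per-sample totals are conserved exactly.  Collapsed feature ids are the
    truncated lineage strings.
    """
    if not 1 <= rank <= 7:
        raise ValueError(f"rank must be in 1..7, got {rank}")
    missing = [f for f in table.feature_ids if f not in taxonomy]
    if missing:
        raise KeyError(f"features without taxonomy: {missing[:5]}")
    groups: dict[str, list[int]] = {}
    for j, fid in enumerate(table.feature_ids):
        key = ";".join(taxonomy.tokens(fid)[:rank])
        groups.setdefault(key, []).append(j)
    new_ids = list(groups)
    new_counts = np.empty((table.n_samples, len(new_ids)), dtype=np.int64)
    for k, key in enumerate(new_ids):
        new_counts[:, k] = table.counts[:, groups[key]].sum(axis=1)
    return FeatureTable(table.sample_ids, tuple(new_ids), new_counts)
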