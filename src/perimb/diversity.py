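"""Rarefaction, alpha diversity, weighted UniFrac and PCoA."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .core import DistanceMatrix, FeatureTable, RootedTree
from .rng import substream

__all__ = [
    "rarefy",
    "shannon",
    "alpha_diversity",
    "weighted_unifrac",
    "pcoa",
    "rarefaction_curves",
    "PcoaResult",
]


def rarefy(table: FeatureTable, depth: int, seed: int = 0) -> FeatureTable:
    """Subsample each sample without replacement to exactly ``depth`` reads.

    Samples with fewer than ``depth`` total reads are dropped.  Each sample
    uses a sub-stream keyed by its id, so sample order is irrelevant.
    """
    depth = int(depth)
    if depth < 1:
        raise ValueError(f"depth must be >= 1, got {depth}")
    totals = table.totals()
    keep = []
    rows = []
    for i, sid in enumerate(table.sample_ids):
        if totals[i] < depth:
            continue
        keep.append(sid)
        if totals[i] == depth:
            rows.append(table.counts[i])
        else:
            rng = substream(seed, "rarefy", sid)
            rows.append(rng.multivariate_hypergeometric(table.counts[i], depth))
    counts = np.array(rows, dtype=np.int64) if rows else np.zeros(
        (0, table.n_features), dtype=np.int64)
    return FeatureTable(tuple(keep), table.feature_ids, counts)


def shannon(counts) -> float:
    """Shannon index in bits: H = -sum p_i log2 p_i over nonzero taxa."""
    c = np.asarray(counts, dtype=float)
    total = c.sum()
    if total <= 0:
        raise ValueError("Shannon index undefined for an all-zero sample")
    p = c[c > 0] / total
    return float(-(p * np.log2(p)).sum())


def alpha_diversity(table: FeatureTable) -> pd.DataFrame:
    """Per-sample Shannon (bits) and observed feature count."""
    rows = []
    for i, sid in enumerate(table.sample_ids):
        c = table.counts[i]
        rows.append({
            "sample_id": sid,
            "shannon": shannon(c),
            "observed_features": int((c > 0).sum()),
        })
    return pd.DataFrame(rows).set_index("sample_id")


def _branch_arrays(table: FeatureTable, tree: RootedTree):
    """Per-branch lengths and per-sample subtree read proportions.

    Returns (lengths, P) where P[b, s] is the fraction of sample s's reads
    on leaves descending branch b.
    """
    totals = table.totals()
    if np.any(totals == 0):
        bad = table.sample_ids[int(np.argmin(totals))]
        raise ValueError(f"sample {bad!r} has zero total reads")
    rel = table.counts / totals[:, None]
    leaf_set = {t.name for t in tree.root.tips()}
    nz = table.counts.sum(axis=0) > 0
    missing = [f for f, use in zip(table.feature_ids, nz) if use and f not in leaf_set]
    if missing:
        raise KeyError(f"feature(s) absent from tree: {missing[:5]}")
    fidx = {f: j for j, f in enumerate(table.feature_ids)}
    n = table.n_samples
    lengths = []
    props = []
    node_p = {}
    for node in tree.root.postorder(include_self=True):
        if node.is_tip():
            j = fidx.get(node.name)
            p = rel[:, j].copy() if j is not None else np.zeros(n)
        else:
            p = np.zeros(n)
            for child in node.children:
                p += node_p[id(child)]
        node_p[id(node)] = p
        if node.parent is not None:
            lengths.append(node.length or 0.0)
            props.append(p)
    return np.asarray(lengths), np.asarray(props)


def weighted_unifrac(table: FeatureTable, tree: RootedTree,
                     normalized: bool = False) -> DistanceMatrix:
    """Weighted UniFrac between all sample pairs.

    Raw form: d(A,B) = sum_b l_b |p_A(b) - p_B(b)|; the normalized variant
    divides by sum_b l_b (p_A(b) + p_B(b)).
    """
    lengths, props = _branch_arrays(table, tree)
    X = (props * lengths[:, None]).T  # samples x branches, weighted
    d = pdist(X, metric="cityblock")
    if normalized:
        s = X.sum(axis=1)
        iu = np.triu_indices(table.n_samples, k=1)
        denom = s[iu[0]] + s[iu[1]]
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(denom > 0, d / denom, 0.0)
    return DistanceMatrix(table.sample_ids, squareform(d))


@dataclass
class PcoaResult:
    sample_ids: tuple
    coordinates: np.ndarray        # samples x kept axes
    eigenvalues: np.ndarray        # positive, non-increasing
    proportion_explained: np.ndarray
    negative_eigenvalues: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        cols = [f"PC{k + 1}" for k in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=list(self.sample_ids),
                            columns=cols)


def pcoa(dm: DistanceMatrix, eig_tol: float = 1e-10) -> PcoaResult:
    """Classic metric MDS: Gower-center the squared distances, eigendecompose.

    Negative eigenvalues are dropped from the embedding but reported.
    """
    D = dm.data
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D * D) @ J
    B = (B + B.T) / 2
    w, V = np.linalg.eigh(B)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    scale = max(abs(w[0]), 1.0) if n else 1.0
    pos = w > eig_tol * scale
    neg = w < -eig_tol * scale
    wp = w[pos]
    coords = V[:, pos] * np.sqrt(wp)
    prop = wp / wp.sum() if wp.size else wp
    return PcoaResult(
        sample_ids=dm.sample_ids,
        coordinates=coords,
        eigenvalues=wp,
        proportion_explained=prop,
        negative_eigenvalues=w[neg],
    )


def rarefaction_curves(table: FeatureTable, depths, iterations: int = 10,
                       seed: int = 0) -> pd.DataFrame:
    """Mean observed-feature count per sample at each depth.

    Depths at or above a sample's total report its full richness (the curve
    plateau).  Within one iteration the subsamples are nested (prefixes of a
    single shuffled read vector), so every per-sample curve is monotone
    non-decreasing by construction.
    """
    depths = sorted(int(d) for d in depths)
    if not depths:
        raise ValueError("depth grid is empty")
    if any(d < 1 for d in depths):
        raise ValueError("depths must be >= 1")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    totals = table.totals()
    out = {}
    for i, sid in enumerate(table.sample_ids):
        counts = table.counts[i]
        richness = int((counts > 0).sum())
        rng = substream(seed, "rarefaction-curve", sid)
        reads = np.repeat(np.arange(table.n_features), counts)
        acc = np.zeros(len(depths))
        for _ in range(iterations):
            shuffled = rng.permutation(reads)
            for k, d in enumerate(depths):
                if d >= totals[i]:
                    acc[k] += richness
                else:
                    acc[k] += len(np.unique(shuffled[:d]))
        out[sid] = acc / iterations
    return pd.DataFrame(out, index=depths).T.rename_axis("sample_id")
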