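"""Batch-effect diagnostics and contaminant identification.

Contaminant evidence is scored per feature and per sequencing batch:

* ``frequency_score`` — does a feature's relative frequency scale inversely
  with sample DNA concentration?  Compared via the residual sums of squares
  of log-frequency on log-concentration under a fixed slope of -1
  (contaminant) versus slope 0 (genuine); the score is the lower tail of
  their ratio under F(n-1, n-1).  Small means contaminant-like.
* ``prevalence_score`` — is the feature enriched in negative controls?
  One-sided Fisher exact probability from the presence/absence x {NC, true
  sample} table.  Small means contaminant-like.

``classify_contaminants`` combines the two (Fisher's method, df=4), flags a
feature when its score drops below the threshold in any batch or when it is
present in at least half the negative controls of a batch, and returns the
filtered table with flagged features and NC samples removed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score

from .core import FeatureTable, SampleMetadata

__all__ = [
    "clr_transform",
    "detect_batch_effects",
    "frequency_score",
    "prevalence_score",
    "classify_contaminants",
    "BatchDiagnostics",
    "ContaminantReport",
]


def clr_transform(table: FeatureTable, pseudocount: float = 1.0) -> pd.DataFrame:
    """Centered log-ratio of counts + pseudocount; each row sums to zero."""
    if pseudocount <= 0:
        raise ValueError(f"pseudocount must be > 0, got {pseudocount}")
    if table.n_samples == 0 or table.n_features == 0:
        raise ValueError("cannot CLR-transform an empty table")
    logs = np.log(table.counts + float(pseudocount))
    clr = logs - logs.mean(axis=1, keepdims=True)
    return pd.DataFrame(clr, index=list(table.sample_ids),
                        columns=list(table.feature_ids))


@dataclass
class BatchDiagnostics:
    correlation: pd.DataFrame        # sample x sample Pearson r
    merges: np.ndarray               # scipy linkage matrix
    cluster_labels: pd.Series        # k-cut assignment, k = #batches
    ari_batch: float
    ari_site: float
    excluded_samples: list


def detect_batch_effects(table: FeatureTable, metadata: SampleMetadata,
                         pseudocount: float = 1.0,
                         linkage_method: str = "average") -> BatchDiagnostics:
    """Correlation heat-map ingredients + cluster/batch agreement.

    CLR rows are correlated (Pearson), clustered agglomeratively on 1 - r,
    and the dendrogram is cut at k = number of batches; agreement of the cut
    with batch labels and with site labels is reported as adjusted Rand
    indices.
    """
    md = metadata.for_samples(table.sample_ids)
    batches = md["batch"].astype(str)
    if batches.nunique() < 2:
        raise ValueError("batch-effect detection requires >= 2 batches")
    totals = table.totals()
    excluded = [s for s, t in zip(table.sample_ids, totals) if t == 0]
    if excluded:
        warnings.warn(
            f"excluding {len(excluded)} zero-total sample(s) from "
            f"batch diagnostics: {excluded[:5]}")
        keep = [s for s in table.sample_ids if s not in set(excluded)]
        table = table.select_samples(keep)
        md = md.loc[keep]
        batches = md["batch"].astype(str)
    clr = clr_transform(table, pseudocount)
    corr = np.corrcoef(clr.to_numpy())
    corr = np.clip((corr + corr.T) / 2, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    merges = linkage(squareform(dist, checks=False), method=linkage_method)
    k = batches.nunique()
    labels = fcluster(merges, t=k, criterion="maxclust")
    ari_batch = adjusted_rand_score(batches.to_numpy(), labels)
    ari_site = adjusted_rand_score(md["site"].astype(str).to_numpy(), labels)
    ids = list(table.sample_ids)
    return BatchDiagnostics(
        correlation=pd.DataFrame(corr, index=ids, columns=ids),
        merges=merges,
        cluster_labels=pd.Series(labels, index=ids, name="cluster"),
        ari_batch=float(ari_batch),
        ari_site=float(ari_site),
        excluded_samples=excluded,
    )


def frequency_score(frequencies, concentrations, min_samples: int = 5) -> float:
    """Lower-tail F probability that frequency tracks 1/concentration.

    Only samples where the feature occurs (frequency > 0) and concentration
    is known enter the fit; fewer than ``min_samples`` such samples gives a
    missing score (NaN).
    """
    f = np.asarray(frequencies, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    ok = np.isfinite(c) & (c > 0) & np.isfinite(f) & (f > 0)
    if ok.sum() < min_samples:
        return float("nan")
    y = np.log(f[ok])
    x = np.log(c[ok])
    n = ok.sum()
    # contaminant model: y = -x + b  ->  residuals of (y + x) about its mean
    r_cont = (y + x) - (y + x).mean()
    ssr_cont = float(r_cont @ r_cont)
    # non-contaminant model: y = b
    r_non = y - y.mean()
    ssr_non = float(r_non @ r_non)
    if ssr_non == 0.0:
        return 0.5 if ssr_cont == 0.0 else 1.0
    F = ssr_cont / ssr_non
    return float(stats.f.cdf(F, n - 1, n - 1))


def prevalence_score(present_nc: int, total_nc: int,
                     present_true: int, total_true: int) -> float:
    """One-sided Fisher exact probability of enrichment in negative controls."""
    if total_nc < 1:
        return float("nan")
    if present_nc == 0 and present_true == 0:
        return float("nan")
    table = [[present_nc, total_nc - present_nc],
             [present_true, total_true - present_true]]
    return float(stats.fisher_exact(table, alternative="greater")[1])


def _combine_scores(p_freq: float, p_prev: float) -> float:
    """Fisher's method (chi2 with df=4, upper tail) where both exist."""
    have_f = np.isfinite(p_freq)
    have_p = np.isfinite(p_prev)
    if have_f and have_p:
        chi2 = -2.0 * (np.log(max(p_freq, 1e-300)) + np.log(max(p_prev, 1e-300)))
        return float(stats.chi2.sf(chi2, df=4))
    if have_f:
        return float(p_freq)
    if have_p:
        return float(p_prev)
    return float("nan")


@dataclass
class ContaminantReport:
    scores: pd.DataFrame             # (feature, batch) rows: freq/prev/combined
    flagged: tuple                   # feature ids flagged as contaminants
    n_removed: int
    filtered_table: FeatureTable
    method: str
    threshold: float


def classify_contaminants(table: FeatureTable, metadata: SampleMetadata,
                          threshold: float = 0.1, method: str = "combined",
                          nc_prevalence_cutoff: float = 0.5,
                          min_samples: int = 5) -> ContaminantReport:
    """Score every feature per batch and remove those called contaminants.

    A feature is flagged when its ``method`` score is below ``threshold`` in
    at least one batch, or when it is present in at least
    ``nc_prevalence_cutoff`` of a batch's negative controls.  The filtered
    table drops flagged features and all negative-control samples.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    if method not in ("frequency", "prevalence", "combined"):
        raise ValueError(f"unknown method {method!r}")
    md = metadata.for_samples(table.sample_ids)
    if "batch" not in md.columns:
        raise ValueError("metadata must provide a 'batch' column")
    batches = md["batch"].astype(str)
    is_nc = md["is_negative_control"].to_numpy(dtype=bool)
    conc = (md["dna_concentration"].to_numpy(dtype=float)
            if "dna_concentration" in md.columns
            else np.full(len(md), np.nan))
    counts = table.counts.astype(float)
    totals = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = np.where(totals[:, None] > 0, counts / totals[:, None], 0.0)

    rows = []
    flagged = set()
    for bname in sorted(batches.unique()):
        in_batch = (batches == bname).to_numpy()
        true_mask = in_batch & ~is_nc
        nc_mask = in_batch & is_nc
        n_true = int(true_mask.sum())
        n_nc = int(nc_mask.sum())
        present = counts > 0
        for j, fid in enumerate(table.feature_ids):
            p_freq = frequency_score(freqs[true_mask, j], conc[true_mask],
                                     min_samples=min_samples)
            if n_nc >= 1:
                p_prev = prevalence_score(int(present[nc_mask, j].sum()), n_nc,
                                          int(present[true_mask, j].sum()), n_true)
            else:
                p_prev = float("nan")
            p_comb = _combine_scores(p_freq, p_prev)
            score = {"frequency": p_freq, "prevalence": p_prev,
                     "combined": p_comb}[method]
            nc_prev = (present[nc_mask, j].sum() / n_nc) if n_nc else 0.0
            by_score = np.isfinite(score) and score < threshold
            by_nc = n_nc > 0 and nc_prev >= nc_prevalence_cutoff
            if by_score or by_nc:
                flagged.add(fid)
            rows.append({
                "feature_id": fid, "batch": bname,
                "freq_score": p_freq, "prev_score": p_prev,
                "combined_score": p_comb, "nc_prevalence": float(nc_prev),
                "flagged_by_score": bool(by_score),
                "flagged_by_nc_prevalence": bool(by_nc),
            })

    scores = pd.DataFrame(rows)
    scores["is_contaminant"] = scores["feature_id"].isin(flagged)
    flagged_tuple = tuple(f for f in table.feature_ids if f in flagged)
    filtered = table.drop_features(flagged_tuple)
    keep_samples = [s for s, nc in zip(table.sample_ids, is_nc) if not nc]
    filtered = filtered.select_samples(keep_samples)
    return ContaminantReport(
        scores=scores, flagged=flagged_tuple, n_removed=len(flagged_tuple),
        filtered_table=filtered, method=method, threshold=threshold,
    )
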