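"""Community-level statistics: PERMANOVA, ANCOM, target screen, clinical summary.

PERMANOVA here is the multi-term, sequential (Type I) variant: terms are
partitioned in the order given, so R-squared values depend on term order —
callers supplying several covariates should order them deliberately.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import DistanceMatrix, FeatureTable, SampleMetadata, Taxonomy
from .rng import substream

__all__ = [
    "permanova",
    "PermanovaResult",
    "ancom",
    "AncomResult",
    "screen_targets",
    "ScreenResult",
    "summarize_clinical",
    "proportion_summary",
    "DEFAULT_SCREEN_TARGETS",
]


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

@dataclass
class PermanovaResult:
    terms: list                     # ordered term names
    df: dict                        # term -> degrees of freedom (+ Residuals)
    ss: dict                        # term -> sum of squares
    r2: dict                        # term -> R^2 (+ Residuals, Total)
    f: dict                         # term -> pseudo-F
    p: dict                         # term -> permutation p-value
    n_permutations: int
    exact: bool

    def to_dict(self):
        return {
            "terms": self.terms,
            "df": self.df, "ss": self.ss, "r2": self.r2,
            "f": self.f, "p": self.p,
            "n_permutations": self.n_permutations, "exact": self.exact,
        }


def _design_columns(series: pd.Series, term: str) -> np.ndarray:
    """Covariate -> centered design columns (dummies for categoricals)."""
    if series.isna().any():
        raise ValueError(f"term {term!r} has missing values")
    if series.dtype == object or series.dtype.name in ("category", "bool"):
        dummies = pd.get_dummies(series.astype(str), drop_first=True)
        X = dummies.to_numpy(dtype=float)
    else:
        X = series.to_numpy(dtype=float)[:, None]
    return X - X.mean(axis=0)


def _hat(X: np.ndarray) -> np.ndarray:
    return X @ np.linalg.pinv(X)


def permanova(dm: DistanceMatrix, metadata, terms, n_permutations: int = 999,
              seed: int = 0, exact: bool = False) -> PermanovaResult:
    """Sequential multi-term PERMANOVA on a distance matrix.

    Sums of squares are partitioned in the listed term order via traces of
    nested projection matrices against the Gower-centered inner-product
    matrix.  P-values permute whole sample rows: Monte Carlo estimates use
    ``(1 + #{F_perm >= F_obs}) / (1 + n_permutations)`` and are never zero;
    ``exact=True`` enumerates all n! permutations instead (identity
    included), for small n.
    """
    md = metadata.df if isinstance(metadata, SampleMetadata) else metadata
    missing = [s for s in dm.sample_ids if s not in md.index]
    if missing:
        raise KeyError(f"samples without metadata: {missing[:5]}")
    md = md.loc[list(dm.sample_ids)]
    terms = list(terms)
    if not terms:
        raise ValueError("need at least one model term")
    n = dm.n_samples
    D = dm.data
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ (D * D) @ J
    ss_total = float(np.trace(G))

    ones = np.ones((n, 1))
    X = ones
    rank_prev = 1
    hats = [_hat(X)]
    dfs = []
    for term in terms:
        if term not in md.columns:
            raise KeyError(f"metadata has no column {term!r}")
        X = np.hstack([X, _design_columns(md[term], term)])
        rank = np.linalg.matrix_rank(X)
        df_term = rank - rank_prev
        if df_term == 0:
            raise ValueError(
                f"term {term!r} is collinear with earlier terms (adds no df)")
        dfs.append(df_term)
        rank_prev = rank
        hats.append(_hat(X))
    df_resid = n - rank_prev
    if df_resid <= 0:
        raise ValueError("model exhausts all degrees of freedom")

    def _partition(Gm):
        tr = [float((H * Gm).sum()) for H in hats]  # tr(H G), H symmetric
        ss = [tr[k + 1] - tr[k] for k in range(len(terms))]
        ss_res = float(np.trace(Gm)) - tr[-1]
        return ss, ss_res

    ss_terms, ss_res = _partition(G)
    f_obs = [
        (ss_terms[k] / dfs[k]) / (ss_res / df_resid)
        for k in range(len(terms))
    ]

    counts = np.zeros(len(terms))
    if exact:
        total = 0
        for perm in itertools.permutations(range(n)):
            Gp = G[np.ix_(perm, perm)]
            ssp, ssr = _partition(Gp)
            for k in range(len(terms)):
                fp = (ssp[k] / dfs[k]) / (ssr / df_resid)
                if fp >= f_obs[k] - 1e-12:
                    counts[k] += 1
            total += 1
        pvals = counts / total
        n_done = total
    else:
        if n_permutations < 99:
            raise ValueError("n_permutations must be >= 99")
        rng = substream(seed, "permanova")
        for _ in range(n_permutations):
            perm = rng.permutation(n)
            Gp = G[np.ix_(perm, perm)]
            ssp, ssr = _partition(Gp)
            for k in range(len(terms)):
                fp = (ssp[k] / dfs[k]) / (ssr / df_resid)
                if fp >= f_obs[k] - 1e-12:
                    counts[k] += 1
        pvals = (1.0 + counts) / (1.0 + n_permutations)
        n_done = n_permutations

    r2 = {t: ss_terms[k] / ss_total for k, t in enumerate(terms)}
    r2["Residuals"] = ss_res / ss_total
    r2["Total"] = 1.0
    return PermanovaResult(
        terms=terms,
        df={**{t: dfs[k] for k, t in enumerate(terms)}, "Residuals": df_resid},
        ss={**{t: ss_terms[k] for k, t in enumerate(terms)},
            "Residuals": ss_res, "Total": ss_total},
        r2=r2,
        f={t: f_obs[k] for k, t in enumerate(terms)},
        p={t: float(pvals[k]) for k, t in enumerate(terms)},
        n_permutations=n_done,
        exact=exact,
    )


# ---------------------------------------------------------------------------
# ANCOM
# ---------------------------------------------------------------------------

@dataclass
class AncomResult:
    table: pd.DataFrame             # per taxon: W, reject, direction
    cutoff: int                     # minimum W for rejection
    group_sizes: dict
    low_w_artifact: bool            # all-zero W with tiny groups

    @property
    def w(self) -> pd.Series:
        return self.table["W"]

    def rejected(self):
        return list(self.table.index[self.table["reject"]])


def ancom(table: FeatureTable, metadata, group: str, alpha: float = 0.05,
          cutoff_fraction: float = 0.7, test: str = "anova",
          pseudocount: float = 1.0) -> AncomResult:
    """Classic ANCOM W statistic over pairwise log-ratios.

    For every ordered taxon pair (i, j) the log-ratio
    ``log((x_i + pc) / (x_j + pc))`` is tested across groups (one-way ANOVA
    by default, Mann-Whitney via ``test='mannwhitney'`` for two groups);
    Benjamini-Hochberg adjustment is applied within each taxon's m-1 tests
    and W_i counts adjusted p-values below ``alpha``.  A taxon is rejected
    when W_i >= cutoff_fraction * (m - 1).
    """
    md = metadata.df if isinstance(metadata, SampleMetadata) else metadata
    md = md.loc[list(table.sample_ids)]
    if group not in md.columns:
        raise KeyError(f"metadata has no column {group!r}")
    labels = md[group]
    if labels.isna().any():
        raise ValueError(f"group column {group!r} has missing values")
    labels = labels.astype(str)
    groups = sorted(labels.unique())
    if len(groups) < 2:
        raise ValueError("ANCOM needs >= 2 groups")
    group_idx = {g: np.flatnonzero((labels == g).to_numpy()) for g in groups}
    sizes = {g: len(ix) for g, ix in group_idx.items()}
    if min(sizes.values()) < 2:
        small = min(sizes, key=sizes.get)
        raise ValueError(f"group {small!r} has fewer than 2 samples")
    if test not in ("anova", "mannwhitney"):
        raise ValueError(f"unknown test {test!r}")
    if test == "mannwhitney" and len(groups) != 2:
        raise ValueError("mannwhitney requires exactly 2 groups")

    m = table.n_features
    if m < 2:
        raise ValueError("ANCOM needs >= 2 taxa")
    L = np.log(table.counts + float(pseudocount))

    W = np.zeros(m, dtype=int)
    for i in range(m):
        ratios = L[:, i][:, None] - L  # n x m, column j = log(x_i/x_j)
        ratios = np.delete(ratios, i, axis=1)
        if test == "anova":
            res = sps.f_oneway(*(ratios[group_idx[g]] for g in groups), axis=0)
            pvals = np.asarray(res.pvalue)
        else:
            g1, g2 = groups
            res = sps.mannwhitneyu(ratios[group_idx[g1]], ratios[group_idx[g2]],
                                   axis=0)
            pvals = np.asarray(res.pvalue)
        pvals = np.where(np.isfinite(pvals), pvals, 1.0)
        adj = sps.false_discovery_control(pvals, method="bh")
        W[i] = int((adj < alpha).sum())

    cutoff = int(np.ceil(cutoff_fraction * (m - 1)))
    reject = W >= cutoff

    # direction: group with highest mean CLR
    clr = L - L.mean(axis=1, keepdims=True)
    group_means = {g: clr[group_idx[g]].mean(axis=0) for g in groups}
    stacked = np.vstack([group_means[g] for g in groups])
    direction = [groups[k] for k in np.argmax(stacked, axis=0)]

    low_w = bool((W == 0).all() and min(sizes.values()) < 5)
    if low_w:
        warnings.warn(
            "all W scores are zero with very small groups; "
            "results are likely artifacts")
    out = pd.DataFrame({
        "W": W, "reject": reject, "direction": direction,
    }, index=list(table.feature_ids)).rename_axis("taxon")
    return AncomResult(table=out, cutoff=cutoff, group_sizes=sizes,
                       low_w_artifact=low_w)


# ---------------------------------------------------------------------------
# Vaginal-health target screen
# ---------------------------------------------------------------------------

#: Shipped default: only taxa named in the source assay description.
DEFAULT_SCREEN_TARGETS = (
    "Lactobacillus", "Sneathia", "Gardnerella", "Aerococcus", "Fusobacterium",
    "Peptoniphilus", "Porphyromonas", "Prevotella",
    "Lactobacillus iners", "Lactobacillus jensenii", "Lactobacillus crispatus",
)


@dataclass
class ScreenResult:
    abundances: pd.DataFrame        # samples x targets, relative abundance
    detected: dict                  # target -> bool

    @property
    def n_detected(self) -> int:
        return int(sum(self.detected.values()))


def _matches_target(tokens, target: str) -> bool:
    parts = target.split()
    if len(parts) >= 2:  # species target, e.g. "Lactobacillus iners"
        want = "_".join(parts)
        for tok in tokens:
            if tok.startswith("s__"):
                name = tok[3:]
                if name == want or name == parts[-1] or name.replace("_", " ") == target:
                    return True
                # lineage may carry genus in g__ and bare species epithet in s__
        for tok in tokens:
            if tok.startswith("g__") and tok[3:] == parts[0]:
                for tok2 in tokens:
                    if tok2.startswith("s__") and parts[-1] in tok2[3:]:
                        return True
        return False
    for tok in tokens:
        if tok.startswith("g__") and tok[3:] == target:
            return True
    return False


def screen_targets(table: FeatureTable, taxonomy: Taxonomy, targets=None
                   ) -> ScreenResult:
    """Relative abundance of genus/species targets; detected if ever nonzero."""
    targets = list(DEFAULT_SCREEN_TARGETS if targets is None else targets)
    if not targets:
        raise ValueError("target list is empty")
    missing = [f for f in table.feature_ids if f not in taxonomy]
    if missing:
        raise KeyError(f"features without taxonomy: {missing[:5]}")
    totals = table.totals().astype(float)
    abund = pd.DataFrame(0.0, index=list(table.sample_ids), columns=targets)
    token_cache = {f: taxonomy.tokens(f) for f in table.feature_ids}
    for target in targets:
        cols = [j for j, f in enumerate(table.feature_ids)
                if _matches_target(token_cache[f], target)]
        if cols:
            with np.errstate(invalid="ignore", divide="ignore"):
                frac = np.where(totals > 0,
                                table.counts[:, cols].sum(axis=1) / totals, 0.0)
            abund[target] = frac
    detected = {t: bool((abund[t] > 0).any()) for t in targets}
    return ScreenResult(abundances=abund, detected=detected)


# ---------------------------------------------------------------------------
# Clinical summary
# ---------------------------------------------------------------------------

def proportion_summary(numerator: int, denominator: int) -> dict:
    """Percentage (one decimal) with counts echoed, Table-1 style."""
    if denominator == 0:
        raise ZeroDivisionError("zero denominator in proportion summary")
    pct = round(100.0 * numerator / denominator, 1)
    return {"percent": pct, "counts": f"{numerator}/{denominator}",
            "numerator": int(numerator), "denominator": int(denominator)}


def summarize_clinical(metadata, variables: dict) -> list:
    """Summarize covariates: continuous -> median (IQR); categorical -> %.

    ``variables`` maps column name to ``"continuous"`` or ``"categorical"``.
    Missing values are excluded from denominators.  Categorical variables
    are summarized as the percentage of truthy values (non-zero numbers, or
    the lexicographically last level for two-level strings, reported
    explicitly).
    """
    md = metadata.df if isinstance(metadata, SampleMetadata) else metadata
    rows = []
    for var, kind in variables.items():
        if var not in md.columns:
            raise KeyError(f"metadata has no column {var!r}")
        series = md[var].dropna()
        if kind == "continuous":
            values = pd.to_numeric(series)
            q25, q50, q75 = np.percentile(values, [25, 50, 75])
            rows.append({
                "variable": var, "kind": "continuous",
                "median": float(q50), "iqr_low": float(q25),
                "iqr_high": float(q75),
                "summary": f"{q50:g} ({q25:g}-{q75:g})",
            })
        elif kind == "categorical":
            if series.dtype == object:
                levels = sorted(series.astype(str).unique())
                level = levels[-1]
                num = int((series.astype(str) == level).sum())
            else:
                level = None
                num = int((pd.to_numeric(series) != 0).sum())
            summ = proportion_summary(num, len(series))
            rows.append({
                "variable": var, "kind": "categorical", "level": level,
                **summ,
                "summary": f"{summ['percent']}% ({summ['counts']})",
            })
        else:
            raise ValueError(f"unknown variable kind {kind!r} for {var!r}")
    return rows
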