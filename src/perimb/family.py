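"""Resampling tests of family structure.

* ``twin_bootstrap_test`` — is the mean pairwise distance between co-twin
  samples of one sample type smaller than expected?  The null reference is a
  bootstrap of means of distances drawn with replacement from all pairwise
  distances of that sample type; the observed twin mean is compared against
  a t-based confidence interval over the bootstrap means (one-sided: reject
  only when the twins are MORE similar than the interval allows).
* ``shared_asv_test`` — do mothers share more ASVs (presence/absence) with
  their own neonates than with neonates from other families?  One-tailed
  Welch t-test of true-pair shared counts against randomly drawn
  cross-family pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .core import DistanceMatrix, FeatureTable, SampleMetadata
from .rng import substream

__all__ = ["twin_bootstrap_test", "TwinTestResult",
           "shared_asv_test", "SharedAsvTestResult"]


@dataclass
class TwinTestResult:
    stratum: str                      # all | mono | di
    observed_twin_mean: float | None
    ci_low: float | None
    ci_high: float | None
    n_twin_pairs: int
    n_bootstrap: int
    confidence: float
    reject: bool | None               # None when underpowered
    warning: str | None = None

    def to_dict(self):
        return {
            "stratum": self.stratum,
            "observed_twin_mean": self.observed_twin_mean,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "n_twin_pairs": self.n_twin_pairs,
            "n_bootstrap": self.n_bootstrap,
            "confidence": self.confidence,
            "reject": self.reject, "warning": self.warning,
        }


def twin_bootstrap_test(dm: DistanceMatrix, metadata, stratum: str = "all",
                        n_bootstrap: int = 1000, confidence: float = 0.95,
                        seed: int = 0,
                        exclude_twin_pairs_from_pool: bool = False,
                        method: str = "t") -> TwinTestResult:
    """Bootstrap test of twin-pair similarity within one sample type.

    ``dm`` must hold the samples of a single sample type.  Eligible pairs
    are twin pairs (optionally restricted by chorionicity) with both
    members' samples present in ``dm``.  Each bootstrap replicate draws
    ``n_twin_pairs`` distances with replacement from the pool of all
    pairwise distances and records their mean; the CI is
    ``mean +- t_{(1+conf)/2, B-1} * sd`` over the bootstrap means
    (``method='percentile'`` uses the empirical quantiles instead).
    Rejection is one-sided: observed twin mean below the lower CI bound.
    """
    if stratum not in ("all", "mono", "di"):
        raise ValueError(f"stratum must be all/mono/di, got {stratum!r}")
    if n_bootstrap < 100:
        raise ValueError("n_bootstrap must be >= 100")
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must be in (0, 1)")
    md = metadata.df if isinstance(metadata, SampleMetadata) else metadata
    present = [s for s in dm.sample_ids if s in md.index]
    md = md.loc[present]

    neo = md[(md.get("role") == "neonate") & md["twin_pair_id"].notna()]
    if stratum != "all":
        neo = neo[neo["chorionicity"] == stratum]
    pairs = []
    for pair_id, grp in neo.groupby("twin_pair_id"):
        # one sample per subject within a single-sample-type matrix
        by_subject = grp.groupby("subject_id").head(1)
        if len(by_subject) == 2:
            a, b = by_subject.index
            pairs.append((a, b))
    n_pairs = len(pairs)
    if n_pairs < 2:
        msg = (f"only {n_pairs} eligible twin pair(s) in stratum "
               f"{stratum!r}; test is underpowered")
        warnings.warn(msg)
        return TwinTestResult(
            stratum=stratum, observed_twin_mean=None, ci_low=None,
            ci_high=None, n_twin_pairs=n_pairs, n_bootstrap=n_bootstrap,
            confidence=confidence, reject=None, warning=msg)

    observed = float(np.mean([dm.between(a, b) for a, b in pairs]))
    pool = dm.condensed()
    if exclude_twin_pairs_from_pool:
        twin_d = {tuple(sorted(p)) for p in pairs}
        ids = dm.sample_ids
        keep = []
        k = 0
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                if tuple(sorted((ids[i], ids[j]))) not in twin_d:
                    keep.append(k)
                k += 1
        pool = pool[keep]
    rng = substream(seed, "twin-bootstrap", stratum)
    draws = rng.choice(pool, size=(n_bootstrap, n_pairs), replace=True)
    boot_means = draws.mean(axis=1)
    if method == "t":
        m = float(boot_means.mean())
        s = float(boot_means.std(ddof=1))
        tcrit = float(sps.t.ppf((1 + confidence) / 2, n_bootstrap - 1))
        ci_low, ci_high = m - tcrit * s, m + tcrit * s
    elif method == "percentile":
        lo = (1 - confidence) / 2
        ci_low, ci_high = (float(np.quantile(boot_means, lo)),
                           float(np.quantile(boot_means, 1 - lo)))
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return TwinTestResult(
        stratum=stratum, observed_twin_mean=observed,
        ci_low=ci_low, ci_high=ci_high, n_twin_pairs=n_pairs,
        n_bootstrap=n_bootstrap, confidence=confidence,
        reject=bool(observed < ci_low), warning=None)


@dataclass
class SharedAsvTestResult:
    mean_true_pairs: float
    mean_random_pairs: float
    n_true: int
    n_random: int
    p_value: float
    alternative: str = "greater"
    degenerate_variance: bool = False

    def to_dict(self):
        return {
            "mean_true_pairs": self.mean_true_pairs,
            "mean_random_pairs": self.mean_random_pairs,
            "n_true": self.n_true, "n_random": self.n_random,
            "p_value": self.p_value, "alternative": self.alternative,
            "degenerate_variance": self.degenerate_variance,
        }


def shared_asv_test(table: FeatureTable, metadata, n_random_pairs: int = 1000,
                    seed: int = 0, mother_sites=("VD", "AF"),
                    neonate_sites=("CB", "GL", "M")) -> SharedAsvTestResult:
    """Shared-ASV comparison: own-neonate pairs vs random cross-family pairs.

    A subject's presence set is the union of features with nonzero counts
    over its listed sites; counts themselves are ignored.  Random pairs are
    drawn with replacement, mother and neonate always from different
    families.  One-tailed Welch t-test, alternative: true pairs share more.
    """
    md = metadata.df if isinstance(metadata, SampleMetadata) else metadata
    present = [s for s in table.sample_ids if s in md.index]
    md = md.loc[present]

    def _presence_sets(role, sites):
        sets = {}
        fams = {}
        sub = md[(md["role"] == role) & md["site"].isin(sites)]
        for subject, grp in sub.groupby("subject_id"):
            mask = np.zeros(table.n_features, dtype=bool)
            for sid in grp.index:
                mask |= table.sample_counts(sid) > 0
            sets[subject] = mask
            fams[subject] = grp["family_id"].iloc[0]
        return sets, fams

    mothers, mother_fam = _presence_sets("mother", mother_sites)
    neonates, neonate_fam = _presence_sets("neonate", neonate_sites)

    true_shared = []
    for mom, fam in mother_fam.items():
        for neo, nfam in neonate_fam.items():
            if nfam == fam:
                true_shared.append(int((mothers[mom] & neonates[neo]).sum()))
    fam_count = len({f for f in mother_fam.values()
                     if f in set(neonate_fam.values())})
    if fam_count < 2:
        raise ValueError("need >= 2 families with both a mother and a neonate")

    mom_list = sorted(mothers)
    neo_list = sorted(neonates)
    cross_possible = any(mother_fam[m] != neonate_fam[n]
                         for m in mom_list for n in neo_list)
    if not cross_possible:
        raise ValueError("no cross-family mother-neonate pair possible")
    rng = substream(seed, "shared-asv")
    random_shared = []
    while len(random_shared) < n_random_pairs:
        m = mom_list[rng.integers(len(mom_list))]
        n = neo_list[rng.integers(len(neo_list))]
        if mother_fam[m] == neonate_fam[n]:
            continue
        random_shared.append(int((mothers[m] & neonates[n]).sum()))

    true_arr = np.asarray(true_shared, dtype=float)
    rand_arr = np.asarray(random_shared, dtype=float)
    degenerate = bool(true_arr.std() == 0 and rand_arr.std() == 0)
    if degenerate:
        p = 1.0 if true_arr.mean() <= rand_arr.mean() else 0.0
        p = max(p, np.nextafter(0, 1))  # keep p in (0, 1]
    else:
        p = float(sps.ttest_ind(true_arr, rand_arr, equal_var=False,
                                alternative="greater").pvalue)
        if not np.isfinite(p):
            p = 1.0
    return SharedAsvTestResult(
        mean_true_pairs=float(true_arr.mean()),
        mean_random_pairs=float(rand_arr.mean()),
        n_true=len(true_arr), n_random=len(rand_arr),
        p_value=p, degenerate_variance=degenerate)
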