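import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from perimb.core import DistanceMatrix, FeatureTable, SampleMetadata, Taxonomy
from perimb.stats import (
    ancom,
    permanova,
    proportion_summary,
    screen_targets,
    summarize_clinical,
)


def oracle_permanova_f(D, labels):
    """Classic one-factor pseudo-F from within-group squared distances."""
    labels = np.asarray(labels)
    n = len(labels)
    a = len(np.unique(labels))
    sst = (D ** 2).sum() / (2 * n)
    ssw = 0.0
    for g in np.unique(labels):
        ix = np.flatnonzero(labels == g)
        ssw += (D[np.ix_(ix, ix)] ** 2).sum() / (2 * len(ix))
    ssa = sst - ssw
    return (ssa / (a - 1)) / (ssw / (n - a))


def _md(ids, **cols):
    df = pd.DataFrame(index=pd.Index(ids, name="sample_id"))
    df["site"] = cols.pop("site", "VD")
    for k, v in cols.items():
        df[k] = v
    return SampleMetadata(df, validate_twins=False)


class TestPermanova:
    def test_perfect_separation_r2_one(self):
        ids = list("abcd")
        D = np.array([[0, 0, 1, 1], [0, 0, 1, 1],
                      [1, 1, 0, 0], [1, 1, 0, 0]], float)
        md = _md(ids, group=["x", "x", "y", "y"])
        res = permanova(DistanceMatrix(ids, D), md, ["group"], exact=True)
        assert res.r2["group"] == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_p_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(6, 3))
        D = squareform(pdist(pts))
        labels = np.array(["a", "a", "a", "b", "b", "b"])
        f_obs = oracle_permanova_f(D, labels)
        cnt = sum(
            oracle_permanova_f(D, labels[list(perm)]) >= f_obs - 1e-12
            for perm in itertools.permutations(range(6)))
        p_oracle = cnt / 720
        ids = [f"s{i}" for i in range(6)]
        md = _md(ids, g=list(labels))
        res = permanova(DistanceMatrix(ids, D), md, ["g"], exact=True)
        assert res.p["g"] == pytest.approx(p_oracle, abs=1e-12)
        assert res.f["g"] == pytest.approx(f_obs, rel=1e-9)

    def test_r2_partition_sums_to_one(self):
        rng = np.random.default_rng(3)
        n = 16
        pts = rng.normal(size=(n, 5))
        D = squareform(pdist(pts))
        ids = [f"s{i}" for i in range(n)]
        md = _md(ids, g=list(rng.choice(["a", "b"], n)),
                 x=rng.normal(size=n), h=list(rng.choice(["u", "v", "w"], n)))
        res = permanova(DistanceMatrix(ids, D), md, ["g", "x", "h"],
                        n_permutations=99, seed=0)
        total = sum(res.r2[t] for t in res.terms) + res.r2["Residuals"]
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_p_never_zero(self):
        ids = list("abcdefgh")
        rng = np.random.default_rng(1)
        D = squareform(pdist(rng.normal(size=(8, 2))))
        md = _md(ids, g=["a"] * 4 + ["b"] * 4)
        res = permanova(DistanceMatrix(ids, D), md, ["g"],
                        n_permutations=99, seed=0)
        assert res.p["g"] >= 1.0 / 100

    def test_sample_reordering_invariance(self):
        rng = np.random.default_rng(5)
        n = 12
        D = squareform(pdist(rng.normal(size=(n, 3))))
        ids = [f"s{i}" for i in range(n)]
        g = list(rng.choice(["a", "b"], n))
        md = _md(ids, g=g)
        dm = DistanceMatrix(ids, D)
        res1 = permanova(dm, md, ["g"], n_permutations=99, seed=0)
        order = list(rng.permutation(ids))
        res2 = permanova(dm.submatrix(order), md, ["g"],
                         n_permutations=99, seed=0)
        assert res1.r2["g"] == pytest.approx(res2.r2["g"], abs=1e-9)

    def test_collinear_term_named(self):
        ids = list("abcd")
        D = squareform(pdist(np.arange(8).reshape(4, 2).astype(float)))
        md = _md(ids, g=["x", "x", "y", "y"], g2=["x", "x", "y", "y"])
        with pytest.raises(ValueError, match="g2"):
            permanova(DistanceMatrix(ids, D), md, ["g", "g2"], exact=True)

    def test_missing_covariate_sample(self):
        ids = list("abc")
        D = np.zeros((3, 3))
        md = _md(["a", "b"], g=["x", "y"])
        with pytest.raises(KeyError):
            permanova(DistanceMatrix(ids, D), md, ["g"], exact=True)

    def test_null_calibration_small(self):
        rej = 0
        n_runs = 50
        for seed in range(n_runs):
            rng = np.random.default_rng(seed)
            D = squareform(pdist(rng.normal(size=(16, 4))))
            ids = [f"s{i}" for i in range(16)]
            md = _md(ids, g=list(rng.permutation(["a"] * 8 + ["b"] * 8)))
            res = permanova(DistanceMatrix(ids, D), md, ["g"],
                            n_permutations=99, seed=seed)
            rej += res.p["g"] <= 0.05
        assert rej / n_runs <= 0.12


class TestAncom:
    def _spiked(self, seed=0, m=20, n=30, factor=20.0):
        rng = np.random.default_rng(seed)
        base = rng.dirichlet(np.ones(m) * 2)
        shifted = base.copy()
        shifted[3 if m > 3 else 0] *= factor
        shifted /= shifted.sum()
        c1 = rng.multinomial(3000, base, size=n)
        c2 = rng.multinomial(3000, shifted, size=n)
        ids = [f"s{i}" for i in range(2 * n)]
        t = FeatureTable(ids, [f"T{j}" for j in range(m)], np.vstack([c1, c2]))
        md = _md(ids, g=["a"] * n + ["b"] * n)
        return t, md

    def test_spiked_taxon_attains_max_w(self):
        t, md = self._spiked(seed=1)
        res = ancom(t, md, "g")
        assert res.table.loc["T3", "W"] == res.table["W"].max()
        assert res.table.loc["T3", "reject"]
        assert res.table.loc["T3", "direction"] == "b"

    def test_null_no_rejections(self):
        rng = np.random.default_rng(2)
        base = rng.dirichlet(np.ones(20) * 2)
        counts = rng.multinomial(3000, base, size=40)
        ids = [f"s{i}" for i in range(40)]
        t = FeatureTable(ids, [f"T{j}" for j in range(20)], counts)
        md = _md(ids, g=["a"] * 20 + ["b"] * 20)
        res = ancom(t, md, "g")
        assert not res.table["reject"].any()

    def test_two_taxa_w_bounded(self):
        t, md = self._spiked(seed=3, m=2)
        res = ancom(t, md, "g")
        assert set(res.table["W"]) <= {0, 1}

    def test_group_too_small(self):
        ids = ["a", "b", "c"]
        t = FeatureTable(ids, ["T0", "T1"], [[1, 2], [3, 4], [5, 6]])
        md = _md(ids, g=["x", "y", "y"])
        with pytest.raises(ValueError, match="x"):
            ancom(t, md, "g")

    def test_sample_scaling_invariance(self):
        # with pseudocount 0 on strictly positive tables, W is exactly
        # invariant to scaling any single sample's counts
        rng = np.random.default_rng(4)
        counts = rng.integers(1, 50, size=(12, 8))
        ids = [f"s{i}" for i in range(12)]
        t1 = FeatureTable(ids, [f"T{j}" for j in range(8)], counts)
        scaled = counts.copy()
        scaled[5] *= 13
        t2 = FeatureTable(ids, [f"T{j}" for j in range(8)], scaled)
        md = _md(ids, g=["a"] * 6 + ["b"] * 6)
        r1 = ancom(t1, md, "g", pseudocount=1e-300)
        r2 = ancom(t2, md, "g", pseudocount=1e-300)
        # log(x + 1e-300) == log(x) exactly for integer x >= 1
        assert r1.table["W"].tolist() == r2.table["W"].tolist()

    def test_mannwhitney_option(self):
        t, md = self._spiked(seed=5)
        res = ancom(t, md, "g", test="mannwhitney")
        assert res.table.loc["T3", "W"] == res.table["W"].max()

    def test_low_w_artifact_flag(self):
        rng = np.random.default_rng(6)
        counts = rng.integers(1, 50, size=(4, 6))
        ids = list("abcd")
        t = FeatureTable(ids, [f"T{j}" for j in range(6)], counts)
        md = _md(ids, g=["x", "x", "y", "y"])
        with pytest.warns(UserWarning, match="artifact"):
            res = ancom(t, md, "g")
        assert res.low_w_artifact


class TestScreenTargets:
    def _fixture(self):
        tax = Taxonomy({
            "f1": "d__B;p__P;c__C;o__O;f__F;g__Lactobacillus;s__lactobacillus_iners",
            "f2": "d__B;p__P;c__C;o__O;f__F;g__Lactobacillus;s__lactobacillus_jensenii",
            "f3": "d__B;p__P;c__C;o__O;f__F;g__Gardnerella;s__g_vaginalis",
            "f4": "d__B;p__P;c__C;o__O;f__F;g__Prevotella",
            "f5": "Unassigned",
        })
        t = FeatureTable(["s1", "s2"], ["f1", "f2", "f3", "f4", "f5"],
                         [[10, 0, 0, 0, 0], [2, 2, 4, 0, 2]])
        return t, tax

    def test_full_abundance_single_target(self):
        t, tax = self._fixture()
        res = screen_targets(t, tax, ["Lactobacillus"])
        assert res.abundances.loc["s1", "Lactobacillus"] == pytest.approx(1.0)
        assert res.detected["Lactobacillus"]

    def test_absent_target(self):
        t, tax = self._fixture()
        res = screen_targets(t, tax, ["Sneathia"])
        assert not res.detected["Sneathia"]
        assert (res.abundances["Sneathia"] == 0).all()

    def test_hand_enumerated_counts(self):
        t, tax = self._fixture()
        targets = ["Lactobacillus", "Gardnerella", "Prevotella", "Sneathia",
                   "Lactobacillus iners", "Lactobacillus jensenii"]
        res = screen_targets(t, tax, targets)
        # by string scan: Lactobacillus (f1,f2), Gardnerella (f3),
        # L. iners (f1, s2 only nonzero rows), L. jensenii (f2); Prevotella
        # is present in the taxonomy but has zero counts everywhere
        assert res.n_detected == 4

    def test_monotone_in_targets(self):
        t, tax = self._fixture()
        r1 = screen_targets(t, tax, ["Lactobacillus"])
        r2 = screen_targets(t, tax, ["Lactobacillus", "Gardnerella"])
        assert r2.n_detected >= r1.n_detected

    def test_empty_target_list(self):
        t, tax = self._fixture()
        with pytest.raises(ValueError):
            screen_targets(t, tax, [])

    def test_species_matching(self):
        t, tax = self._fixture()
        res = screen_targets(t, tax, ["Lactobacillus iners"])
        assert res.detected["Lactobacillus iners"]
        assert res.abundances.loc["s2", "Lactobacillus iners"] == pytest.approx(0.2)


class TestSummarizeClinical:
    def test_preterm_percentage(self):
        assert proportion_summary(37, 141)["percent"] == 26.2

    def test_monochorionic_percentage(self):
        assert proportion_summary(7, 37)["percent"] == 18.9

    def test_median_iqr(self):
        md = _md([f"s{i}" for i in range(5)], Age=[1, 2, 3, 4, 5])
        rows = summarize_clinical(md, {"Age": "continuous"})
        assert rows[0]["median"] == 3
        assert rows[0]["iqr_low"] == 2
        assert rows[0]["iqr_high"] == 4

    def test_categorical_from_binary_column(self):
        values = [1] * 37 + [0] * (141 - 37)
        md = _md([f"s{i}" for i in range(141)], Preterm=values)
        rows = summarize_clinical(md, {"Preterm": "categorical"})
        assert rows[0]["percent"] == 26.2
        assert rows[0]["counts"] == "37/141"

    def test_zero_denominator(self):
        with pytest.raises(ZeroDivisionError):
            proportion_summary(1, 0)

    def test_unknown_variable(self):
        md = _md(["s1"])
        with pytest.raises(KeyError):
            summarize_clinical(md, {"Nope": "continuous"})
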