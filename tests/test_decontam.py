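import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from perimb.core import FeatureTable
from perimb.decontam import (
    classify_contaminants,
    clr_transform,
    detect_batch_effects,
    frequency_score,
    prevalence_score,
)
from perimb.synth import CohortConfig, generate_cohort


class TestClr:
    def test_constant_vector_maps_to_zero(self):
        t = FeatureTable(["s"], list("abcd"), [[1, 1, 1, 1]])
        assert clr_transform(t, 1.0).to_numpy().tolist() == [[0, 0, 0, 0]]

    def test_two_taxa_analytic(self):
        # counts (1,7) + 1 -> (2,8); geometric mean 4 -> (-log2, +log2)
        t = FeatureTable(["s"], ["a", "b"], [[1, 7]])
        row = clr_transform(t, 1.0).to_numpy()[0]
        assert row[0] == pytest.approx(-math.log(2), abs=1e-12)
        assert row[1] == pytest.approx(math.log(2), abs=1e-12)

    def test_pseudocount_must_be_positive(self):
        t = FeatureTable(["s"], ["a"], [[1]])
        with pytest.raises(ValueError):
            clr_transform(t, 0.0)

    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_rows_sum_to_zero(self, seed):
        rng = np.random.default_rng(seed)
        t = FeatureTable([f"s{i}" for i in range(4)],
                         [f"f{j}" for j in range(9)],
                         rng.integers(0, 40, size=(4, 9)))
        sums = clr_transform(t, 0.5).to_numpy().sum(axis=1)
        np.testing.assert_allclose(sums, 0.0, atol=1e-9)


class TestFrequencyScore:
    def test_perfect_contaminant_scores_zero(self):
        c = np.geomspace(0.5, 50, 10)
        f = 0.3 / c
        assert frequency_score(f, c) == pytest.approx(0.0, abs=1e-12)

    def test_constant_frequency_scores_one(self):
        c = np.geomspace(0.5, 50, 10)
        f = np.full(10, 0.02)
        assert frequency_score(f, c) == pytest.approx(1.0, abs=1e-12)

    def test_too_few_samples_is_missing(self):
        assert math.isnan(frequency_score([0.1] * 4, [1, 2, 3, 4]))

    def test_all_zero_is_missing(self):
        assert math.isnan(frequency_score([0.0] * 10, np.arange(1, 11)))

    def test_scale_invariance_in_concentration(self):
        rng = np.random.default_rng(0)
        c = rng.lognormal(size=12)
        f = rng.dirichlet(np.ones(12))
        s1 = frequency_score(f, c)
        s2 = frequency_score(f, 7.3 * c)
        assert s1 == pytest.approx(s2, rel=1e-9)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(1)
        c = rng.lognormal(size=15)
        f = rng.random(15) + 0.01
        perm = rng.permutation(15)
        assert frequency_score(f, c) == pytest.approx(
            frequency_score(f[perm], c[perm]), rel=1e-9)


class TestPrevalenceScore:
    def test_exact_hypergeometric_tail(self):
        # present in 5/5 NCs, 0/20 true samples -> 1 / C(25,5)
        expected = 1.0 / math.comb(25, 5)
        assert prevalence_score(5, 5, 0, 20) == pytest.approx(expected, rel=1e-9)

    def test_enumeration_oracle(self):
        # P(X >= 3) for hypergeometric(M=12, present=6, nc draws=4)
        from scipy.stats import hypergeom
        expected = float(hypergeom.sf(2, 12, 6, 4))
        assert prevalence_score(3, 4, 3, 8) == pytest.approx(expected, rel=1e-9)

    def test_everywhere_present_scores_one(self):
        assert prevalence_score(5, 5, 20, 20) == pytest.approx(1.0)

    def test_absent_everywhere_missing(self):
        assert math.isnan(prevalence_score(0, 5, 0, 20))

    def test_no_nc_missing(self):
        assert math.isnan(prevalence_score(0, 0, 3, 20))


class TestClassifyContaminants:
    def test_planted_recovery(self, default_cohort):
        rep = classify_contaminants(default_cohort.table,
                                    default_cohort.metadata, threshold=0.1)
        truth = set(default_cohort.truth.contaminant_ids)
        flagged = set(rep.flagged)
        tp = len(truth & flagged)
        assert tp / len(truth) >= 0.8          # recall
        assert tp / max(len(flagged), 1) >= 0.8  # precision
        assert rep.n_removed == len(rep.flagged)

    def test_filtered_table_is_set_difference(self, default_cohort):
        table = default_cohort.table
        rep = classify_contaminants(table, default_cohort.metadata)
        kept = set(table.feature_ids) - set(rep.flagged)
        assert set(rep.filtered_table.feature_ids) == kept
        md = default_cohort.metadata.df
        assert all(not md.loc[s, "is_negative_control"]
                   for s in rep.filtered_table.sample_ids)
        for s in rep.filtered_table.sample_ids:
            for f in rep.filtered_table.feature_ids:
                assert (rep.filtered_table.counts[
                            rep.filtered_table.sample_index(s),
                            rep.filtered_table.feature_index(f)]
                        == table.counts[table.sample_index(s),
                                        table.feature_index(f)])

    def test_threshold_bounds(self, default_cohort):
        with pytest.raises(ValueError):
            classify_contaminants(default_cohort.table,
                                  default_cohort.metadata, threshold=1.5)

    def test_scores_permutation_equivariant(self, default_cohort):
        table = default_cohort.table
        rep1 = classify_contaminants(table, default_cohort.metadata)
        rng = np.random.default_rng(0)
        order = list(rng.permutation(list(table.sample_ids)))
        rep2 = classify_contaminants(table.select_samples(order),
                                     default_cohort.metadata)
        s1 = rep1.scores.set_index(["feature_id", "batch"]).sort_index()
        s2 = rep2.scores.set_index(["feature_id", "batch"]).sort_index()
        np.testing.assert_allclose(s1["combined_score"], s2["combined_score"],
                                   rtol=1e-9)
        assert set(rep1.flagged) == set(rep2.flagged)

    def test_rerun_flags_only_own_evidence(self):
        # after filtering, negative controls are gone, so any feature flagged
        # on a second pass must carry its own frequency evidence — none may be
        # flagged on the strength of evidence that left with removed features
        # or dropped NC samples
        cohort = generate_cohort(CohortConfig(seed=1, n_contaminants=0,
                                              batch_effect=0.0))
        rep1 = classify_contaminants(cohort.table, cohort.metadata)
        rep2 = classify_contaminants(rep1.filtered_table, cohort.metadata)
        new = set(rep2.flagged) - set(rep1.flagged)
        assert len(new) <= 0.02 * cohort.table.n_features
        flagged_rows = rep2.scores[rep2.scores["feature_id"].isin(new)]
        hit = flagged_rows[flagged_rows["flagged_by_score"]
                           | flagged_rows["flagged_by_nc_prevalence"]]
        assert not hit["flagged_by_nc_prevalence"].any()
        assert hit["prev_score"].isna().all()

    def test_null_false_positive_rate(self):
        rates = []
        for seed in range(10):
            cfg = CohortConfig(seed=seed, n_contaminants=0, batch_effect=0.0)
            cohort = generate_cohort(cfg)
            rep = classify_contaminants(cohort.table, cohort.metadata,
                                        threshold=0.1)
            rates.append(len(rep.flagged) / cohort.table.n_features)
        assert np.mean(rates) <= 0.1 + 0.05

    def test_planted_score_separation(self, default_cohort):
        rep = classify_contaminants(default_cohort.table,
                                    default_cohort.metadata,
                                    method="frequency")
        truth = set(default_cohort.truth.contaminant_ids)
        s = rep.scores.dropna(subset=["freq_score"])
        contam = s[s["feature_id"].isin(truth)]["freq_score"]
        clean = s[~s["feature_id"].isin(truth)]["freq_score"]
        assert contam.median() < clean.median()


class TestBatchDiagnostics:
    def test_needs_two_batches(self, random_table, simple_metadata):
        t = random_table(6, 10)
        md = simple_metadata(t.sample_ids, batch="B1")
        with pytest.raises(ValueError, match="2 batches"):
            detect_batch_effects(t, md)

    def test_identical_samples_correlate_fully(self, simple_metadata):
        counts = [[5, 1, 9, 2], [5, 1, 9, 2], [1, 8, 2, 7], [2, 9, 1, 6]]
        t = FeatureTable(["a", "b", "c", "d"], list("wxyz"), counts)
        md = simple_metadata(t.sample_ids, batch=["B1", "B2", "B1", "B2"])
        diag = detect_batch_effects(t, md)
        assert diag.correlation.loc["a", "b"] == pytest.approx(1.0)

    def test_zero_total_sample_excluded_with_warning(self, simple_metadata):
        counts = [[5, 1, 9, 2], [0, 0, 0, 0], [1, 8, 2, 7], [2, 9, 1, 6]]
        t = FeatureTable(["a", "b", "c", "d"], list("wxyz"), counts)
        md = simple_metadata(t.sample_ids, batch=["B1", "B2", "B1", "B2"])
        with pytest.warns(UserWarning, match="zero-total"):
            diag = detect_batch_effects(t, md)
        assert diag.excluded_samples == ["b"]
        assert "b" not in diag.correlation.index

    def test_batch_dominant_regime(self):
        cfg = CohortConfig(seed=2, n_families=12, n_contaminants=0,
                           batch_effect=3.0, subject_sigma=0.3,
                           n_negative_controls=0)
        cohort = generate_cohort(cfg)
        diag = detect_batch_effects(cohort.table, cohort.metadata)
        assert diag.ari_batch > diag.ari_site
        assert diag.ari_batch > 0.5

    def test_site_dominant_regime(self):
        cfg = CohortConfig(seed=2, n_families=12, n_contaminants=0,
                           batch_effect=0.0, subject_sigma=0.3,
                           n_negative_controls=0)
        cohort = generate_cohort(cfg)
        diag = detect_batch_effects(cohort.table, cohort.metadata)
        assert diag.ari_site > diag.ari_batch
        assert diag.ari_site > 0.2
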