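"""Prior-informed imputation: partition, MPD, imputation, Rubin pooling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from linkbias.linkage_core import PairSet
from linkbias.pii_imputer import (Mpd, PiiConfig, build_prior,
                                  fit_likelihood_model, impute_voi,
                                  modified_probability_distribution,
                                  partition_links, rubins_rules, run_pii)


def _prob_pairs(rows):
    df = pd.DataFrame(rows, columns=["admission_id", "micro_id",
                                     "match_probability"])
    return PairSet(df=df, blocking="none")


def _adm(ids):
    return pd.DataFrame({"admission_id": ids})


class TestPartition:
    def test_high_probability_is_unequivocal_link(self):
        part = partition_links(_adm([1]), _prob_pairs([(1, 1, 0.95)]),
                               PiiConfig())
        assert list(part.unequivocal_links) == [1]

    def test_no_candidates_is_unequivocal_nonlink(self):
        part = partition_links(_adm([1, 2]), _prob_pairs([(1, 1, 0.95)]),
                               PiiConfig())
        assert list(part.unequivocal_nonlinks) == [2]

    def test_intermediate_probability_is_equivocal(self):
        part = partition_links(_adm([1]), _prob_pairs([(1, 1, 0.5)]),
                               PiiConfig())
        assert list(part.equivocal) == [1]

    @pytest.mark.parametrize("p", [0.9, 0.2])
    def test_cutoffs_are_strict(self, p):
        part = partition_links(_adm([1]), _prob_pairs([(1, 1, p)]),
                               PiiConfig())
        assert list(part.equivocal) == [1]

    def test_three_sets_partition_admissions(self):
        pairs = _prob_pairs([(1, 1, 0.95), (2, 2, 0.5), (3, 3, 0.05)])
        part = partition_links(_adm([1, 2, 3, 4]), pairs, PiiConfig())
        all_ids = sorted([*part.unequivocal_links, *part.unequivocal_nonlinks,
                          *part.equivocal])
        assert all_ids == [1, 2, 3, 4]

    def test_out_of_band_candidates_dropped_from_equivocal_lists(self):
        pairs = _prob_pairs([(1, 1, 0.5), (1, 2, 0.05)])
        part = partition_links(_adm([1]), pairs, PiiConfig())
        assert part.candidates["micro_id"].tolist() == [1]


class TestPrior:
    @pytest.mark.parametrize("probs,expected", [
        ([0.5, 0.7], 0.7), ([0.3], 0.3), ([0.2, 0.2, 0.2], 0.2)])
    def test_prior_is_max_candidate_probability(self, probs, expected):
        assert build_prior(probs) == expected

    def test_empty_candidate_list_rejected(self):
        with pytest.raises(ValueError):
            build_prior([])


class TestMpd:
    def test_hand_arithmetic(self):
        mpd = modified_probability_distribution(0.3, 0.5)
        assert mpd.p_one == pytest.approx(0.30)

    def test_absorbing_prior(self):
        assert modified_probability_distribution(1.0, 0.4).p_one == 1.0

    def test_flat_prior_returns_likelihood(self):
        assert modified_probability_distribution(0.5, 0.37).p_one == \
            pytest.approx(0.37)

    def test_degenerate_masses_rejected(self):
        with pytest.raises(ValueError):
            modified_probability_distribution(1.0, 0.0)

    @given(st.floats(0.01, 0.99), st.floats(0.01, 0.99))
    def test_normalisation(self, prior, lik):
        mpd = modified_probability_distribution(prior, lik)
        assert mpd.p_zero + mpd.p_one == pytest.approx(1.0)

    @given(st.floats(0.01, 0.98), st.floats(0.01, 0.99))
    def test_monotone_in_prior(self, prior, lik):
        lo = modified_probability_distribution(prior, lik).p_one
        hi = modified_probability_distribution(prior + 0.01, lik).p_one
        assert hi >= lo

    @given(st.floats(0.01, 0.99), st.floats(0.01, 0.98))
    def test_monotone_in_likelihood(self, prior, lik):
        lo = modified_probability_distribution(prior, lik).p_one
        hi = modified_probability_distribution(prior, lik + 0.01).p_one
        assert hi >= lo


class TestImputeVoi:
    def test_confident_mpd_accepted_at_low_threshold(self):
        voi, prov = impute_voi(Mpd(0.05, 0.95), 0.5,
                               PiiConfig(mpd_threshold=0.1),
                               np.random.default_rng(0))
        assert (voi, prov) == (1, "mpd")

    def test_uncertain_mpd_routed_to_mi_at_high_threshold(self):
        voi, prov = impute_voi(Mpd(0.55, 0.45), 0.8,
                               PiiConfig(mpd_threshold=0.9),
                               np.random.default_rng(0))
        assert prov == "mi"

    def test_zero_threshold_is_deterministic_argmax(self):
        cfg = PiiConfig(mpd_threshold=0.0)
        outs = {impute_voi(Mpd(0.4, 0.6), 0.1, cfg,
                           np.random.default_rng(s))[0] for s in range(5)}
        assert outs == {1}


class TestLikelihoodModel:
    def test_intercept_only_recovers_prevalence(self):
        df = pd.DataFrame({"voi": [1] * 30 + [0] * 70})
        model = fit_likelihood_model(df, predictors=())
        np.testing.assert_allclose(model.predict(df), 0.30, atol=1e-6)

    def test_constant_predictor_degenerates_to_intercept(self):
        df = pd.DataFrame({"voi": [1] * 30 + [0] * 70, "renal_status": 1})
        model = fit_likelihood_model(df, predictors=("renal_status",))
        np.testing.assert_allclose(model.predict(df), 0.30, atol=1e-6)

    def test_separated_fit_falls_back_to_ridge(self):
        df = pd.DataFrame({"voi": [1] * 20 + [0] * 20,
                           "renal_status": [1] * 20 + [0] * 20})
        with pytest.warns(UserWarning):
            model = fit_likelihood_model(df, predictors=("renal_status",))
        p = model.predict(df)
        assert np.all(np.isfinite(p)) and np.all((p > 0) & (p < 1))

    def test_single_outcome_value_rejected(self):
        with pytest.raises(ValueError):
            fit_likelihood_model(pd.DataFrame({"voi": [1, 1, 1]}),
                                 predictors=())


class TestRunPii:
    def _scored(self, adm_ids, probs):
        rows = [(a, a, p) for a, p in zip(adm_ids, probs)]
        return _prob_pairs(rows)

    def _adm_cov(self, ids, rng):
        return pd.DataFrame({
            "admission_id": ids,
            "renal_status": rng.integers(0, 2, len(ids)),
        })

    def test_all_unequivocal_gives_identical_datasets(self):
        rng = np.random.default_rng(0)
        adm = self._adm_cov(np.arange(1, 21), rng)
        pairs = self._scored(np.arange(1, 11), [0.95] * 10)
        cfg = PiiConfig(predictors=("renal_status",))
        datasets = run_pii(adm, pairs, cfg, rng=np.random.default_rng(1))
        assert len(datasets) == 5
        for ds in datasets[1:]:
            pd.testing.assert_series_equal(ds["voi"], datasets[0]["voi"])
        assert set(datasets[0]["provenance"]) == {"fixed"}

    def test_unequivocal_values_constant_across_imputations(self):
        rng = np.random.default_rng(2)
        adm = self._adm_cov(np.arange(1, 101), rng)
        probs = [0.95] * 20 + [0.5] * 30 + [0.05] * 50
        pairs = self._scored(np.arange(1, 101), probs)
        cfg = PiiConfig(predictors=("renal_status",), mpd_threshold=0.9)
        datasets = run_pii(adm, pairs, cfg, rng=np.random.default_rng(3))
        fixed_ids = list(range(1, 21)) + list(range(51, 101))
        for ds in datasets:
            sub = ds[ds["admission_id"].isin(fixed_ids)]
            expect = [1] * 20 + [0] * 50
            assert sub.sort_values("admission_id")["voi"].tolist() == expect

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(2)
        adm = self._adm_cov(np.arange(1, 101), rng)
        probs = [0.95] * 20 + [0.5] * 30 + [0.05] * 50
        pairs = self._scored(np.arange(1, 101), probs)
        cfg = PiiConfig(predictors=("renal_status",), mpd_threshold=0.9)
        d1 = run_pii(adm, pairs, cfg, rng=np.random.default_rng(7))
        d2 = run_pii(adm, pairs, cfg, rng=np.random.default_rng(7))
        for a, b in zip(d1, d2):
            pd.testing.assert_frame_equal(a, b)

    def test_threshold_one_routes_all_equivocal_to_mi(self):
        rng = np.random.default_rng(2)
        adm = self._adm_cov(np.arange(1, 101), rng)
        probs = [0.95] * 20 + [0.5] * 30 + [0.05] * 50
        pairs = self._scored(np.arange(1, 101), probs)
        cfg = PiiConfig(predictors=("renal_status",), mpd_threshold=1.0)
        ds = run_pii(adm, pairs, cfg, rng=np.random.default_rng(5))[0]
        equivocal = ds[ds["admission_id"].between(21, 50)]
        assert set(equivocal["provenance"]) == {"mi"}

    def test_threshold_zero_is_deterministic_posterior_classifier(self):
        rng = np.random.default_rng(2)
        adm = self._adm_cov(np.arange(1, 101), rng)
        probs = [0.95] * 20 + [0.5] * 30 + [0.05] * 50
        pairs = self._scored(np.arange(1, 101), probs)
        cfg = PiiConfig(predictors=("renal_status",), mpd_threshold=0.0)
        datasets = run_pii(adm, pairs, cfg, rng=np.random.default_rng(5))
        for ds in datasets[1:]:
            pd.testing.assert_series_equal(ds["voi"], datasets[0]["voi"])
        assert "mi" not in set(datasets[0]["provenance"])


class TestRubinsRules:
    def test_hand_computed_example(self):
        pooled = rubins_rules([1, 2, 3], [1, 1, 1])
        assert pooled.point == pytest.approx(2.0)
        assert pooled.within_var == pytest.approx(1.0)
        assert pooled.between_var == pytest.approx(1.0)
        assert pooled.total_var == pytest.approx(1 + (4 / 3), abs=1e-4)

    def test_degenerate_between_variance(self):
        pooled = rubins_rules([2.5, 2.5, 2.5], [1, 1, 1])
        assert pooled.between_var == 0.0
        assert pooled.total_var == 1.0
        assert pooled.df == np.inf
        assert pooled.ci[0] == pytest.approx(2.5 - 1.959964, abs=1e-4)

    @given(st.floats(0.1, 10))
    def test_scale_equivariance(self, c):
        base = rubins_rules([1, 2, 3], [1, 1, 1])
        scaled = rubins_rules([c, 2 * c, 3 * c], [1, 1, 1])
        assert scaled.point == pytest.approx(c * base.point)
        assert scaled.between_var == pytest.approx(c * c * base.between_var)
        assert scaled.total_var - scaled.within_var == pytest.approx(
            c * c * (base.total_var - base.within_var))

    @given(st.lists(st.floats(-5, 5), min_size=2, max_size=8),
           st.lists(st.floats(0, 4), min_size=2, max_size=8))
    def test_total_variance_dominates_within(self, est, var):
        m = min(len(est), len(var))
        pooled = rubins_rules(est[:m], var[:m])
        assert pooled.total_var >= pooled.within_var
        assert pooled.between_var >= 0

    def test_too_few_imputations_rejected(self):
        with pytest.raises(ValueError):
            rubins_rules([1.0], [1.0])
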