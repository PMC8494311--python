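import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from circinfer import (
    CohortConfig,
    association_battery,
    build_regressors,
    build_trial_set,
    define_groups,
    fit_lme_variants,
    kendall_tau,
    mann_whitney_f,
    simulate_cohort,
    simulate_responses,
    symmetric_trial_average,
)
from circinfer.models import PARAM_NAMES, ModelParams
from circinfer.traitstats import LME_VARIANTS


def _toy_tables():
    trials = pd.DataFrame(
        {
            "trial_id": [0, 1, 2],
            "prior_p": [0.8, 0.5, 0.3],
            "like_p": [0.3, 0.7, 0.3],
        }
    )
    responses = pd.DataFrame(
        {
            "participant_id": [0, 0, 0],
            "trial_id": [0, 1, 2],
            "confidence": [0.5, 0.9, 0.2],
            "rt": [1.0, 2.0, 3.0],
        }
    )
    traits = pd.DataFrame({"participant_id": [0], "AQ": [20], "PDI": [5]})
    return responses, trials, traits


class TestBuildRegressors:
    def test_worked_values(self):
        reg = build_regressors(*_toy_tables())
        # c = 0.5 -> zero absolute confidence
        assert reg.loc[0, "abs_confidence"] == pytest.approx(0.0)
        # prior .8 vs likelihood .3: cues disagree -> -|0.8 - 0.5|
        assert reg.loc[0, "prior_congruency"] == pytest.approx(-0.3)
        # prior exactly 0.5 contributes zero congruency (sgn(0) = 0)
        assert reg.loc[1, "prior_congruency"] == pytest.approx(0.0)
        # cues agree below 0.5 -> +|0.3 - 0.5|
        assert reg.loc[2, "prior_congruency"] == pytest.approx(0.2)
        np.testing.assert_allclose(reg["abs_likelihood"], [0.2, 0.2, 0.2])

    def test_row_permutation_equivariance(self):
        responses, trials, traits = _toy_tables()
        reg = build_regressors(responses, trials, traits)
        perm = [2, 0, 1]
        reg_p = build_regressors(responses.iloc[perm].reset_index(drop=True), trials, traits)
        pd.testing.assert_frame_equal(
            reg.iloc[perm].reset_index(drop=True), reg_p
        )

    def test_join_failures_raise(self):
        responses, trials, traits = _toy_tables()
        with pytest.raises(ValueError, match="trial_id"):
            build_regressors(responses.assign(trial_id=[0, 1, 99]), trials, traits)
        with pytest.raises(ValueError, match="participant"):
            build_regressors(responses, trials, traits.assign(participant_id=[7]))


class TestKendallTau:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ((1, 2, 3), (2, 4, 6), 1.0),
            ((1, 2, 3), (1, 3, 2), 1 / 3),
            ((1, 2, 3, 4), (4, 3, 2, 1), -1.0),
        ],
    )
    def test_enumerated_values(self, x, y, expected):
        out = kendall_tau(x, y)
        assert out.statistic == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_flagged(self):
        with pytest.warns(RuntimeWarning):
            out = kendall_tau([1, 1, 1], [1, 2, 3])
        assert np.isnan(out.statistic) and "zero_variance" in out.flags

    def test_length_validation(self):
        with pytest.raises(ValueError):
            kendall_tau([1, 2], [1, 2])


class TestMannWhitneyF:
    def test_complete_separation(self):
        out = mann_whitney_f([5, 6, 7], [1, 2, 3])
        assert out.effect_size == pytest.approx(1.0)

    def test_identical_multisets_give_half(self):
        out = mann_whitney_f([1, 2, 2, 3], [1, 2, 2, 3])
        assert out.effect_size == pytest.approx(0.5)

    def test_brute_force_pair_count(self):
        # pairs (1,2),(1,4),(3,2),(3,4): only 3>2 -> f = 1/4
        out = mann_whitney_f([1, 3], [2, 4])
        assert out.effect_size == pytest.approx(0.25)

    @given(
        st.lists(st.integers(0, 20), min_size=2, max_size=15),
        st.lists(st.integers(0, 20), min_size=2, max_size=15),
    )
    @settings(max_examples=50, deadline=None)
    def test_complement_identity(self, x, y):
        assert mann_whitney_f(x, y).effect_size + mann_whitney_f(y, x).effect_size == pytest.approx(1.0)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_f([], [1, 2])


class TestDefineGroups:
    def test_clean_percentiles(self):
        traits = pd.DataFrame({"participant_id": range(100), "AQ": range(1, 101)})
        groups = define_groups(traits)
        low = set(traits.loc[groups["aq_group"] == "low", "AQ"])
        high = set(traits.loc[groups["aq_group"] == "high", "AQ"])
        assert low == set(range(1, 16))
        assert high == set(range(86, 101))

    def test_degenerate_scores_rejected(self):
        traits = pd.DataFrame({"participant_id": range(50), "AQ": 20})
        with pytest.raises(ValueError, match="identical"):
            define_groups(traits)

    def test_tiny_sample_rejected(self):
        traits = pd.DataFrame({"participant_id": range(3), "AQ": [1, 2, 3]})
        with pytest.raises(ValueError, match="too small"):
            define_groups(traits)

    def test_cohort_scale_group_sizes(self):
        """On 176 synthetic participants with the study's trait moments the
        15% tails land near the reported group sizes (29 and 30)."""
        cohort = simulate_cohort(176, seed=12)
        groups = define_groups(cohort.profiles)
        sizes = groups["aq_group"].value_counts()
        assert 26 <= sizes["low"] <= 45
        assert 26 <= sizes["high"] <= 45
        assert groups["nd_low"].sum() >= 1


class TestAssociationBattery:
    def _fits_from_profiles(self, profiles):
        fits = profiles[["participant_id", *PARAM_NAMES]].copy()
        fits["model"] = "CINI"
        return fits

    def test_layout_and_adjustment(self):
        cohort = simulate_cohort(80, seed=13)
        out = association_battery(self._fits_from_profiles(cohort.profiles), cohort.profiles)
        assert len(out) == 16
        assert set(out["table"]) == {"correlations", "groups"}
        assert (out.groupby("table").size() == 8).all()
        valid = out["p"].notna()
        assert out.loc[valid, "p"].between(0, 1).all()
        # Benjamini-Hochberg never decreases a p-value
        assert (out.loc[valid, "p_adjusted"] >= out.loc[valid, "p"] - 1e-12).all()

    def test_injected_coupling_detected(self):
        cfg = CohortConfig(couplings={"a_s": {"AQ": 0.8}})
        cohort = simulate_cohort(176, cfg, seed=14)
        out = association_battery(self._fits_from_profiles(cohort.profiles), cohort.profiles)
        row = out[(out["contrast"] == "AQ") & (out["parameter"] == "a_s")].iloc[0]
        assert row["statistic"] > 0.3
        assert row["p_adjusted"] < 0.05

    def test_degenerate_parameters_flagged(self):
        cohort = simulate_cohort(40, seed=15)
        fits = self._fits_from_profiles(cohort.profiles)
        fits[list(PARAM_NAMES)] = 0.5
        with pytest.warns(RuntimeWarning):
            out = association_battery(fits, cohort.profiles)
        corr = out[out["table"] == "correlations"]
        assert corr["statistic"].isna().all()


class TestSymmetricTrialAverage:
    def test_noise_free_model_responses_unchanged(self, trials81, cini_params):
        r = simulate_responses("CINI", cini_params, trials81, noise_sd=1e-9, seed=0)
        avg = symmetric_trial_average(r, trials81)
        assert len(avg) == 45
        merged = avg.merge(
            r.merge(trials81, on="trial_id"), on=["prior_p", "like_p"]
        )
        np.testing.assert_allclose(merged["avg_L_c"], merged["L_c"], atol=1e-9)

    def test_mirror_difference_definition(self):
        trials = pd.DataFrame({"trial_id": [0, 1], "prior_p": [0.7, 0.3], "like_p": [0.9, 0.1]})
        trials["L_p"] = np.log(trials["prior_p"] / (1 - trials["prior_p"]))
        trials["L_s"] = np.log(trials["like_p"] / (1 - trials["like_p"]))
        responses = pd.DataFrame(
            {"participant_id": 0, "trial_id": [0, 1], "L_c": [2.0, -1.0]}
        )
        avg = symmetric_trial_average(responses, trials)
        assert len(avg) == 1
        assert avg.loc[0, "avg_L_c"] == pytest.approx(1.5)

    def test_missing_mirror_flagged(self):
        trials = pd.DataFrame({"trial_id": [0], "prior_p": [0.7], "like_p": [0.9]})
        trials["L_p"] = np.log(7 / 3)
        trials["L_s"] = np.log(9)
        responses = pd.DataFrame({"participant_id": 0, "trial_id": [0], "L_c": [2.0]})
        avg = symmetric_trial_average(responses, trials)
        assert avg.loc[0, "flag"] == "missing_mirror"
        assert avg.loc[0, "avg_L_c"] == pytest.approx(2.0)

    def test_noise_reduction_near_root_two(self):
        """Averaging two independent noisy mirror cells halves the variance."""
        trials = build_trial_set(8100, seed=0, full_coverage=False)
        params = ModelParams(0.8, 0.8, 0.1, 0.1)
        r = simulate_responses("CINI", params, trials, noise_sd=1.0, seed=1)
        merged = r.merge(trials, on="trial_id")
        pred = merged.groupby(["prior_p", "like_p"]).apply(
            lambda g: float(
                np.asarray(
                    __import__("circinfer").predict(
                        "CINI", g["L_p"].iloc[0], g["L_s"].iloc[0], params
                    )
                )
            ),
            include_groups=False,
        )
        cell = merged.groupby(["prior_p", "like_p"])["L_c"].mean()
        raw_rmse = np.sqrt(((cell - pred) ** 2).mean())
        avg = symmetric_trial_average(r, trials)
        avg_pred = avg.apply(
            lambda row: float(
                np.asarray(
                    __import__("circinfer").predict("CINI", row["L_p"], row["L_s"], params)
                )
            ),
            axis=1,
        )
        avg_rmse = np.sqrt(((avg["avg_L_c"] - avg_pred) ** 2).mean())
        assert raw_rmse / avg_rmse == pytest.approx(np.sqrt(2), rel=0.25)


@pytest.fixture(scope="module")
def regressors():
    cohort = simulate_cohort(20, seed=16)
    return build_regressors(cohort.responses, cohort.trials, cohort.profiles)


class TestLmeVariants:

    def test_core_recovers_injected_rt_effect(self, regressors):
        """Reaction times were generated faster on confident trials, so the
        rt coefficient on absolute confidence must be negative."""
        out = fit_lme_variants(regressors, {"LME_core": LME_VARIANTS["LME_core"]})
        coef = out["LME_core"].coefficients
        assert coef.loc["rt", "estimate"] < 0
        assert coef.loc["rt", "p"] < 0.05
        # the cue effect is carried partly by per-participant random
        # slopes, so judge the fixed effect at the conventional level
        assert coef.loc["abs_likelihood", "estimate"] > 0
        assert coef.loc["abs_likelihood", "p"] < 0.05

    def test_all_variants_fit_with_expected_terms(self, regressors):
        out = fit_lme_variants(regressors)
        assert set(out) == set(LME_VARIANTS)
        assert all(np.isfinite(v.bic) for v in out.values())
        aq = out["LME_AQ"].coefficients.index
        assert any("AQ:abs_likelihood:prior_congruency" in t for t in aq)
        rti = out["LME_rtInteract"].coefficients.index
        assert any("AQ:rt" in t for t in rti) and any("PDI:rt" in t for t in rti)
        # parsimony under the null: the trait-free core beats the
        # heaviest variant on BIC
        assert out["LME_core"].bic < out["LME_rtInteract"].bic

    def test_single_participant_rejected(self):
        cohort = simulate_cohort(2, seed=17)
        reg = build_regressors(cohort.responses, cohort.trials, cohort.profiles)
        with pytest.raises(ValueError, match="participants"):
            fit_lme_variants(reg[reg["participant_id"] == 0])
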