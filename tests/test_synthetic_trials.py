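import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

from episelect import ParameterError
from episelect import synthetic_trials as syn
from episelect import trial_stats as ts
from episelect.emergence_analysis import aupec


class TestEpiMixture:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ParameterError):
            syn.EpiMixture(0.5, 0.5, 0.5)

    def test_negative_fraction_rejected(self):
        with pytest.raises(ParameterError):
            syn.EpiMixture(-0.1, 0.5, 0.6)

    def test_moments_match_enumeration(self):
        mix = syn.EpiMixture(0.2, 0.3, 0.5, 10.0, 4.0)
        # brute-force over the three components
        vals = np.array([10.0, -4.0, 0.0])
        probs = np.array([0.2, 0.3, 0.5])
        m, v = mix.moments()
        assert m == pytest.approx(float(probs @ vals))
        assert v == pytest.approx(float(probs @ vals**2 - (probs @ vals) ** 2))


class TestSimParamsValidation:
    def test_negative_variance_rejected(self):
        with pytest.raises(ParameterError):
            syn.SimParams(wt_mean_by_env={"E": 1.0}, line_var=-1.0)

    def test_rho_out_of_range(self):
        with pytest.raises(ParameterError):
            syn.SimParams(wt_mean_by_env={"E": 1.0}, tiller_yield_rho=1.5)

    def test_counts_at_least_one(self):
        with pytest.raises(ParameterError):
            syn.SimParams(wt_mean_by_env={"E": 1.0}, n_epi_lines=0)

    def test_unknown_rep_environment(self):
        with pytest.raises(ParameterError):
            syn.SimParams(wt_mean_by_env={"E": 1.0}, n_reps_by_env={"X": 2})


class TestEpiF2Trial:
    def test_degenerate_variances_give_structural_means(self):
        params = syn.SimParams(
            wt_mean_by_env={"F2": 70.0}, line_var=0.0, block_var=0.0, resid_var=0.0,
            n_epi_lines=5, plants_or_plots_per_line_per_rep=3,
            n_reps_by_env={"F2": 2}, seed=1,
        )
        df = syn.simulate_epiF2_trial(params)
        assert (df["yield_g"] == 70.0).all()

    def test_seeded_determinism(self, f2_params):
        a = syn.simulate_epiF2_trial(f2_params)
        b = syn.simulate_epiF2_trial(f2_params)
        pd.testing.assert_frame_equal(a, b)

    def test_different_seed_differs(self, f2_params, f2_plants):
        other = syn.simulate_epiF2_trial(dataclasses.replace(f2_params, seed=8))
        assert not other["yield_g"].equals(f2_plants["yield_g"])

    def test_layout_wt_checks_in_every_block(self, f2_plants):
        per_block = f2_plants.groupby("block")["cohort"].agg(lambda s: "WT" in set(s))
        assert per_block.all()

    def test_each_family_once_per_replication(self, f2_params, f2_plants):
        epi = f2_plants[f2_plants["cohort"] == "epiF2"]
        counts = epi.groupby(["line_id", "replication"]).size()
        assert (counts == f2_params.plants_or_plots_per_line_per_rep).all()
        assert epi.groupby("line_id")["replication"].nunique().eq(3).all()

    def test_record_invariants(self, f2_plants):
        assert (f2_plants["yield_g"] >= 0).all()
        assert (f2_plants["height_cm"] >= 0).all()
        assert (f2_plants["tiller_count"] >= 0).all()
        assert f2_plants["tiller_count"].dtype.kind == "i"
        assert (f2_plants["days_to_flowering"] >= 1).all()

    def test_tiller_yield_correlation_calibrated(self):
        # >= 4500 plants; observed plant-level correlation within +-0.05 of target
        params = syn.SimParams(
            wt_mean_by_env={"F2": 70.0}, line_var=9.0, block_var=4.0, resid_var=100.0,
            epi_mixture=syn.EpiMixture(0.15, 0.05, 0.80, 12.0, 10.0),
            tiller_yield_rho=0.52, tiller_effect_logfc=0.15,
            n_epi_lines=100, plants_or_plots_per_line_per_rep=15,
            n_reps_by_env={"F2": 3}, seed=5,
        )
        df = syn.simulate_epiF2_trial(params)
        assert len(df) >= 4500
        r = np.corrcoef(df["yield_g"], df["tiller_count"])[0, 1]
        assert abs(r - 0.52) < 0.05

    def test_mixture_calibration_recovers_skewed_counts(self):
        # fractions chosen so the downstream contrast flags ~9 higher and
        # ~4 lower lines out of 100 (includes the alpha=0.05 false positives);
        # oracle = repeated simulation + the trial-stats contrast
        ups, downs = [], []
        for s in range(4):
            params = syn.SimParams(
                wt_mean_by_env={"F2": 70.0}, line_var=0.0, block_var=4.0,
                resid_var=100.0,
                epi_mixture=syn.EpiMixture(0.068, 0.018, 0.914, 15.0, 15.0),
                n_epi_lines=100, plants_or_plots_per_line_per_rep=15,
                n_reps_by_env={"F2": 3}, seed=100 + s,
            )
            df = syn.simulate_epiF2_trial(params).rename(columns={"line_id": "genotype"})
            fit = ts.fit_trait_model(df, ts.TraitModelSpec("yield_g"))
            contrasts = ts.contrast_lines_vs_wt(fit)
            ups.append((contrasts["direction"] == "higher").sum())
            downs.append((contrasts["direction"] == "lower").sum())
        # binomial-scale sampling error: sd ~ 3 per replicate, 4 replicates
        assert abs(np.mean(ups) - 9) < 4.5
        assert abs(np.mean(downs) - 4) < 3.5


class TestEpiF3Trial:
    def test_degenerate_all_plots_share_wt_mean(self):
        params = syn.SimParams(
            wt_mean_by_env={"A": 100.0, "B": 50.0}, line_var=0.0, block_var=0.0,
            resid_var=0.0, n_epi_lines=9, n_wt_lines=2,
            plants_or_plots_per_line_per_rep=1,
            n_reps_by_env={"A": 2, "B": 2}, seed=0,
        )
        plots = syn.simulate_epiF3_multienv_trial(params)
        for env, mean in params.wt_mean_by_env.items():
            assert (plots.loc[plots["environment_id"] == env, "yield_kg_ha_std"] == mean).all()

    def test_unknown_environment_in_effects_rejected(self, f3_params):
        with pytest.raises(ParameterError):
            syn.simulate_epiF3_multienv_trial(
                f3_params, category_effects={"ML.HI": {"nowhere": 0.2}}
            )

    def test_unknown_category_label_rejected(self, f3_params):
        with pytest.raises(ParameterError):
            syn.simulate_epiF3_multienv_trial(f3_params, category_effects={"XX.YY": 0.2})

    def test_wt_environment_means_near_targets(self):
        # targets 5999 and 2335 kg/ha; WT sample means within 3 SE
        params = syn.SimParams(
            wt_mean_by_env={"normalN": 5999.0, "lowN": 2335.0},
            line_var=150.0**2, block_var=80.0**2, resid_var=300.0**2,
            n_epi_lines=27, n_wt_lines=19, plants_or_plots_per_line_per_rep=1,
            n_reps_by_env={"normalN": 3, "lowN": 2}, seed=2,
        )
        plots = syn.simulate_epiF3_multienv_trial(params)
        wt = plots[plots["cohort"] == "WT"]
        for env, target in params.wt_mean_by_env.items():
            line_means = wt[wt["environment_id"] == env].groupby("line_id")["yield_kg_ha_std"].mean()
            se = line_means.std() / math.sqrt(len(line_means))
            assert abs(line_means.mean() - target) < 3 * se

    def test_moisture_standardization_round_trips(self, f3_plots):
        back = ts.standardize_yield(
            f3_plots["raw_grain_weight"].values,
            f3_plots["moisture_g_per_kg"].values,
            f3_plots["plot_area_m2"].values,
        )
        np.testing.assert_allclose(back, f3_plots["yield_kg_ha_std"].values, rtol=1e-9)

    def test_seeded_determinism(self, f3_params):
        a = syn.simulate_epiF3_multienv_trial(f3_params)
        b = syn.simulate_epiF3_multienv_trial(f3_params)
        pd.testing.assert_frame_equal(a, b)

    def test_variance_component_recovery_single_fit(self):
        params = syn.SimParams(
            wt_mean_by_env={"E": 1000.0}, line_var=0.0, block_var=25.0**2,
            resid_var=100.0**2, n_epi_lines=12, n_wt_lines=1,
            plants_or_plots_per_line_per_rep=6, n_reps_by_env={"E": 4}, seed=9,
        )
        plots = syn.simulate_epiF3_multienv_trial(params)
        df = plots.rename(columns={"line_id": "genotype"})
        ref = sorted(df["genotype"].unique())[0]
        fit = ts.fit_trait_model(df, ts.TraitModelSpec("yield_kg_ha_std"), reference=ref)
        ivs = ts.variance_component_intervals(fit)
        lo, hi = ivs["resid_var"]
        assert lo <= params.resid_var <= hi


class TestEmergenceSimulation:
    def test_zero_delay_matches_standard(self):
        params = syn.SimParams(wt_mean_by_env={"E": 1.0}, seed=0)
        series = syn.simulate_emergence(params, {"L1": 0.0})
        early = next(s for s in series if s.planting == "early")
        std = next(s for s in series if s.planting == "standard")
        assert early.counts == std.counts

    def test_infinite_delay_zero_aupec(self):
        params = syn.SimParams(wt_mean_by_env={"E": 1.0}, seed=0)
        series = syn.simulate_emergence(params, {"L1": float("inf")})
        early = next(s for s in series if s.planting == "early")
        assert all(c == 0 for c in early.counts)
        assert aupec(early.days, early.counts) == 0.0

    def test_aupec_strictly_decreasing_in_delay(self):
        params = syn.SimParams(wt_mean_by_env={"E": 1.0}, seed=0)
        delays = [0.0, 4.0, 8.0, 12.0, 16.0, 20.0]
        series = syn.simulate_emergence(params, {f"L{i}": d for i, d in enumerate(delays)})
        std_final = max(s.counts[-1] for s in series if s.planting == "standard")
        areas = [
            aupec(s.days, np.asarray(s.counts) / std_final)
            for d in delays
            for s in series
            if s.planting == "early" and s.line_id == f"L{delays.index(d)}"
        ]
        assert all(a > b for a, b in zip(areas, areas[1:]))

    def test_counts_nondecreasing(self):
        params = syn.SimParams(wt_mean_by_env={"E": 1.0}, seed=0)
        for s in syn.simulate_emergence(params, {"A": 3.0, "B": 11.0}):
            assert all(b >= a for a, b in zip(s.counts, s.counts[1:]))

    def test_bad_day_grid_rejected(self):
        params = syn.SimParams(wt_mean_by_env={"E": 1.0}, seed=0)
        with pytest.raises(ParameterError):
            syn.simulate_emergence(params, {"A": 0.0}, days=(5, 5, 6))


class TestReversionCounts:
    def test_rate_zero(self):
        assert syn.simulate_reversion_counts(500, 0.0, seed=3) == 0

    def test_rate_one(self):
        assert syn.simulate_reversion_counts(500, 1.0, seed=3) == 500

    def test_rate_out_of_range(self):
        with pytest.raises(ParameterError):
            syn.simulate_reversion_counts(10, 1.5, seed=0)

    def test_binomial_moments(self):
        # n=6650, rate=0.0015 -> mean 9.975, sd sqrt(n p (1-p))
        n, p, reps = 6650, 0.0015, 10_000
        counts = np.array([syn.simulate_reversion_counts(n, p, seed=s) for s in range(reps)])
        se = math.sqrt(n * p * (1 - p) / reps)
        assert abs(counts.mean() - 9.975) < 3 * se

    def test_deterministic_given_seed(self):
        assert syn.simulate_reversion_counts(1000, 0.3, seed=5) == syn.simulate_reversion_counts(1000, 0.3, seed=5)
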