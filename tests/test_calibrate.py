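"""Least-squares calibration: residual layout, bounded fits, recovery."""

import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from phenodyn.calibrate import (
    FitSpec,
    FrequencyDataset,
    extract_off_therapy,
    fit,
    growth_rate_from_doubling,
    residual_vector,
)
from phenodyn.models import (
    UNTREATED,
    ContractError,
    ModelId,
    ModelParams,
    TreatmentSchedule,
)
from phenodyn.synthetic import (
    generate,
    reference_scenarios,
    untreated_calibration_dataset,
)

from oracles import euler_adrn_frequency


class TestGrowthRate:
    def test_doubling_time_of_27_hours(self):
        r = growth_rate_from_doubling(27.0)
        assert r == pytest.approx(math.log(2) / 27)
        assert round(r, 3) == 0.026

    def test_identity_r_times_td_is_ln2(self):
        for td in (1.0, 12.0, 27.0, 100.0):
            assert growth_rate_from_doubling(td) * td == pytest.approx(math.log(2))
        assert growth_rate_from_doubling(math.log(2)) == pytest.approx(1.0)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            growth_rate_from_doubling(0.0)


class TestFrequencyDataset:
    def test_simplex_violation_rejected(self):
        df = pd.DataFrame({
            "time_h": [0.0, 24.0], "replicate": ["r1", "r1"],
            "freq_adrn": [0.6, 0.6], "freq_mes": [0.5, 0.4],
        })
        with pytest.raises(ContractError):
            FrequencyDataset(df)

    def test_needs_two_times_per_replicate(self):
        df = pd.DataFrame({
            "time_h": [0.0], "replicate": ["r1"],
            "freq_adrn": [0.6], "freq_mes": [0.4],
        })
        with pytest.raises(ContractError):
            FrequencyDataset(df)


class TestExtractOffTherapy:
    def test_holiday_segment_from_treated_design(self, untreated_params):
        scen = reference_scenarios(seed=5)
        data = generate(scen["treated-cell-type"])
        off = extract_off_therapy(data)
        # only the 96 -> 264 h drug holiday survives, per replicate
        assert sorted(off.frame["time_h"].unique()) == [96.0, 264.0]
        assert off.condition == "UNTREATED"
        assert off.schedule == UNTREATED
        assert len(off.replicates) == 2

    def test_untreated_data_pass_through_whole(self):
        scen = reference_scenarios(seed=5)
        data = generate(scen["untreated-baseline"])
        off = extract_off_therapy(data)
        assert off.n_records == data.n_records


class TestResidualVector:
    def test_zero_on_self_consistent_data(self, untreated_params):
        scen = reference_scenarios(seed=2, noise_sd=0.0)
        data = generate(scen["untreated-baseline"])
        res = residual_vector(ModelId.BASELINE, untreated_params, data)
        assert np.all(np.abs(res) < 1e-6)

    def test_length_counts_post_initial_times(self, untreated_params):
        df = pd.DataFrame({
            "time_h": [48.0, 96.0], "replicate": ["r1", "r1"],
            "freq_adrn": [0.85, 0.9], "freq_mes": [0.15, 0.1],
        })
        data = FrequencyDataset(df)
        assert len(residual_vector(ModelId.BASELINE, untreated_params, data)) == 2
        assert len(residual_vector(ModelId.BASELINE, untreated_params, data,
                                   mode="adrn")) == 1

    def test_misspecified_alpha_rss_matches_euler_oracle(self, r_hour):
        """RSS against alpha=0.6-generated data agrees with direct Euler arithmetic."""
        gen = ModelParams(r=r_hour, alpha=0.6, beta=1.0)
        scen = reference_scenarios(seed=3, noise_sd=0.0)
        data = generate(replace(scen["untreated-baseline"], params=gen))
        wrong = ModelParams(r=r_hour, alpha=0.484, beta=1.0)
        res = residual_vector(ModelId.BASELINE, wrong, data)
        rss = float(np.sum(res**2))
        assert rss > 0
        # oracle: per replicate, Euler-integrate both parameter sets from 48 h
        x0 = data._series_arrays["r1"][1][0]
        exp = 0.0
        for t in (72.0, 96.0):
            xa_true, _ = euler_adrn_frequency(
                r=r_hour, alpha=0.6, beta=1.0, x0=(0.85, 0.15), t0=48.0, t_end=t)
            xa_fit, _ = euler_adrn_frequency(
                r=r_hour, alpha=0.484, beta=1.0, x0=(x0, 1 - x0), t0=48.0, t_end=t)
            exp += 2 * (xa_fit - xa_true) ** 2  # ADRN and MES entries
        assert rss == pytest.approx(2 * exp, rel=1e-3)  # 2 identical replicates


class TestFitSpec:
    def test_free_fixed_overlap_rejected(self):
        with pytest.raises(ContractError):
            FitSpec(model=ModelId.BASELINE, free=("alpha",),
                    fixed={"alpha": 0.5, "r": 0.026})

    def test_start_outside_bounds_rejected(self):
        with pytest.raises(ContractError):
            FitSpec(model=ModelId.BASELINE, free=("alpha",), fixed={"r": 0.026},
                    start={"alpha": 1.5})


class TestFit:
    def test_noise_free_baseline_recovery(self, r_hour):
        # pooled control + drug-holiday data: the control arm alone spans
        # too little of the frequency range to pin alpha and beta jointly
        data = untreated_calibration_dataset(seed=11, noise_sd=0.0)
        res = fit(FitSpec(model=ModelId.BASELINE, free=("alpha", "beta"),
                          fixed={"r": r_hour}), data)
        assert res.converged
        assert res.estimates["alpha"] == pytest.approx(0.484, abs=1e-3)
        assert res.estimates["beta"] == pytest.approx(1.0, abs=1e-3)

    def test_noise_free_gamma_recovery(self, r_hour):
        scen = reference_scenarios(seed=11, noise_sd=0.0)
        data = generate(scen["treated-cell-type"])
        res = fit(FitSpec(model=ModelId.CELLTYPE_THERAPY, free=("gamma",),
                          fixed={"r": r_hour, "alpha": 0.484, "beta": 1.0}), data)
        assert res.estimates["gamma"] == pytest.approx(0.01, abs=1e-3)
        assert res.rss < 1e-12

    def test_gamma_recovery_median_under_noise(self, r_hour):
        """Median fitted gamma over noisy datasets within 10% of truth."""
        scen = reference_scenarios()
        spec = FitSpec(model=ModelId.CELLTYPE_THERAPY, free=("gamma",),
                       fixed={"r": r_hour, "alpha": 0.484, "beta": 1.0})
        g = [
            fit(spec, generate(replace(scen["treated-cell-type"], seed=s))).estimates["gamma"]
            for s in range(50)
        ]
        assert abs(np.median(g) - 0.01) / 0.01 < 0.10

    def test_beta_bound_activity(self, r_hour):
        """Generating beta above the cap leaves the fitted beta at the bound."""
        scen = reference_scenarios(seed=0, noise_sd=0.0)
        gen = replace(scen["untreated-baseline"].params, beta=1.26)
        data = generate(replace(scen["untreated-baseline"], params=gen))
        res = fit(FitSpec(model=ModelId.BASELINE, free=("alpha", "beta"),
                          fixed={"r": r_hour}), data)
        assert res.estimates["beta"] > 0.999

    def test_all_fixed_spec_reports_rss_with_k_zero(self, untreated_params):
        scen = reference_scenarios(seed=4)
        data = generate(scen["untreated-baseline"])
        res = fit(FitSpec(model=ModelId.BASELINE, free=(),
                          fixed=untreated_params.as_dict()), data)
        assert res.k == 0 and res.n_iter == 0
        expected = float(np.sum(
            residual_vector(ModelId.BASELINE, untreated_params, data) ** 2))
        assert res.rss == pytest.approx(expected)

    def test_objective_never_increases(self, r_hour):
        """Fitted RSS is bounded by the RSS at the starting point."""
        scen = reference_scenarios()
        for s in (0, 1, 2):
            data = generate(replace(scen["untreated-baseline"], seed=s))
            spec = FitSpec(model=ModelId.BASELINE, free=("alpha", "beta"),
                           fixed={"r": r_hour})
            start_params = spec.build_params(
                {n: spec.start_for(n) for n in spec.free})
            start_rss = float(np.sum(
                residual_vector(ModelId.BASELINE, start_params, data) ** 2))
            assert fit(spec, data).rss <= start_rss + 1e-12

    def test_multi_start_never_worse(self, r_hour):
        scen = reference_scenarios(seed=6)
        data = generate(scen["untreated-baseline"])
        spec = FitSpec(model=ModelId.BASELINE, free=("alpha", "beta"),
                       fixed={"r": r_hour})
        single = fit(spec, data)
        multi = fit(replace(spec, n_restarts=3), data, seed=1)
        assert multi.rss <= single.rss + 1e-12
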