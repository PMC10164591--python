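"""Rate estimators: modal slope, end-product slope, burst fitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tailkin.types as T
from tailkin.gel import timecourse_table
from tailkin.kinetics import simulate
from tailkin.rates import (
    burst_fit,
    deadenylation_rate,
    endproduct_rate,
    relative_specific_activity,
)
from tailkin.types import InsufficientDataError, InvalidInputError


class TestDeadenylationRate:
    def test_closed_form_least_squares(self):
        assert deadenylation_rate([0, 5, 10], [70, 60, 50]) == pytest.approx(2.0)

    def test_flat_series_gives_zero(self):
        assert deadenylation_rate([0, 5, 10, 15], [70, 70, 70, 70]) == 0.0

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            deadenylation_rate([0, 5], [70, 60])
        # points after the modal length collapses do not count as usable
        with pytest.raises(InsufficientDataError):
            deadenylation_rate([0, 5, 10, 15], [70, 2, 0, 0])

    def test_exact_on_noiseless_linear_input_and_unit_invariance(self):
        t_min = np.arange(0.0, 12.0, 2.0)
        modal = 70.0 - 3.0 * t_min
        assert deadenylation_rate(t_min, modal) == pytest.approx(3.0, abs=1e-12)
        # same data with times in seconds, converted back to minutes
        t_s = t_min * 60.0
        assert deadenylation_rate(t_s / 60.0, modal) == pytest.approx(3.0, abs=1e-12)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(slope=st.floats(0.1, 8.0), intercept=st.floats(20.0, 80.0))
    def test_recovers_any_linear_series(self, slope, intercept):
        t = np.linspace(0.0, 10.0, 7)
        modal = intercept - slope * t
        keep = modal >= 5.0
        if keep.sum() < 3:
            return
        assert deadenylation_rate(t, modal) == pytest.approx(slope, rel=1e-9)

    def test_parameter_recovery_on_synchronous_distributive_run(self, default_params):
        # true synchronous shortening 4 nt/min: the per-molecule removal
        # rate is k_on * [E] * (k_cat_total / k_off) nt/s
        sub = T.SubstrateSpec("A70", 80, 70, 0, False, 20.0)
        p = default_params
        nt_per_engagement = (p.k_cat_ccr4 + p.k_cat_caf1) / p.k_off
        conc_e = 4.0 / (p.k_on * nt_per_engagement * 60.0)
        grid = np.linspace(0.0, 20 * 60.0, 21)
        ens = simulate(sub, T.mini_complex(conc_e), (), default_params, grid,
                       n_molecules=10000, seed=11)
        table = timecourse_table(ens)
        rate = deadenylation_rate(table.time_s / 60.0, table.modal_tail_nt)
        assert rate == pytest.approx(4.0, rel=0.10)


class TestEndproductRate:
    def test_linear_accumulation_arithmetic(self):
        rate = endproduct_rate([0.0, 1.0, 2.0], [0.0, 0.5, 1.0], conc_total=20.0)
        assert rate == pytest.approx(10.0)

    def test_all_zero_fractions_give_zero(self):
        assert endproduct_rate([0, 1, 2, 3], [0, 0, 0, 0], 20.0) == 0.0

    def test_lag_phase_is_excluded(self):
        t = np.arange(0.0, 10.0)
        f = np.where(t < 5, 0.0, (t - 5) * 0.1)
        rate = endproduct_rate(t, f, conc_total=10.0)
        assert rate == pytest.approx(1.0, rel=1e-6)

    def test_wt_mut_scenario_ratio_near_50(self):
        # the SRE(WT)/SRE(MUT) pair is generated with tethered vs basal
        # kinetics configured for a ~50-fold end-product rate ratio
        from tailkin.scenarios import scenario
        ratios = []
        for seed in (21, 40, 60):
            wt = scenario("smaug_sre_wt", seed=seed, n_molecules=2000)
            mut = scenario("smaug_sre_mut", seed=seed + 1, n_molecules=2000)
            tw, tm = timecourse_table(wt), timecourse_table(mut)
            r_wt = endproduct_rate(tw.time_s / 60.0, tw.frac_deadenylated, 20.0)
            r_mut = endproduct_rate(tm.time_s / 60.0, tm.frac_deadenylated, 20.0)
            ratios.append(r_wt / r_mut)
        assert np.mean(ratios) == pytest.approx(50.0, rel=0.25)


class TestBurstFit:
    def test_pure_linear_data_has_negligible_burst(self):
        t = np.linspace(0.0, 30.0, 16)
        A, k, v = burst_fit(t, 0.2 * t)
        assert A == pytest.approx(0.0, abs=0.05)
        assert v == pytest.approx(0.2, rel=0.05)

    def test_self_consistency_at_one_percent_noise(self):
        rng = np.random.default_rng(5)
        t = np.linspace(0.0, 30.0, 25)
        true = 6.0 * (1.0 - np.exp(-2.0 * t)) + 0.05 * t
        noisy = true * (1.0 + 0.01 * rng.standard_normal(t.size))
        A, k, v = burst_fit(t, noisy)
        assert A == pytest.approx(6.0, rel=0.10)
        assert k == pytest.approx(2.0, rel=0.15)
        assert v == pytest.approx(0.05, rel=0.15)

    def test_pure_burst_limit_amplitude_is_one_per_enzyme(self, default_params):
        # with handoff disabled each enzyme completes exactly one RNA, so the
        # fitted amplitude equals the enzyme concentration
        import dataclasses
        p = dataclasses.replace(default_params, handoff_rate=0.0,
                                tether_off_scale=1e-12)
        ens = simulate(T.tce_a70(conc=50.0), T.mini_complex(5.0), (T.smaug(300.0),),
                       p, np.array([0.0, 1.0, 2.0, 3.0, 5.0, 10.0, 20.0, 40.0]),
                       n_molecules=10000, seed=8, pre_bound=True)
        table = timecourse_table(ens)
        A, k, v = burst_fit(table.time_s.to_numpy(),
                            table.frac_deadenylated.to_numpy() * 50.0)
        assert A / 5.0 == pytest.approx(1.0, rel=0.05)
        assert v == pytest.approx(0.0, abs=0.01)

    def test_burst_reading_at_first_time_point_gives_1p2_per_enzyme(self, burst_ensemble):
        # the gel-lane reading: product present at the 5-s time point,
        # divided by the enzyme concentration (12% of 50 nM over 5 nM)
        table = timecourse_table(burst_ensemble)
        amplitude = table.frac_deadenylated.iloc[1] * 50.0
        assert amplitude / 5.0 == pytest.approx(1.2, rel=0.10)

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            burst_fit([0, 1, 2, 3], [0, 1, 2, 3])


class TestRelativeSpecificActivity:
    def test_heterodimer_worked_example(self):
        # 250 nM heterodimer matches 5 nM of the full complex: 2%
        assert relative_specific_activity(5.0, 250.0) == pytest.approx(0.02)

    def test_zero_concentration_rejected(self):
        with pytest.raises(InvalidInputError):
            relative_specific_activity(0.0, 250.0)
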