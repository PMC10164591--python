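"""Core simulator: occupancy, PABPC packing, and the stochastic process."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tailkin.types as T
from tailkin.kinetics import effector_occupancy, pabpc_load, simulate
from tailkin.types import InvalidInputError, KineticParams


class TestEffectorOccupancy:
    @pytest.mark.parametrize("conc, kd, expected", [
        (0.0, 3.0, 0.0),           # no ligand
        (3.0, 3.0, 0.5),           # half-saturation identity
        (30.0, 3.0, 30.0 / 33.0),  # simple arithmetic
    ])
    def test_occupancy_values(self, conc, kd, expected):
        sub = T.sre_only_a70(conc=20.0)
        assert effector_occupancy(T.EffectorSpec("cup", conc, kd), sub) == pytest.approx(expected)

    def test_smaug_requires_functional_sre(self):
        smg = T.smaug(80.0)
        assert effector_occupancy(smg, T.sre_only_a70(wild_type=False)) == 0.0
        assert effector_occupancy(smg, T.fam7_a20()) == 0.0
        assert effector_occupancy(smg, T.sre_only_a70(wild_type=True)) > 0.98

    def test_negative_concentration_rejected(self):
        with pytest.raises(InvalidInputError):
            T.EffectorSpec("cup", -1.0, 3.0)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(conc=st.floats(0, 1e4), kd=st.floats(0.01, 1e3))
    def test_occupancy_bounded_and_monotone(self, conc, kd):
        sub = T.sre_only_a70()
        occ = effector_occupancy(T.EffectorSpec("pabpc", conc, kd), sub)
        assert 0.0 <= occ < 1.0
        assert effector_occupancy(T.EffectorSpec("pabpc", conc + 1.0, kd), sub) >= occ


class TestPabpcLoad:
    def test_four_copies_on_70nt_tail_at_saturation(self):
        # maximal packing with the 17-nt footprint
        assert pabpc_load(70, KineticParams(), conc=1e6) == 4

    def test_nothing_binds_an_absent_tail(self):
        assert pabpc_load(0, KineticParams(), conc=1e6) == 0

    def test_half_saturation_matches_site_filling_oracle(self):
        # brute force: 4 independent sites each occupied w.p. 0.5; the
        # expected copy number over all 2^4 fill states, rounded half up
        sites, occ = 4, 0.5
        expected_copies = 0.0
        for state in range(2 ** sites):
            p = 1.0
            n = 0
            for s in range(sites):
                if state >> s & 1:
                    p *= occ
                    n += 1
                else:
                    p *= 1 - occ
            expected_copies += p * n
        oracle = int(np.floor(expected_copies + 0.5))
        assert pabpc_load(70, KineticParams(), conc=10.0, kd=10.0) == oracle

    def test_monotone_in_conc_and_tail(self):
        p = KineticParams()
        loads_conc = [pabpc_load(70, p, c) for c in (0, 5, 10, 40, 200)]
        assert loads_conc == sorted(loads_conc)
        loads_tail = [pabpc_load(t, p, 200.0) for t in (0, 17, 34, 70)]
        assert loads_tail == sorted(loads_tail)

    def test_bad_footprint_rejected(self):
        with pytest.raises(InvalidInputError):
            KineticParams(pabpc_footprint=0)


class TestSimulateBasics:
    def test_no_enzyme_leaves_tails_untouched(self, default_params):
        ens = simulate(T.fam7_a20(50.0), T.mini_complex(0.0), (), default_params,
                       [0.0, 60.0, 600.0], n_molecules=200, seed=1)
        for state in ens.states:
            assert np.all(state.tail_lengths == 20)

    def test_invalid_inputs_rejected(self, default_params):
        sub = T.fam7_a20(50.0)
        enz = T.mini_complex(5.0)
        with pytest.raises(InvalidInputError):
            simulate(sub, enz, (), default_params, [], n_molecules=10, seed=1)
        with pytest.raises(InvalidInputError):
            simulate(sub, enz, (), default_params, [0.0, 60.0], n_molecules=0, seed=1)
        with pytest.raises(InvalidInputError):
            KineticParams(k_on=-1.0)

    def test_conservation_and_monotone_tails(self, small_basal_ensemble):
        ens = small_basal_ensemble
        n = ens.states[0].tail_lengths.size
        prev = None
        for state in ens.states:
            tails = state.tail_lengths
            assert tails.size == n
            assert tails.min() >= 0 and tails.max() <= 20
            if prev is not None:
                assert np.all(tails <= prev)
            prev = tails

    def test_pabpc_copies_respect_footprint(self, default_params):
        sub = T.sre_only_a70(conc=5.0)
        ens = simulate(sub, T.mini_complex(2.0), (T.pabpc(200.0),), default_params,
                       np.linspace(0, 1200, 5), n_molecules=400, seed=3)
        fp = default_params.pabpc_footprint
        for state in ens.states:
            assert np.all(state.pabpc_copies <= state.tail_lengths // fp)

    def test_identical_seed_gives_bit_identical_ensembles(self, default_params):
        sub = T.sre_only_a70(conc=20.0)
        args = (sub, T.mini_complex(2.0), (T.smaug(80.0),), default_params,
                np.linspace(0, 300, 7))
        a = simulate(*args, n_molecules=500, seed=9)
        b = simulate(*args, n_molecules=500, seed=9)
        c = simulate(*args, n_molecules=500, seed=10)
        for sa, sb in zip(a.states, b.states):
            assert np.array_equal(sa.tail_lengths, sb.tail_lengths)
            assert np.array_equal(sa.enzyme_bound, sb.enzyme_bound)
        assert any(not np.array_equal(sa.tail_lengths, sc.tail_lengths)
                   for sa, sc in zip(a.states, c.states))


class TestMechanisticLimits:
    def test_fully_processive_limit_matches_gamma_moments(self):
        # one enzyme pre-engaged per molecule, no dissociation, no handoff:
        # per-molecule completion time is Gamma(70, 50/s): mean 1.4 s,
        # variance 70/50^2 = 0.028 s^2
        p = KineticParams(tether_off_scale=1e-12, k_off=0.0, handoff_rate=0.0)
        sub = T.tce_a70(conc=50.0)
        grid = np.arange(0.0, 3.0, 0.01)
        ens = simulate(sub, T.mini_complex(50.0), (T.smaug(1e6),), p, grid,
                       n_molecules=3000, seed=2, pre_bound=True)
        F = np.array([np.mean(s.tail_lengths == 0) for s in ens.states])
        mean = np.trapezoid(1.0 - F, grid)
        var = np.trapezoid(2.0 * grid * (1.0 - F), grid) - mean ** 2
        assert mean == pytest.approx(70.0 / 50.0, rel=0.02)
        assert var == pytest.approx(70.0 / 50.0 ** 2, rel=0.15)

    def test_processive_limit_only_initially_engaged_finish(self, default_params):
        p = KineticParams(tether_off_scale=1e-12, k_off=0.0, handoff_rate=0.0)
        sub = T.tce_a70(conc=50.0)
        ens = simulate(sub, T.mini_complex(5.0), (T.smaug(1e6),), p,
                       [0.0, 60.0], n_molecules=2000, seed=4, pre_bound=True)
        bound0 = ens.states[0].enzyme_bound
        final = ens.states[-1].tail_lengths
        assert np.all(final[bound0] == 0)
        assert np.all(final[~bound0] == 70)

    def test_burst_fraction_matches_renewal_oracle(self, burst_ensemble):
        # analytic oracle: per enzyme, completions by 5 s are the first tail
        # (Gamma(70, 50/s), ~1.4 s) plus a second if the exponential handoff
        # wait fits into the remaining 5 - 2*1.4 = 2.2 s:
        # 1 + (1 - exp(-0.1*2.2)) = 1.1975 per enzyme; 5 nM enzyme on 50 nM
        # RNA gives 11.98% fully deadenylated.
        frac5 = float(np.mean(burst_ensemble.states[1].tail_lengths == 0))
        oracle = (1.0 + (1.0 - np.exp(-0.1 * 2.2))) * 5.0 / 50.0
        assert frac5 == pytest.approx(oracle, abs=0.01)

    def test_distributive_limit_matches_single_molecule_oracle(self, default_params):
        # with a large excess of enzyme the population process reduces to
        # independent single-molecule kinetics; compare removal-count
        # distributions at a fixed time against a brute-force CTMC oracle
        p = default_params
        conc_e = 500.0
        sub = T.fam7_a20(conc=50.0)
        t_star = 5.0
        ens = simulate(sub, T.mini_complex(conc_e), (), p, [0.0, t_star],
                       n_molecules=10000, seed=11)
        removed = 20 - ens.states[1].tail_lengths

        rng = np.random.default_rng(1234)
        kb = p.k_on * conc_e
        kcat = p.k_cat_ccr4 + p.k_cat_caf1
        oracle = np.empty(10000, dtype=np.int64)
        for i in range(10000):
            t, tail, bound = 0.0, 20, False
            while True:
                rate = kb if not bound else (p.k_off + (kcat if tail > 0 else 0.0))
                t += rng.exponential(1.0 / rate)
                if t >= t_star:
                    break
                if not bound:
                    bound = True
                elif tail > 0 and rng.random() < kcat / (p.k_off + kcat):
                    tail -= 1
                else:
                    bound = False
            oracle[i] = 20 - tail

        hi = max(removed.max(), oracle.max())
        bins = np.arange(hi + 2)
        obs = np.bincount(removed, minlength=hi + 1)
        exp = np.bincount(oracle, minlength=hi + 1)
        # pool sparse bins, then a two-sample chi-square at alpha = 0.01
        from scipy.stats import chi2
        mask = (obs + exp) >= 10
        o = np.append(obs[mask], obs[~mask].sum())
        e = np.append(exp[mask], exp[~mask].sum())
        with np.errstate(divide="ignore", invalid="ignore"):
            stat = np.nansum((o - e) ** 2 / (o + e))
        df = o.size - 1
        assert stat < chi2.ppf(0.99, df)

    def test_single_dead_subunit_cuts_rate_to_20_percent(self, default_params):
        # equal subunit rates with theta_dead = 0.6: engaged catalysis is
        # 0.4 * 25 = 10 nt/s vs 50, and per-engagement removals scale the
        # same way, so the mean removal rate is 20% of wild type
        sub = T.fam7_a20(conc=50.0)
        grid = [0.0, 600.0]
        wt = simulate(sub, T.mini_complex(5.0), (), default_params, grid,
                      n_molecules=4000, seed=21)
        dead = simulate(sub, T.mini_complex(5.0, caf1_active=False), (),
                        default_params, grid, n_molecules=4000, seed=22)
        r_wt = np.mean(20 - wt.states[1].tail_lengths)
        r_dead = np.mean(20 - dead.states[1].tail_lengths)
        assert r_dead / r_wt == pytest.approx(0.2, rel=0.15)

    def test_both_dead_removes_exactly_zero(self, default_params):
        sub = T.fam7_a20(conc=50.0)
        ens = simulate(sub, T.mini_complex(5.0, ccr4_active=False, caf1_active=False),
                       (), default_params, [0.0, 600.0], n_molecules=300, seed=23)
        assert np.all(ens.states[-1].tail_lengths == 20)

    def test_not_module_gate_blocks_smaug(self, default_params):
        # without the NOT module the complex barely responds to Smaug
        sub = T.sre_only_a70(conc=20.0)
        grid = [0.0, 600.0]
        plain = simulate(sub, T.core_complex(10.0), (), default_params, grid,
                         n_molecules=3000, seed=31)
        with_smg = simulate(sub, T.core_complex(10.0), (T.smaug(80.0),),
                            default_params, grid, n_molecules=3000, seed=32)
        r0 = np.mean(70 - plain.states[1].tail_lengths)
        r1 = np.mean(70 - with_smg.states[1].tail_lengths)
        assert abs(r1 - r0) / r0 < 0.05
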