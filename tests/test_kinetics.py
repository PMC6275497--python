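"""Bell escape rates, MFPT estimation, rate scaling, and f_FL solvers."""

import numpy as np
import pytest
from scipy.linalg import expm

from ribofold.kinetics import (BellParameters, KineticScheme, bell_rate,
                               kmc_ffl, master_equation_ffl, mfpt_censored,
                               preeq_ffl, profile_rmsd, scale_rates,
                               assemble_profile)
from ribofold.equilibrium import EquilibriumSummary
from ribofold.units import KB


class TestBellRate:
    def test_zero_force_returns_k0(self):
        p = BellParameters()
        assert bell_rate(0.0, p) == pytest.approx(3.4e-4)

    def test_doubling_force(self):
        # F* = ln2 kT/dx = 8.703 pN at 291 K, dx = 0.32 nm
        p = BellParameters()
        f_double = np.log(2) * KB * 291.0 / 0.32 * 1.66054
        assert f_double == pytest.approx(8.703, abs=0.005)
        assert bell_rate(f_double, p) == pytest.approx(2 * p.k0, rel=1e-9)

    def test_20_pn(self):
        # direct evaluation: beta F dx = 1.593 -> k = 1.674e-3 s^-1
        assert bell_rate(20.0) == pytest.approx(1.672e-3, rel=1e-3)

    def test_admissible_range_warnings(self):
        with pytest.warns(UserWarning):
            BellParameters(k0=5e-3)
        with pytest.warns(UserWarning):
            BellParameters(dx=0.05)

    def test_invalid(self):
        with pytest.raises(ValueError):
            BellParameters(k0=-1.0)


class TestMFPT:
    def test_no_censoring(self):
        est = mfpt_censored(np.full(50, 1.0), 50, 4.0)
        assert est.value == pytest.approx(1.0)

    def test_formula_with_censoring(self):
        # N=2, one event at 1 us, one censored at 4 us -> (1+4)/1 = 5
        est = mfpt_censored([1.0], 2, 4.0)
        assert est.value == pytest.approx(5.0)

    def test_all_censored_lower_bound(self):
        est = mfpt_censored([], 10, 4.0)
        assert est.lower_bound_only
        assert est.value == pytest.approx(40.0)

    def test_recovers_exponential_rate_under_censoring(self, rng):
        # Monte-Carlo oracle: censored exponential data, ~30% censoring
        k_true, n = 1.0, 400
        t_sim = 1.2  # exp(-1.2) ~ 30% of trajectories censored
        t = rng.exponential(1.0 / k_true, size=n)
        events = t[t <= t_sim]
        est = mfpt_censored(events, n, t_sim)
        k_hat = 1.0 / est.value
        se = k_true / np.sqrt(len(events))
        assert abs(k_hat - k_true) < 3 * se


class TestKMC:
    def test_degenerate_single_exponential(self):
        # only UA -> UR at k0: f_FL(t) = 1 - exp(-k0 t) = 0.264 at 900 s
        scheme = KineticScheme(kf=0.0, ku=0.0, ke_u=3.4e-4, ke_f=0.0)
        res = kmc_ffl(scheme, t_total=900.0, n_replicas=4000, seed=2)
        expected = 1.0 - np.exp(-3.4e-4 * 900.0)
        assert expected == pytest.approx(0.2636, abs=1e-4)
        assert abs(res.f_fl - expected) < 3 * max(res.se, 1e-3)

    def test_zero_time(self):
        scheme = KineticScheme(kf=1.0, ku=1.0, ke_u=0.1, ke_f=0.1)
        assert kmc_ffl(scheme, t_total=0.0, n_replicas=10, seed=0).f_fl == 0.0

    def test_zero_outflow_raises(self):
        scheme = KineticScheme(kf=0.0, ku=0.0, ke_u=0.0, ke_f=0.0)
        with pytest.raises(ValueError):
            kmc_ffl(scheme, t_total=1.0, n_replicas=2, seed=0)

    @pytest.mark.parametrize("kf,ku,ke", [
        (1e-3, 1e-3, 1e-3), (1e-2, 1e-3, 5e-4), (1e-3, 1e-2, 2e-3),
    ])
    def test_matches_master_equation(self, kf, ku, ke):
        scheme = KineticScheme(kf=kf, ku=ku, ke_u=ke, ke_f=2 * ke)
        exact = master_equation_ffl(scheme, 900.0)
        res = kmc_ffl(scheme, 900.0, n_replicas=3000, seed=11)
        assert abs(res.f_fl - exact) < 3 * max(res.se, 1e-3)

    def test_master_equation_is_expm(self):
        # the solver really is the matrix exponential of the generator
        scheme = KineticScheme(kf=2e-3, ku=1e-3, ke_u=1e-3, ke_f=3e-3)
        q = scheme.generator()
        p = np.array([1.0, 0, 0, 0]) @ expm(q * 500.0)
        assert master_equation_ffl(scheme, 500.0) == pytest.approx(
            p[2] + p[3])

    def test_survival_non_increasing(self):
        scheme = KineticScheme(kf=1e-2, ku=1e-3, ke_u=1e-3, ke_f=3e-3)
        res = kmc_ffl(scheme, 900.0, n_replicas=500, seed=3)
        s = res.survival(np.linspace(0, 900, 50))
        assert np.all(np.diff(s) <= 1e-12)


class TestPreeq:
    def test_unfolded_baseline(self):
        # P_f = 0, F_u = 0: f = 1 - exp(-k0 t) = 0.264 at 900 s
        assert preeq_ffl(1.0, 0.0, 0.0, 0.0, 900.0) == pytest.approx(
            0.2636, abs=1e-4)

    def test_long_time_limit(self):
        assert preeq_ffl(0.5, 0.5, 5.0, 10.0, 1e9) == pytest.approx(1.0)

    def test_monotone_in_time_and_force(self):
        ts = [100.0, 500.0, 900.0]
        vals = [preeq_ffl(0.3, 0.7, 2.0, 15.0, t) for t in ts]
        assert vals == sorted(vals)
        ffs = [5.0, 10.0, 20.0]
        vals = [preeq_ffl(0.3, 0.7, 2.0, ff, 900.0) for ff in ffs]
        assert vals == sorted(vals)

    def test_population_sum_validated(self):
        with pytest.raises(ValueError):
            preeq_ffl(0.5, 0.6, 0.0, 0.0, 900.0)


class TestScaleRates:
    def test_identity_when_already_anchored(self):
        L = [21, 41, 61]
        ku = [4.9e-2, 9.8e-3, 4.9e-4]
        kf = [1e-3, 1e-2, 0.14]
        rs = scale_rates(L, kf, ku, 4.9e-4, 0.14 / 4.9e-4)
        assert rs.factor_u == pytest.approx(1.0)
        assert rs.factor_f == pytest.approx(1.0)

    def test_input_scale_invariance(self):
        L = [21, 61]
        rs1 = scale_rates(L, [1.0, 2.0], [3.0, 4.0], 4.9e-4, 100.0)
        rs2 = scale_rates(L, [2.0, 4.0], [6.0, 8.0], 4.9e-4, 100.0)
        assert np.allclose(rs1.kf, rs2.kf)
        assert np.allclose(rs1.ku, rs2.ku)

    def test_ratios_preserved_and_anchor_exact(self):
        L = [21, 41, 61]
        kf = [0.3, 1.1, 2.9]
        ku = [5.0, 1.0, 0.2]
        rs = scale_rates(L, kf, ku, 4.9e-4, 285.7)
        assert rs.ku[2] == pytest.approx(4.9e-4, rel=1e-12)
        assert rs.kf[2] / rs.ku[2] == pytest.approx(285.7, rel=1e-12)
        assert rs.ku[0] / rs.ku[1] == pytest.approx(ku[0] / ku[1])

    def test_missing_anchor(self):
        with pytest.raises(ValueError):
            scale_rates([], [], [], 4.9e-4, 1.0)


def _summary(L, p_f, f_u, f_f):
    return EquilibriumSummary(L=L, p_u=1 - p_f, p_f=p_f,
                              f_u_pn=f_u, f_f_pn=f_f)


class TestProfile:
    def test_preeq_matches_kmc_in_fast_folding_regime(self):
        # folding/unfolding >= 100x escape: the preequilibrium assumption
        # holds and the two solvers agree closely
        from ribofold.kinetics import RateSet, bell_rate
        summaries = [_summary(L, pf, 2.0, ff) for L, pf, ff in
                     [(10, 0.05, 25.0), (20, 0.5, 18.0), (30, 0.95, 4.0)]]
        ke_max = float(bell_rate(25.0))
        # detailed-balance-consistent rates: kf/ku = P_f/P_u per L
        kf = np.full(3, 200 * ke_max)
        ku = np.array([kf[i] * s.p_u / s.p_f
                       for i, s in enumerate(summaries)])
        rates = RateSet(np.array([10., 20., 30.]), kf, ku, kf, ku,
                        1.0, 1.0, 4.9e-4, 1.0)
        prof = assemble_profile(summaries, rates, t=900.0,
                                n_replicas=20000, seed=4)
        diff = np.abs(prof.table.f_fl_kmc - prof.table.f_fl_preeq)
        assert np.all(diff < 0.02)
        assert not prof.table.flagged.any()

    def test_grid_mismatch_raises(self):
        from ribofold.kinetics import RateSet
        summaries = [_summary(10, 0.5, 1.0, 2.0)]
        rates = RateSet(np.array([20.0]), np.ones(1), np.ones(1),
                        np.ones(1), np.ones(1), 1, 1, 4.9e-4, 1.0)
        with pytest.raises(ValueError):
            assemble_profile(summaries, rates)


class TestProfileRMSD:
    def test_identity_and_offset(self):
        import pandas as pd
        a = pd.DataFrame({"L": [1, 2, 3], "f_fl_kmc": [0.1, 0.5, 0.3]})
        b = pd.DataFrame({"L": [1, 2, 3], "f_fl": [0.1, 0.5, 0.3]})
        assert profile_rmsd(a, b) == pytest.approx(0.0)
        b["f_fl"] += 0.1
        assert profile_rmsd(a, b) == pytest.approx(0.1)

    def test_hand_computed_three_point(self):
        import pandas as pd
        a = pd.DataFrame({"L": [1, 2, 3], "f_fl_kmc": [0.2, 0.4, 0.9]})
        b = pd.DataFrame({"L": [1, 2, 3], "f_fl": [0.1, 0.6, 0.8]})
        # sqrt((0.01+0.04+0.01)/3)
        assert profile_rmsd(a, b) == pytest.approx(np.sqrt(0.06 / 3))

    def test_no_shared_L(self):
        import pandas as pd
        a = pd.DataFrame({"L": [1], "f_fl_kmc": [0.2]})
        b = pd.DataFrame({"L": [2], "f_fl": [0.1]})
        with pytest.raises(ValueError):
            profile_rmsd(a, b)


class TestBellProperties:
    """Bell-model identities: multiplicativity in force and bounds."""

    from hypothesis import given, settings, strategies as st

    @given(st.floats(min_value=0.0, max_value=40.0),
           st.floats(min_value=0.0, max_value=40.0))
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_force_additivity_multiplies_rates(self, f1, f2):
        p = BellParameters()
        lhs = bell_rate(f1 + f2, p)
        rhs = bell_rate(f1, p) * bell_rate(f2, p) / p.k0
        assert lhs == pytest.approx(rhs, rel=1e-12)

    @given(st.floats(min_value=0.0, max_value=1.0),
           st.floats(min_value=0.0, max_value=30.0),
           st.floats(min_value=0.0, max_value=30.0),
           st.floats(min_value=0.0, max_value=3600.0))
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_preeq_ffl_is_a_probability(self, p_f, f_u, f_f, t):
        val = preeq_ffl(1.0 - p_f, p_f, f_u, f_f, t)
        assert 0.0 <= val <= 1.0
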