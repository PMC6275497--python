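"""Transition-path extraction and pathway estimators vs ground truth."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from ribofold.fixtures import SyntheticTrajectorySpec, make_synthetic_tp_ensemble
from ribofold.pathway import (TPEnsemble, compare_phi, contact_states,
                              extract_tps, mechanism_report, p_tp_given_q,
                              p_tp_nn, phi_values, TP, UNFOLDED, FOLDED)


class TestExtractTPs:
    def test_last_exit_first_entry(self):
        # TP starts at the *last* frame below 0.3 before the first crossing
        q = [0.1, 0.2, 0.35, 0.25, 0.4, 0.8]
        assert extract_tps(q) == [(3, 5)]

    def test_brute_force_on_random_walks(self, rng):
        # oracle: scan all (s, e) candidates directly
        def brute(q, lo, hi):
            out, s = [], None
            for t, v in enumerate(q):
                if v < lo:
                    s = t
                elif v > hi and s is not None:
                    out.append((s, t))
                    s = None
            return out

        for _ in range(20):
            q = np.clip(np.cumsum(rng.normal(0, 0.15, 300)) + 0.5, -0.2, 1.2)
            assert extract_tps(q) == brute(q, 0.3, 0.7)

    def test_monotone_series_single_tp(self):
        q = np.linspace(0.1, 0.9, 17)
        assert len(extract_tps(q)) == 1

    def test_confined_series_no_tp(self):
        q = np.linspace(0.4, 0.6, 50)
        assert extract_tps(q) == []

    def test_unfolding_direction_mirrors(self):
        q = [0.9, 0.8, 0.65, 0.75, 0.6, 0.2]
        assert extract_tps(q, direction="unfolding") == [(3, 5)]
        assert extract_tps(q) == []

    def test_multiple_tps(self):
        q = [0.1, 0.8, 0.2, 0.9, 0.5]
        assert extract_tps(q) == [(0, 1), (2, 3)]


class TestContactStates:
    def test_boundary_is_strictly_not_formed(self):
        r0 = np.array([0.5])
        d = np.array([[0.6], [0.6000001], [0.5999999]])
        formed = contact_states(d, r0, lam=1.2)
        assert formed.tolist() == [[False], [False], [True]]

    def test_native_and_extended_frames(self):
        r0 = np.array([0.5, 0.6])
        native = r0[None, :]
        extended = 10 * r0[None, :]
        assert contact_states(native, r0).all()
        assert not contact_states(extended, r0).any()


class TestPhi:
    def test_limits(self):
        pairs = np.array([[0, 4], [0, 5], [1, 6]])
        formed = np.zeros((10, 3), dtype=bool)
        formed[:, :2] = True  # contacts of residue 0 always formed on TPs
        ens = TPEnsemble(formed, np.full(10, TP), pairs)
        phi = phi_values(ens, n_residues=7)
        assert phi[0] == pytest.approx(1.0)
        assert phi[1] == pytest.approx(0.0)
        assert np.isnan(phi[2])  # residue 2 has no contacts: undefined

    def test_empty_ensemble_raises(self):
        pairs = np.array([[0, 4]])
        ens = TPEnsemble(np.zeros((5, 1), bool), np.full(5, UNFOLDED), pairs)
        with pytest.raises(ValueError):
            phi_values(ens)


class TestPTPnn:
    def test_hand_arithmetic(self):
        assert p_tp_nn(0.05, 1.0) == pytest.approx(0.1 / 1.1)

    def test_vanishing_tp_time(self):
        assert p_tp_nn(1e-12, 1.0) == pytest.approx(0.0, abs=1e-10)

    def test_unfolding_harvest_formula(self):
        # 2 t / (2 t + (pU/pF) tU)
        val = p_tp_nn(0.05, 2.0, harvest="unfolding", p_u=0.2, p_f=0.8)
        assert val == pytest.approx(0.1 / (0.1 + 0.25 * 2.0))

    def test_unfolding_needs_populations(self):
        with pytest.raises(ValueError):
            p_tp_nn(0.05, 2.0, harvest="unfolding")
        with pytest.raises(ValueError):
            p_tp_nn(0.05, 2.0, harvest="unfolding", p_u=1.0, p_f=0.0)

    def test_folding_and_unfolding_agree_on_reversible_chain(self, rng):
        # discrete-state Markov oracle: a two-state random walk on Q where
        # both harvest directions see the same TPs at equilibrium
        n_states = 21
        q_grid = np.linspace(0, 1, n_states)
        g = 120.0 * (q_grid - 0.1) ** 2 * (q_grid - 0.9) ** 2  # ~3 kT barrier
        beta = 1.0
        p_acc = np.exp(-beta * np.clip(np.diff(g), 0, None))
        state = 0
        traj = np.empty(400000, dtype=int)
        for t in range(traj.size):
            step = 1 if rng.random() < 0.5 else -1
            nxt = min(max(state + step, 0), n_states - 1)
            dg = g[nxt] - g[state]
            if dg <= 0 or rng.random() < np.exp(-beta * dg):
                state = nxt
            traj[t] = state
        q = q_grid[traj]
        p_f_eq = (q > 0.5).mean()
        p_u_eq = 1 - p_f_eq
        tps_f = extract_tps(q)
        tps_u = extract_tps(q, direction="unfolding")
        t_tp = np.mean([e - s for s, e in tps_f + tps_u])
        # MFPTs from mean segment lengths between commitments
        t_f_mfpt = q.size * p_u_eq / max(len(tps_f), 1)
        t_u_mfpt = q.size * p_f_eq / max(len(tps_u), 1)
        est_f = p_tp_nn(t_tp, t_f_mfpt, harvest="folding")
        est_u = p_tp_nn(t_tp, t_u_mfpt, harvest="unfolding",
                        p_u=p_u_eq, p_f=p_f_eq)
        assert est_f == pytest.approx(est_u, rel=0.3)


class TestPTPGivenQ:
    def test_independence_identity(self):
        spec = SyntheticTrajectorySpec(n_contacts=5, p_tp=0.4, p_nontp=0.4,
                                       ptp_nn=0.12, n_frames=40000, seed=3)
        ens = make_synthetic_tp_ensemble(spec)
        vals = p_tp_given_q(ens, spec.ptp_nn, pq_nn_mode="reweighted")
        # exact in expectation; finite-sample deviation is binomial
        assert np.allclose(vals, spec.ptp_nn, atol=0.01)

    def test_tp_only_contact_gives_one(self):
        spec = SyntheticTrajectorySpec(n_contacts=3, p_tp=[0.5, 0.5, 0.5],
                                       p_nontp=[0.0, 0.2, 0.2],
                                       ptp_nn=0.1, n_frames=50000, seed=4)
        ens = make_synthetic_tp_ensemble(spec)
        vals = p_tp_given_q(ens, spec.ptp_nn, pq_nn_mode="reweighted")
        assert vals[0] == pytest.approx(1.0)

    def test_matches_generator_ground_truth(self):
        spec = SyntheticTrajectorySpec(
            n_contacts=8,
            p_tp=np.linspace(0.2, 0.9, 8),
            p_nontp=np.linspace(0.05, 0.3, 8),
            ptp_nn=0.15, n_frames=100000, seed=5)
        ens = make_synthetic_tp_ensemble(spec)
        est = p_tp_given_q(ens, spec.ptp_nn)
        truth = spec.true_p_tp_given_q()
        # binomial error propagated through the Bayes ratio
        n_tp = (ens.labels == TP).sum()
        se = 3 * np.sqrt(truth * (1 - truth) / n_tp + 1e-6)
        assert np.all(np.abs(est - truth) < np.maximum(se, 0.02))

    def test_phi_matches_generator(self):
        spec = SyntheticTrajectorySpec(
            n_contacts=8, p_tp=np.linspace(0.2, 0.9, 8), p_nontp=0.1,
            ptp_nn=0.15, n_frames=100000, seed=6)
        ens = make_synthetic_tp_ensemble(spec)
        phi = phi_values(ens)
        truth = spec.true_phi()
        n_tp = (ens.labels == TP).sum()
        se = 3 * np.sqrt(0.25 / n_tp)
        m = ~np.isnan(truth)
        assert np.all(np.abs(phi[m] - truth[m]) < np.maximum(se, 0.02))


class TestFromTrajectory:
    def test_labels_and_folded_exclusion(self):
        q = np.array([0.1, 0.25, 0.5, 0.8, 0.9, 0.6, 0.2])
        r0 = np.array([0.5])
        d = np.where(q > 0.5, 0.5, 2.0)[:, None]
        ens = TPEnsemble.from_trajectory(q, d, r0, np.array([[0, 4]]),
                                         stop_at_first_fold=False)
        assert ens.labels.tolist() == [UNFOLDED, TP, TP, TP, FOLDED,
                                       UNFOLDED, UNFOLDED]
        # folded frames excluded from nn statistics
        assert len(ens.nn_frames) == 6

    def test_stop_at_first_fold(self):
        q = np.array([0.1, 0.8, 0.1, 0.8])
        d = np.full((4, 1), 2.0)
        ens = TPEnsemble.from_trajectory(q, d, np.array([0.5]),
                                         np.array([[0, 4]]))
        assert len(ens.labels) == 2


class TestComparePhi:
    @staticmethod
    def _ref(res, phi, ddg):
        return pd.DataFrame({"residue": res, "phi_exp": phi, "ddg_kj": ddg})

    def test_identical_ranking(self):
        phi = np.array([0.1, 0.5, 0.9, 0.3, 0.7])
        ref = self._ref(np.arange(5), phi, np.full(5, 10.0))
        cmp = compare_phi(phi, ref)
        assert cmp.spearman_r == pytest.approx(1.0)

    def test_reversed_ranking(self):
        phi = np.array([0.1, 0.5, 0.9, 0.3, 0.7])
        ref = self._ref(np.arange(5), 1 - phi, np.full(5, 10.0))
        assert compare_phi(phi, ref).spearman_r == pytest.approx(-1.0)

    def test_ddg_filter_and_brute_force_rank(self):
        phi = np.array([0.2, 0.4, 0.6, 0.8, 1.0])
        phi_exp = np.array([0.3, 0.1, 0.5, 0.9, 0.6])
        ddg = np.array([10.0, 5.0, 9.0, 12.0, 8.0])  # residue 1 filtered
        ref = self._ref(np.arange(5), phi_exp, ddg)
        cmp = compare_phi(phi, ref, ddg_filter_kj=7.0)
        keep = ddg > 7.0
        r_expected, _ = spearmanr(phi[keep], phi_exp[keep])
        assert cmp.spearman_r == pytest.approx(r_expected)
        assert len(cmp.pairs) == 4

    def test_too_few_pairs_undefined(self):
        phi = np.array([0.2, 0.4])
        ref = self._ref([0, 1], [0.1, 0.2], [10.0, 10.0])
        assert np.isnan(compare_phi(phi, ref).spearman_r)


class TestMechanismReport:
    def test_top_contacts_ranking_and_tie_break(self):
        spec = SyntheticTrajectorySpec(
            n_contacts=6, p_tp=[0.9, 0.9, 0.5, 0.3, 0.2, 0.1],
            p_nontp=[0.05, 0.05, 0.2, 0.2, 0.2, 0.2],
            ptp_nn=0.1, n_frames=30000, seed=8)
        ens = make_synthetic_tp_ensemble(spec)
        rep = mechanism_report(ens, t_tp=0.05, mfpt=0.45)
        top = rep.top_contacts(3)
        assert len(top) == 3
        # the two TP-enriched contacts dominate the ranking
        assert set(map(tuple, top[["i", "j"]].values[:2])) == {(0, 4), (1, 5)}
        assert rep.ptp_nn == pytest.approx(0.1 / (0.1 + 0.45))

    def test_subsampling_invariance_in_expectation(self):
        spec = SyntheticTrajectorySpec(
            n_contacts=6, p_tp=np.linspace(0.3, 0.8, 6), p_nontp=0.15,
            ptp_nn=0.2, n_frames=80000, seed=9)
        ens = make_synthetic_tp_ensemble(spec)
        sub = TPEnsemble(ens.contact_formed[::2], ens.labels[::2],
                         ens.pairs, harvest=ens.harvest)
        phi_full = phi_values(ens)
        phi_sub = phi_values(sub)
        n_tp = (sub.labels == TP).sum()
        se = 3 * np.sqrt(0.25 / n_tp)
        assert np.all(np.abs(phi_full - phi_sub)[~np.isnan(phi_full)]
                      < np.maximum(2 * se, 0.03))


class TestExtractTPsProperty:
    """Property: the scanner equals the brute-force candidate scan for
    arbitrary bounded series, in both directions."""

    from hypothesis import given, settings, strategies as st

    @staticmethod
    def _brute(q, lo, hi, direction):
        if direction == "folding":
            react = lambda v: v < lo
            prod = lambda v: v > hi
        else:
            react = lambda v: v > hi
            prod = lambda v: v < lo
        out, s = [], None
        for t, v in enumerate(q):
            if react(v):
                s = t
            elif prod(v) and s is not None:
                out.append((s, t))
                s = None
        return out

    @given(st.lists(st.floats(min_value=-0.2, max_value=1.2,
                              allow_nan=False), max_size=120),
           st.sampled_from(["folding", "unfolding"]))
    @settings(deadline=None, derandomize=True, max_examples=80)
    def test_matches_brute_force(self, q, direction):
        assert extract_tps(q, direction=direction) == \
            self._brute(q, 0.3, 0.7, direction)
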