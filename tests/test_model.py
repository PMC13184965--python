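"""Lag gate, networks, rollout, loss terms, and gradients."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import neuraldfba as nd
from neuraldfba.model import (
    DamnModel,
    LagParams,
    LossWeights,
    Trajectory,
    decay_weight,
    lag_gate,
    loss_and_gradients,
    loss_biomass_monotone,
    loss_fit,
    loss_flux_positivity,
    loss_steady_state,
    rollout,
    total_loss,
)


def small_model(six_panel, seed=3, dt=0.5, **kw):
    net, irr, tmat = six_panel
    return DamnModel(tmat, irr.internal_stoichiometry(), dt=dt, seed=seed, **kw)


class TestLagGate:
    def test_zero_at_origin(self):
        assert lag_gate(0.0, LagParams(5.0, 1.0)) == 0.0

    def test_one_after_onset(self):
        assert lag_gate(10.0, LagParams(5.0, 1.0)) == 1.0

    def test_ramp_value(self):
        got = lag_gate(2.0, LagParams(5.0, 1.0))
        assert got == pytest.approx(1.0 - np.exp(-2.0), abs=1e-12)
        assert got == pytest.approx(0.864665, abs=1e-6)

    @given(tlag=st.floats(0.1, 10.0), klag=st.floats(0.01, 5.0))
    @settings(max_examples=50, deadline=None)
    def test_monotone_and_bounded(self, tlag, klag):
        t = np.linspace(0.0, 2 * tlag + 1.0, 200)
        r = lag_gate(t, LagParams(tlag, klag))
        assert np.all(r >= 0.0) and np.all(r <= 1.0)
        assert np.all(np.diff(r) >= -1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            lag_gate(-0.1, LagParams(1.0, 1.0))


class TestDecayWeight:
    def test_no_decay_is_constant(self):
        assert decay_weight(17, 0.5, 0.0) == 0.5

    def test_exponential_value(self):
        assert decay_weight(1, 1.0, 1.0) == pytest.approx(np.exp(-1.0))

    def test_initial_value(self):
        assert decay_weight(0, 0.1, 0.25) == pytest.approx(0.1)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            decay_weight(1, -1.0, 0.0)


class TestLagNet:
    def test_zero_weight_net_returns_defaults(self, six_panel):
        m = small_model(six_panel, tlag0=2.5, klag0=0.8)
        for w in m.lag_net.mlp.W:
            w[...] = 0.0
        lag = nd.predict_lag(m.lag_net, np.ones((4, 7)))
        assert np.allclose(lag.tlag, 2.5, atol=1e-9)
        assert np.allclose(lag.klag, 0.8, atol=1e-9)

    def test_deterministic(self, six_panel):
        m = small_model(six_panel)
        C0 = np.arange(7.0)[None, :]
        a, b = m.lag_net(C0), m.lag_net(C0)
        assert np.array_equal(a.tlag, b.tlag) and np.array_equal(a.klag, b.klag)

    def test_seeded_reproducibility(self, six_panel):
        m1 = small_model(six_panel, seed=9)
        m2 = small_model(six_panel, seed=9)
        C0 = np.linspace(0, 5, 7)[None, :]
        assert np.array_equal(m1.lag_net(C0).tlag, m2.lag_net(C0).tlag)

    def test_dimension_mismatch(self, six_panel):
        m = small_model(six_panel)
        with pytest.raises(ValueError):
            m.lag_net(np.ones((1, 5)))


class TestFluxNet:
    def test_zero_weight_net_gives_zero_flux(self, six_panel):
        m = small_model(six_panel)
        for w in m.flux_net.mlp.W:
            w[...] = 0.0
        for b in m.flux_net.mlp.b:
            b[...] = 0.0
        V = nd.predict_flux(m.flux_net, np.ones((2, 7)))
        assert np.allclose(V, 0.0)

    def test_nonnegative_option(self, six_panel):
        m = small_model(six_panel, nonnegative_flux=True)
        rng = np.random.default_rng(0)
        V = m.flux_net(rng.uniform(0, 20, size=(50, 7)))
        assert np.all(V >= 0.0)

    def test_output_dimension_is_expanded_reactions(self, six_panel):
        _, irr, _ = six_panel
        m = small_model(six_panel)
        assert m.flux_net(np.ones((1, 7))).shape == (1, irr.n_reactions)

    def test_dimension_mismatch(self, six_panel):
        m = small_model(six_panel)
        with pytest.raises(ValueError):
            m.flux_net(np.ones((1, 3)))


class TestRollout:
    def test_zero_flux_keeps_initial_state(self, six_panel):
        m = small_model(six_panel)
        for w in m.flux_net.mlp.W:
            w[...] = 0.0
        for b in m.flux_net.mlp.b:
            b[...] = 0.0
        C0 = np.array([5.0, 0, 0, 10.0, 0, 0, 0.002])
        traj = m.simulate(C0, tmax=4.0)
        assert np.allclose(traj.C, C0[:, None])
        assert traj.C.shape[1] == 9

    def test_closed_gate_freezes_state(self, six_panel):
        m = small_model(six_panel, tlag0=1e3, klag0=1.0)
        for w in m.lag_net.mlp.W:
            w[...] = 0.0
        m.lag_net.mlp.b[-1][1] = -30.0   # klag -> floor, gate ~ 0
        C0 = np.array([5.0, 1, 0, 10.0, 0, 0, 0.002])
        traj = m.simulate(C0, tmax=4.0)
        assert np.allclose(traj.C, C0[:, None], atol=1e-6)

    def test_euler_identity_per_step(self, six_panel):
        m = small_model(six_panel)
        C0 = np.array([5.0, 3.0, 0, 10.0, 2.0, 0, 0.02])
        traj = m.simulate(C0, tmax=3.0)
        Tm = m.transport.T
        for t in range(1, traj.C.shape[1]):
            step = traj.r[t] * (Tm @ traj.V[:, t]) * m.dt
            assert np.allclose(traj.C[:, t] - traj.C[:, t - 1], step,
                               rtol=0, atol=1e-12)

    def test_matches_independent_euler_oracle(self, six_panel):
        """100 random instances against a separately written stepper."""
        net, irr, tmat = six_panel
        rng = np.random.default_rng(42)
        for trial in range(100):
            m = DamnModel(tmat, irr.internal_stoichiometry(), dt=0.25,
                          seed=int(rng.integers(1 << 16)),
                          lag_hidden=(4,), flux_hidden=(8,))
            for p in m.parameters():
                p += rng.normal(0, 0.05, size=p.shape)
            C0 = rng.uniform(0.5, 15.0, size=7)
            C0[-1] = rng.uniform(0.001, 0.1)
            n_steps = int(rng.integers(3, 20))
            traj = m.simulate(C0, tmax=n_steps * 0.25)

            # oracle: direct formula evaluation, no shared rollout code
            lag = m.lag_net(C0[None, :])
            tl, kl = float(lag.tlag[0]), float(lag.klag[0])
            C = C0.copy().astype(float)
            for t in range(1, n_steps + 1):
                tt = t * 0.25
                r = 1.0 if tt > tl else 1.0 - np.exp(-kl * tt)
                v = m.flux_net(C[None, :])[0]
                C = C + r * (tmat.T @ v) * 0.25
            assert np.allclose(traj.C[:, -1], C, rtol=1e-10, atol=1e-12)

    def test_nonfinite_state_aborts_with_step(self, six_panel):
        m = small_model(six_panel)
        m.flux_net.mlp.b[-1][:] = 1e200
        with pytest.raises(RuntimeError, match="step"):
            m.simulate(np.array([5, 0, 0, 0, 0, 0, 1e3]), tmax=10.0)


def _traj(C, V=None, dt=1.0):
    C = np.asarray(C, dtype=float)
    n = C.shape[1]
    V = np.zeros((2, n)) if V is None else np.asarray(V, dtype=float)
    return Trajectory(times=np.arange(n) * dt, C=C, V=V, r=np.ones(n))


class TestLossTerms:
    def test_fit_zero_when_identical(self):
        C = np.array([[1.0, 2.0, 3.0]])
        assert np.allclose(loss_fit(_traj(C), C), 0.0)

    def test_fit_hand_value(self):
        traj = _traj([[1.0, 1.0], [2.0, 2.0]])
        C_true = np.array([[np.nan, 1.0], [np.nan, 4.0]])
        got = loss_fit(traj, C_true)
        assert got[1] == pytest.approx(2.0)   # ((0)^2 + (2)^2) / 2

    def test_fit_mask_ignores_other_channels(self):
        traj = _traj([[1.0, 5.0], [2.0, 7.0]])
        C_true = np.array([[np.nan, 1.0], [np.nan, 7.0]])
        mask = np.array([[False, False], [True, True]])
        assert np.allclose(loss_fit(traj, C_true, mask), 0.0)

    def test_fit_grid_mismatch(self):
        with pytest.raises(ValueError):
            loss_fit(_traj([[1.0, 2.0]]), np.ones((1, 3)))

    def test_monotone_zero_for_increasing_biomass(self):
        traj = _traj([[0.0, 0.0, 0.0], [0.1, 0.2, 0.4]])
        assert np.allclose(loss_biomass_monotone(traj, biomass_index=1), 0.0)

    def test_monotone_penalizes_drop(self):
        traj = _traj([[1.0, 0.8]])
        got = loss_biomass_monotone(traj, biomass_index=0)
        assert got[1] == pytest.approx(0.04)

    def test_monotone_constant_is_zero(self):
        traj = _traj([[0.5, 0.5, 0.5]])
        assert np.allclose(loss_biomass_monotone(traj, 0), 0.0)

    def test_monotone_printed_variant_penalizes_increase(self):
        traj = _traj([[1.0, 1.3]])
        got = loss_biomass_monotone(traj, 0, sign="printed")
        assert got[1] == pytest.approx(0.09)

    def test_steady_state_null_space_is_zero(self):
        S = np.array([[1.0, -1.0]])
        traj = _traj([[0.0, 0.0]], V=[[2.0, 2.0], [2.0, 2.0]])
        assert np.allclose(loss_steady_state(traj, S), 0.0)

    def test_steady_state_hand_value(self):
        S = np.array([[1.0, -1.0]])
        traj = _traj([[0.0, 0.0]], V=[[0.0, 2.0], [0.0, 1.0]])
        got = loss_steady_state(traj, S)
        assert got[1] == pytest.approx(1.0)

    def test_positivity_zero_iff_nonnegative(self):
        traj = _traj([[0.0, 0.0]], V=[[0.0, 3.0], [0.0, 1.0]])
        assert np.allclose(loss_flux_positivity(traj), 0.0)

    def test_positivity_hand_value(self):
        traj = _traj([[0.0, 0.0]], V=[[0.0, -1.0], [0.0, 3.0]])
        got = loss_flux_positivity(traj)
        assert got[1] == pytest.approx(0.5)

    def test_total_hand_sum(self):
        parts = [np.array([0.0, p]) for p in (1.0, 2.0, 3.0, 4.0)]
        w = LossWeights(lam=np.ones(4), k=np.zeros(4))
        assert total_loss(parts, w) == pytest.approx(10.0)

    def test_total_linear_in_lambda(self):
        rng = np.random.default_rng(0)
        parts = [np.abs(rng.normal(size=6)) for _ in range(4)]
        w1 = LossWeights(lam=np.array([1.0, 0.5, 2.0, 0.1]),
                         k=np.array([0.0, 0.1, 0.2, 0.3]))
        w2 = LossWeights(lam=2 * w1.lam, k=w1.k)
        assert total_loss(parts, w2) == pytest.approx(2 * total_loss(parts, w1))

    def test_total_grid_mismatch(self):
        w = LossWeights()
        with pytest.raises(ValueError):
            total_loss([np.zeros(3), np.zeros(3), np.zeros(3), np.zeros(4)], w)

    def test_weights_validate(self):
        with pytest.raises(ValueError):
            LossWeights(lam=np.array([1.0, 1.0, 0.0, 1.0]))
        with pytest.raises(ValueError):
            LossWeights(k=np.array([0.0, -0.1, 0.0, 0.0]))


class TestTrainingGradients:
    def _setup(self, six_panel):
        m = small_model(six_panel, gate_tau=1e-3)
        rng = np.random.default_rng(0)
        B, S = 3, 7
        C0 = rng.uniform(2, 10, size=(B, S))
        C0[:, -1] = 0.05
        T = 8
        C_true = np.full((B, S, T + 1), np.nan)
        C_true[:, -1, 1:] = rng.uniform(0.05, 1.0, size=(B, T))
        w = LossWeights(lam=np.array([1.0, 0.7, 0.3, 0.2]),
                        k=np.array([0.0, 0.1, 0.25, 0.5]))
        for p in m.parameters():
            p += rng.normal(0, 0.05, size=p.shape)
        return m, C0, C_true, w

    def test_finite_difference_agreement(self, six_panel):
        """Analytic backward pass vs central differences on sampled weights."""
        m, C0, C_true, w = self._setup(six_panel)
        m.zero_grad()
        _, _ = loss_and_gradients(C0, C_true, m, w)
        grads = [g.copy() for g in m.gradients()]
        rng = np.random.default_rng(1)
        for p, g in zip(m.parameters(), grads):
            for idx in [tuple(rng.integers(0, s) for s in p.shape)
                        for _ in range(3)]:
                orig = p[idx]
                best = np.inf
                for eps in (1e-5, 1e-6):
                    p[idx] = orig + eps
                    lp, _ = loss_and_gradients(C0, C_true, m, w, accumulate=False)
                    p[idx] = orig - eps
                    lm, _ = loss_and_gradients(C0, C_true, m, w, accumulate=False)
                    p[idx] = orig
                    fd = (lp - lm) / (2 * eps)
                    best = min(best, abs(fd - g[idx])
                               / max(abs(fd), abs(g[idx]), 1e-6))
                assert best < 1e-4

    def test_residual_structure_with_frozen_flux_net(self, six_panel):
        """With zero fluxes the objective reduces to the data-fit term of
        the constant trajectory; all other terms vanish exactly."""
        m, C0, C_true, _ = self._setup(six_panel)
        for wmat in m.flux_net.mlp.W:
            wmat[...] = 0.0
        for b in m.flux_net.mlp.b:
            b[...] = 0.0
        w = LossWeights(lam=np.ones(4), k=np.zeros(4))
        tot, parts = loss_and_gradients(C0, C_true, m, w, accumulate=False)
        assert parts[1] == 0.0 and parts[2] == 0.0 and parts[3] == 0.0
        expect = 0.0
        for b in range(C0.shape[0]):
            obs = C_true[b, -1, 1:]
            expect += np.sum((C0[b, -1] - obs) ** 2) / C0.shape[0]
        assert tot == pytest.approx(expect)

    def test_conservation_couples_growth_to_consumption(self, six_panel):
        """When S V = 0 holds, biomass increase must be matched by substrate
        decrease through the transport rows."""
        net, irr, tmat = six_panel
        S_int = irr.internal_stoichiometry().toarray()
        # a flux in the null space: uptake of glc feeding growth exactly
        V = np.zeros(irr.n_reactions)
        j_up = irr.reaction_ids.index("upt_glc")
        j_gr = irr.reaction_ids.index("growth")
        V[j_up] = 1.0
        V[j_gr] = -S_int[0, j_up] / S_int[0, j_gr]
        assert np.allclose(S_int @ V, 0.0)
        dC = tmat.T @ V
        bio = tmat.biomass_index
        assert dC[bio] > 0
        assert dC[tmat.species_ids.index("glc")] < 0


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, six_panel, tmp_path):
        m = small_model(six_panel, seed=5)
        rng = np.random.default_rng(2)
        for p in m.parameters():
            p += rng.normal(0, 0.1, size=p.shape)
        path = tmp_path / "model.npz"
        m.save(str(path))
        m2 = DamnModel.load(str(path))
        C0 = np.array([5.0, 0, 2.0, 0, 0, 1.0, 0.002])
        t1 = m.simulate(C0, tmax=5.0)
        t2 = m2.simulate(C0, tmax=5.0)
        assert np.allclose(t1.C, t2.C, atol=0, rtol=0)
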