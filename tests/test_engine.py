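"""Harmonic engine: Hessian, equilibrium covariance, samplers."""

import numpy as np
import pytest

import idenet as I
from idenet.engine import (
    KB,
    EngineError,
    bond_energy,
    bond_hessian,
    per_bead_rmsf,
)


def dumbbell(K=100.0, r0=0.5):
    topo = I.Structure([1, 3], ["A", "A"], [[0, 0, 0], [r0, 0, 0]])
    return I.ElasticNetwork(topo, [0], [1], [r0], [K])


def finite_difference_hessian(net, coords, eps=1e-6):
    n = coords.size
    H = np.zeros((n, n))
    flat = coords.ravel().copy()

    def energy(x):
        return bond_energy(net, x.reshape(-1, 3))

    for a in range(n):
        for b in range(a, n):
            xpp = flat.copy(); xpp[a] += eps; xpp[b] += eps
            xpm = flat.copy(); xpm[a] += eps; xpm[b] -= eps
            xmp = flat.copy(); xmp[a] -= eps; xmp[b] += eps
            xmm = flat.copy(); xmm[a] -= eps; xmm[b] -= eps
            H[a, b] = H[b, a] = (
                energy(xpp) - energy(xpm) - energy(xmp) + energy(xmm)
            ) / (4 * eps * eps)
    return H


class TestHessian:
    def test_single_bond_closed_form(self):
        net = dumbbell(K=123.0)
        H = I.assemble_hessian(net)
        expected = np.zeros((6, 6))
        expected[0, 0] = expected[3, 3] = 123.0
        expected[0, 3] = expected[3, 0] = -123.0
        np.testing.assert_allclose(H, expected, atol=1e-12)

    def test_row_sums_vanish(self, truth_20):
        _, net = truth_20
        H = I.assemble_hessian(net)
        np.testing.assert_allclose(H, H.T, atol=1e-12)
        # translation invariance: displacing all beads equally costs nothing
        for k in range(3):
            shift = np.zeros(3 * net.n_beads)
            shift[k::3] = 1.0
            np.testing.assert_allclose(H @ shift, 0, atol=1e-9)

    def test_matches_finite_differences_at_reference(self, truth_20):
        _, net = truth_20
        H = I.assemble_hessian(net)
        Hfd = finite_difference_hessian(net, net.topology.positions)
        np.testing.assert_allclose(H, Hfd, atol=1e-4)

    def test_strained_geometry_hessian_matches_finite_differences(self):
        net = dumbbell(K=200.0, r0=0.5)
        rng = np.random.default_rng(2)
        coords = net.topology.positions + rng.normal(0, 0.05, (2, 3))
        H = bond_hessian(net, coords)
        Hfd = finite_difference_hessian(net, coords, eps=1e-5)
        np.testing.assert_allclose(H, Hfd, atol=1e-4)

    def test_coincident_beads_rejected(self):
        topo = I.Structure([1, 3], ["A", "A"], [[0, 0, 0], [0, 0, 0]])
        net = I.ElasticNetwork(topo, [0], [1], [0.5], [100.0])
        with pytest.raises(EngineError, match="coincide"):
            I.assemble_hessian(net)


class TestEquilibriumCovariance:
    def test_dumbbell_bond_variance_closed_form(self):
        model = I.HarmonicModel(dumbbell(K=100.0), 300.0)
        var = I.predicted_distance_variance(model)
        assert var[0] == pytest.approx(model.kBT / 100.0, rel=1e-9)

    def test_doubling_stiffness_halves_covariance(self, truth_20):
        _, net = truth_20
        C1 = I.equilibrium_covariance(I.HarmonicModel(net, 300.0))
        C2 = I.equilibrium_covariance(I.HarmonicModel(net.with_constants(2 * net.K), 300.0))
        np.testing.assert_allclose(C2, C1 / 2, atol=1e-12)

    def test_disconnected_network_names_component(self):
        topo = I.Structure(
            [1, 3, 5, 7], ["A"] * 4,
            [[0, 0, 0], [0.5, 0, 0], [5, 5, 5], [5.5, 5, 5.0]],
        )
        net = I.ElasticNetwork(topo, [0, 2], [1, 3], [0.5, 0.5], [100.0, 100.0])
        with pytest.raises(EngineError, match="disconnected"):
            I.equilibrium_covariance(I.HarmonicModel(net))

    def test_rmsf_matches_monte_carlo(self, stiff_truth_20):
        _, net = stiff_truth_20
        model = I.HarmonicModel(net, 150.0)
        C = I.equilibrium_covariance(model)
        expected = per_bead_rmsf(C)
        ens = I.sample_ensemble(model, 20_000, seed=7, coord_covariance=C)
        dev = ens.frames - ens.frames.mean(axis=0)
        measured = np.sqrt(np.mean(np.sum(dev**2, axis=2), axis=0))
        se = expected / np.sqrt(2 * 20_000)
        assert np.all(np.abs(measured - expected) < 3 * se)

    def test_predicted_distance_variance_tracks_gaussian_sampling(self, stiff_truth_20):
        _, net = stiff_truth_20
        model = I.HarmonicModel(net, 150.0)
        C = I.equilibrium_covariance(model)
        var_ana = I.predicted_distance_variance(model, C)
        ens = I.sample_ensemble(model, 50_000, seed=7, coord_covariance=C)
        d = np.linalg.norm(ens.frames[:, net.bond_j] - ens.frames[:, net.bond_i], axis=2)
        np.testing.assert_allclose(d.var(axis=0), var_ana, rtol=0.05)

    def test_rigid_limit_variances_vanish(self):
        vars_by_K = [
            I.predicted_distance_variance(I.HarmonicModel(dumbbell(K=K), 300.0))[0]
            for K in (1e2, 1e4, 1e6)
        ]
        assert vars_by_K[0] > vars_by_K[1] > vars_by_K[2]
        assert vars_by_K[2] == pytest.approx(KB * 300.0 / 1e6, rel=1e-9)


class TestGaussianSampler:
    def test_deterministic_under_seed(self, truth_20):
        _, net = truth_20
        model = I.HarmonicModel(net)
        a = I.sample_ensemble(model, 5, seed=3)
        b = I.sample_ensemble(model, 5, seed=3)
        np.testing.assert_array_equal(a.frames, b.frames)

    def test_mean_is_reference_within_3se(self, truth_20):
        _, net = truth_20
        model = I.HarmonicModel(net, 300.0)
        C = I.equilibrium_covariance(model)
        n = 20_000
        ens = I.sample_ensemble(model, n, seed=5, coord_covariance=C)
        se = np.sqrt(np.diag(C).reshape(-1, 3) / n)
        dev = np.abs(ens.frames.mean(axis=0) - net.topology.positions)
        assert np.all(dev < 4 * se + 1e-12)

    def test_sample_covariance_converges(self, stiff_truth_20):
        _, net = stiff_truth_20
        model = I.HarmonicModel(net, 150.0)
        C = I.equilibrium_covariance(model)
        ens = I.sample_ensemble(model, 50_000, seed=9, coord_covariance=C)
        disp = (ens.frames - net.topology.positions[None]).reshape(50_000, -1)
        S = disp.T @ disp / 50_000
        rel = np.linalg.norm(S - C) / np.linalg.norm(C)
        assert rel < 0.05


class TestLangevin:
    def test_two_bead_variance_matches_boltzmann_quadrature(self):
        """Sampled bond-length variance equals the exact radial Boltzmann
        average Var(d) under P(d) ~ d^2 exp(-K (d - r0)^2 / 2 kBT) — the
        d^2 Jacobian makes this measurably smaller than the linearised
        kBT/K at this stiffness."""
        import scipy.integrate

        K, r0 = 100.0, 0.5
        net = dumbbell(K=K, r0=r0)
        model = I.HarmonicModel(net, 300.0)
        d_grid = np.linspace(1e-4, 3.0, 100_001)
        w = d_grid**2 * np.exp(-K / (2 * model.kBT) * (d_grid - r0) ** 2)
        norm = scipy.integrate.simpson(w, x=d_grid)
        mean = scipy.integrate.simpson(d_grid * w, x=d_grid) / norm
        expected = scipy.integrate.simpson((d_grid - mean) ** 2 * w, x=d_grid) / norm

        ens = I.langevin_dynamics(model, n_steps=400_000, dt=2e-3, friction=1.0,
                                  seed=4, stride=20)
        d = np.linalg.norm(ens.frames[:, 1] - ens.frames[:, 0], axis=1)
        skip = len(d) // 10
        assert d[skip:].var() == pytest.approx(expected, rel=0.05)

    def test_zero_temperature_relaxes_to_reference(self, truth_20):
        _, net = truth_20
        model = I.HarmonicModel(net, 0.0)
        x0 = net.topology.positions + np.random.default_rng(0).normal(0, 0.05, (20, 3))
        ens = I.langevin_dynamics(model, n_steps=50_000, dt=1e-4, seed=1,
                                  stride=50_000, initial_positions=x0)
        rij = ens.frames[-1][net.bond_j] - ens.frames[-1][net.bond_i]
        d = np.linalg.norm(rij, axis=1)
        np.testing.assert_allclose(d, net.r0, atol=1e-3)

    def test_bit_identical_under_seed(self, truth_20):
        _, net = truth_20
        model = I.HarmonicModel(net, 300.0)
        kw = dict(n_steps=2_000, dt=1e-4, seed=8, stride=100)
        a = I.langevin_dynamics(model, **kw)
        b = I.langevin_dynamics(model, **kw)
        np.testing.assert_array_equal(a.frames, b.frames)

    def test_unstable_timestep_rejected(self, stiff_truth_20):
        _, net = stiff_truth_20
        with pytest.raises(EngineError, match="unstable"):
            I.langevin_dynamics(I.HarmonicModel(net), n_steps=10, dt=1e-2)

    def test_agrees_with_analytic_on_bond_variances(
        self, stiff_truth_20, langevin_bond_variances
    ):
        """The module's central oracle pair: overdamped sampling vs the
        Hessian pseudo-inverse, per-bond, within blocked standard errors."""
        _, net = stiff_truth_20
        var_ana = I.predicted_distance_variance(I.HarmonicModel(net, 50.0))
        v, se = langevin_bond_variances
        assert np.all(np.abs(v - var_ana) <= 3 * se)


class TestEvaluators:
    def test_analytic_evaluator_contract(self, truth_20):
        _, net = truth_20
        var = I.AnalyticEvaluator(300.0)(net)
        assert var.shape == (net.n_bonds,)
        assert np.all(var > 0)

    def test_ensemble_evaluator_reproduces_distance_stats(self, truth_20):
        _, net = truth_20
        ens = I.sample_ensemble(I.HarmonicModel(net), 200, seed=2)
        var = I.EnsembleEvaluator(ens)(net)
        _, dvar = I.distance_stats(ens)
        np.testing.assert_allclose(var, dvar[net.bond_i, net.bond_j], atol=1e-12)
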