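"""SAR closed form, spectral normalization, delays, and the simulators."""

import math

import numpy as np
import pytest
from scipy.signal import hilbert

from scfc.core import BoldTrace, compute_fc
from scfc.dynamics import (CouplingConfig, ModelSpec, make_delay_table,
                           normalize_sc, sar_fc, sar_sample, simulate)
from scfc.synthetic import SyntheticConfig, make_sc


class TestNormalizeSC:
    def test_two_region_exchange_matrix_unchanged(self):
        c = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert np.allclose(normalize_sc(c), c)

    def test_scale_invariance(self, rng):
        a = rng.random((10, 10))
        c = np.triu(a, 1); c = c + c.T
        assert np.allclose(normalize_sc(3.0 * c), normalize_sc(c))

    def test_unit_spectral_radius(self, rng):
        a = rng.random((15, 15))
        c = np.triu(a, 1); c = c + c.T
        lam = np.linalg.eigvalsh(normalize_sc(c))[-1]
        assert lam == pytest.approx(1.0, abs=1e-10)

    def test_rejects_asymmetric_or_negative(self):
        with pytest.raises(ValueError):
            normalize_sc(np.array([[0.0, 1.0], [0.0, 0.0]]))
        with pytest.raises(ValueError):
            normalize_sc(np.array([[0.0, -1.0], [-1.0, 0.0]]))

    def test_zero_matrix_passes_through(self):
        assert np.array_equal(normalize_sc(np.zeros((4, 4))), np.zeros((4, 4)))


class TestSarFC:
    def test_uncoupled_connectome_gives_identity_fc(self, small_sc):
        sc = small_sc.replace(weights=np.zeros((20, 20)),
                              lengths=np.zeros((20, 20)))
        assert np.allclose(sar_fc(sc, 0.5).values, np.eye(20))

    def test_two_region_closed_form(self, two_region_sc):
        # A = [[1,-.5],[-.5,1]]; Sigma ~ [[1.25,1],[1,1.25]] -> r = 0.8
        fc = sar_fc(two_region_sc, 0.5)
        assert fc.values[0, 1] == pytest.approx(0.8, abs=1e-12)

    def test_independent_of_noise_scale(self, small_sc):
        assert np.allclose(sar_fc(small_sc, 0.6, sigma=1.0).values,
                           sar_fc(small_sc, 0.6, sigma=7.0).values)

    def test_instability_reported_with_bound(self, small_sc):
        with pytest.raises(ValueError, match="instability"):
            sar_fc(small_sc, 1.0)

    def test_matches_monte_carlo_sample_correlation(self):
        sc = make_sc(SyntheticConfig(n_regions=20, seed=0))
        analytic = sar_fc(sc, 0.6).values
        draws = sar_sample(sc, 0.6, 200_000, seed=1)
        sample = np.corrcoef(draws)
        assert np.abs(analytic - sample).max() < 0.02


class TestDelayTable:
    def test_reference_arithmetic(self, two_region_sc):
        # 60 mm at 6 m/s sampled at 1 ms -> 10 steps
        table = make_delay_table(two_region_sc, velocity=6.0, dt=1e-3)
        assert table.steps[0, 1] == 10

    def test_infinite_velocity_means_no_delays(self, small_sc):
        assert make_delay_table(small_sc, math.inf, 1e-3).max_delay == 0

    def test_halving_dt_doubles_steps(self, two_region_sc):
        a = make_delay_table(two_region_sc, 6.0, 1e-3).steps
        b = make_delay_table(two_region_sc, 6.0, 5e-4).steps
        assert np.array_equal(b, 2 * a)

    def test_invalid_inputs_rejected(self, small_sc):
        with pytest.raises(ValueError):
            make_delay_table(small_sc, -1.0, 1e-3)
        with pytest.raises(ValueError):
            make_delay_table(small_sc, 6.0, 0.0)


class TestModelSpec:
    def test_unknown_model_and_params_rejected(self):
        with pytest.raises(ValueError, match="unknown model"):
            ModelSpec("hopfield")
        with pytest.raises(ValueError, match="unknown parameter"):
            ModelSpec("rate", {"gain": 2.0})
        with pytest.raises(ValueError, match="positive"):
            ModelSpec("rate", {"tau": -1.0})


class TestSimulate:
    def test_uncoupled_noiseless_rate_model_stays_at_rest(self, small_sc):
        cfg = CouplingConfig(coupling_strength=0.0, noise_sd=0.0, dt=1e-3,
                             duration=1.0, seed=0, transient=0.5)
        tr = simulate(ModelSpec("rate"), small_sc, cfg)
        assert np.all(tr.values == 0.0)

    def test_uncoupled_rate_model_matches_ou_stationary_variance(self, small_sc):
        # dx = -x/tau dt + sigma dW -> Var = sigma^2 * tau / 2
        tau, sigma = 0.02, 1.5
        cfg = CouplingConfig(coupling_strength=0.0, noise_sd=sigma, dt=1e-3,
                             duration=500 * tau, seed=3, transient=2.0)
        tr = simulate(ModelSpec("rate", {"tau": tau}), small_sc, cfg)
        assert tr.values.var() == pytest.approx(sigma ** 2 * tau / 2, rel=0.05)

    def test_bit_reproducible(self, small_sc):
        cfg = CouplingConfig(coupling_strength=0.5, noise_sd=1.0, dt=1e-3,
                             duration=2.0, seed=5, transient=0.5)
        a = simulate(ModelSpec("rate"), small_sc, cfg)
        b = simulate(ModelSpec("rate"), small_sc, cfg)
        assert np.array_equal(a.values, b.values)

    @pytest.mark.parametrize("model_id,noise", [("rate", 0.5), ("kuramoto", 2.0),
                                                ("wilson_cowan", 1.0)])
    def test_uncoupled_long_run_fc_is_diagonal(self, small_sc, model_id, noise):
        # Oscillator models need phase-diffusing noise to decorrelate:
        # identical deterministic oscillators stay phase-locked forever.
        cfg = CouplingConfig(coupling_strength=0.0, noise_sd=noise, dt=1e-3,
                             duration=60.0, seed=2, transient=2.0)
        tr = simulate(ModelSpec(model_id), small_sc, cfg)
        # thin to weakly dependent samples before correlating
        fc = compute_fc(BoldTrace(values=tr.values[:, ::200], sampling_interval=0.2))
        off = fc.values[np.triu_indices(20, 1)]
        t_eff = tr.values[:, ::200].shape[1]
        assert np.abs(off).max() < 4.0 / math.sqrt(t_eff)

    def test_kuramoto_identical_frequencies_synchronize(self):
        # all-to-all coupling, identical natural frequencies, no noise
        from scfc.core import Parcellation, StructuralConnectome
        n = 10
        w = np.ones((n, n)) - np.eye(n)
        sc = StructuralConnectome(Parcellation.canonical(n), w,
                                  np.where(w > 0, 50.0, 0.0))
        spec = ModelSpec("kuramoto", {"freq_sd": 0.0})
        cfg = CouplingConfig(coupling_strength=5.0, noise_sd=0.0, dt=1e-4,
                             duration=1.0, seed=1, transient=3.0)
        tr = simulate(spec, sc, cfg)
        # order parameter from emitted sin(theta) via analytic signal
        phase = np.angle(hilbert(tr.values, axis=1))
        r = np.abs(np.exp(1j * phase).mean(axis=0)).mean()
        assert r > 0.99

    @pytest.mark.parametrize("k,locks", [(1.0, True), (0.3, False)])
    def test_two_oscillator_locking_boundary(self, two_region_sc, k, locks):
        # phase difference obeys dphi/dt = dw - 2kC sin(phi):
        # locking iff |dw| <= 2kC.  spread 0.2 Hz -> dw = 1.257 rad/s;
        # 2kC = 2.0 (locks) or 0.6 (drifts).
        spec = ModelSpec("kuramoto", {"freq_sd": 0.0, "freq_spread": 0.2})
        cfg = CouplingConfig(coupling_strength=k, noise_sd=0.0, dt=1e-4,
                             duration=20.0, seed=0, transient=5.0)
        tr = simulate(spec, two_region_sc, cfg)
        ph = np.unwrap(np.angle(hilbert(tr.values, axis=1)), axis=1)
        slip = abs((ph[0] - ph[1])[-1] - (ph[0] - ph[1])[0]) / 20.0
        if locks:
            assert slip < 0.05
        else:
            assert slip > 0.5

    def test_delayed_and_undelayed_rate_models_differ(self, small_sc):
        cfg_fast = CouplingConfig(coupling_strength=0.5, noise_sd=1.0, dt=1e-3,
                                  duration=5.0, seed=4, transient=1.0,
                                  velocity=math.inf)
        cfg_slow = CouplingConfig(coupling_strength=0.5, noise_sd=1.0, dt=1e-3,
                                  duration=5.0, seed=4, transient=1.0, velocity=2.0)
        a = simulate(ModelSpec("rate_delay"), small_sc, cfg_fast)
        b = simulate(ModelSpec("rate_delay"), small_sc, cfg_slow)
        assert not np.allclose(a.values, b.values)

    def test_fitzhugh_nagumo_oscillates_and_stays_finite(self, small_sc):
        cfg = CouplingConfig(coupling_strength=0.1, noise_sd=0.01, dt=1e-4,
                             duration=5.0, seed=6, transient=1.0)
        tr = simulate(ModelSpec("fitzhugh_nagumo"), small_sc, cfg)
        assert np.all(np.isfinite(tr.values))
        assert tr.values.std() > 0.1  # limit-cycle amplitude, not a fixed point

    def test_fc_insensitive_to_transient_beyond_two_seconds(self, small_sc):
        def run(transient):
            cfg = CouplingConfig(coupling_strength=0.6, noise_sd=1.0, dt=1e-3,
                                 duration=120.0, seed=9, transient=transient)
            tr = simulate(ModelSpec("rate"), small_sc, cfg)
            return compute_fc(BoldTrace(values=tr.values[:, ::100],
                                        sampling_interval=0.1)).values
        a, b = run(2.0), run(4.0)
        iu = np.triu_indices(20, 1)
        assert np.corrcoef(a[iu], b[iu])[0, 1] > 0.9
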