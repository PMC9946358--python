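import numpy as np
import pytest

from bioink_optics.inverse_fit import (
    FitConfig,
    Measurement,
    _eval_seed,
    fit_optical_properties,
    objective,
    pso_minimize,
)
from bioink_optics.optics_core import OpticalProperties
from bioink_optics.photon_mc import SlabGeometry
from bioink_optics.synthetic_data import NOISE_FREE, NoiseModel, synth_measurement


def _quick_cfg(**kw):
    base = dict(
        n_particles=12,
        n_iterations=30,
        photons_per_eval=8_000,
        polish_photons_factor=25,
        polish_eval_seeds=1,
        seed=0,
    )
    base.update(kw)
    return FitConfig(**base)


class TestMeasurementValidation:
    def test_rejects_unnormalized_angular(self):
        with pytest.raises(ValueError):
            Measurement(
                T_total=0.5,
                R_total=0.1,
                angular_edges_deg=np.array([0.0, 45.0, 90.0]),
                angular=np.array([0.6, 0.5]),
                thickness=1.0,
                n_sample=1.34,
            )

    def test_rejects_t_plus_r_above_one(self):
        with pytest.raises(ValueError):
            Measurement(
                T_total=0.8,
                R_total=0.3,
                angular_edges_deg=np.array([0.0, 90.0]),
                angular=np.array([1.0]),
                thickness=1.0,
                n_sample=1.34,
            )


class TestObjective:
    def test_self_consistency_exact_zero(self, idx30_props, slab_air):
        """A noise-free measurement generated with the evaluation seed and
        photon count reproduces itself: the misfit is exactly 0."""
        cfg = FitConfig(photons_per_eval=10_000, seed=4)
        meas = synth_measurement(
            idx30_props,
            slab_air,
            NOISE_FREE,
            n_photons=cfg.photons_per_eval,
            forward_seed=_eval_seed(cfg),
        )
        truth = {"mu_s": idx30_props.mu_s, "g": idx30_props.g}
        assert objective(truth, meas, cfg) == 0.0

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            FitConfig(weights=(0.0, 0.0, 0.0))

    def test_zero_weight_terms_ignore_mismatch(self, idx30_props, slab_air):
        cfg = FitConfig(photons_per_eval=10_000, seed=4, weights=(0.0, 0.0, 1.0))
        meas = synth_measurement(
            idx30_props,
            slab_air,
            NOISE_FREE,
            n_photons=cfg.photons_per_eval,
            forward_seed=_eval_seed(cfg),
        )
        # corrupt the scalars the weights ignore
        meas.T_total, meas.R_total = 0.123, 0.456
        truth = {"mu_s": idx30_props.mu_s, "g": idx30_props.g}
        assert objective(truth, meas, cfg) == 0.0

    @pytest.mark.parametrize("metric", ["cvm", "log"])
    def test_misfit_grows_away_from_truth(self, slab_air, metric):
        props = OpticalProperties(0.0, 2.0, 0.9, 1.37)
        meas = synth_measurement(props, slab_air, NOISE_FREE, seed=2, n_photons=100_000)
        cfg = FitConfig(photons_per_eval=20_000, seed=3, angular_metric=metric)
        at_truth = objective({"mu_s": 2.0, "g": 0.9}, meas, cfg)
        away = objective({"mu_s": 4.0, "g": 0.9}, meas, cfg)
        assert away > at_truth

    def test_missing_angular_with_weight_rejected(self):
        meas = Measurement(
            T_total=0.9,
            R_total=0.05,
            angular_edges_deg=np.array([0.0]),
            angular=np.array([]),
            thickness=1.0,
            n_sample=1.34,
        )
        with pytest.raises(ValueError):
            objective({"mu_s": 1.0, "g": 0.9}, meas, FitConfig())


class TestPSO:
    def test_quadratic_minimum(self):
        cfg = FitConfig(seed=1)
        f = lambda x: (x[0] - 3.0) ** 2 + (x[1] - 0.5) ** 2
        x, fx, trace = pso_minimize(f, np.array([[0.0, 10.0], [0.0, 1.0]]), cfg)
        assert np.allclose(x, [3.0, 0.5], atol=1e-3)
        assert np.all(np.diff(trace) <= 0)

    def test_deterministic(self):
        cfg = FitConfig(seed=7)
        f = lambda x: np.sin(5 * x[0]) + x[1] ** 2
        a = pso_minimize(f, np.array([[-2.0, 2.0], [-1.0, 1.0]]), cfg)
        b = pso_minimize(f, np.array([[-2.0, 2.0], [-1.0, 1.0]]), cfg)
        assert np.array_equal(a[0], b[0]) and a[1] == b[1]
        assert np.array_equal(a[2], b[2])

    def test_rastrigin_default_strength(self):
        """2-D Rastrigin: 40 particles x 200 iterations reaches < 1.0 in at
        least 95% of 20 seeded runs (baseline strength calibration)."""

        def rastrigin(x):
            return 20.0 + np.sum(x**2 - 10.0 * np.cos(2 * np.pi * x))

        bounds = np.array([[-2.0, 2.0], [-2.0, 2.0]])
        wins = 0
        for s in range(20):
            cfg = FitConfig(n_particles=40, n_iterations=200, seed=s)
            _, fx, _ = pso_minimize(rastrigin, bounds, cfg)
            if fx < 1.0:
                wins += 1
        assert wins >= 19

    def test_nonfinite_objective_resampled(self):
        calls = {"n": 0}

        def f(x):
            calls["n"] += 1
            return np.nan if x[0] < 0.5 else (x[0] - 0.7) ** 2

        cfg = FitConfig(n_particles=8, n_iterations=20, seed=3)
        x, fx, _ = pso_minimize(f, np.array([[0.0, 1.0]]), cfg)
        assert np.isfinite(fx)
        assert abs(x[0] - 0.7) < 0.05


class TestRecovery:
    @pytest.mark.parametrize(
        "mu_s, g",
        [(1.0, 0.5), (1.0, 0.99), (5.0, 0.9)],
    )
    def test_noise_free_grid(self, mu_s, g, slab_air):
        """Parameter recovery across the scattering-strength x anisotropy
        plane where a quasi-ballistic component survives: mu_s within 5%,
        mu_s' within 15%.  (The thick forward-peaked corner, mu_s ~ 12 and
        g ~ 0.99, is exercised at full protocol strength elsewhere via the
        untuned-ink condition.)"""
        props = OpticalProperties(0.0, mu_s, g, 1.37)
        meas = synth_measurement(props, slab_air, NOISE_FREE, seed=21, n_photons=400_000)
        fit = fit_optical_properties(meas, _quick_cfg(seed=2))
        assert fit.mu_s_hat == pytest.approx(mu_s, rel=0.05)
        assert fit.mu_s_prime_hat == pytest.approx(props.mu_s_prime, rel=0.15)

    def test_diffuse_regime_recovers_transport_coefficient(self, slab_air):
        """Optically thick, weakly anisotropic slab (mu_s = 12, g = 0.5,
        transport depth 6): the similarity relation makes (mu_s, g)
        separately unidentifiable from T/R and the angular scan — direct
        objective probes along mu_s(1-g) = const are flat within noise even
        at 4e5 photons/eval — but the transport coefficient mu_s' itself is
        still recovered from the scalar observables alone (the goniometer
        scan is shape-less there and only adds shot noise, so it is dropped
        — the classic integrating-sphere-only inversion)."""
        props = OpticalProperties(0.0, 12.0, 0.5, 1.37)
        meas = synth_measurement(props, slab_air, NOISE_FREE, seed=21, n_photons=400_000)
        fit = fit_optical_properties(meas, _quick_cfg(seed=2, weights=(1.0, 1.0, 0.0)))
        assert fit.mu_s_prime_hat == pytest.approx(6.0, rel=0.15)

    def test_noisy_replicates_median(self, slab_air):
        """1% relative noise at (mu_s=5, g=0.9): the median of replicate
        fits stays within 10% of truth."""
        props = OpticalProperties(0.0, 5.0, 0.9, 1.37)
        hats = []
        for s in range(3):
            meas = synth_measurement(
                props, slab_air, NoiseModel(), seed=100 + s, n_photons=200_000
            )
            fit = fit_optical_properties(meas, _quick_cfg(seed=s))
            hats.append(fit.mu_s_hat)
        assert np.median(hats) == pytest.approx(5.0, rel=0.10)

    def test_angular_scan_carries_anisotropy(self, slab_air):
        """Dropping the angular term (T and R only) degrades g recovery:
        the angular scan is what pins the anisotropy."""
        props = OpticalProperties(0.0, 5.0, 0.9, 1.37)
        meas = synth_measurement(props, slab_air, NOISE_FREE, seed=31, n_photons=400_000)
        cheap = dict(n_particles=10, n_iterations=15, photons_per_eval=5_000,
                     refine=False)
        full = fit_optical_properties(meas, _quick_cfg(seed=3, **cheap))
        scalars_only = fit_optical_properties(
            meas, _quick_cfg(seed=3, weights=(1.0, 1.0, 0.0), **cheap)
        )
        err_full = abs(full.g_hat - 0.9)
        err_scalars = abs(scalars_only.g_hat - 0.9)
        assert err_scalars > err_full

    def test_trace_monotone_within_stages(self, idx30_props, slab_air):
        meas = synth_measurement(
            idx30_props, slab_air, NOISE_FREE, seed=41, n_photons=100_000
        )
        cfg = _quick_cfg(seed=4)
        fit = fit_optical_properties(meas, cfg)
        start = 0
        for n_iters in [cfg.n_iterations] + [s[4] for s in cfg.refine_stages]:
            stage = fit.trace[start : start + n_iters]
            assert np.all(np.diff(stage) <= 0)
            start += n_iters
        assert fit.config.bounds["mu_s"][0] <= fit.mu_s_hat <= fit.config.bounds["mu_s"][1]

    def test_fit_reproducible(self, idx30_props, slab_air):
        meas = synth_measurement(
            idx30_props, slab_air, NOISE_FREE, seed=51, n_photons=50_000
        )
        cfg = _quick_cfg(seed=6, refine=False, n_iterations=8)
        a = fit_optical_properties(meas, cfg)
        b = fit_optical_properties(meas, cfg)
        assert a.mu_s_hat == b.mu_s_hat and a.g_hat == b.g_hat
        assert np.array_equal(a.trace, b.trace)
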