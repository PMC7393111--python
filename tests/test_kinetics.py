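import warnings

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import kstest

from secforce.kinetics import (
    BarrierParams,
    RipEvent,
    barrier_shape_diagnostic,
    binned_lifetime_transform,
    cumulative_hazard,
    folded_lifetime,
    rip_force_cdf,
    rip_force_pdf,
    sample_rip_forces,
    survival,
    unfolding_rate,
)
from secforce.simulate import RipSimConfig, simulate_rip_dataset


def _random_params(rng):
    return BarrierParams(
        log10_tau0=rng.uniform(2.0, 8.0),
        dx_ddagger=rng.uniform(0.5, 3.0),
        dG_ddagger=rng.uniform(8.0, 25.0),
    )


class TestRateLaw:
    def test_zero_force_rate_is_intrinsic(self, mtx_params):
        assert unfolding_rate(0.0, mtx_params) == pytest.approx(10.0**-5.46, rel=1e-12)
        # ligand-stabilized DHFR unfolds spontaneously on the 1e-6/s scale
        assert 1e-6 < unfolding_rate(0.0, mtx_params) < 1e-5

    def test_lifetime_near_matched_force(self, mtx_params, mn_params):
        # at ~10.6 pN the MTX lifetime is ~5.2e3 s (1/0.0115 min^-1)
        assert folded_lifetime(10.6, mtx_params) == pytest.approx(5.2e3, rel=0.05)
        # at ~11.8 pN the doubly liganded lifetime is ~4.6e4 s (1/0.00130 min^-1)
        assert folded_lifetime(11.8, mn_params) == pytest.approx(4.6e4, rel=0.05)

    def test_lifetime_is_inverse_rate(self, mtx_params):
        grid = np.linspace(0.0, 30.0, 50)
        assert np.allclose(folded_lifetime(grid, mtx_params) * unfolding_rate(grid, mtx_params), 1.0)

    def test_lifetime_monotone_decreasing_up_to_30pN(self, mtx_params, mn_params):
        grid = np.linspace(0.0, 30.0, 200)
        for p in (mtx_params, mn_params):
            assert np.all(np.diff(folded_lifetime(grid, p)) < 0)

    def test_bell_limit(self):
        rng = np.random.default_rng(0)
        p = BarrierParams(log10_tau0=4.0, dx_ddagger=1.5, dG_ddagger=12.0, nu=1.0)
        forces = rng.uniform(0.0, 60.0, size=20)
        expected = p.k0 * np.exp(forces * p.dx_ddagger / p.thermal_energy)
        assert np.allclose(unfolding_rate(forces, p), expected, rtol=1e-12)

    def test_capped_beyond_peak(self, mtx_params):
        f_star = mtx_params.peak_force
        assert unfolding_rate(f_star + 5.0, mtx_params) == pytest.approx(
            unfolding_rate(f_star, mtx_params), rel=1e-9
        )

    def test_rejects_negative_force(self, mtx_params):
        with pytest.raises(ValueError):
            unfolding_rate(-1.0, mtx_params)


class TestCumulativeHazard:
    def test_zero_at_zero_force(self, mtx_params):
        assert cumulative_hazard(0.0, 10.0, mtx_params) == 0.0

    def test_matches_quadrature_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            p = _random_params(rng)
            force = rng.uniform(1.0, 1.1 * p.peak_force)  # include capped region
            rate = rng.uniform(0.5, 20.0)
            oracle = quad(lambda f: unfolding_rate(f, p) / rate, 0.0, force,
                          limit=200, points=[min(p.peak_force, force)])[0]
            assert cumulative_hazard(force, rate, p) == pytest.approx(oracle, rel=1e-6)

    def test_inverse_in_loading_rate(self, mtx_params):
        lam = cumulative_hazard(30.0, 10.0, mtx_params)
        assert cumulative_hazard(30.0, 5.0, mtx_params) == pytest.approx(2 * lam, rel=1e-12)

    def test_rejects_non_positive_rate(self, mtx_params):
        with pytest.raises(ValueError):
            cumulative_hazard(10.0, 0.0, mtx_params)

    def test_survival_is_decreasing_probability(self, mtx_params):
        grid = np.linspace(0.0, 70.0, 300)
        s = survival(grid, 10.0, mtx_params)
        assert s[0] == 1.0
        assert np.all((s > 0) & (s <= 1))
        assert np.all(np.diff(s) < 0)


class TestRupturePdf:
    def test_total_mass_accounting(self, mtx_params):
        # integral of the density up to F_c plus the survival there is unity
        rate = 10.0
        fc = mtx_params.critical_force
        mass = quad(lambda f: rip_force_pdf(f, rate, mtx_params), 0.0, fc,
                    limit=400, points=[mtx_params.peak_force])[0]
        assert mass + survival(fc, rate, mtx_params) == pytest.approx(1.0, abs=1e-8)

    def test_mode_above_40pN_at_fast_pulling(self, mtx_params):
        grid = np.linspace(1.0, 56.0, 2000)
        dens = rip_force_pdf(grid, 10.0, mtx_params)
        mode = grid[np.argmax(dens)]
        assert 40.0 <= mode <= 50.0

    def test_mean_force_drops_with_loading_rate(self, mtx_params):
        grid = np.linspace(0.01, mtx_params.critical_force, 4000)

        def mean_force(rate):
            dens = rip_force_pdf(grid, rate, mtx_params)
            return np.trapezoid(grid * dens, grid) / np.trapezoid(dens, grid)

        assert mean_force(1.0) < mean_force(10.0)


class TestSampler:
    def test_reproducible_and_seed_sensitive(self, mtx_params):
        f1, c1 = sample_rip_forces(500, 10.0, mtx_params, seed=5)
        f2, _ = sample_rip_forces(500, 10.0, mtx_params, seed=5)
        f3, _ = sample_rip_forces(500, 10.0, mtx_params, seed=6)
        assert np.array_equal(f1, f2)
        assert not np.array_equal(f1, f3)

    @pytest.mark.parametrize("rate", [2.0, 15.0])
    def test_matches_closed_form_cdf(self, mtx_params, rate):
        forces, censored = sample_rip_forces(100_000, rate, mtx_params, seed=1)
        kept = forces[~censored]
        total = rip_force_cdf(mtx_params.critical_force, rate, mtx_params)
        stat = kstest(kept, lambda x: rip_force_cdf(x, rate, mtx_params) / total).statistic
        assert stat < 0.01

    def test_censoring_recorded_at_critical_force(self, mtx_params):
        forces, censored = sample_rip_forces(50_000, 15.0, mtx_params, seed=2)
        assert censored.any()
        assert np.all(forces[censored] == mtx_params.critical_force)
        assert np.all(forces[~censored] < mtx_params.critical_force)


class TestBinnedLifetimeTransform:
    def test_single_event_estimator_arithmetic(self):
        ev = [RipEvent("m", "c", rip_force=20.0, loading_rate=4.0)]
        tab = binned_lifetime_transform(ev, bin_width=2.0)
        assert len(tab) == 1
        # S = 1/2, p = 1/dF  ->  tau = dF/(2 r)
        assert tab.lifetime_s.iloc[0] == pytest.approx(2.0 / (2 * 4.0))

    def test_recovers_lifetime_curve(self, mtx_params):
        rate = 10.0
        forces, censored = sample_rip_forces(5000, rate, mtx_params, seed=3)
        events = [RipEvent("m", "MTX", float(f), rate) for f, c in zip(forces, censored) if not c]
        tab = binned_lifetime_transform(events, bin_width=2.0)
        kept = np.array([e.rip_force for e in events])
        lo, hi = np.quantile(kept, [0.1, 0.9])
        central = tab[(tab.force_pN >= lo) & (tab.force_pN <= hi)]
        truth = folded_lifetime(central.force_pN.to_numpy(), mtx_params)
        assert np.all(np.abs(central.lifetime_s.to_numpy() - truth) / truth < 0.15)

    def test_split_half_consistency(self, mtx_params):
        rate = 10.0
        forces, _ = sample_rip_forces(4000, rate, mtx_params, seed=4)
        events = [RipEvent("m", "MTX", float(f), rate) for f in forces]
        full = binned_lifetime_transform(events, 2.0).set_index("force_pN").lifetime_s
        halves = [
            binned_lifetime_transform(events[i::2], 2.0).set_index("force_pN").lifetime_s
            for i in (0, 1)
        ]
        common = full.index.intersection(halves[0].index).intersection(halves[1].index)
        # drop sparsely populated extreme bins where the estimator is noisy
        counts = binned_lifetime_transform(events, 2.0).set_index("force_pN")["count"]
        common = [f for f in common if counts[f] >= 50]
        avg = (halves[0][common] + halves[1][common]) / 2
        assert np.all(np.abs(avg - full[common]) / full[common] < 0.35)

    def test_single_bin_warns(self):
        ev = [RipEvent("m", "c", 20.0 + 0.01 * i, 4.0) for i in range(5)]
        with pytest.warns(UserWarning, match="single force bin"):
            binned_lifetime_transform(ev, bin_width=10.0)


class TestShapeDiagnostic:
    def test_single_barrier_data_prefers_single(self, mtx_params):
        preferred = []
        for seed in (100, 101, 102):
            events = simulate_rip_dataset(
                RipSimConfig(params=mtx_params, n_per_speed=(150, 150), seed=seed)
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rep = barrier_shape_diagnostic(events)
            preferred.append(rep["preferred"])
        assert preferred.count("single") >= 2

    def test_separated_mixture_prefers_mixture(self):
        labile = BarrierParams(log10_tau0=2.5, dx_ddagger=3.0, dG_ddagger=12.0)
        stable = BarrierParams(log10_tau0=5.46, dx_ddagger=1.67, dG_ddagger=15.3)
        events = simulate_rip_dataset(RipSimConfig(params=labile, n_per_speed=(75, 75), seed=6))
        events += simulate_rip_dataset(RipSimConfig(params=stable, n_per_speed=(75, 75), seed=7))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = barrier_shape_diagnostic(events)
        assert rep["preferred"] == "mixture"
        assert rep["loglik_mixture"] >= rep["loglik_single"]
        assert 0.3 < rep["mixture_weight"] < 0.7

    def test_requires_enough_events(self, mtx_params):
        events = [RipEvent("m", "c", 20.0, 4.0)] * 10
        with pytest.raises(ValueError):
            barrier_shape_diagnostic(events)


def test_barrier_params_validation():
    with pytest.raises(ValueError):
        BarrierParams(log10_tau0=5.0, dx_ddagger=-1.0, dG_ddagger=15.0)
    with pytest.raises(ValueError):
        BarrierParams(log10_tau0=5.0, dx_ddagger=1.0, dG_ddagger=15.0, nu=1.5)


def test_rip_event_validation():
    with pytest.raises(ValueError):
        RipEvent("m", "c", rip_force=-1.0, loading_rate=4.0)
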