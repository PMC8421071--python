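import numpy as np
import pytest
from oracles import huber_irls_oracle, ols_closed_form

from titerflow import (
    ChannelMap,
    EventTable,
    PopulationSpec,
    bootstrap_ci,
    calibrate_volume,
    robust_linear_fit,
    simulate_population,
    viv,
    volume_proxy,
)
from titerflow.errors import (
    DegenerateDataError,
    InsufficientDataError,
    ParameterError,
)


def pair_table(proxy_x, proxy_y, reporter):
    ev = np.column_stack([proxy_x, proxy_y, reporter])
    return EventTable(ev, ("FSC-W", "SSC-H", "FL1"))


class TestVolumeProxy:
    @pytest.mark.parametrize("x,y,expect", [
        (3.0, 4.0, 5.0),
        (0.0, 0.0, 0.0),
        (1.0, 1.0, np.sqrt(2)),
    ])
    def test_magnitude(self, cmap, x, y, expect):
        t = pair_table([x], [y], [1.0])
        assert volume_proxy(t, cmap)[0] == pytest.approx(expect, abs=1e-12)

    def test_missing_channel(self, cmap, make_table):
        t = make_table(channels=("FSC-W", "FL1"))
        with pytest.raises(Exception, match="SSC-H"):
            volume_proxy(t, cmap)


class TestRobustLinearFit:
    def test_perfect_line(self):
        x = np.linspace(0, 10, 100)
        fit = robust_linear_fit(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2, abs=1e-10)
        assert fit.intercept == pytest.approx(1, abs=1e-10)
        assert fit.scale == pytest.approx(0, abs=1e-12)

    def test_scale_recovers_gaussian_sd(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 10, 50_000)
        y = 3 * x + rng.normal(0, 0.5, 50_000)
        fit = robust_linear_fit(x, y)
        assert fit.scale == pytest.approx(0.5, rel=0.03)
        assert fit.slope == pytest.approx(3, rel=0.01)

    def test_agrees_with_independent_oracle(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(-5, 5, 500)
        y = 1.5 * x - 2 + rng.standard_t(3, 500)
        fit = robust_linear_fit(x, y)
        slope, intercept, scale = huber_irls_oracle(x, y)
        assert fit.slope == pytest.approx(slope, rel=1e-7)
        assert fit.intercept == pytest.approx(intercept, rel=1e-7)
        assert fit.scale == pytest.approx(scale, rel=1e-7)

    def test_outlier_resistance_vs_ols(self):
        rng = np.random.default_rng(2)
        x = np.linspace(0, 10, 1000)
        y = x.copy()
        bad = rng.choice(1000, size=10, replace=False)
        y[bad] += 100.0
        fit = robust_linear_fit(x, y)
        ols_slope, _ = ols_closed_form(x, y)
        assert abs(fit.slope - 1) < 0.02
        assert abs(ols_slope - 1) > 0.05

    def test_equals_ols_when_no_downweighting(self):
        # residuals tiny relative to scale spread: all weights 1
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 1, 200)
        y = 4 * x + 2 + rng.normal(0, 0.1, 200)
        fit = robust_linear_fit(x, y, k=50.0)  # huge k: nothing clipped
        slope, intercept = ols_closed_form(x, y)
        assert fit.slope == pytest.approx(slope, rel=1e-9)
        assert fit.intercept == pytest.approx(intercept, rel=1e-9)

    def test_constant_x_rejected(self):
        with pytest.raises(DegenerateDataError):
            robust_linear_fit(np.ones(10), np.arange(10.0))

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            robust_linear_fit(np.array([1.0, 2.0]), np.array([1.0, 2.0]))


class TestViv:
    def test_power_law_gives_zero_rsd(self, cmap):
        rng = np.random.default_rng(0)
        proxy = rng.lognormal(4, 0.3, 1000)
        reporter = 7 * proxy**1.3
        # emit proxy through a single channel pair (y=0 keeps magnitude=x)
        t = pair_table(proxy, np.zeros_like(proxy), reporter)
        r = viv(t, cmap)
        assert r.rsd == pytest.approx(0, abs=1e-10)
        assert r.slope == pytest.approx(1.3, abs=1e-8)

    def test_reporter_scale_invariance(self, cmap):
        rng = np.random.default_rng(1)
        proxy = rng.lognormal(4, 0.3, 2000)
        reporter = 5 * proxy * rng.lognormal(0, 0.25, 2000)
        t1 = pair_table(proxy, proxy, reporter)
        t2 = pair_table(proxy, proxy, 10 * reporter)
        r1, r2 = viv(t1, cmap), viv(t2, cmap)
        assert r2.rsd == pytest.approx(r1.rsd, abs=1e-12)
        assert r2.slope == pytest.approx(r1.slope, abs=1e-9)

    def test_recovers_injected_viv_sd(self, cmap):
        spec = PopulationSpec(
            n_events=20_000, seed=10, viv_sd=0.30, expr_extrinsic_sd=0.0,
            scatter_noise_sd=0.0, auto_meanlog=np.log(1e-3), auto_sdlog=0.0,
        )
        t, _ = simulate_population(spec, dose=100.0)
        r = viv(t, cmap)
        assert r.rsd == pytest.approx(0.30, rel=0.05)

    def test_monotone_in_injected_sd(self, cmap):
        rsds = []
        for sd in (0.1, 0.3, 0.6):
            spec = PopulationSpec(
                n_events=10_000, seed=11, viv_sd=sd, expr_extrinsic_sd=0.0,
                scatter_noise_sd=0.0, auto_meanlog=np.log(1e-3), auto_sdlog=0.0,
            )
            t, _ = simulate_population(spec, dose=100.0)
            rsds.append(viv(t, cmap).rsd)
        assert rsds[0] < rsds[1] < rsds[2]

    def test_nonpositive_dropped_and_counted(self, cmap):
        proxy = np.full(200, 10.0)
        proxy[:5] = -1.0  # becomes proxy 1.41.., still positive: use reporter
        reporter = np.full(200, 50.0) + np.arange(200)
        reporter[:8] = -2.0
        t = pair_table(np.abs(proxy) * np.arange(1, 201),
                       np.zeros(200), reporter)
        r = viv(t, cmap)
        assert r.n_dropped == 8
        assert r.n_used == 192

    def test_too_few_usable(self, cmap):
        t = pair_table([1, 2, 3], [0, 0, 0], [-1, -1, -1])
        with pytest.raises(InsufficientDataError):
            viv(t, cmap)

    def test_warns_below_min_events(self, cmap):
        rng = np.random.default_rng(2)
        proxy = rng.lognormal(4, 0.2, 50)
        t = pair_table(proxy, proxy, proxy * 2)
        with pytest.warns(UserWarning, match="only 50 events"):
            viv(t, cmap)


class TestBootstrapCI:
    def test_constant_data_zero_width(self):
        ci = bootstrap_ci(np.full(4, 4.0), "median", seed=0)
        assert ci.lower == ci.upper == ci.point == 4.0

    def test_seeded_determinism(self):
        rng = np.random.default_rng(0)
        x = rng.lognormal(2, 0.5, 300)
        a = bootstrap_ci(x, "median", seed=42)
        b = bootstrap_ci(x, "median", seed=42)
        assert (a.lower, a.upper) == (b.lower, b.upper)

    def test_nboot_guard(self):
        with pytest.raises(ParameterError):
            bootstrap_ci(np.arange(10.0), "median", n_boot=1)

    def test_empty_guard(self):
        with pytest.raises(ParameterError):
            bootstrap_ci(np.array([]), "median")

    def test_width_shrinks_like_sqrt_n(self):
        rng = np.random.default_rng(5)
        widths = {}
        for n in (500, 2000):
            w = []
            for rep in range(20):
                x = rng.lognormal(2, 0.5, n)
                ci = bootstrap_ci(x, "median", n_boot=400, seed=rep)
                w.append(ci.width)
            widths[n] = np.mean(w)
        ratio = widths[500] / widths[2000]
        assert 1.6 <= ratio <= 2.4

    def test_viv_rsd_statistic(self, cmap):
        spec = PopulationSpec(
            n_events=2000, seed=12, viv_sd=0.3, expr_extrinsic_sd=0.0,
            scatter_noise_sd=0.0, auto_meanlog=np.log(1e-3), auto_sdlog=0.0,
        )
        t, _ = simulate_population(spec, dose=100.0)
        pairs = np.column_stack([volume_proxy(t, cmap), t.channel("FL1")])
        ci = bootstrap_ci(pairs, "viv_rsd", n_boot=100, seed=1)
        assert ci.lower <= ci.point <= ci.upper
        assert ci.lower < 0.3 < ci.upper or abs(ci.point - 0.3) < 0.03

    def test_callable_statistic(self):
        x = np.arange(100.0)
        ci = bootstrap_ci(x, statistic=np.mean, n_boot=200, seed=3)
        assert ci.point == pytest.approx(49.5)
        assert ci.lower < ci.point < ci.upper


class TestCalibrateVolume:
    def test_identity_map(self):
        rng = np.random.default_rng(0)
        vol = rng.uniform(20, 120, 5000)
        cal = calibrate_volume(vol, vol, seed=1)
        assert cal.slope == pytest.approx(1.0, rel=0.02)
        assert abs(cal.intercept) < 0.02 * np.mean(vol)

    def test_affine_map_recovered(self):
        rng = np.random.default_rng(0)
        vol = rng.uniform(20, 120, 5000)
        proxy = 2 * vol + 5
        cal = calibrate_volume(proxy, vol, seed=7)
        assert cal.slope == pytest.approx(2.0, rel=0.02)
        # intercept MC noise floor is ~1% of the response scale
        assert abs(cal.intercept - 5) < 0.02 * np.mean(proxy)

    def test_n_draws_guard(self):
        with pytest.raises(DegenerateDataError):
            calibrate_volume(np.arange(10.0), np.arange(10.0), n_draws=1)

    def test_constant_vector_guard(self):
        with pytest.raises(DegenerateDataError):
            calibrate_volume(np.ones(10), np.arange(10.0))

    def test_empty_guard(self):
        with pytest.raises(ParameterError):
            calibrate_volume(np.array([]), np.arange(10.0))

    def test_excluded_groups_recorded(self):
        rng = np.random.default_rng(0)
        vol = rng.uniform(20, 60, 500)
        cal = calibrate_volume(vol, vol, seed=0,
                               excluded_groups=("gate4", "gate6", "gate9"))
        assert cal.excluded_groups == ("gate4", "gate6", "gate9")
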