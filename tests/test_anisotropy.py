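import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import pepstaple as ps
from pepstaple.anisotropy import (
    AnisotropyError,
    FitError,
    anisotropy_from_bound_fraction,
    logistic_curve,
)


class TestElementaryObservables:
    @pytest.mark.parametrize("P,S,G,expected", [
        (50, 100, 1.0, 200.0),
        (0, 100, 2.0, 100.0),
        (100, 0, 0.5, 100.0),
    ])
    def test_total_intensity(self, P, S, G, expected):
        assert ps.total_intensity(ps.AnisotropyRead(P, S, G)) == expected

    def test_anisotropy_examples(self):
        # S == G*P: numerator vanishes
        assert ps.anisotropy(ps.AnisotropyRead(P=50, S=100, G=2.0)) == 0.0
        # no perpendicular signal: upper limit
        assert ps.anisotropy(ps.AnisotropyRead(P=0, S=77, G=1.0)) == 1.0
        assert ps.anisotropy(ps.AnisotropyRead(P=50, S=100, G=1.0)) == pytest.approx(0.25)

    def test_anisotropy_undefined_at_zero_intensity(self):
        with pytest.raises(AnisotropyError):
            ps.anisotropy(ps.AnisotropyRead(P=0, S=0, G=1.0))

    @given(P=st.floats(0, 1e6), S=st.floats(0, 1e6), G=st.floats(0.01, 10))
    def test_anisotropy_bounded(self, P, S, G):
        read = ps.AnisotropyRead(P, S, G)
        if S + 2 * G * P > 0:
            r = ps.anisotropy(read)
            # bounds attained only in the degenerate single-channel limits
            # (or when S underflows against G*P at float precision)
            assert -0.5 <= r <= 1.0

    def test_intensity_is_anisotropy_denominator(self):
        # the two observables share the same normalisation
        read = ps.AnisotropyRead(P=33.0, S=71.0, G=1.1)
        r = ps.anisotropy(read)
        assert r * ps.total_intensity(read) == pytest.approx(read.S - read.G * read.P)


class TestBoundFraction:
    def test_endpoints_and_midpoint(self):
        assert ps.bound_fraction(0.05, 0.05, 0.25) == 0.0
        assert ps.bound_fraction(0.25, 0.05, 0.25, lam=1.0) == 1.0
        assert ps.bound_fraction(0.15, 0.05, 0.25, lam=1.0) == pytest.approx(0.5)

    def test_degenerate_window(self):
        with pytest.raises(AnisotropyError):
            ps.bound_fraction(0.1, 0.2, 0.2)

    def test_overshoot_clamped_with_warning(self):
        with pytest.warns(UserWarning):
            assert ps.bound_fraction(0.40, 0.05, 0.25) == 1.0
        # small overshoot within tolerance clamps silently
        assert ps.bound_fraction(0.252, 0.05, 0.25) == 1.0

    def test_inverse_round_trip_with_lambda(self):
        for lam in (0.5, 1.0, 2.0):
            lb = np.linspace(0, 1, 11)
            r = anisotropy_from_bound_fraction(lb, 0.02, 0.3, lam)
            back = [ps.bound_fraction(ri, 0.02, 0.3, lam) for ri in r]
            np.testing.assert_allclose(back, lb, atol=1e-12)


class TestAggregation:
    def test_hand_arithmetic(self):
        series = ps.TitrationSeries(
            mode="competition", x=np.array([1e-6, 1e-5]),
            reads=[[0.10, 0.12, 0.14], [0.2]])
        agg = ps.aggregate_replicates(series)
        assert agg["mean"].iloc[0] == pytest.approx(0.12)
        assert agg["sd"].iloc[0] == pytest.approx(0.02)
        assert agg["sd"].iloc[1] == 0.0  # single replicate

    def test_identical_replicates_zero_sd(self):
        series = ps.TitrationSeries(
            mode="competition", x=np.array([1e-6, 1e-5]),
            reads=[[0.1, 0.1, 0.1], [0.2, 0.2, 0.2]])
        assert (ps.aggregate_replicates(series)["sd"] == 0).all()

    def test_matches_independent_recomputation(self):
        rng = np.random.default_rng(11)
        x = np.array([1e-6, 3e-6, 1e-5])
        reps = [list(rng.normal(0.1, 0.01, 3)) for _ in x]
        series = ps.TitrationSeries(mode="competition", x=x, reads=reps)
        agg = ps.aggregate_replicates(series)
        for k, r in enumerate(reps):
            m = sum(r) / len(r)
            sd = math.sqrt(sum((v - m) ** 2 for v in r) / (len(r) - 1))
            assert agg["mean"].iloc[k] == pytest.approx(m)
            assert agg["sd"].iloc[k] == pytest.approx(sd)


class TestQuadraticModel:
    def test_collapses_to_hyperbolic_isotherm(self):
        kd = 1.5e-6
        x = np.logspace(-8, -4, 20)
        lb = ps.quadratic_bound_fraction(x, kd, 1e-30)
        np.testing.assert_allclose(lb, x / (x + kd), rtol=1e-6)

    def test_half_saturation_at_kd(self):
        kd = 1.5e-6
        lb = ps.quadratic_bound_fraction(np.array([kd]), kd, kd * 1e-6)
        assert lb[0] == pytest.approx(0.5, abs=1e-4)

    def test_monotone_and_saturating(self):
        x = np.logspace(-9, -2, 60)
        lb = ps.quadratic_bound_fraction(x, 1.5e-6, 50e-9)
        assert np.all(np.diff(lb) >= 0)
        assert lb[-1] == pytest.approx(1.0, abs=1e-3)


class TestDirectFit:
    def test_noiseless_recovery(self):
        cfg = ps.SimulationConfig(noise_sd_anisotropy=0.0, tracer_conc=50e-9)
        series = ps.simulate_direct_titration(1.5e-6, r_min=0.05, r_max=0.25, config=cfg)
        fit = ps.fit_direct_titration(series)
        assert fit.converged
        assert fit.Kd == pytest.approx(1.5e-6, rel=1e-6)
        assert fit.r_min == pytest.approx(0.05, abs=1e-8)
        assert fit.r_max == pytest.approx(0.25, abs=1e-8)

    def test_scale_equivariance(self):
        cfg = ps.SimulationConfig(noise_sd_anisotropy=0.0)
        base = ps.simulate_direct_titration(1.5e-6, config=cfg)
        c = 10.0
        scaled = ps.TitrationSeries(mode="direct", x=base.x * c, reads=base.reads,
                                    tracer_conc=base.tracer_conc * c)
        kd1 = ps.fit_direct_titration(base).Kd
        kd2 = ps.fit_direct_titration(scaled).Kd
        assert kd2 / kd1 == pytest.approx(c, rel=1e-5)

    def test_under_determined(self):
        series = ps.TitrationSeries(mode="direct", x=np.array([1e-6, 1e-5]),
                                    reads=[[0.1], [0.2]])
        with pytest.raises(FitError):
            ps.fit_direct_titration(series)

    def test_requires_direct_mode(self):
        series = ps.TitrationSeries(mode="competition", x=np.array([1e-6, 1e-5]),
                                    reads=[[0.1], [0.2]])
        with pytest.raises(AnisotropyError):
            ps.fit_direct_titration(series)


class TestCompetitionFit:
    def test_noiseless_4pl_recovery(self):
        cfg = ps.SimulationConfig(noise_sd_anisotropy=0.0)
        series = ps.simulate_competition_logistic(
            50e-6, p=1.2, r_min=-0.03, r_max=0.12, config=cfg)
        fit = ps.fit_competition(series)
        assert fit.IC50 == pytest.approx(50e-6, rel=1e-6)
        assert fit.hill == pytest.approx(1.2, rel=1e-6)
        assert fit.r_min == pytest.approx(-0.03, rel=1e-6)
        assert fit.r_max == pytest.approx(0.12, rel=1e-6)
        assert not fit.monotonicity_warning

    def test_restrained_floor_is_exact(self):
        cfg = ps.SimulationConfig(noise_sd_anisotropy=0.0)
        series = ps.simulate_competition_logistic(50e-6, config=cfg)
        fit = ps.fit_competition(series, restrain_rmin=True, rmin_value=-0.03)
        assert fit.restrained_rmin
        assert fit.r_min == -0.03  # fixed, bit-exact
        assert fit.IC50 == pytest.approx(50e-6, rel=1e-4)

    def test_matches_equilibrium_bisection_oracle(self):
        cfg = ps.SimulationConfig(noise_sd_anisotropy=0.0, tracer_conc=50e-9,
                                  protein_conc=15e-6)
        series = ps.simulate_competition_equilibrium(1.5e-6, 3e-6, config=cfg)
        fit = ps.fit_competition(series)
        truth = series.ground_truth["half_displacement"]
        assert abs(fit.IC50 - truth) / truth < 0.05

    def test_flat_data_flagged(self):
        x = np.logspace(-6, -3, 10)
        rng = np.random.default_rng(3)
        reads = [list(0.12 + rng.normal(0, 1e-4, 3)) for _ in x]
        series = ps.TitrationSeries(mode="competition", x=x, reads=reads)
        try:
            fit = ps.fit_competition(series)
            assert fit.monotonicity_warning or fit.IC50 > x[-1]
        except FitError:
            pass  # refusing to fit a flat curve is equally acceptable

    def test_scale_equivariance(self):
        cfg = ps.SimulationConfig(noise_sd_anisotropy=0.0)
        base = ps.simulate_competition_logistic(50e-6, config=cfg)
        c = 7.0
        scaled = ps.TitrationSeries(mode="competition", x=base.x * c, reads=base.reads,
                                    tracer_conc=base.tracer_conc)
        f1, f2 = ps.fit_competition(base), ps.fit_competition(scaled)
        assert f2.IC50 / f1.IC50 == pytest.approx(c, rel=1e-5)

    def test_replicate_scatter_gives_ic50_sd(self):
        cfg = ps.SimulationConfig(noise_sd_anisotropy=0.003, replicates=3, seed=5)
        series = ps.simulate_competition_logistic(50e-6, config=cfg)
        fit = ps.fit_competition(series)
        assert fit.IC50_sd is not None and fit.IC50_sd > 0
        assert fit.IC50_sd < fit.IC50  # scatter far smaller than the estimate


class TestDeltaDeltaG:
    def test_reproduces_screen_fold_improvement(self):
        # 199 uM -> 49 uM at 298.15 K: ~3.5 kJ/mol, 4-fold
        ddg = ps.delta_delta_g(199e-6, 49e-6, 298.15)
        assert ddg == pytest.approx(3.47, abs=0.01)
        assert round(199 / 49) == 4

    def test_equal_ic50_is_zero(self):
        assert ps.delta_delta_g(1e-4, 1e-4) == 0.0

    def test_fourfold_is_rt_ln4(self):
        assert ps.delta_delta_g(100e-6, 25e-6, 298.15) == pytest.approx(
            8.314 * 298.15 * math.log(4) / 1000, rel=1e-12)

    @given(a=st.floats(1e-9, 1e-2), b=st.floats(1e-9, 1e-2))
    def test_antisymmetry(self, a, b):
        assert ps.delta_delta_g(a, b) == pytest.approx(-ps.delta_delta_g(b, a), abs=1e-12)

    def test_domain_errors(self):
        with pytest.raises(AnisotropyError):
            ps.delta_delta_g(0.0, 1e-6)
        with pytest.raises(AnisotropyError):
            ps.delta_delta_g(1e-6, 1e-6, temperature=0.0)
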