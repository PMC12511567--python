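import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from lipidsense.kinetics import (
    CyclingParams,
    FitError,
    KineticParams,
    KineticsError,
    assemble_loading_dataset,
    equilibrium_initial_state,
    fit_exponential_discharge,
    fit_global_two_state,
    integrate_two_state_ode,
    loaded_fraction,
    rate_eigenvalues,
    steady_state_loaded_fraction,
)
from lipidsense.synthetic import LoadingSimSpec, simulate_loading_timecourse

rates = st.floats(1e-3, 1e2)


def random_params(rng):
    k1, k2, k3 = 10.0 ** rng.uniform(-2.5, 2.5, size=3)
    return KineticParams(k1=k1, k2=k2, k3=k3, T=0.75)


class TestEquilibrium:
    def test_symmetric_rates_split_evenly(self):
        a0, b0 = equilibrium_initial_state(KineticParams(1.0, 1.0, 1.0, T=0.75))
        assert a0 == b0 == pytest.approx(0.375)

    def test_three_to_one(self):
        a0, b0 = equilibrium_initial_state(KineticParams(3.0, 1.0, 1.0, T=0.75))
        assert (a0, b0) == (pytest.approx(0.1875), pytest.approx(0.5625))

    def test_no_inactivation(self):
        a0, b0 = equilibrium_initial_state(KineticParams(0.0, 1.0, 1.0, T=0.75))
        assert (a0, b0) == (0.75, 0.0)

    def test_degenerate_equilibrium(self):
        with pytest.raises(KineticsError, match="degenerate"):
            equilibrium_initial_state(KineticParams(0.0, 0.0, 1.0))


class TestEigenvalues:
    def test_factorized_case(self):
        # with k1 = 0 the characteristic polynomial factors as (λ+k2)(λ+k3)
        r1, r2 = rate_eigenvalues(KineticParams(0.0, 2.0, 5.0))
        assert (r1, r2) == (pytest.approx(-2.0), pytest.approx(-5.0))

    def test_unit_rates(self):
        r1, r2 = rate_eigenvalues(KineticParams(1.0, 1.0, 1.0))
        assert r1 == pytest.approx((-3 + np.sqrt(5)) / 2)
        assert r2 == pytest.approx((-3 - np.sqrt(5)) / 2)

    def test_no_loading_conserves(self):
        r1, r2 = rate_eigenvalues(KineticParams(1.0, 1.0, 0.0))
        assert r1 == 0.0 and r2 < 0

    @settings(derandomize=True, max_examples=50)
    @given(k1=rates, k2=rates, k3=rates)
    def test_vieta(self, k1, k2, k3):
        """Root sum/product equal −(k1+k2+k3) and k2·k3; both roots ≤ 0."""
        r1, r2 = rate_eigenvalues(KineticParams(k1, k2, k3))
        assert r1 + r2 == pytest.approx(-(k1 + k2 + k3), rel=1e-9)
        assert r1 * r2 == pytest.approx(k2 * k3, rel=1e-6, abs=1e-12)
        assert r2 <= r1 <= 0


class TestLoadedFraction:
    def test_starts_at_zero(self):
        sol = loaded_fraction(KineticParams(1.0, 0.5, 10.0), [0.0])
        assert sol.C[0] == 0.0

    def test_single_exponential_limit(self):
        # k1 = 0: the whole pool is active, C(t) = T(1 − e^{−k3 t})
        p = KineticParams(0.0, 1.0, 5.0, T=0.75)
        t = np.array([0.05, 0.2, 1.0])
        expected = p.T * -np.expm1(-p.k3 * t)
        np.testing.assert_allclose(loaded_fraction(p, t).C, expected, rtol=1e-12)
        assert loaded_fraction(p, [0.2]).C[0] == pytest.approx(
            0.75 * (1 - np.exp(-1.0))
        )

    def test_matches_ode_oracle_spot_check(self):
        p = KineticParams(1.0, 0.5, 10.0, T=0.75)
        t = np.array([0.01, 0.1, 1.0, 10.0])
        np.testing.assert_allclose(
            loaded_fraction(p, t).C, integrate_two_state_ode(p, t).C, atol=1e-8
        )

    def test_matches_ode_oracle_random_sweep(self):
        """Closed form ≡ stiff ODE integration to 1e-8 over 100 random
        parameter draws (the eigen-decomposition, not any printed closed
        form, is the reference solution)."""
        rng = np.random.default_rng(42)
        t = np.geomspace(1e-3, 1e3, 12)
        for _ in range(100):
            p = random_params(rng)
            np.testing.assert_allclose(
                loaded_fraction(p, t).C,
                integrate_two_state_ode(p, t).C,
                atol=1e-8,
            )

    def test_degenerate_eigenvalues_confluent_branch(self):
        # k1 = 0, k2 = k3 makes the discriminant vanish exactly
        p = KineticParams(0.0, 2.0, 2.0, T=0.75)
        sol = loaded_fraction(p, np.geomspace(1e-3, 10, 20))
        assert sol.degenerate
        ode = integrate_two_state_ode(p, sol.times)
        np.testing.assert_allclose(sol.C, ode.C, atol=1e-8)

    @settings(derandomize=True, max_examples=40)
    @given(k1=rates, k2=rates, k3=rates)
    def test_monotone_bounded_and_conserved(self, k1, k2, k3):
        p = KineticParams(k1, k2, k3, T=0.75)
        t = np.geomspace(1e-4, 1e4, 50)
        sol = loaded_fraction(p, t)
        assert np.all(np.diff(sol.C) >= -1e-12)
        assert np.all(sol.C <= p.T + 1e-12)
        np.testing.assert_allclose(sol.A + sol.B + sol.C, p.T, atol=1e-9)

    def test_long_time_limit_is_T(self):
        p = KineticParams(1.0, 0.5, 10.0, T=0.75)
        r1, r2 = rate_eigenvalues(p)
        t_inf = 100.0 / min(abs(r) for r in (r1, r2) if r != 0)
        assert loaded_fraction(p, [t_inf]).C[0] == pytest.approx(p.T, abs=1e-6)

    def test_negative_time_rejected(self):
        with pytest.raises(KineticsError):
            loaded_fraction(KineticParams(1.0, 1.0, 1.0), [-1.0])


class TestOdeOracle:
    def test_conservation(self):
        p = KineticParams(0.3, 0.7, 20.0, T=0.75)
        sol = integrate_two_state_ode(p, np.geomspace(1e-3, 100, 30))
        np.testing.assert_allclose(sol.A + sol.B + sol.C, p.T, atol=1e-8)

    def test_k1_zero_closed_form(self):
        p = KineticParams(0.0, 1.0, 3.0, T=0.75)
        t = np.geomspace(1e-2, 10, 10)
        np.testing.assert_allclose(
            integrate_two_state_ode(p, t).C, p.T * -np.expm1(-p.k3 * t), atol=1e-8
        )


class TestAssembleDataset:
    @staticmethod
    def make(times, condition="c"):
        return pd.DataFrame(
            {"condition": condition, "time_s": times,
             "fraction_loaded": np.linspace(0.1, 0.5, len(times)),
             "replicate": 0}
        )

    def test_manual_window_is_closed(self):
        qf = self.make([0.01, 0.1])
        manual = self.make([10, 30, 120, 600, 1200])
        merged = assemble_loading_dataset(qf, manual)
        manual_times = merged.loc[merged["source"] == "manual", "time_s"]
        assert sorted(manual_times) == [30, 120, 600]

    def test_empty_quenched_flow(self):
        merged = assemble_loading_dataset(None, self.make([30, 60, 120]))
        assert set(merged["source"]) == {"manual"}
        assert len(merged) == 3

    def test_infinite_window_is_identity_concat(self):
        qf = self.make([0.01, 0.1])
        manual = self.make([10, 1200])
        merged = assemble_loading_dataset(qf, manual, manual_window=(0, np.inf))
        assert len(merged) == 4

    def test_empty_result_raises(self):
        with pytest.raises(KineticsError, match="empty"):
            assemble_loading_dataset(None, self.make([10.0, 20.0]),
                                     manual_window=(30, 600))


class TestGlobalFit:
    def test_noise_free_recovery(self):
        spec = LoadingSimSpec(noise_sd=0.0, replicates=1, seed=0)
        data = simulate_loading_timecourse(spec)
        res = fit_global_two_state(data, seed=1)
        assert res.k3 == pytest.approx(30.0, rel=1e-4)
        for cond, truth in spec.conditions.items():
            fitted = res.condition_params[cond]
            assert fitted.k1 == pytest.approx(truth.k1, rel=1e-4)
            assert fitted.k2 == pytest.approx(truth.k2, rel=1e-4)
        assert res.rss < 1e-12

    def test_noisy_recovery_of_shared_k3(self, two_condition_dataset):
        res = fit_global_two_state(two_condition_dataset, seed=1)
        assert res.k3 == pytest.approx(30.0, rel=0.10)
        assert res.converged
        assert all(se >= 0 or np.isnan(se) for se in res.stderr.values())

    def test_recovery_median_relative_error(self):
        """Across seeded noisy replicates (σ = 0.02), the median relative
        error of every recovered rate stays below 15%."""
        truth = dict(LoadingSimSpec().conditions)
        errors = {name: [] for name in
                  [f"{c}.{k}" for c in truth for k in ("k1", "k2")] + ["k3"]}
        for seed in range(15):
            data = simulate_loading_timecourse(
                LoadingSimSpec(replicates=10, seed=100 + seed))
            res = fit_global_two_state(data, seed=seed, n_starts=8)
            errors["k3"].append(abs(res.k3 - 30.0) / 30.0)
            for cond, p in truth.items():
                f = res.condition_params[cond]
                errors[f"{cond}.k1"].append(abs(f.k1 - p.k1) / p.k1)
                errors[f"{cond}.k2"].append(abs(f.k2 - p.k2) / p.k2)
        for name, errs in errors.items():
            assert np.median(errs) < 0.15, (name, errs)

    def test_single_condition_rejected(self):
        df = pd.DataFrame({"condition": "only", "time_s": [1.0, 10.0],
                           "fraction_loaded": [0.1, 0.2]})
        with pytest.raises(KineticsError, match="2 conditions"):
            fit_global_two_state(df)

    def test_narrow_time_span_rejected(self):
        df = pd.concat([
            pd.DataFrame({"condition": c, "time_s": [1.0, 2.0, 3.0, 4.0],
                          "fraction_loaded": [0.1, 0.2, 0.3, 0.4]})
            for c in ("a", "b")
        ])
        with pytest.raises(KineticsError, match="decade"):
            fit_global_two_state(df)


class TestDischargeFit:
    @staticmethod
    def decay(kd, c0=0.6, noise=0.0, seed=0):
        t = np.linspace(0, 600, 25)
        rng = np.random.default_rng(seed)
        y = c0 * np.exp(-kd * t) + rng.normal(0, noise, t.shape)
        return pd.DataFrame({"time_s": t, "fraction_loaded": np.clip(y, 0, 1)})

    def test_exact_decay(self):
        fit = fit_exponential_discharge(self.decay(0.01))
        assert fit.kd == pytest.approx(0.01, rel=1e-6)
        assert fit.c0 == pytest.approx(0.6, rel=1e-6)

    def test_constant_data(self):
        df = pd.DataFrame({"time_s": [0, 60, 120], "fraction_loaded": [0.5] * 3})
        fit = fit_exponential_discharge(df)
        assert fit.kd == 0.0

    def test_noisy_recovery(self):
        fit = fit_exponential_discharge(self.decay(0.01, noise=0.02, seed=5))
        assert fit.kd == pytest.approx(0.01, rel=0.15)

    def test_increasing_data_flagged(self):
        df = pd.DataFrame({"time_s": [0, 60, 120],
                           "fraction_loaded": [0.1, 0.3, 0.5]})
        assert fit_exponential_discharge(df).increasing_warning


def cycle_steady_state_numeric(p: CyclingParams) -> float:
    """Independent oracle: integrate the 3-state cycle A⇌B, A→C, C→A to
    stationarity and read off C/(A+B+C)."""

    def rhs(_t, y):
        a, b, c = y
        return [-(p.k1 + p.k3) * a + p.k2 * b + p.kd * c,
                p.k1 * a - p.k2 * b,
                p.k3 * a - p.kd * c]

    slowest = min(r for r in (p.k1, p.k2, p.k3, p.kd) if r > 0)
    t_end = 200.0 / slowest
    sol = solve_ivp(rhs, (0, t_end), [1.0, 0.0, 0.0], method="LSODA",
                    rtol=1e-10, atol=1e-12)
    a, b, c = sol.y[:, -1]
    return c / (a + b + c)


class TestSteadyStateCycling:
    def test_absorbing_loaded_state(self):
        assert steady_state_loaded_fraction(CyclingParams(1, 1, 1, 0)) == 1.0

    def test_balanced_loading_and_discharge(self):
        assert steady_state_loaded_fraction(
            CyclingParams(0.0, 1.0, 2.0, 2.0)
        ) == pytest.approx(0.5)

    @pytest.mark.parametrize(
        "params",
        [CyclingParams(0.5, 0.2, 3.0, 0.05),
         CyclingParams(2.0, 1.0, 30.0, 0.01),
         CyclingParams(0.01, 0.5, 0.2, 1.0)],
    )
    def test_matches_cycle_ode_oracle(self, params):
        assert steady_state_loaded_fraction(params) == pytest.approx(
            cycle_steady_state_numeric(params), abs=1e-6
        )

    def test_requires_k2_positive(self):
        with pytest.raises(KineticsError):
            steady_state_loaded_fraction(CyclingParams(1.0, 0.0, 1.0, 1.0))

    def test_undefined_without_any_cycling(self):
        with pytest.raises(KineticsError):
            steady_state_loaded_fraction(CyclingParams(1.0, 1.0, 0.0, 0.0))

    @settings(derandomize=True, max_examples=40)
    @given(q=rates, kd=rates, k3=rates)
    def test_monotone_in_conformational_bias_and_discharge(self, q, kd, k3):
        """The loaded fraction falls as the equilibrium shifts inactive
        (larger k1/k2) and as discharge accelerates."""
        base = steady_state_loaded_fraction(CyclingParams(q, 1.0, k3, kd))
        more_inactive = steady_state_loaded_fraction(
            CyclingParams(q * 2, 1.0, k3, kd))
        faster_discharge = steady_state_loaded_fraction(
            CyclingParams(q, 1.0, k3, kd * 2))
        assert more_inactive <= base + 1e-12
        assert faster_discharge <= base + 1e-12

    def test_cycling_frequency_gates_equilibrium_sensitivity(self):
        """Slow cycling hides the conformational equilibrium (ratio of
        steady-state fractions → 1); fast cycling exposes it fully
        (ratio → (1+q_high)/(1+q_low))."""
        q_low, q_high, k3 = 0.1, 10.0, 1.0
        ratios = []
        for kd in (1e-4, 1e-2, 1.0, 1e2, 1e4):
            lo = steady_state_loaded_fraction(CyclingParams(q_low, 1.0, k3, kd))
            hi = steady_state_loaded_fraction(CyclingParams(q_high, 1.0, k3, kd))
            ratios.append(lo / hi)
        assert ratios[0] == pytest.approx(1.0, abs=1e-3)
        assert all(b >= a - 1e-12 for a, b in zip(ratios, ratios[1:]))
        assert ratios[-1] == pytest.approx((1 + q_high) / (1 + q_low), rel=1e-3)
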