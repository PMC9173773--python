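import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phagescreen.kinetics import (
    MODES,
    KineticParams,
    ThTTrace,
    apply_inhibition,
    default_params,
    fit_inhibition,
    halftime,
    load_traces_csv,
    save_traces_csv,
    select_mode,
    simulate_seeded_assay,
    simulate_trace,
    with_noise,
)

TIMES = np.linspace(1e-4, 12.0, 80)


class TestParams:
    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            KineticParams(k_n=-1, k_2=0, k_plus=0)

    def test_seed_fraction_bounds(self):
        with pytest.raises(ValueError):
            KineticParams(k_n=0, k_2=0, k_plus=1, seed_mass_fraction=1.5)

    def test_seed_number_from_mean_length(self):
        p = KineticParams(
            k_n=0, k_2=0, k_plus=1, m0=2.0, seed_mass_fraction=0.3,
            mean_seed_length=100,
        )
        P0, M0 = p.initial_state()
        assert M0 == pytest.approx(0.6)
        assert P0 == pytest.approx(0.006)

    def test_apply_inhibition_selective(self):
        p = default_params()
        q = apply_inhibition(p, "secondary", 0.5)
        assert q.k_2 == pytest.approx(0.5 * p.k_2)
        assert q.k_n == p.k_n and q.k_plus == p.k_plus
        with pytest.raises(ValueError):
            apply_inhibition(p, "secondary", 0.0)
        with pytest.raises(ValueError):
            apply_inhibition(p, "tertiary", 0.5)


class TestSimulateTrace:
    def test_no_nucleation_source_stays_flat(self):
        p = KineticParams(k_n=0.0, k_2=1e-4, k_plus=1e4, seed_mass_fraction=0.0)
        trace = simulate_trace(p, TIMES)
        assert np.allclose(trace.signal, 0.0, atol=1e-9)

    def test_elongation_only_matches_closed_form(self):
        # k_n = k_2 = 0 with seeds: P constant, m(t) = m(0) exp(-2 k+ P0 t)
        p = KineticParams(
            k_n=0.0, k_2=0.0, k_plus=1e4, m0=3.0, seed_mass_fraction=0.3,
            mean_seed_length=500,
        )
        t = np.linspace(1e-4, 0.5, 60)
        trace = simulate_trace(p, t)
        P0, M0 = p.initial_state()
        m_exact = (p.m0 - M0) * np.exp(-2 * p.k_plus * P0 * t)
        assert np.abs(trace.signal - (p.m0 - m_exact) / p.m0).max() < 1e-6

    def test_heavily_seeded_no_lag(self):
        p = KineticParams(k_n=0.0, k_2=0.0, k_plus=1e4, seed_mass_fraction=0.3)
        trace = simulate_trace(p, np.linspace(1e-4, 1.0, 100))
        d = np.diff(trace.signal)
        assert np.all(d >= -1e-9)
        assert np.all(d[1:] <= d[:-1] + 1e-9)  # concave: fastest at t=0

    def test_halftime_scaling_with_monomer(self):
        # secondary-dominated unseeded: t50 ~ m0^(-(n2+1)/2) within 5%
        t50 = {}
        for m0 in (2.0, 4.0):
            p = KineticParams(k_n=1e-12, k_2=2e-5, k_plus=1e4, m0=m0)
            tt = np.geomspace(1e-4, 3000, 3000)
            t50[m0] = halftime(simulate_trace(p, tt))
        gamma = np.log(t50[4.0] / t50[2.0]) / np.log(2.0)
        expected = -(2 + 1) / 2
        assert abs(gamma - expected) / abs(expected) < 0.05

    def test_mass_conservation_and_monotonicity_fuzz(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            p = KineticParams(
                k_n=10 ** rng.uniform(-9, -6),
                k_2=10 ** rng.uniform(-6, -4),
                k_plus=10 ** rng.uniform(3, 5),
                m0=float(rng.uniform(1, 5)),
                seed_mass_fraction=float(rng.uniform(0, 0.1)),
            )
            trace = simulate_trace(p, np.linspace(1e-4, 200.0, 300))
            assert trace.signal.min() >= -1e-9
            assert trace.signal.max() <= 1.0 + 1e-9
            assert np.all(np.diff(trace.signal) >= -1e-7)
            # monomer + fibril mass is m0 by construction; plateau reaches m0
            assert trace.signal[-1] > 0.99

    def test_nonmonotone_times_rejected(self):
        with pytest.raises(ValueError):
            simulate_trace(default_params(), [0.0, 1.0, 0.5])


class TestHalftime:
    def test_crossing_at_known_time(self):
        trace = ThTTrace(np.array([0.0, 10.0, 20.0]), np.array([0.0, 0.5, 1.0]))
        assert halftime(trace) == pytest.approx(10.0)

    def test_dense_grid_oracle(self):
        p = default_params()
        coarse = simulate_trace(p, np.linspace(1e-4, 12, 60))
        dense = simulate_trace(p, np.linspace(1e-4, 12, 4000))
        dt = 12 / 59
        assert abs(halftime(coarse) - halftime(dense)) < dt

    def test_never_crossing_errors(self):
        trace = ThTTrace(np.array([0.0, 1.0, 2.0]), np.array([0.4, 0.3, 0.2]))
        with pytest.raises(ValueError):
            halftime(trace)


class TestNormalization:
    def test_raw_fluorescence_affine_normalized(self):
        p = default_params()
        trace = simulate_trace(p, TIMES)
        raw = ThTTrace(trace.times, 50.0 + 400.0 * trace.signal)
        norm = raw.normalized()
        assert norm.is_normalized
        assert np.allclose(norm.signal, trace.signal, atol=2e-3)

    def test_already_normalized_passthrough(self):
        p = default_params()
        trace = simulate_trace(p, TIMES)
        assert trace.normalized() is trace


class TestFitInhibition:
    def _make_traces(self, mode, concs_factors, noise, seed, base=None):
        base = base or default_params()
        rng = np.random.default_rng(seed)
        traces = []
        for conc, factor in concs_factors:
            p = apply_inhibition(base, mode, factor) if factor < 1 else base
            tr = simulate_trace(p, TIMES, labels={"inhibitor_uM": conc})
            traces.append(with_noise(tr, noise, rng))
        return traces

    def test_secondary_factor_recovery_within_15pct(self):
        truth = [(0.0, 1.0), (1.0, 0.5), (3.0, 0.2)]
        traces = self._make_traces("secondary", truth, noise=0.01, seed=4)
        fit = fit_inhibition(traces, "secondary")
        for conc, expected in truth[1:]:
            assert fit.factors[conc] == pytest.approx(expected, rel=0.15)

    def test_zero_inhibitor_only_errors(self):
        traces = self._make_traces("secondary", [(0.0, 1.0)], noise=0.0, seed=0)
        with pytest.raises(ValueError, match="2 inhibitor"):
            fit_inhibition(traces, "secondary")

    def test_missing_control_errors(self):
        traces = self._make_traces(
            "secondary", [(1.0, 0.5), (3.0, 0.2)], noise=0.0, seed=0
        )
        with pytest.raises(ValueError, match="zero-inhibitor"):
            fit_inhibition(traces, "secondary")

    def test_null_data_gives_factors_near_one(self):
        traces = self._make_traces(
            "secondary", [(0.0, 1.0), (1.0, 1.0), (3.0, 1.0)], noise=0.01, seed=8
        )
        fit = fit_inhibition(traces, "secondary")
        assert all(f > 0.75 for f in fit.factors.values())

    def test_select_mode_ranks_generating_mode_first(self):
        truth = [(0.0, 1.0), (1.0, 0.3), (3.0, 0.1)]
        traces = self._make_traces("secondary", truth, noise=0.005, seed=4)
        fits = select_mode(traces)
        assert fits[0].mode == "secondary"
        assert fits[0].mean_residual_error <= fits[-1].mean_residual_error


class TestSeededAssay:
    def test_secondary_inhibitor_delays_low_seed(self):
        p = default_params()
        control, inhibited = simulate_seeded_assay(p, 0.01, ("secondary", 0.1))
        assert halftime(inhibited) > 1.2 * halftime(control)

    def test_secondary_inhibitor_spares_high_seed(self):
        p = default_params()
        control, inhibited = simulate_seeded_assay(p, 0.30, ("secondary", 0.1))
        assert halftime(inhibited) == pytest.approx(halftime(control), rel=0.05)

    def test_no_inhibition_identical(self):
        p = default_params()
        control, inhibited = simulate_seeded_assay(p, 0.01, ("secondary", 1.0))
        assert np.allclose(control.signal, inhibited.signal)


class TestTraceIO:
    def test_csv_roundtrip(self, tmp_path):
        p = default_params()
        traces = [
            simulate_trace(
                p, TIMES,
                labels={"monomer_uM": 3.0, "inhibitor_uM": c, "seed_fraction": 0.0},
            )
            for c in (0.0, 1.0)
        ]
        path = tmp_path / "traces.csv"
        save_traces_csv(traces, path)
        loaded = load_traces_csv(path)
        assert len(loaded) == 2
        by_conc = {t.labels["inhibitor_uM"]: t for t in loaded}
        assert np.allclose(by_conc[1.0].signal, traces[1].signal)


class TestMonotonicityProperties:
    @given(scale=st.floats(min_value=1.5, max_value=10.0))
    @settings(max_examples=8, deadline=None)
    def test_faster_elongation_shortens_halftime(self, scale):
        p = default_params()
        t = np.geomspace(1e-3, 300, 800)
        base_t50 = halftime(simulate_trace(p, t))
        from dataclasses import replace

        fast = replace(p, k_plus=p.k_plus * scale)
        assert halftime(simulate_trace(fast, t)) < base_t50

    def test_weaker_inhibition_shortens_halftime(self):
        p = default_params()
        t = np.geomspace(1e-3, 300, 800)
        t50s = []
        for factor in (0.1, 0.4, 0.7, 1.0):
            q = apply_inhibition(p, "secondary", factor)
            t50s.append(halftime(simulate_trace(q, t)))
        assert t50s == sorted(t50s, reverse=True)
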