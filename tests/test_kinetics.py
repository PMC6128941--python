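"""Trace preprocessing and exponential fitting of cleavage kinetics."""

import numpy as np
import pytest

from ribodrop import kinetics, synthetic
from ribodrop.kinetics import (
    GelTimecourse,
    KineticTrace,
    background_subtract,
    fit_biexponential,
    fit_gel_timecourse,
    fit_monoexponential,
    gel_cleaved_fraction,
    normalize_to_endpoint,
    select_model,
)
from ribodrop.presets import NoiseSpec


class TestBackgroundSubtract:
    def test_identical_traces_cancel(self):
        tr = KineticTrace(np.linspace(0, 5, 10), np.linspace(1, 4, 10))
        out = background_subtract(tr, tr)
        np.testing.assert_array_equal(out.intensities, 0.0)

    def test_zero_control_is_identity(self):
        tr = KineticTrace(np.linspace(0, 5, 10), np.linspace(1, 4, 10))
        ctrl = KineticTrace(np.linspace(0, 5, 10), np.zeros(10))
        np.testing.assert_array_equal(
            background_subtract(tr, ctrl).intensities, tr.intensities
        )

    def test_control_interpolated_onto_sample_grid(self):
        sample = KineticTrace(np.array([0.0, 2.0, 4.0]), np.array([5.0, 7.0, 9.0]))
        ctrl = KineticTrace(np.arange(5.0), np.arange(5.0))  # control(t) = t
        out = background_subtract(sample, ctrl)
        np.testing.assert_allclose(out.intensities, [5.0, 5.0, 5.0])

    def test_disjoint_ranges_rejected(self):
        a = KineticTrace(np.array([0.0, 1.0]), np.zeros(2))
        b = KineticTrace(np.array([5.0, 6.0]), np.zeros(2))
        with pytest.raises(ValueError, match="disjoint"):
            background_subtract(a, b)


class TestNormalizeToEndpoint:
    def test_scale_factor_from_gel_fraction(self):
        tr = KineticTrace(np.array([0.0, 5.0, 10.0]), np.array([0.0, 100.0, 200.0]))
        out = normalize_to_endpoint(tr, 0.8, 10.0)
        assert out.intensities[-1] == pytest.approx(0.8)
        np.testing.assert_allclose(
            out.intensities, tr.intensities * 0.004, rtol=1e-12
        )

    def test_already_normalised_trace_unchanged(self):
        tr = KineticTrace(np.array([0.0, 1.0]), np.array([0.2, 1.0]))
        out = normalize_to_endpoint(tr, 1.0, 1.0)
        np.testing.assert_array_equal(out.intensities, tr.intensities)

    def test_zero_trace_cannot_scale(self):
        tr = KineticTrace(np.array([0.0, 1.0]), np.zeros(2))
        with pytest.raises(ValueError, match="zero"):
            normalize_to_endpoint(tr, 0.5, 1.0)

    def test_anchor_outside_range_rejected(self):
        tr = KineticTrace(np.array([0.0, 1.0]), np.array([0.0, 1.0]))
        with pytest.raises(ValueError, match="outside"):
            normalize_to_endpoint(tr, 0.5, 5.0)


def _grid_search_tau(trace, n=2000):
    """Independent brute-force oracle: exhaustive log grid over tau."""
    taus = np.geomspace(1e-3, 1e4, n)
    sse = [
        np.sum((1 - np.exp(-(trace.times - trace.t0) / tau)
                - trace.intensities) ** 2)
        for tau in taus
    ]
    return taus[int(np.argmin(sse))]


class TestMonoFit:
    def test_exact_unit_tau(self):
        t = np.linspace(0, 8, 30)
        fit = fit_monoexponential(KineticTrace(t, 1 - np.exp(-t)))
        assert fit.tau == pytest.approx(1.0, rel=1e-9)

    def test_noisy_fit_matches_grid_search_oracle(self):
        t = np.linspace(0, 10, 50)
        tr = synthetic.generate_fret_trace("mono", t, k0=0.6,
                                           noise=NoiseSpec(0.01, 7))
        fit = fit_monoexponential(tr)
        oracle = _grid_search_tau(tr)
        assert fit.tau == pytest.approx(oracle, rel=5e-3)

    def test_too_few_points_rejected(self):
        with pytest.raises(kinetics.FitError):
            fit_monoexponential(KineticTrace(np.arange(3.0), np.zeros(3)))


class TestBiexpFit:
    def test_rate_ordering_always_holds(self, rng):
        t = np.linspace(0, 200, 80)
        for _ in range(5):
            k1 = 10 ** rng.uniform(-2, 0)
            k2 = k1 * 10 ** rng.uniform(-3, -0.5)
            tr = synthetic.generate_fret_trace(
                "bi", t, k1=k1, k2=k2, A1=rng.uniform(0.2, 0.8),
                noise=NoiseSpec(0.01, int(rng.integers(1 << 30))),
            )
            fit = fit_biexponential(tr)
            assert fit.k1 > fit.k2
            assert 0.0 <= fit.A1 <= 1.0

    def test_unit_amplitude_nests_to_mono(self):
        t = np.linspace(0, 10, 60)
        tr = synthetic.generate_fret_trace("bi", t, k1=0.6, k2=1e-3, A1=1.0)
        bi = fit_biexponential(tr)
        mono = fit_monoexponential(tr)
        # fast phase matches the mono rate; slow phase carries ~no amplitude
        assert bi.A1 * bi.k1 + (1 - bi.A1) * bi.k2 == pytest.approx(
            mono.k0, rel=1e-3
        ) or bi.k1 == pytest.approx(mono.k0, rel=1e-3)

    def test_scale_equivariance_through_normalisation(self):
        t = np.linspace(0, 530, 200)
        tr = synthetic.generate_fret_trace("bi", t, k1=1e-2, k2=1.5e-4, A1=0.5)
        scaled = KineticTrace(t, tr.intensities * 37.5, condition=tr.condition)
        renorm = normalize_to_endpoint(
            scaled, float(tr.intensities[-1]), t[-1]
        )
        a = fit_biexponential(tr)
        b = fit_biexponential(renorm)
        assert b.k1 == pytest.approx(a.k1, rel=1e-9)
        assert b.k2 == pytest.approx(a.k2, rel=1e-9)


class TestModelSelection:
    def test_no_improvement_prefers_mono(self):
        mono = kinetics.MonoFit(1.0, 1.0, 0.5, 20)
        bi = kinetics.BiexpFit(0.5, 2.0, 0.5, 2.0, 0.5, 0.5, 20)
        assert select_model(mono, bi).preferred == "mono"

    def test_mono_generated_data_prefers_mono(self):
        t = np.linspace(0, 10, 100)
        tr = synthetic.generate_fret_trace("mono", t, k0=0.6,
                                           noise=NoiseSpec(0.01, 11))
        sel = select_model(fit_monoexponential(tr), fit_biexponential(tr))
        assert sel.preferred == "mono"

    def test_well_separated_bi_data_prefers_bi(self):
        t = np.linspace(0, 400, 100)
        tr = synthetic.generate_fret_trace("bi", t, k1=0.1, k2=0.001, A1=0.5,
                                           noise=NoiseSpec(0.01, 11))
        sel = select_model(fit_monoexponential(tr), fit_biexponential(tr))
        assert sel.preferred == "bi"

    def test_mismatched_traces_rejected(self):
        mono = kinetics.MonoFit(1.0, 1.0, 0.5, 20)
        bi = kinetics.BiexpFit(0.5, 2.0, 0.5, 2.0, 0.5, 0.1, 30)
        with pytest.raises(ValueError):
            select_model(mono, bi)


class TestGelFit:
    def test_shared_tau_fit_recovers_generator(self, preset):
        gel = synthetic.preset_gel_timecourse()
        fit = fit_gel_timecourse(gel)
        assert fit.k0 == pytest.approx(preset.k0_gel_buffer, rel=1e-6)
        assert fit.fret_effect == pytest.approx(preset.fret_effect, rel=1e-6)

    def test_shared_tau_cannot_beat_independent_fits(self):
        t = np.linspace(0, 20, 30)
        a = synthetic.generate_gel_timecourse(2.0, 0.1, 1.0, 1.0, t)
        b = synthetic.generate_gel_timecourse(8.0, 0.1, 1.0, 1.0, t)
        mixed = GelTimecourse(t, a.I_cleaved, b.I_uncleaved)
        shared = fit_gel_timecourse(mixed)
        only_cl = fit_gel_timecourse(GelTimecourse(t, a.I_cleaved, a.I_uncleaved))
        only_un = fit_gel_timecourse(GelTimecourse(t, b.I_cleaved, b.I_uncleaved))
        assert shared.sse > only_cl.sse + only_un.sse


class TestGelCleavedFraction:
    @pytest.mark.parametrize("cl,un,expected", [
        (10.0, 0.0, 1.0),
        (0.0, 10.0, 0.0),
        (50.0, 50.0, 0.3717),
    ])
    def test_known_values(self, cl, un, expected):
        assert gel_cleaved_fraction(cl, un, 1.69) == pytest.approx(
            expected, abs=1e-4
        )

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            gel_cleaved_fraction(0.0, 0.0, 1.69)
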