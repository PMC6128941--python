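"""Generators reproduce their closed-form models and are seed-reproducible."""

import numpy as np
import pytest

from ribodrop import synthetic
from ribodrop.presets import CMDEX_PLYS, NoiseSpec, ParameterPreset


class TestFretTrace:
    def test_mono_half_rise_at_ln2_over_k(self):
        tr = synthetic.generate_fret_trace(
            "mono", np.array([0.0, 1.1552, 10.0]), k0=0.6
        )
        assert tr.intensities[1] == pytest.approx(0.5, abs=1e-4)

    def test_mono_zero_at_dead_time(self):
        tr = synthetic.generate_fret_trace(
            "mono", np.array([0.5, 1.0, 2.0]), k0=3.7, t0=0.5
        )
        assert tr.intensities[0] == 0.0

    def test_bi_with_unit_amplitude_degenerates_to_mono(self):
        t = np.linspace(0, 20, 40)
        bi = synthetic.generate_fret_trace("bi", t, k1=0.6, k2=0.001, A1=1.0)
        mono = synthetic.generate_fret_trace("mono", t, k0=0.6)
        np.testing.assert_allclose(bi.intensities, mono.intensities, rtol=1e-15)

    def test_plateau_approaches_one(self):
        tr = synthetic.generate_fret_trace("mono", np.array([0.0, 1e4]), k0=0.6)
        assert tr.intensities[-1] == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("kwargs", [
        dict(model="mono", k0=-0.5),
        dict(model="mono", k0=None),
        dict(model="bi", k1=0.1, k2=-1.0, A1=0.5),
        dict(model="bi", k1=0.1, k2=0.01, A1=1.5),
        dict(model="other", k0=1.0),
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            synthetic.generate_fret_trace(times=np.linspace(0, 5, 10), **kwargs)

    def test_non_increasing_time_grid_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            synthetic.generate_fret_trace(
                "mono", np.array([0.0, 2.0, 1.0]), k0=0.5
            )


class TestGelTimecourse:
    def test_endpoints_match_model_asymptotes(self):
        gel = synthetic.generate_gel_timecourse(
            tau=2.0, C=0.3, Imax_cleaved=1.5, Imax_uncleaved=2.0,
            times=np.array([0.0, 1.0, 1e5]),
        )
        assert gel.I_cleaved[0] == pytest.approx(0.3)        # C at t=0
        assert gel.I_uncleaved[0] == pytest.approx(2.0)      # Imax at t=0
        assert gel.I_cleaved[-1] == pytest.approx(1.8)       # Imax + C
        assert gel.I_uncleaved[-1] == pytest.approx(0.3)     # C
    def test_preset_plateau_ratio_is_fret_effect(self, preset):
        gel = synthetic.preset_gel_timecourse(times=np.array([0.0, 1e6]))
        span_cl = gel.I_cleaved[-1] - gel.I_cleaved[0]
        span_un = gel.I_uncleaved[0] - gel.I_uncleaved[-1]
        assert span_cl / span_un == pytest.approx(preset.fret_effect, rel=1e-9)

    def test_nonpositive_tau_rejected(self):
        with pytest.raises(ValueError, match="tau"):
            synthetic.generate_gel_timecourse(
                tau=0.0, C=0.1, Imax_cleaved=1.0, Imax_uncleaved=1.0,
                times=np.linspace(0, 5, 10),
            )


class TestFrapTrace:
    def test_full_bleach_is_zero_at_bleach_time(self):
        tr = synthetic.generate_frap_trace(
            "whole_droplet", np.array([-1.0, 0.0, 50.0]), A=1.0, tau=22.0
        )
        assert tr.intensities[0] == 1.0
        assert tr.intensities[1] == 0.0

    def test_tau_derived_from_diffusion(self):
        tr = synthetic.generate_frap_trace(
            "spot", np.array([-1.0, 0.0, 1.270, 100.0]), A=1.0, D=1.0, r=2.0
        )
        # value at t = tau should be 1 - 1/e for the derived tau = 1.270 s
        assert tr.intensities[2] == pytest.approx(1 - np.exp(-1), abs=1e-3)
        assert tr.intensities[-1] == pytest.approx(1.0, abs=1e-12)

    def test_exactly_one_timescale_source_required(self):
        t = np.linspace(-1, 10, 20)
        with pytest.raises(ValueError, match="exactly one"):
            synthetic.generate_frap_trace("spot", t, tau=1.0, D=1.0, r=2.0)
        with pytest.raises(ValueError, match="exactly one"):
            synthetic.generate_frap_trace("spot", t, r=2.0)

    def test_bleach_time_must_lie_on_grid(self):
        with pytest.raises(ValueError, match="bleach"):
            synthetic.generate_frap_trace(
                "whole_droplet", np.linspace(0, 10, 20), tau=5.0, t_bleach=-3.0
            )


class TestPartitionMeasurement:
    def test_coacervate_fraction_from_K(self):
        m = synthetic.generate_partition_measurement(
            K=9600, c_ini=0.5, V_coac=3.0, V_ini=150.0
        )
        F = m.I_coac / (m.I_coac + m.I_sup)
        assert F == pytest.approx(0.99492, abs=1e-5)

    def test_K_of_one_gives_volume_fraction(self):
        m = synthetic.generate_partition_measurement(
            K=1.0, c_ini=0.5, V_coac=3.0, V_ini=150.0
        )
        F = m.I_coac / (m.I_coac + m.I_sup)
        assert F == pytest.approx(3.0 / 150.0, rel=1e-12)

    def test_volume_ordering_enforced(self):
        with pytest.raises(ValueError, match="V_coac"):
            synthetic.generate_partition_measurement(
                K=10, c_ini=0.5, V_coac=150.0, V_ini=150.0
            )


class TestReproducibility:
    def test_seeded_generation_is_bit_identical(self):
        t = np.linspace(0, 10, 50)
        a = synthetic.generate_fret_trace("mono", t, k0=0.6,
                                          noise=NoiseSpec(0.05, 42))
        b = synthetic.generate_fret_trace("mono", t, k0=0.6,
                                          noise=NoiseSpec(0.05, 42))
        c = synthetic.generate_fret_trace("mono", t, k0=0.6,
                                          noise=NoiseSpec(0.05, 43))
        np.testing.assert_array_equal(a.intensities, b.intensities)
        assert not np.array_equal(a.intensities, c.intensities)

    def test_sigma_zero_reproduces_model_exactly(self):
        t = np.linspace(0, 10, 50)
        tr = synthetic.generate_fret_trace("mono", t, k0=0.6)
        np.testing.assert_array_equal(
            tr.intensities, 1.0 - np.exp(-0.6 * t)
        )


class TestPreset:
    def test_serialisation_round_trip(self, preset, tmp_path):
        path = tmp_path / "preset.cfg"
        preset.to_file(path)
        assert ParameterPreset.from_file(path) == preset

    def test_invariant_violations_rejected(self):
        with pytest.raises(ValueError):
            ParameterPreset(name="bad", k0_buffer=-1.0)
        with pytest.raises(ValueError):
            ParameterPreset(name="bad", A1_bulk=1.5)
        with pytest.raises(ValueError):
            ParameterPreset(name="bad", k1_bulk=1e-4, k2_bulk=1e-2)
        with pytest.raises(ValueError):
            ParameterPreset(name="bad", K_ribozyme=0.5)
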