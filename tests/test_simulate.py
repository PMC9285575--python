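"""Offset schemes and forward Z-spectrum simulation properties."""

import math

import numpy as np
import pytest

import glucocest as gc
from glucocest.simulate import ensure_s0


class TestMakeOffsetList:
    def test_invivo_scheme_has_61_offsets(self):
        offs = gc.make_offset_list(0.2, 6.0)
        assert len(offs) == 61
        assert offs[0] == pytest.approx(6.0) and offs[-1] == pytest.approx(-6.0)

    def test_invitro_scheme_has_201_offsets(self):
        assert len(gc.make_offset_list(0.1, 10.0)) == 201

    def test_symmetry_and_step(self):
        offs = gc.make_offset_list(0.5, 3.0, descending=False)
        assert np.allclose(offs, -offs[::-1])
        assert np.allclose(np.diff(offs), 0.5)

    def test_degenerate_range(self):
        with pytest.raises(ValueError, match="single offset"):
            gc.make_offset_list(1.0, 0.0)
        assert list(gc.make_offset_list(1.0, 0.0, allow_degenerate=True)) == [0.0]

    def test_non_commensurate_raises_naming_both(self):
        with pytest.raises(ValueError, match="6.1.*0.2|0.2.*6.1"):
            gc.make_offset_list(0.2, 6.1)

    def test_ensure_s0_appends_extra_frame(self):
        offs = ensure_s0(gc.make_offset_list(0.2, 6.0), -10.0)
        assert len(offs) == 62 and offs[-1] == -10.0
        # already present: unchanged
        offs2 = ensure_s0(gc.make_offset_list(0.1, 10.0), -10.0)
        assert len(offs2) == 201


class TestSimulateZSpectrum:
    def test_no_agent_gives_symmetric_spectrum(self, invitro_acq, sat3, water7):
        z = gc.simulate_zspectrum(gc.glucose(), 0.0, 7.0, water7, sat3, invitro_acq)
        assert abs(z.asymmetry(1.2)) <= 1e-10
        assert abs(z.asymmetry(0.8)) <= 1e-10

    def test_zero_b1_gives_unit_z(self, invitro_acq, water7):
        sat = gc.SaturationScheme(0.0, 5.0)
        z = gc.simulate_zspectrum(gc.glucose(), 20.0, 6.2, water7, sat, invitro_acq)
        assert np.allclose(z.signals, 1.0, atol=1e-9)

    def test_z_in_unit_interval_and_recovers_off_resonance(self, glucose_spectrum):
        z = glucose_spectrum
        assert np.all(z.signals >= 0.0) and np.all(z.signals <= 1.0)
        assert z.signal_at(-10.0) == pytest.approx(1.0, abs=1e-9)

    def test_concentration_monotonicity(self, invitro_acq, sat3, water7):
        sts = [
            gc.simulate_zspectrum(gc.glucose(), c, 6.2, water7, sat3, invitro_acq).asymmetry(1.2)
            for c in (0.0, 10.0, 20.0, 50.0)
        ]
        assert np.all(np.diff(sts) > 0)

    def test_expm_and_ode_paths_agree_end_to_end(self, sat3, water7):
        acq = gc.AcquisitionConfig(B0=7.0, offsets=tuple(gc.make_offset_list(1.0, 5.0)))
        za = gc.simulate_zspectrum(gc.glucose(), 20.0, 6.2, water7, sat3, acq, solver="expm")
        zb = gc.simulate_zspectrum(gc.glucose(), 20.0, 6.2, water7, sat3, acq, solver="ode")
        assert np.max(np.abs(za.signals - zb.signals)) < 1e-6


@pytest.fixture(scope="module")
def st_by_condition():
    """ST at 1.2 ppm for both agents across pH, fields and B1 = 2, 3 uT."""
    offs = (1.2, -1.2)  # s0 appended automatically at -10
    out = {}
    for b0 in (3.0, 7.0):
        water = gc.water_preset(b0, "solution")
        acq = gc.AcquisitionConfig(B0=b0, offsets=(1.2, -1.2, -10.0))
        for agent in (gc.glucose(), gc.omg3()):
            for b1 in (2.0, 3.0):
                sat = gc.SaturationScheme(b1, 5.0)
                for ph in (6.0, 6.2, 6.4, 6.6, 6.8, 7.0, 7.4):
                    z = gc.simulate_zspectrum(agent, 20.0, ph, water, sat, acq)
                    out[(b0, agent.name, b1, ph)] = z.signals[1] - z.signals[0]
    return out


class TestOrdinalContrastPatterns:
    """The pH/B1/B0 response structure of the two agents."""

    def test_glucose_prefers_acidic_ph(self, st_by_condition):
        for ph in (6.0, 6.2, 6.4):
            assert st_by_condition[(7.0, "glucose", 3.0, ph)] > st_by_condition[(7.0, "glucose", 3.0, 7.4)]

    def test_3omg_peaks_near_neutral_ph(self, st_by_condition):
        curve = {ph: st_by_condition[(7.0, "3OMG", 3.0, ph)] for ph in (6.0, 6.2, 6.4, 6.6, 6.8, 7.0, 7.4)}
        assert max(curve, key=curve.get) == 7.0

    def test_glucose_peak_ph_below_3omg_peak_ph(self, st_by_condition):
        phs = (6.0, 6.2, 6.4, 6.6, 6.8, 7.0, 7.4)
        glc = max(phs, key=lambda p: st_by_condition[(7.0, "glucose", 3.0, p)])
        omg = max(phs, key=lambda p: st_by_condition[(7.0, "3OMG", 3.0, p)])
        assert glc < omg

    @pytest.mark.parametrize("agent", ["glucose", "3OMG"])
    def test_higher_field_gives_higher_st(self, st_by_condition, agent):
        for ph in (6.0, 6.2, 6.4, 6.6, 6.8, 7.0, 7.4):
            assert st_by_condition[(7.0, agent, 2.0, ph)] >= st_by_condition[(3.0, agent, 2.0, ph)]
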