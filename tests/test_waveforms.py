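"""Waveform construction, dephasing, encoding spectra and B-matrices."""

import math
from dataclasses import replace

import numpy as np
import pytest
from scipy.integrate import trapezoid

from epogse.units import GAMMA, b_si_to_ms_um2, b_ms_um2_to_si
from epogse.waveforms import (
    EPOGSEParams,
    attenuation_from_spectrum,
    b_matrix_ideal,
    b_matrix_numeric,
    build_ideal_epogse,
    build_spin_echo_sequence,
    calibrate_amplitude,
    commensurate_dt,
    dephasing_trace,
    encoding_spectrum,
)


@pytest.fixture(scope="module")
def p100():
    return EPOGSEParams.from_frequency_hz(100.0, G_max=0.1, chi_deg=30.0)


class TestParams:
    def test_rejects_bad_chi(self):
        with pytest.raises(ValueError, match="chi"):
            EPOGSEParams.from_frequency_hz(100.0, chi_deg=91.0)

    def test_rejects_undersampled_dt(self):
        w = 2 * math.pi * 100
        with pytest.raises(ValueError, match="undersample"):
            EPOGSEParams(G_max=0.1, omega_m=w, chi_deg=0, T_train=0.02, dt=2.5e-4)

    def test_rejects_fractional_half_periods(self):
        w = 2 * math.pi * 100
        with pytest.raises(ValueError, match="half-period"):
            EPOGSEParams(G_max=0.1, omega_m=w, chi_deg=0, T_train=0.0213, dt=5e-5)

    def test_commensurate_dt_divides_quarter_period(self):
        for nu in (50.0, 200.0, 300.0):
            w = 2 * math.pi * nu
            dt = commensurate_dt(w, 1.6e-6)
            assert dt <= 1.6e-6 * (1 + 1e-9)
            q = (math.pi / (2 * w)) / dt
            assert abs(q - round(q)) < 1e-6


class TestIdealTrain:
    def test_chi0_is_linear_x_polarisation(self, p100):
        w = build_ideal_epogse(replace(p100, chi_deg=0.0))
        assert np.all(w.g[:, 1] == 0.0)
        assert np.all(w.g[:, 2] == 0.0)
        assert np.abs(w.g[:, 0]).max() == pytest.approx(0.1)

    def test_chi45_circular_constant_magnitude(self, p100):
        p = replace(p100, chi_deg=45.0)
        w = build_ideal_epogse(p)
        overlap = (w.times > 1.01 * p.quarter_period) & (w.times < 0.99 * p.T_train)
        mag = np.linalg.norm(w.g[overlap], axis=1)
        assert mag == pytest.approx(0.1 / math.sqrt(2), rel=1e-9)

    def test_chi30_amplitude_ratio_is_cot(self, p100):
        w = build_ideal_epogse(p100)
        ratio = np.abs(w.g[:, 0]).max() / np.abs(w.g[:, 1]).max()
        assert ratio == pytest.approx(1.0 / math.tan(math.radians(30.0)), rel=1e-9)


class TestDephasing:
    @pytest.mark.parametrize("chi", [0.0, 30.0, 45.0, 90.0])
    @pytest.mark.parametrize("nu", [50.0, 100.0])
    def test_spin_echo_refocuses(self, chi, nu):
        p = EPOGSEParams.from_frequency_hz(nu, G_max=0.08, chi_deg=chi)
        tr = dephasing_trace(build_spin_echo_sequence(p))
        assert np.all(np.abs(tr.F[-1]) < 1e-6 * np.abs(tr.F).max())
        assert np.all(tr.F[0] == 0.0)

    def test_zero_waveform_gives_zero_trace(self, p100):
        w = build_ideal_epogse(replace(p100, G_max=0.0))
        assert np.all(dephasing_trace(w).F == 0.0)

    def test_cosine_peak_dephasing_is_gamma_g_over_omega(self, p100):
        p = replace(p100, chi_deg=0.0)
        tr = dephasing_trace(build_ideal_epogse(p))
        peak = np.abs(tr.F[:, 0]).max()
        assert peak == pytest.approx(GAMMA * p.G_max / p.omega_m, rel=1e-3)


class TestEncodingSpectrum:
    def test_chi0_has_no_yy_weight(self, p100):
        tr = dephasing_trace(build_spin_echo_sequence(replace(p100, chi_deg=0.0)))
        spec = encoding_spectrum(tr)
        assert np.abs(spec.filter[:, 1, 1]).max() < 1e-12 * np.abs(spec.filter[:, 0, 0]).max()

    def test_chi45_diagonals_equal_and_peak_at_omega_m(self, p100):
        """At χ = 45° the two diagonal filter elements carry the same
        envelope peaked at ±ω_m and integrate to the same weight.  The two
        spin-echo trains interfere with opposite parity on the two channels
        (the 180° pulse inverts only the x dephasing), so the fine fringes
        interleave; equality holds for the fringe-averaged envelope."""
        p = replace(p100, chi_deg=45.0)
        tr = dephasing_trace(build_spin_echo_sequence(p))
        spec = encoding_spectrum(tr)
        xx = spec.filter[:, 0, 0].real
        yy = spec.filter[:, 1, 1].real
        # equal total weight (equal b on both axes) — exact
        assert trapezoid(xx, spec.omega_grid) == pytest.approx(
            trapezoid(yy, spec.omega_grid), rel=1e-9
        )
        # both channels filter the same narrow band around ω_m: the peak of
        # each diagonal sits at ±ω_m and the weight fraction in the
        # half-octave band around ω_m matches between the channels.  (The
        # detailed fringe/shoulder profiles differ — the idealised cosine
        # and delayed-sine channels are different windowed carriers.)
        om = spec.omega_grid
        assert abs(om[np.argmax(xx)]) == pytest.approx(p.omega_m, rel=0.15)
        assert abs(om[np.argmax(yy)]) == pytest.approx(p.omega_m, rel=0.15)
        pos_band = (om > 0.5 * p.omega_m) & (om < 1.5 * p.omega_m)
        pos = om > 0
        frac_x = trapezoid(xx[pos_band], om[pos_band]) / trapezoid(xx[pos], om[pos])
        frac_y = trapezoid(yy[pos_band], om[pos_band]) / trapezoid(yy[pos], om[pos])
        assert frac_x > 0.8 and frac_y > 0.8
        assert frac_x == pytest.approx(frac_y, abs=0.1)
        # diagonals are real and non-negative
        assert np.abs(spec.filter[:, 0, 0].imag).max() < 1e-9 * xx.max()
        assert xx.min() > -1e-12 * xx.max()

    def test_offdiagonal_imaginary_part_integrates_to_zero(self, p100):
        spec = encoding_spectrum(dephasing_trace(build_spin_echo_sequence(p100)))
        im = spec.filter[:, 0, 1].imag
        scale = trapezoid(np.abs(im), spec.omega_grid)
        assert abs(trapezoid(im, spec.omega_grid)) < 1e-6 * max(scale, 1e-300)

    def test_narrow_grid_warns(self, p100):
        tr = dephasing_trace(build_spin_echo_sequence(p100))
        with pytest.warns(UserWarning, match="omega_grid"):
            encoding_spectrum(tr, omega_grid=np.linspace(-p100.omega_m, p100.omega_m, 64))

    def test_parseval_beta_matches_bmatrix_trace(self, p100):
        """Frequency-domain attenuation with a flat spectrum equals b·D0."""
        tr = dephasing_trace(build_spin_echo_sequence(p100))
        spec = encoding_spectrum(tr)
        D0 = 2e-9
        beta_f = attenuation_from_spectrum(spec, lambda om: np.full_like(om, D0))
        beta_t = b_matrix_numeric(tr).b_si * D0
        assert beta_f == pytest.approx(beta_t, rel=1e-3)


class TestBMatrix:
    def test_single_axis_cosine_trace_identity(self):
        # >=5 periods: numeric trace approaches gamma^2 G^2 T / (2 w^2)
        nu = 100.0
        p = EPOGSEParams.from_frequency_hz(nu, G_max=0.1, chi_deg=0.0, nominal_T=50e-3)
        assert p.T_train * nu >= 5
        tr = dephasing_trace(build_ideal_epogse(p))
        expected = GAMMA**2 * p.G_max**2 * p.T_train / (2 * p.omega_m**2)
        assert b_matrix_numeric(tr).b_si == pytest.approx(expected, rel=0.01)

    def test_chi45_diagonal_split(self, p100):
        p = replace(p100, chi_deg=45.0)
        B = b_matrix_numeric(dephasing_trace(build_spin_echo_sequence(p))).B
        assert B[0, 0] == pytest.approx(B[1, 1], rel=1e-2)
        assert B[0, 0] == pytest.approx(np.trace(B) / 2, rel=1e-2)

    def test_zero_gradient_zero_matrix(self, p100):
        B = b_matrix_numeric(dephasing_trace(build_spin_echo_sequence(replace(p100, G_max=0.0)))).B
        assert np.all(B == 0.0)

    def test_positive_semidefinite(self, p100):
        B = b_matrix_numeric(dephasing_trace(build_spin_echo_sequence(p100))).B
        assert np.all(np.linalg.eigvalsh(B) >= -1e-9 * np.trace(B))

    def test_opposed_rotations_cancel_off_diagonals(self):
        p = EPOGSEParams.from_frequency_hz(200.0, G_max=0.1, chi_deg=30.0)
        assert p.T_train * 200.0 >= 5  # >=5 oscillations per train
        B = b_matrix_numeric(dephasing_trace(build_spin_echo_sequence(p))).B
        assert abs(B[0, 1]) / np.trace(B) < 1e-3

    def test_same_rotation_off_diagonal_follows_cos_sin_chi(self):
        vals = {}
        for chi in (0.0, 30.0, 60.0):
            p = EPOGSEParams.from_frequency_hz(
                100.0, G_max=0.1, chi_deg=chi, opposed_rotations=False
            )
            B = b_matrix_numeric(dephasing_trace(build_spin_echo_sequence(p))).B
            vals[chi] = B[0, 1] / np.trace(B)
        assert vals[0.0] == pytest.approx(0.0, abs=1e-9)
        # cos(30)sin(30) == cos(60)sin(60): equal off-diagonal weight
        assert vals[30.0] == pytest.approx(vals[60.0], rel=1e-2)
        assert abs(vals[30.0]) > 1e-3

    def test_ideal_off_diagonal_vanishes_as_inverse_frequency(self):
        ratios = []
        for nu in (50.0, 100.0, 200.0):
            p = EPOGSEParams(
                G_max=0.1,
                omega_m=2 * math.pi * nu,
                chi_deg=45.0,
                T_train=0.04,
                dt=commensurate_dt(2 * math.pi * nu, 5e-5),
                opposed_rotations=False,
            )
            B = b_matrix_ideal(p, n_trains=1).B
            ratios.append(abs(B[0, 1]) / np.trace(B))
        assert ratios[0] == pytest.approx(2 * ratios[1], rel=1e-9)
        assert ratios[1] == pytest.approx(2 * ratios[2], rel=1e-9)

    @pytest.mark.parametrize(
        "G_mT_m, b_expected",
        [(80.0, 0.045), (300.0, 0.63)],
        ids=["clinical-80mT", "experimental-300mT"],
    )
    def test_b_value_feasibility_two_40ms_trains_100hz(self, G_mT_m, b_expected):
        """Available b at 100 Hz for state-of-the-art gradient systems."""
        w = 2 * math.pi * 100.0
        p = EPOGSEParams(
            G_max=G_mT_m * 1e-3,
            omega_m=w,
            chi_deg=45.0,
            T_train=0.04,
            dt=commensurate_dt(w, 5e-5),
        )
        assert b_matrix_ideal(p, n_trains=2).b_ms_um2 == pytest.approx(b_expected, rel=0.05)


class TestCalibration:
    def test_quadrupled_b_doubles_g(self, p100):
        g1 = calibrate_amplitude(b_ms_um2_to_si(0.2), p100)
        g2 = calibrate_amplitude(b_ms_um2_to_si(0.8), p100)
        assert g2 == pytest.approx(2 * g1, rel=1e-9)

    def test_round_trip(self, p100):
        G = calibrate_amplitude(b_ms_um2_to_si(0.8), p100)
        tr = dephasing_trace(build_spin_echo_sequence(replace(p100, G_max=G)))
        assert b_si_to_ms_um2(b_matrix_numeric(tr).b_si) == pytest.approx(0.8, rel=1e-6)

    def test_g_scales_linearly_with_frequency_at_fixed_b_and_t(self):
        # b = gamma^2 G^2 T/(2 w^2): same b and T => G ~ w
        Gs = {}
        for nu in (50.0, 100.0):
            w = 2 * math.pi * nu
            p = EPOGSEParams(
                G_max=1.0, omega_m=w, chi_deg=0.0, T_train=0.04, dt=commensurate_dt(w, 4e-5)
            )
            Gs[nu] = calibrate_amplitude(b_ms_um2_to_si(0.4), p)
        assert Gs[100.0] == pytest.approx(2 * Gs[50.0], rel=1e-3)

    def test_rejects_nonpositive_target(self, p100):
        with pytest.raises(ValueError):
            calibrate_amplitude(0.0, p100)


def test_waveform_io_round_trip(tmp_path, p100):
    from epogse.io import read_waveform, write_waveform

    w = build_spin_echo_sequence(p100)
    write_waveform(tmp_path / "w.tsv", w, params={"chi_deg": 30.0})
    back = read_waveform(tmp_path / "w.tsv")
    assert np.allclose(back.g, w.g, atol=1e-12)
    assert back.omega_m == w.omega_m
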