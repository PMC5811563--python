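"""EP-OGSE gradient waveform construction and spectral diffusion encoding.

An elliptically polarised OGSE train drives two orthogonal oscillating
gradients, a cosine on the in-plane x̂ axis scaled by cos χ and a
quarter-period-delayed sine on ŷ scaled by sin χ.  χ = 0° is linear
polarisation along x̂, χ = 45° circular polarisation, χ = 90° linear along ŷ.
Two such trains bracket a refocusing pulse in a spin echo; running the second
train with the opposed rotation sense (χ₂ = −χ₁) cancels the off-diagonal
diffusion-weighting terms that would otherwise couple the two axes.

The dephasing vector F(t) = γ∫g_eff dt′ and its spectrum F(ω) act as a
frequency-selective filter on the temporal diffusion spectrum D(ω): under the
Gaussian phase approximation the attenuation exponent is
β = (1/2π)∫ F(ω)·D(ω)·Fᵀ(−ω) dω, which for a filter concentrated at ±ω_m
collapses to β = Σᵢⱼ Bᵢⱼ(ω_m) Dᵢⱼ(ω_m) with B(ω_m) = ∫F(t)Fᵀ(t) dt.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid, trapezoid

from .units import GAMMA, b_si_to_ms_um2

__all__ = [
    "EPOGSEParams",
    "GradientWaveform",
    "DephasingTrace",
    "EncodingSpectrum",
    "BMatrix",
    "commensurate_dt",
    "build_ideal_epogse",
    "build_spin_echo_sequence",
    "dephasing_trace",
    "encoding_spectrum",
    "attenuation_from_spectrum",
    "b_matrix_numeric",
    "b_matrix_ideal",
    "calibrate_amplitude",
]

#: Minimum number of samples per oscillation period (aliasing guard).
MIN_SAMPLES_PER_PERIOD = 50


@dataclass(frozen=True)
class EPOGSEParams:
    """Parameters of an idealised EP-OGSE encoding.

    Parameters
    ----------
    G_max:
        Peak gradient amplitude (T/m).
    omega_m:
        Angular modulation frequency (rad/s).
    chi_deg:
        Ellipticity angle χ in degrees, 0–90.
    T_train:
        Duration of the oscillating part of one train (s).  Must be an
        integer number of half-periods π/ω_m so each train refocuses itself.
    dt:
        Waveform sampling interval (s); at least 50 samples per period.
    opposed_rotations:
        If True the second spin-echo train is built with χ₂ = −χ₁, which
        eliminates the off-diagonal B-matrix terms.
    plane_axes:
        Two orthonormal lab-frame vectors spanning the encoding plane.
    gap:
        Optional zero-gradient gap (s) around the refocusing pulse; the pulse
        itself is treated as instantaneous.
    """

    G_max: float
    omega_m: float
    chi_deg: float
    T_train: float
    dt: float
    opposed_rotations: bool = True
    plane_axes: tuple[tuple[float, ...], tuple[float, ...]] = (
        (1.0, 0.0, 0.0),
        (0.0, 1.0, 0.0),
    )
    gap: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.chi_deg <= 90.0):
            raise ValueError("chi_deg must lie in [0, 90]")
        if self.omega_m <= 0:
            raise ValueError("omega_m must be positive")
        if self.G_max < 0:
            raise ValueError("G_max must be non-negative")
        if self.T_train <= 0 or self.dt <= 0 or self.gap < 0:
            raise ValueError("durations must be positive")
        period = 2.0 * math.pi / self.omega_m
        if self.dt > period / MIN_SAMPLES_PER_PERIOD:
            raise ValueError(
                f"dt={self.dt:g} s undersamples the oscillation: need "
                f"dt <= period/{MIN_SAMPLES_PER_PERIOD} = {period / MIN_SAMPLES_PER_PERIOD:g} s"
            )
        n_half = self.T_train * self.omega_m / math.pi
        if abs(n_half - round(n_half)) > 1e-6 or round(n_half) < 1:
            raise ValueError(
                "T_train must be a positive integer number of half-periods "
                f"pi/omega_m (got {n_half:g} half-periods)"
            )
        # the quarter period must sit on the sample grid so that channel
        # switch-on/off instants coincide with samples (jump handling below)
        n_quarter = (period / 4.0) / self.dt
        if abs(n_quarter - round(n_quarter)) > 1e-6 * max(1.0, n_quarter):
            raise ValueError(
                "dt must divide the quarter period pi/(2*omega_m) "
                "(see commensurate_dt())"
            )
        ex = np.asarray(self.plane_axes[0], float)
        ey = np.asarray(self.plane_axes[1], float)
        if (
            not np.isclose(np.linalg.norm(ex), 1.0)
            or not np.isclose(np.linalg.norm(ey), 1.0)
            or abs(float(ex @ ey)) > 1e-10
        ):
            raise ValueError("plane_axes must be orthonormal")

    @property
    def chi_rad(self) -> float:
        return math.radians(self.chi_deg)

    @property
    def quarter_period(self) -> float:
        return math.pi / (2.0 * self.omega_m)

    @property
    def train_duration(self) -> float:
        """Full duration of one train, T plus the trailing quarter period."""
        return self.T_train + self.quarter_period

    @classmethod
    def from_frequency_hz(
        cls,
        nu_hz: float,
        *,
        G_max: float = 0.1,
        chi_deg: float = 0.0,
        nominal_T: float = 25e-3,
        dt: float | None = None,
        **kwargs,
    ) -> "EPOGSEParams":
        """Build parameters at an ordinary frequency, snapping the train
        length to the integer number of *full* periods nearest ``nominal_T``
        (the experimental trains were nominally 25 ms).

        Full periods (rather than the minimal half-period refocusing
        requirement) keep the time-average of the y-channel dephasing at
        zero, so the two diagonal filter elements share an identical shape
        scaled by χ; with an odd number of half-periods the ŷ filter leaks
        weight to ω ≈ 0.
        """
        omega = 2.0 * math.pi * nu_hz
        n_per = max(1, round(nominal_T * omega / (2.0 * math.pi)))
        T = n_per * 2.0 * math.pi / omega
        if dt is None:
            dt = (2.0 * math.pi / omega) / 200.0
        return cls(G_max=G_max, omega_m=omega, chi_deg=chi_deg, T_train=T, dt=dt, **kwargs)


@dataclass
class GradientWaveform:
    """Sampled effective gradient train g(t).

    ``g`` holds the *effective* gradient: polarity is inverted after the
    refocusing pulse, so the refocusing condition is simply ∫g dt = 0.
    """

    times: np.ndarray  # (n,), s
    g: np.ndarray  # (n, 3), T/m
    dt: float
    echo_time_index: int  # sample index of the refocusing-pulse midpoint (0 if none)
    omega_m: float

    def scaled(self, factor: float) -> "GradientWaveform":
        return GradientWaveform(self.times, self.g * factor, self.dt, self.echo_time_index, self.omega_m)

    def rotated(self, R: np.ndarray) -> "GradientWaveform":
        """Waveform with gradient vectors rotated into a new frame (g ← g Rᵀ)."""
        return GradientWaveform(self.times, self.g @ np.asarray(R, float).T, self.dt, self.echo_time_index, self.omega_m)


@dataclass
class DephasingTrace:
    """Dephasing vector F(t) = γ∫₀ᵗ g_eff dt′ (rad/m)."""

    times: np.ndarray
    F: np.ndarray  # (n, 3)
    dt: float
    omega_m: float


@dataclass
class EncodingSpectrum:
    """Spectral weighting filter of the diffusion spectrum tensor.

    ``filter[k]`` is the 3×3 matrix F(ω)Fᵀ(−ω) at ``omega_grid[k]``; its real
    non-negative diagonals peak at ±ω_m and sharpen with the number of
    oscillations, and the imaginary off-diagonal parts are odd in ω.
    """

    omega_grid: np.ndarray  # (m,), rad/s, symmetric about 0
    F_omega: np.ndarray  # (m, 3) complex
    filter: np.ndarray  # (m, 3, 3) complex
    omega_m: float


@dataclass
class BMatrix:
    """Frequency-specific 3×3 diffusion weighting matrix (SI s/m²)."""

    B: np.ndarray
    omega_m: float

    @property
    def b_si(self) -> float:
        """b-value (trace) in s/m²."""
        return float(np.trace(self.B))

    @property
    def b_ms_um2(self) -> float:
        """b-value in the reporting unit ms/μm²."""
        return b_si_to_ms_um2(self.b_si)


def commensurate_dt(omega_m: float, dt_nominal: float) -> float:
    """Largest dt ≤ ``dt_nominal`` that divides the quarter period π/(2ω_m).

    Channel switch-on/off instants then fall exactly on sample points, which
    the jump-aware trapezoid treatment below relies on.
    """
    qt = math.pi / (2.0 * omega_m)
    return qt / math.ceil(qt / dt_nominal - 1e-12)


def _train_channels(
    params: EPOGSEParams,
    t: np.ndarray,
    *,
    start_is_global: bool,
    end_is_global: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Unit-amplitude per-channel scalar samples of one train on local grid t.

    x-channel: cos(ω t) on [0, T]; y-channel: sin(ω t) on [π/(2ω), T + π/(2ω)].
    The channels switch on and off at extrema of the oscillation, i.e. the
    sampled waveform has jump discontinuities there.  A jump sample interior
    to the sequence is stored at half value — the correct trapezoid-rule
    representation of a step located exactly on a grid point — while a jump
    coinciding with the global start or end keeps its full value (there is no
    adjacent zero cell to balance).
    """
    w = params.omega_m
    dt = params.dt
    qt = params.quarter_period
    T = params.T_train
    eps = 0.25 * dt

    u = np.where(t <= T + eps, np.cos(w * t), 0.0)
    at_T = np.abs(t - T) < eps
    u[at_T] *= 0.5
    at_0 = np.abs(t) < eps
    if not start_is_global:
        u[at_0] *= 0.5

    v = np.where((t >= qt - eps) & (t <= T + qt + eps), np.sin(w * t), 0.0)
    at_qt = np.abs(t - qt) < eps
    v[at_qt] *= 0.5
    at_end = np.abs(t - (T + qt)) < eps
    if not end_is_global:
        v[at_end] *= 0.5
    return u, v


def _null_moment(g: np.ndarray, dt: float) -> np.ndarray:
    """Subtract the (tiny) residual zeroth gradient moment as a uniform DC
    term — the numerical analogue of the moment trimming every scanner
    sequence applies — so the refocusing condition holds to machine accuracy."""
    residual = trapezoid(g, dx=dt, axis=0)
    duration = dt * (g.shape[0] - 1)
    return g - residual[None, :] / duration


def build_ideal_epogse(params: EPOGSEParams) -> GradientWaveform:
    """Single idealised EP-OGSE train.

    The x̂ component is G cos χ · cos(ω_m t) from t = 0 to T; the ŷ component
    G sin χ · sin(ω_m t) switches on after the initiation quarter period
    π/(2ω_m) and runs a quarter period past T.
    """
    n = int(round(params.train_duration / params.dt)) + 1
    t = np.arange(n) * params.dt
    u, v = _train_channels(params, t, start_is_global=True, end_is_global=True)
    ex = np.asarray(params.plane_axes[0], float)
    ey = np.asarray(params.plane_axes[1], float)
    chi = params.chi_rad
    g = params.G_max * (
        math.cos(chi) * u[:, None] * ex[None, :] + math.sin(chi) * v[:, None] * ey[None, :]
    )
    return GradientWaveform(times=t, g=g, dt=params.dt, echo_time_index=0, omega_m=params.omega_m)


def build_spin_echo_sequence(params: EPOGSEParams, *, null_moment: bool = True) -> GradientWaveform:
    """Two EP-OGSE trains around an (instantaneous) refocusing pulse.

    Returns the *effective* gradient: the second train's polarity is
    inverted, so ∫g_eff dt = 0 is the refocusing condition.  With
    ``opposed_rotations`` the second train is built with χ₂ = −χ₁
    (sin(−χ) = −sin χ flips only the ŷ channel before inversion), which
    cancels the off-diagonal B-matrix terms.  The two trains abut at a shared
    sample (plus an optional zero-gradient gap for the pulse).
    """
    n = int(round(params.train_duration / params.dt)) + 1
    t_local = np.arange(n) * params.dt
    n_gap = int(round(params.gap / params.dt))

    u1, v1 = _train_channels(params, t_local, start_is_global=True, end_is_global=n_gap > 0)
    u2, v2 = _train_channels(params, t_local, start_is_global=n_gap > 0, end_is_global=True)

    chi2 = -params.chi_rad if params.opposed_rotations else params.chi_rad
    ex = np.asarray(params.plane_axes[0], float)
    ey = np.asarray(params.plane_axes[1], float)
    c1, s1 = math.cos(params.chi_rad), math.sin(params.chi_rad)
    c2, s2 = math.cos(chi2), math.sin(chi2)

    g1 = params.G_max * (c1 * u1[:, None] * ex[None, :] + s1 * v1[:, None] * ey[None, :])
    # effective polarity of everything after the 180° pulse is inverted
    g2 = -params.G_max * (c2 * u2[:, None] * ex[None, :] + s2 * v2[:, None] * ey[None, :])

    if n_gap > 0:
        g = np.vstack([g1, np.zeros((n_gap - 1, 3)), g2])
        echo_idx = n + n_gap // 2
    else:
        # trains share the seam sample; contributions add there
        g = np.zeros((2 * n - 1, 3))
        g[:n] += g1
        g[n - 1 :] += g2
        echo_idx = n - 1
    if null_moment:
        g = _null_moment(g, params.dt)
    times = np.arange(g.shape[0]) * params.dt
    return GradientWaveform(times=times, g=g, dt=params.dt, echo_time_index=echo_idx, omega_m=params.omega_m)


def dephasing_trace(w: GradientWaveform) -> DephasingTrace:
    """Cumulative trapezoidal integral F(t) = γ∫g_eff dt′."""
    F = GAMMA * cumulative_trapezoid(w.g, dx=w.dt, axis=0, initial=0.0)
    return DephasingTrace(times=w.times, F=F, dt=w.dt, omega_m=w.omega_m)


def encoding_spectrum(
    trace: DephasingTrace,
    omega_grid: np.ndarray | None = None,
    *,
    pad_factor: int = 8,
) -> EncodingSpectrum:
    """Spectrum F(ω) = ∫F(t)e^{iωt}dt and filter F(ω)Fᵀ(−ω).

    With ``omega_grid=None`` the spectrum is computed by FFT on the
    zero-padded time grid (padding sharpens the sampling of the ω_m peak);
    an explicit grid triggers direct evaluation of the Fourier integral.
    """
    F = trace.F
    n = F.shape[0]
    if omega_grid is None:
        m = pad_factor * n
        F_omega = trace.dt * np.fft.fft(F, n=m, axis=0)
        omega = 2.0 * np.pi * np.fft.fftfreq(m, d=trace.dt)
        order = np.argsort(omega)
        omega = omega[order]
        F_omega = F_omega[order]
    else:
        omega = np.asarray(omega_grid, float)
        if trace.omega_m > 0 and (omega.min() > -3 * trace.omega_m or omega.max() < 3 * trace.omega_m):
            warnings.warn(
                "omega_grid does not cover ±3·omega_m; the encoding peak may be clipped",
                stacklevel=2,
            )
        phase = np.exp(1j * omega[:, None] * trace.times[None, :])
        wts = np.full(n, trace.dt)
        wts[0] = wts[-1] = 0.5 * trace.dt
        F_omega = (phase * wts[None, :]) @ F
    # F(t) is real, so F(-ω) = conj(F(ω)) and the filter is F(ω) F^H(ω)
    filt = F_omega[:, :, None] * np.conj(F_omega)[:, None, :]
    return EncodingSpectrum(omega_grid=omega, F_omega=F_omega, filter=filt, omega_m=trace.omega_m)


def attenuation_from_spectrum(spec: EncodingSpectrum, D_of_omega) -> float:
    """GPA attenuation exponent β = (1/2π)∫ F(ω)·D(ω)·Fᵀ(−ω) dω.

    ``D_of_omega(omega)`` maps an (m,) array of angular frequencies to either
    an (m,) array of isotropic diffusivities or an (m, 3, 3) tensor array
    (SI m²/s).  Returns β (dimensionless).
    """
    D = np.asarray(D_of_omega(spec.omega_grid))
    if D.ndim == 1:
        integrand = D * np.einsum("mii->m", spec.filter).real
    else:
        integrand = np.einsum("mij,mij->m", spec.filter, D.astype(complex)).real
    return float(trapezoid(integrand, spec.omega_grid) / (2.0 * np.pi))


def b_matrix_numeric(trace: DephasingTrace) -> BMatrix:
    """Time-domain diffusion weighting matrix B = ∫F(t)Fᵀ(t) dt."""
    B = trapezoid(trace.F[:, :, None] * trace.F[:, None, :], dx=trace.dt, axis=0)
    return BMatrix(B=B, omega_m=trace.omega_m)


def b_matrix_ideal(params: EPOGSEParams, n_trains: int = 2) -> BMatrix:
    """Closed-form B-matrix of the idealised trajectory.

    Per train of duration T the in-plane block is

        γ²G²T/(2ω_m²) · [[cos²χ, ε], [ε, sin²χ]],  ε = 2π cos χ sin χ/(T ω_m),

    so the b-value (trace) is γ²G²T_total/(2ω_m²) with T_total = n_trains·T.
    With opposed rotations over an even number of trains the off-diagonal
    terms cancel exactly.
    """
    w = params.omega_m
    chi = params.chi_rad
    pref_train = GAMMA**2 * params.G_max**2 * params.T_train / (2.0 * w**2)
    c, s = math.cos(chi), math.sin(chi)
    off = 2.0 * math.pi * c * s / (params.T_train * w)
    if params.opposed_rotations and n_trains % 2 == 0:
        off = 0.0
    B_plane = pref_train * n_trains * np.array([[c * c, off], [off, s * s]])
    ex = np.asarray(params.plane_axes[0], float)
    ey = np.asarray(params.plane_axes[1], float)
    axes = np.stack([ex, ey])  # (2, 3)
    B = axes.T @ B_plane @ axes
    return BMatrix(B=B, omega_m=w)


def calibrate_amplitude(b_target_si: float, params: EPOGSEParams) -> float:
    """Gradient amplitude G realising a target b-value for the full spin-echo
    sequence.  Exact because b ∝ G²: a unit-amplitude B-matrix is computed
    numerically once and rescaled."""
    if b_target_si <= 0:
        raise ValueError("b_target must be positive")
    from dataclasses import replace

    unit = replace(params, G_max=1.0)
    b_unit = b_matrix_numeric(dephasing_trace(build_spin_echo_sequence(unit))).b_si
    return math.sqrt(b_target_si / b_unit)
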