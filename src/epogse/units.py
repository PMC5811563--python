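"""Unit system and physical constants.

Everything internal is SI: seconds, metres, tesla, rad/s.  The diffusion-MRI
literature reports b in ms/μm² and diffusivities in μm²/ms; the helpers below
are the only sanctioned conversion points, so a silent factor-10³ error cannot
creep in through ad-hoc arithmetic.
"""

from __future__ import annotations

#: Proton gyromagnetic ratio (rad s⁻¹ T⁻¹).
GAMMA = 2.675e8

#: 1 ms/μm² expressed in SI s/m².
_B_SI_PER_MS_UM2 = 1e9

#: 1 μm²/ms expressed in SI m²/s.
_D_SI_PER_UM2_MS = 1e-9


def b_si_to_ms_um2(b_si: float) -> float:
    """Convert a b-value from s/m² to ms/μm²."""
    return b_si / _B_SI_PER_MS_UM2


def b_ms_um2_to_si(b: float) -> float:
    """Convert a b-value from ms/μm² to s/m²."""
    return b * _B_SI_PER_MS_UM2


def d_si_to_um2_ms(d_si: float) -> float:
    """Convert a diffusivity from m²/s to μm²/ms."""
    return d_si / _D_SI_PER_UM2_MS


def d_um2_ms_to_si(d: float) -> float:
    """Convert a diffusivity from μm²/ms to m²/s."""
    return d * _D_SI_PER_UM2_MS


def hz_to_rad_s(nu: float) -> float:
    """Convert an ordinary frequency ν (Hz) to angular frequency ω (rad/s)."""
    import math

    return 2.0 * math.pi * nu


def rad_s_to_hz(omega: float) -> float:
    """Convert an angular frequency ω (rad/s) to ordinary frequency ν (Hz)."""
    import math

    return omega / (2.0 * math.pi)
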