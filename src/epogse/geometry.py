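"""Restriction geometries for analytic spectra and Monte Carlo simulation.

All geometries are impermeable and axially symmetric.  The symmetry (long)
axis is the local z-axis; lengths are in micrometres, matching the scale of
the cellular restrictions the method probes (1.5–4.5 μm in the simulations).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class SphereGeometry:
    """Impermeable sphere of radius ``radius_um`` (μm)."""

    radius_um: float

    def __post_init__(self) -> None:
        if self.radius_um <= 0:
            raise ValueError("sphere radius must be positive")


@dataclass(frozen=True)
class EllipsoidGeometry:
    """Impermeable axially symmetric ellipsoid.

    Parameters
    ----------
    semi_axis_long_um:
        Semi-axis ``a`` along the symmetry (z) axis, μm.
    semi_axis_trans_um:
        The two equal transverse semi-axes ``b``, μm.
    orientation:
        Unit vector of the symmetry axis in the lab frame.  Defaults to ẑ,
        which is the convention the simulator uses (waveforms are rotated,
        not the substrate).
    """

    semi_axis_long_um: float
    semi_axis_trans_um: float
    orientation: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        if self.semi_axis_long_um <= 0 or self.semi_axis_trans_um <= 0:
            raise ValueError("semi-axes must be positive")
        n = np.asarray(self.orientation, dtype=float)
        if not np.isclose(np.linalg.norm(n), 1.0, atol=1e-8):
            raise ValueError("orientation must be a unit vector")

    @property
    def min_semi_axis_um(self) -> float:
        return min(self.semi_axis_long_um, self.semi_axis_trans_um)

    @property
    def is_sphere(self) -> bool:
        return np.isclose(self.semi_axis_long_um, self.semi_axis_trans_um)

    @classmethod
    def from_sphere(cls, sphere: SphereGeometry) -> "EllipsoidGeometry":
        return cls(sphere.radius_um, sphere.radius_um)

    def contains(self, points_um: np.ndarray, rtol: float = 1e-12) -> np.ndarray:
        """Boolean mask of points (…, 3) inside or on the surface."""
        p = np.asarray(points_um, dtype=float)
        q = (
            (p[..., 0] / self.semi_axis_trans_um) ** 2
            + (p[..., 1] / self.semi_axis_trans_um) ** 2
            + (p[..., 2] / self.semi_axis_long_um) ** 2
        )
        return q <= 1.0 + rtol
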