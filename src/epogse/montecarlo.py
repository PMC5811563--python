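"""Monte Carlo random walks in impermeable ellipsoids with phase accrual.

Spins perform fixed-length steps ℓ = √(6 D₀ Δt) in uniformly random 3D
directions; a step crossing the boundary is specularly reflected about the
surface normal at the exact ray–ellipsoid intersection (repeatedly if
needed).  The diffusion-encoding phase of walker i under an effective
gradient g(t) is φᵢ = γ ∫ g(t)·xᵢ(t) dt and the signal is the magnitude of
the ensemble average E = |⟨e^{−iφ}⟩|.

Because φ is linear in the trajectory, an EP-OGSE protocol needs only the
two scalar channel moments per walker,

    Aᵢ = ∫ u(t) xᵢ(t) dt,   Cᵢ = ∫ v(t) xᵢ(t) dt,

where u, v are the unit-amplitude x/y channel waveforms of the spin-echo
sequence.  Every (rotation R, ellipticity χ, b-value) signal then follows
from φᵢ = γG [cos χ (R ê₁)·Aᵢ + sin χ (R ê₂)·Cᵢ] without re-running the
walk — one trajectory realisation shared across all measurements, which is
also a large variance reduction for comparisons across the protocol.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import EllipsoidGeometry
from .units import GAMMA, b_si_to_ms_um2, b_ms_um2_to_si
from .waveforms import (
    EPOGSEParams,
    GradientWaveform,
    b_matrix_numeric,
    build_spin_echo_sequence,
    commensurate_dt,
    dephasing_trace,
)

__all__ = [
    "MCConfig",
    "DirectionScheme",
    "make_direction_scheme",
    "init_positions",
    "step_walkers",
    "evolve_positions",
    "run_simulation",
    "run_epogse_substrate",
    "paper_protocol",
    "PAPER_B_VALUES_HIGH",
    "PAPER_B_VALUES_LOW",
    "PAPER_FREQUENCIES_HZ",
    "PAPER_RADII_UM",
]

#: Protocol grids: ellipsoid semi-axes, frequencies and b-values of the
#: simulation study (b in ms/μm², the b = 0 reference is implicit).
PAPER_RADII_UM = (1.5, 2.5, 3.5, 4.5)
PAPER_FREQUENCIES_HZ = (50.0, 100.0, 200.0, 300.0, 400.0)
PAPER_B_VALUES_HIGH = (0.4, 0.8, 1.6, 3.2)
PAPER_B_VALUES_LOW = (0.15, 0.3, 0.45, 0.6)


@dataclass(frozen=True)
class MCConfig:
    """Random-walk configuration.

    D0 is the intrinsic diffusivity (μm²/ms; 2.0 emulates free water at room
    temperature), ``dt_sim`` the time step in seconds.  The fixed step length
    √(6 D₀ Δt) must stay below a tenth of the smallest semi-axis for the
    boundary interaction to be resolved.
    """

    D0_um2_ms: float = 2.0
    dt_sim: float = 1.6e-6
    n_walkers: int = 20_000
    seed: int = 1234
    max_reflections_per_step: int = 8

    @property
    def step_length_um(self) -> float:
        # D0 in μm²/ms, dt in s → μm²: 6·D0·(dt·1e3 ms)
        return math.sqrt(6.0 * self.D0_um2_ms * self.dt_sim * 1e3)

    def validate_geometry(self, geom: EllipsoidGeometry) -> None:
        if self.step_length_um >= geom.min_semi_axis_um / 10.0:
            raise ValueError(
                f"step length {self.step_length_um:.3f} μm violates the "
                f"resolution bound min(semi-axis)/10 = {geom.min_semi_axis_um / 10:.3f} μm; "
                "reduce dt_sim"
            )


@dataclass(frozen=True)
class DirectionScheme:
    """Rotation operators carrying the encoding plane over the sphere.

    ``rotations[k]`` maps waveform-frame vectors to the lab (substrate)
    frame; the sampled substrate-axis orientations in the waveform frame are
    the third rows of the rotation matrices, i.e. ``directions``.
    """

    rotations: np.ndarray  # (m, 3, 3)

    def __post_init__(self) -> None:
        R = self.rotations
        if not np.allclose(np.einsum("kij,klj->kil", R, R), np.eye(3)[None], atol=1e-8):
            raise ValueError("rotations must be orthogonal")
        if not np.allclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise ValueError("rotations must be proper (det = +1)")

    @property
    def directions(self) -> np.ndarray:
        """Sampled orientations of the substrate axis in the waveform frame."""
        return self.rotations[:, 2, :]

    def __len__(self) -> int:
        return self.rotations.shape[0]


def _repulsion_points(n: int, seed: int, n_iter: int = 2000, lr: float = 0.05) -> np.ndarray:
    """n approximately uniform unit vectors by electrostatic repulsion,
    deterministic for a given seed."""
    rng = np.random.default_rng(seed)
    p = rng.standard_normal((n, 3))
    p /= np.linalg.norm(p, axis=1, keepdims=True)
    for _ in range(n_iter):
        diff = p[:, None, :] - p[None, :, :]
        dist = np.linalg.norm(diff, axis=-1)
        np.fill_diagonal(dist, np.inf)
        force = (diff / dist[..., None] ** 3).sum(axis=1)
        # project onto the tangent plane and step
        force -= (force * p).sum(axis=1, keepdims=True) * p
        p = p + lr * force
        p /= np.linalg.norm(p, axis=1, keepdims=True)
    return p


def make_direction_scheme(n: int = 24, seed: int = 20180213) -> DirectionScheme:
    """Deterministic n-point uniform direction scheme.

    Points are spread by electrostatic-repulsion minimisation from a fixed
    seed and each is completed to a proper rotation whose third row is the
    point (Rodrigues rotation taking ẑ to the point, transposed).
    """
    pts = _repulsion_points(n, seed)
    rotations = np.empty((n, 3, 3))
    z = np.array([0.0, 0.0, 1.0])
    for k, u in enumerate(pts):
        c = float(u @ z)
        if c > 1.0 - 1e-12:
            Rz = np.eye(3)
        elif c < -1.0 + 1e-12:
            Rz = np.diag([1.0, -1.0, -1.0])
        else:
            v = np.cross(z, u)
            s = np.linalg.norm(v)
            vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
            Rz = np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)
        rotations[k] = Rz.T  # third row = u
    return DirectionScheme(rotations=rotations)


def init_positions(geom: EllipsoidGeometry, n: int, rng: np.random.Generator) -> np.ndarray:
    """n points (μm) uniform in the ellipsoid volume, by rejection sampling
    from the bounding box (acceptance π/6 ≈ 0.52)."""
    rt, rl = geom.semi_axis_trans_um, geom.semi_axis_long_um
    out = np.empty((n, 3))
    filled = 0
    while filled < n:
        m = int((n - filled) * 2.2) + 16
        cand = rng.uniform(-1.0, 1.0, size=(m, 3)) * np.array([rt, rt, rl])
        ok = cand[(cand[:, 0] / rt) ** 2 + (cand[:, 1] / rt) ** 2 + (cand[:, 2] / rl) ** 2 <= 1.0]
        take = min(len(ok), n - filled)
        out[filled : filled + take] = ok[:take]
        filled += take
    return out


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency
    _HAVE_NUMBA = False

    def njit(*a, **k):
        def deco(f):
            return f

        return deco if not (len(a) == 1 and callable(a[0])) else a[0]


@njit(cache=True, inline="always", fastmath=True)
def _advance(x, y, z, dx, dy, dz, rt, rl, max_refl):
    """One step with specular reflections; rt < 0 means free space.

    Returns the new position and the number of truncation events (0 or 1).
    """
    if rt < 0.0:
        return x + dx, y + dy, z + dz, 0
    px, py, pz = x / rt, y / rt, z / rl
    qx, qy, qz = (x + dx) / rt, (y + dy) / rt, (z + dz) / rl
    for _ in range(max_refl):
        if qx * qx + qy * qy + qz * qz <= 1.0:
            return qx * rt, qy * rt, qz * rl, 0
        dxs, dys, dzs = qx - px, qy - py, qz - pz
        a = dxs * dxs + dys * dys + dzs * dzs
        b = 2.0 * (px * dxs + py * dys + pz * dzs)
        c = px * px + py * py + pz * pz - 1.0
        disc = b * b - 4.0 * a * c
        if disc < 0.0 or a == 0.0:
            break
        s = (-b + math.sqrt(disc)) / (2.0 * a)
        if s < 0.0:
            s = 0.0
        elif s > 1.0:
            s = 1.0
        hx, hy, hz = px + s * dxs, py + s * dys, pz + s * dzs
        # outward normal in real space at the hit point
        nx, ny, nz = hx / rt, hy / rt, hz / rl
        nn = math.sqrt(nx * nx + ny * ny + nz * nz)
        nx, ny, nz = nx / nn, ny / nn, nz / nn
        # remaining real-space segment beyond the wall
        rx = (qx - hx) * rt
        ry = (qy - hy) * rt
        rz = (qz - hz) * rl
        dot = rx * nx + ry * ny + rz * nz
        rx -= 2.0 * dot * nx
        ry -= 2.0 * dot * ny
        rz -= 2.0 * dot * nz
        px, py, pz = hx * (1.0 - 1e-12), hy * (1.0 - 1e-12), hz * (1.0 - 1e-12)
        qx = px + rx / rt
        qy = py + ry / rt
        qz = pz + rz / rl
    # reflection budget exhausted: truncate the sub-step at the wall
    if qx * qx + qy * qy + qz * qz > 1.0:
        return px * rt, py * rt, pz * rl, 1
    return qx * rt, qy * rt, qz * rl, 1


@njit(cache=True, fastmath=True)
def _walk_channel_moments(pos0, rt, rl, step, u, v, dt_ms, max_refl, seed):
    """Per-walker channel moments A = Σ w_t u_t x_t Δt, C = Σ w_t v_t x_t Δt.

    u, v are the scalar channel waveforms sampled on the walk grid
    (n_steps + 1 points); trapezoid weights in time.  Positions in μm,
    Δt in ms → moments in μm·ms.
    """
    np.random.seed(seed)
    n = pos0.shape[0]
    nt = u.shape[0]
    acc = np.zeros((n, 2, 3))
    trunc = 0
    for i in range(n):
        x, y, z = pos0[i, 0], pos0[i, 1], pos0[i, 2]
        a0 = a1 = a2 = c0 = c1 = c2 = 0.0
        # t = 0 sample, half trapezoid weight
        a0 += 0.5 * u[0] * x
        a1 += 0.5 * u[0] * y
        a2 += 0.5 * u[0] * z
        c0 += 0.5 * v[0] * x
        c1 += 0.5 * v[0] * y
        c2 += 0.5 * v[0] * z
        for t in range(1, nt):
            # uniform direction on the sphere: z uniform, azimuth uniform
            cz = 2.0 * np.random.random() - 1.0
            phi = 6.283185307179586 * np.random.random()
            r = math.sqrt(1.0 - cz * cz)
            x, y, z, tr = _advance(
                x, y, z, step * r * math.cos(phi), step * r * math.sin(phi), step * cz, rt, rl, max_refl
            )
            trunc += tr
            w = 0.5 if t == nt - 1 else 1.0
            ut = w * u[t]
            vt = w * v[t]
            a0 += ut * x
            a1 += ut * y
            a2 += ut * z
            c0 += vt * x
            c1 += vt * y
            c2 += vt * z
        acc[i, 0, 0] = a0 * dt_ms
        acc[i, 0, 1] = a1 * dt_ms
        acc[i, 0, 2] = a2 * dt_ms
        acc[i, 1, 0] = c0 * dt_ms
        acc[i, 1, 1] = c1 * dt_ms
        acc[i, 1, 2] = c2 * dt_ms
    return acc, trunc


@njit(cache=True, fastmath=True)
def _walk_phases(pos0, rt, rl, step, g, dt_ms, max_refl, seed):
    """Direct phase accumulation φ[i, w] = Σ w_t g[t, w]·x_i(t) Δt for a
    list of arbitrary 3-axis waveforms g (n_t, n_wave, 3).  Units: the
    caller folds γ and the gradient amplitude into g."""
    np.random.seed(seed)
    n = pos0.shape[0]
    nt = g.shape[0]
    nw = g.shape[1]
    phases = np.zeros((n, nw))
    trunc = 0
    for i in range(n):
        x, y, z = pos0[i, 0], pos0[i, 1], pos0[i, 2]
        for w in range(nw):
            phases[i, w] += 0.5 * (g[0, w, 0] * x + g[0, w, 1] * y + g[0, w, 2] * z)
        for t in range(1, nt):
            cz = 2.0 * np.random.random() - 1.0
            phi = 6.283185307179586 * np.random.random()
            r = math.sqrt(1.0 - cz * cz)
            x, y, z, tr = _advance(
                x, y, z, step * r * math.cos(phi), step * r * math.sin(phi), step * cz, rt, rl, max_refl
            )
            trunc += tr
            wt = 0.5 if t == nt - 1 else 1.0
            for w in range(nw):
                phases[i, w] += wt * (g[t, w, 0] * x + g[t, w, 1] * y + g[t, w, 2] * z)
        for w in range(nw):
            phases[i, w] *= dt_ms
    return phases, trunc


@njit(cache=True, fastmath=True)
def _walk_positions(pos0, rt, rl, step, n_steps, max_refl, seed):
    """Final positions after n_steps (no phase accrual) — diagnostics and
    equilibration tests for the compiled boundary rule."""
    np.random.seed(seed)
    n = pos0.shape[0]
    out = np.empty_like(pos0)
    trunc = 0
    for i in range(n):
        x, y, z = pos0[i, 0], pos0[i, 1], pos0[i, 2]
        for _ in range(n_steps):
            cz = 2.0 * np.random.random() - 1.0
            phi = 6.283185307179586 * np.random.random()
            r = math.sqrt(1.0 - cz * cz)
            x, y, z, tr = _advance(
                x, y, z, step * r * math.cos(phi), step * r * math.sin(phi), step * cz, rt, rl, max_refl
            )
            trunc += tr
        out[i, 0], out[i, 1], out[i, 2] = x, y, z
    return out, trunc


def evolve_positions(
    positions: np.ndarray,
    n_steps: int,
    cfg: MCConfig,
    geom: EllipsoidGeometry | None,
) -> np.ndarray:
    """Advance walkers ``n_steps`` with the compiled stepper (no encoding)."""
    rt, rl = (geom.semi_axis_trans_um, geom.semi_axis_long_um) if geom is not None else (-1.0, -1.0)
    out, _ = _walk_positions(
        np.ascontiguousarray(positions, dtype=np.float64),
        rt,
        rl,
        cfg.step_length_um,
        n_steps,
        cfg.max_reflections_per_step,
        cfg.seed,
    )
    return out


# ---------------------------------------------------------------------------
# reference numpy stepper (cross-validation of the boundary rule)
# ---------------------------------------------------------------------------


def step_walkers(
    positions: np.ndarray,
    cfg: MCConfig,
    geom: EllipsoidGeometry | None,
    rng: np.random.Generator,
) -> np.ndarray:
    """One fixed-length step for all walkers (vectorised numpy reference).

    ``geom=None`` means free space.  Kept independent of the numba kernel so
    the two boundary implementations can cross-validate each other.
    """
    n = positions.shape[0]
    d = rng.standard_normal((n, 3))
    d *= cfg.step_length_um / np.linalg.norm(d, axis=1, keepdims=True)
    if geom is None:
        return positions + d
    rt, rl = geom.semi_axis_trans_um, geom.semi_axis_long_um
    scale = np.array([rt, rt, rl])
    p = positions / scale
    q = (positions + d) / scale
    for _ in range(cfg.max_reflections_per_step):
        out = (q**2).sum(axis=1) > 1.0
        if not out.any():
            break
        ps, qs = p[out], q[out]
        ds = qs - ps
        a = (ds**2).sum(axis=1)
        b = 2.0 * (ps * ds).sum(axis=1)
        c = (ps**2).sum(axis=1) - 1.0
        s = np.clip((-b + np.sqrt(np.maximum(b**2 - 4 * a * c, 0.0))) / (2 * a), 0.0, 1.0)
        h = ps + s[:, None] * ds
        nrm = h * np.array([1 / rt, 1 / rt, 1 / rl])[None, :]
        nrm /= np.linalg.norm(nrm, axis=1, keepdims=True)
        r = (qs - h) * scale[None, :]
        r -= 2.0 * (r * (nrm)).sum(axis=1, keepdims=True) * nrm
        p_new = h * (1.0 - 1e-12)
        q_new = p_new + r / scale[None, :]
        p[out] = p_new
        q[out] = q_new
    still_out = (q**2).sum(axis=1) > 1.0
    q[still_out] = p[still_out]
    return q * scale


# ---------------------------------------------------------------------------
# simulation drivers
# ---------------------------------------------------------------------------


def _signal_from_phases(phases: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """E = |⟨e^{−iφ}⟩| and its standard error over walkers (last axis is the
    walker axis collapsed; phases shape (n_walkers,) or (n_walkers, m))."""
    c = np.cos(phases)
    s = np.sin(phases)
    n = phases.shape[0]
    cm, sm = c.mean(axis=0), s.mean(axis=0)
    E = np.sqrt(cm**2 + sm**2)
    # delta-method SE of |mean|, dominated by the component along the mean
    var = (c.var(axis=0) * cm**2 + s.var(axis=0) * sm**2) / np.maximum(E**2, 1e-30)
    se = np.sqrt(var / n)
    return E, se


def run_simulation(
    geom: EllipsoidGeometry | None,
    waveforms: list[GradientWaveform],
    scheme: DirectionScheme | None,
    cfg: MCConfig,
) -> pd.DataFrame:
    """Signal table E(waveform, direction) for arbitrary effective waveforms.

    All (waveform, rotation) pairs share one trajectory realisation per seed.
    Waveforms must share the simulation time grid (dt = cfg.dt_sim).
    """
    if geom is not None:
        cfg.validate_geometry(geom)
        rt, rl = geom.semi_axis_trans_um, geom.semi_axis_long_um
    else:
        rt = rl = -1.0
    rotations = scheme.rotations if scheme is not None else np.eye(3)[None]
    nt = len(waveforms[0].times)
    for w in waveforms:
        if len(w.times) != nt or not math.isclose(w.dt, cfg.dt_sim, rel_tol=1e-9):
            raise ValueError("waveforms must share the simulation time grid")
    # fold γ, rotation and unit conversions into the per-sample factors:
    # φ = γ ∫ (R g)·x dt ; x in μm (1e-6 m), dt in ms (1e-3 s)
    n_wave = len(waveforms) * len(rotations)
    g = np.empty((nt, n_wave, 3))
    meta = []
    k = 0
    for iw, w in enumerate(waveforms):
        for ir, R in enumerate(rotations):
            g[:, k, :] = w.g @ R.T
            meta.append((iw, ir))
            k += 1
    g *= GAMMA * 1e-6 * 1e-3  # rad per (μm·ms·T/m)
    rng = np.random.default_rng(cfg.seed)
    pos0 = (
        init_positions(geom, cfg.n_walkers, rng)
        if geom is not None
        else np.zeros((cfg.n_walkers, 3))
    )
    dt_ms = cfg.dt_sim * 1e3
    phases, trunc = _walk_phases(
        pos0, rt, rl, cfg.step_length_um, g, dt_ms, cfg.max_reflections_per_step, cfg.seed
    )
    E, se = _signal_from_phases(phases)
    rows = []
    for k, (iw, ir) in enumerate(meta):
        b_si = b_matrix_numeric(dephasing_trace(waveforms[iw])).b_si
        rows.append(
            {
                "waveform_index": iw,
                "direction_index": ir,
                "b_ms_per_um2": b_si_to_ms_um2(b_si),
                "E": E[k],
                "E_se": se[k],
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["truncated_substeps"] = int(trunc)
    df.attrs["seed"] = cfg.seed
    return df


def _channel_waveforms(nu_hz: float, dt_sim: float, nominal_T: float = 25e-3):
    """Unit-amplitude scalar channel waveforms (u, v) of the spin-echo
    EP-OGSE sequence at frequency ν, on a grid commensurate with dt_sim,
    plus their scalar b-value factors b_u, b_v (SI, per unit G²)."""
    omega = 2.0 * math.pi * nu_hz
    dt = commensurate_dt(omega, dt_sim)
    px = EPOGSEParams.from_frequency_hz(nu_hz, G_max=1.0, chi_deg=0.0, nominal_T=nominal_T, dt=dt)
    py = EPOGSEParams.from_frequency_hz(nu_hz, G_max=1.0, chi_deg=90.0, nominal_T=nominal_T, dt=dt)
    wx = build_spin_echo_sequence(px)
    wy = build_spin_echo_sequence(py)
    u = wx.g[:, 0].copy()
    v = wy.g[:, 1].copy()
    b_u = b_matrix_numeric(dephasing_trace(wx)).b_si
    b_v = b_matrix_numeric(dephasing_trace(wy)).b_si
    return u, v, dt, b_u, b_v


def run_epogse_substrate(
    geom: EllipsoidGeometry,
    nu_hz: float,
    b_values_ms_um2,
    chi_degs,
    scheme: DirectionScheme,
    cfg: MCConfig,
    *,
    nominal_T: float = 25e-3,
    symmetrize_channels: bool = True,
) -> pd.DataFrame:
    """EP-OGSE signal table for one substrate and frequency.

    Runs a single random-walk realisation and composes the signal for every
    (direction, χ, b) from the per-walker channel moments; the gradient
    amplitude is calibrated per (χ, b) so that trace(B) matches the target
    b-value exactly.

    With ``symmetrize_channels`` every measurement is the average of the two
    channel-role assignments (cosine carrier on x̂/sine on ŷ, and the
    mirror).  The two carriers have slightly different encoding filters in
    the idealised spin-echo layout; averaging the mirrored waveforms — the
    counterpart of the experiment's averaging over waveforms of the same
    eccentricity — makes the effective filter identical on both axes, which
    otherwise imprints a spurious χ-modulation on isotropic substrates.
    """
    cfg.validate_geometry(geom)
    u, v, dt, b_u, b_v = _channel_waveforms(nu_hz, cfg.dt_sim, nominal_T)
    rng = np.random.default_rng(cfg.seed)
    pos0 = init_positions(geom, cfg.n_walkers, rng)
    acc, trunc = _walk_channel_moments(
        pos0,
        geom.semi_axis_trans_um,
        geom.semi_axis_long_um,
        math.sqrt(6.0 * cfg.D0_um2_ms * dt * 1e3),
        u,
        v,
        dt * 1e3,
        cfg.max_reflections_per_step,
        cfg.seed,
    )
    A = acc[:, 0, :]  # (n, 3), μm·ms
    C = acc[:, 1, :]
    gamma_scaled = GAMMA * 1e-6 * 1e-3  # rad per (T/m · μm · ms)
    # channel-role variants: (cos-carrier moment on x̂, sin-carrier on ŷ)
    variants = [(A, C, b_u, b_v)]
    if symmetrize_channels:
        variants.append((C, A, b_v, b_u))
    rows = []
    for chi in np.atleast_1d(chi_degs):
        cr = math.radians(chi)
        cchi, schi = math.cos(cr), math.sin(cr)
        for b in np.atleast_1d(b_values_ms_um2):
            if b <= 0:
                continue
            for k, R in enumerate(scheme.rotations):
                e1, e2 = R[:, 0], R[:, 1]
                E_acc, var_acc = 0.0, 0.0
                for M1, M2, bu1, bv1 in variants:
                    b_unit = cchi**2 * bu1 + schi**2 * bv1  # b at G = 1 (SI)
                    G = math.sqrt(b_ms_um2_to_si(float(b)) / b_unit)
                    phases = gamma_scaled * G * (cchi * M1 @ e1 + schi * M2 @ e2)
                    E, se = _signal_from_phases(phases[:, None])
                    E_acc += float(E[0]) / len(variants)
                    var_acc += (float(se[0]) / len(variants)) ** 2
                rows.append(
                    {
                        "a_um": geom.semi_axis_long_um,
                        "b_um": geom.semi_axis_trans_um,
                        "freq_hz": nu_hz,
                        "b_ms_per_um2": float(b),
                        "chi_deg": float(chi),
                        "direction_index": k,
                        "E": E_acc,
                        "E_se": math.sqrt(var_acc),
                    }
                )
    df = pd.DataFrame(rows)
    df.attrs.update(
        seed=cfg.seed,
        dt_sim=dt,
        n_walkers=cfg.n_walkers,
        D0_um2_ms=cfg.D0_um2_ms,
        truncated_substeps=int(trunc),
    )
    return df


def paper_protocol(
    radii_long_um=PAPER_RADII_UM,
    radii_trans_um=PAPER_RADII_UM,
    frequencies_hz=PAPER_FREQUENCIES_HZ,
    b_values_ms_um2=PAPER_B_VALUES_HIGH,
    chi_degs=(0.0, 45.0),
    scheme: DirectionScheme | None = None,
    cfg: MCConfig | None = None,
    *,
    step_budget: float = 5e10,
    progress: bool = False,
) -> pd.DataFrame:
    """Full simulation protocol: every (a, b) semi-axis combination × every
    frequency, with χ = 0°/45°, a b-value ladder and a direction scheme.

    The default grids are the full study protocol; pass reduced grids (and a
    scaled-down ``MCConfig``) for desk-scale runs.  A projected step count
    above ``step_budget`` triggers a warning before the run starts.
    """
    scheme = scheme if scheme is not None else make_direction_scheme()
    cfg = cfg if cfg is not None else MCConfig()
    n_subs = len(radii_long_um) * len(radii_trans_um)
    n_steps_est = sum(
        (25e-3 * 2 + 1.0 / (2 * f)) / cfg.dt_sim for f in frequencies_hz
    ) * cfg.n_walkers * n_subs
    if n_steps_est > step_budget:
        warnings.warn(
            f"projected ~{n_steps_est:.2g} walker-steps exceeds the budget {step_budget:.2g}; "
            "consider fewer substrates/frequencies or fewer walkers",
            stacklevel=2,
        )
    tables = []
    for ia, a in enumerate(radii_long_um):
        for ib, b_ax in enumerate(radii_trans_um):
            geom = EllipsoidGeometry(a, b_ax)
            for f in frequencies_hz:
                sub_cfg = MCConfig(
                    D0_um2_ms=cfg.D0_um2_ms,
                    dt_sim=cfg.dt_sim,
                    n_walkers=cfg.n_walkers,
                    # decorrelate substrates/frequencies deterministically
                    seed=cfg.seed + 1009 * ia + 31 * ib + int(f),
                    max_reflections_per_step=cfg.max_reflections_per_step,
                )
                t = run_epogse_substrate(
                    geom, f, b_values_ms_um2, chi_degs, scheme, sub_cfg
                )
                if progress:  # pragma: no cover
                    print(f"substrate a={a} b={b_ax} f={f} done")
                tables.append(t)
    out = pd.concat(tables, ignore_index=True)
    out.attrs.update(seed=cfg.seed, dt_sim=cfg.dt_sim, n_walkers=cfg.n_walkers)
    return out
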