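"""Shared fixtures.

The Monte Carlo fixtures are session-scoped: a single random-walk
realisation per substrate feeds every test that needs it (the simulator
itself shares one trajectory set across directions, χ and b — part of its
design).  Walker budgets are scaled down from the full study so the whole
suite fits a desk-scale run; the affected tolerances say so where they
apply.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from epogse.geometry import EllipsoidGeometry
from epogse.montecarlo import MCConfig, make_direction_scheme, run_epogse_substrate

SUITE_SEED = 20250918


@pytest.fixture(scope="session")
def scheme():
    return make_direction_scheme()


@pytest.fixture(scope="session")
def sphere_linearity_table(scheme) -> pd.DataFrame:
    """Spheres of radii 1.5 and 4.5 μm at 50 Hz, b up to 3.2 ms/μm²,
    χ = 0°/45° — the Gaussian-phase-approximation linearity check."""
    tables = []
    for radius, dt_sim in ((1.5, 1.6e-6), (4.5, 3.2e-6)):
        cfg = MCConfig(dt_sim=dt_sim, n_walkers=30_000, seed=SUITE_SEED + int(radius * 10))
        tables.append(
            run_epogse_substrate(
                EllipsoidGeometry(radius, radius),
                50.0,
                [0.4, 0.8, 1.6, 3.2],
                [0.0, 45.0],
                scheme,
                cfg,
            )
        )
    out = pd.concat(tables, ignore_index=True)
    # pandas drops attrs on concat; keep the conservation diagnostic
    out.attrs["truncated_substeps"] = sum(t.attrs["truncated_substeps"] for t in tables)
    return out


#: Substrates of the scaled-down tensor-recovery run: two spheres and the
#: two most eccentric (3:1) shapes, prolate and oblate.
RECOVERY_SUBSTRATES = ((1.5, 1.5), (4.5, 4.5), (4.5, 1.5), (1.5, 4.5))
RECOVERY_FREQS_HZ = (200.0, 400.0)


@pytest.fixture(scope="session")
def recovery_tables(scheme) -> dict[tuple[float, float, float], pd.DataFrame]:
    """Signal tables per (a, b, frequency) for the EP-OGSE vs DTI
    equivalence check; frequencies with ≥5 oscillations per train so the
    encoding filter is narrow."""
    out = {}
    for i, (a, b_ax) in enumerate(RECOVERY_SUBSTRATES):
        geom = EllipsoidGeometry(a, b_ax)
        dt_sim = 1.6e-6 if geom.min_semi_axis_um < 2.0 else 3.2e-6
        for f in RECOVERY_FREQS_HZ:
            cfg = MCConfig(dt_sim=dt_sim, n_walkers=20_000, seed=SUITE_SEED + 97 * i + int(f))
            out[(a, b_ax, f)] = run_epogse_substrate(
                geom, f, [0.4, 0.8, 1.6], [0.0, 45.0], scheme, cfg
            )
    return out


@pytest.fixture(scope="session")
def free_diffusion_signal():
    """−ln E / b for free walkers under a 200 Hz spin-echo waveform."""
    import math

    from epogse.montecarlo import run_simulation
    from epogse.waveforms import (
        EPOGSEParams,
        build_spin_echo_sequence,
        calibrate_amplitude,
        commensurate_dt,
    )
    from epogse.units import b_ms_um2_to_si
    from dataclasses import replace

    nu = 200.0
    dt = commensurate_dt(2 * math.pi * nu, 1.6e-6)
    params = EPOGSEParams.from_frequency_hz(nu, G_max=1.0, chi_deg=0.0, nominal_T=10e-3, dt=dt)
    G = calibrate_amplitude(b_ms_um2_to_si(0.8), params)
    w = build_spin_echo_sequence(replace(params, G_max=G))
    cfg = MCConfig(dt_sim=dt, n_walkers=10_000, seed=SUITE_SEED)
    table = run_simulation(None, [w], None, cfg)
    return table
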