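"""Synthetic reference datasets.

``TABLE1_TENSORS`` holds the fitted ex-vivo (D_L, D_T) pairs (μm²/ms) for
gray and white matter at 50 and 100 Hz that serve as worked-example inputs
throughout the package.  ``make_fixtures`` generates, deterministically from
a seed: noiseless powder surfaces over the experimental (b, χ) design, SNR-25
noisy replicates, and a miniature Monte Carlo dataset for quick validation.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import EllipsoidGeometry
from .io import write_manifest, write_signal_table
from .montecarlo import MCConfig, make_direction_scheme, run_epogse_substrate
from .powder import CompartmentTensor, powder_signal

#: Fitted ex-vivo compartment tensors (D_L, D_T) in μm²/ms, by tissue and
#: modulation frequency (Hz) — worked-example inputs.
TABLE1_TENSORS: dict[str, dict[int, tuple[float, float]]] = {
    "gray_matter": {50: (0.73, 0.28), 100: (0.83, 0.28)},
    "white_matter": {50: (0.81, 0.16), 100: (0.89, 0.19)},
}

#: The experimental χ design: 19 steps from 0° to 90° at b = 0.8 ms/μm².
EXPERIMENT_CHI_GRID_DEG = np.linspace(0.0, 90.0, 19)
EXPERIMENT_B_MS_UM2 = 0.8


def powder_surface_table(chi_grid=EXPERIMENT_CHI_GRID_DEG, b=EXPERIMENT_B_MS_UM2) -> pd.DataFrame:
    """Noiseless powder signals over the experimental χ sweep for each
    reference tensor."""
    rows = []
    for tissue, by_freq in TABLE1_TENSORS.items():
        for freq, (dl, dt) in by_freq.items():
            ct = CompartmentTensor(dl, dt)
            for chi in chi_grid:
                rows.append(
                    {
                        "tissue": tissue,
                        "freq_hz": float(freq),
                        "b_ms_per_um2": float(b),
                        "chi_deg": float(chi),
                        "E": float(powder_signal(ct, b, float(chi))),
                    }
                )
    return pd.DataFrame(rows)


def noisy_replicates(clean: pd.DataFrame, snr: float, n_rep: int, seed: int) -> pd.DataFrame:
    """Gaussian noise of SD 1/SNR on each point, ``n_rep`` replicates."""
    rng = np.random.default_rng(seed)
    reps = []
    for r in range(n_rep):
        t = clean.copy()
        t["replicate"] = r
        t["E"] = t["E"].to_numpy() + rng.normal(0.0, 1.0 / snr, size=len(t))
        reps.append(t)
    return pd.concat(reps, ignore_index=True)


def synthetic_direction_table(
    ct: CompartmentTensor,
    scheme,
    b_values,
    chi_degs,
    *,
    freq_hz: float = 0.0,
) -> pd.DataFrame:
    """Noiseless per-direction signals of a single compartment under the
    direction scheme — the clean analogue of a simulated signal table.

    The compartment axis is ẑ in the lab frame; direction k samples the
    orientation ``scheme.directions[k]`` in the waveform frame.
    """
    from .powder import compartment_attenuation

    rows = []
    for chi in np.atleast_1d(chi_degs):
        for b in np.atleast_1d(b_values):
            for k, n_wf in enumerate(scheme.directions):
                beta = compartment_attenuation(ct, n_wf, float(b), float(chi))
                rows.append(
                    {
                        "freq_hz": freq_hz,
                        "b_ms_per_um2": float(b),
                        "chi_deg": float(chi),
                        "direction_index": k,
                        "E": float(np.exp(-beta)),
                    }
                )
    return pd.DataFrame(rows)


def make_fixtures(seed: int, outdir: str | Path, *, mc_walkers: int = 2000) -> dict[str, Path]:
    """Write the fixture set; bit-identical for a given seed.

    Contents: ``powder_surfaces.tsv`` (noiseless χ sweeps),
    ``powder_noisy_snr25.tsv`` (6 replicates at SNR 25, as in the
    experiment's repetition count), and ``mc_mini.tsv`` (one sphere and one
    eccentric ellipsoid at 100/200 Hz, small walker budget).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    clean = powder_surface_table()
    paths["powder_surfaces"] = outdir / "powder_surfaces.tsv"
    clean.to_csv(paths["powder_surfaces"], sep="\t", index=False, float_format="%.10g")

    noisy = noisy_replicates(clean, snr=25.0, n_rep=6, seed=seed)
    paths["powder_noisy"] = outdir / "powder_noisy_snr25.tsv"
    noisy.to_csv(paths["powder_noisy"], sep="\t", index=False, float_format="%.10g")

    scheme = make_direction_scheme()
    cfg = MCConfig(n_walkers=mc_walkers, dt_sim=1.6e-6, seed=seed)
    tables = []
    for geom in (EllipsoidGeometry(2.5, 2.5), EllipsoidGeometry(4.5, 1.5)):
        for freq in (100.0, 200.0):
            tables.append(
                run_epogse_substrate(geom, freq, [0.4, 0.8, 1.6], [0.0, 45.0], scheme, cfg)
            )
    mc = pd.concat(tables, ignore_index=True)
    mc.attrs.update(seed=seed, n_walkers=mc_walkers, dt_sim=cfg.dt_sim)
    paths["mc_mini"] = outdir / "mc_mini.tsv"
    write_signal_table(paths["mc_mini"], mc)

    write_manifest(outdir / "fixtures_manifest.json", {"seed": seed, "mc_walkers": mc_walkers})
    return paths
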