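"""Deterministic synthetic-data generators and closed-form oracles.

Every input the package consumes (sorption tables, diffusivity tables,
drying curves, air schedules, seed-bed images) can be generated here from
the model itself plus an explicit noise specification and seed, so tests
and demonstrations run without measured data.  Generators are pure
functions of their arguments: the same settings and seed give identical
output, and each fixture draws from its own independently seeded stream.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .diffusivity import DiffusivityParams, diffusivity
from .isotherm import IsothermParams, SorptionTable, equilibrium_moisture
from .material import Composition
from .solver import AirSchedule, DryingCurve, SimulationConfig, run

__all__ = [
    "gen_sorption_table",
    "gen_diffusivity_table",
    "gen_drying_experiment",
    "gen_air_schedule",
    "gen_mixing_images",
    "analytic_sphere_mc",
]

#: Humidity steps of a typical stepwise sorption program (fractions).
DESORPTION_RH_STEPS = (0.95, 0.80, 0.70, 0.60, 0.50, 0.40, 0.30, 0.20, 0.10)
SORPTION_RH_STEPS = (0.20, 0.40, 0.60, 0.80, 0.95)


def _noisy_mc(mc: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Multiplicative Gaussian noise on MC, truncated to (0, 1).

    Balance noise scales with signal, hence multiplicative.
    """
    if sigma == 0.0:
        return mc
    noisy = mc * (1.0 + sigma * rng.standard_normal(mc.shape))
    return np.clip(noisy, 1e-6, 1.0 - 1e-6)


def gen_sorption_table(
    params: IsothermParams,
    comp: Composition,
    aw_grid=None,
    T: float = 298.15,
    noise_sigma: float = 0.0,
    seed: int = 0,
    direction: str = "desorption",
) -> SorptionTable:
    """Equilibrium sorption table generated from the isotherm model."""
    if aw_grid is None:
        aw_grid = DESORPTION_RH_STEPS if direction == "desorption" else SORPTION_RH_STEPS
    aw = np.sort(np.asarray(aw_grid, dtype=float))
    if np.any((aw <= 0) | (aw >= 1)):
        raise ValueError("a_w grid must lie strictly within (0, 1)")
    mc = np.array([equilibrium_moisture(a, T, comp, params) for a in aw])
    rng = np.random.default_rng(seed)
    mc = _noisy_mc(mc, noise_sigma, rng)
    return SorptionTable(aw=aw, mc_wb=mc, temp_K=np.full(len(aw), T), direction=direction)


def gen_diffusivity_table(
    params: DiffusivityParams,
    y_grid=None,
    T: float = 298.15,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """(y_w, D_w, T) table generated from the diffusivity model."""
    if y_grid is None:
        y_grid = np.linspace(0.05, 0.4, 8)
    y = np.asarray(y_grid, dtype=float)
    d = diffusivity(y, T, params)
    rng = np.random.default_rng(seed)
    if noise_sigma:
        d = d * (1.0 + noise_sigma * rng.standard_normal(d.shape))
    return pd.DataFrame({"yw": y, "Dw": d, "temp_K": np.full(len(y), T)})


def gen_drying_experiment(
    config: SimulationConfig,
    schedule: AirSchedule,
    t_end: float = 86400.0,
    cadence: float = 3600.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> DryingCurve:
    """Synthetic "experimental" drying curve: solver output plus noise."""
    dense = run(config, schedule, t_end=t_end)
    t_out = np.arange(0.0, t_end + 1e-6, cadence)
    mc = np.interp(t_out, dense.time_s, dense.mc_wb)
    rng = np.random.default_rng(seed)
    mc = _noisy_mc(mc, noise_sigma, rng)
    temp = np.interp(t_out, dense.time_s, dense.temp_seed_K)
    return DryingCurve(time_s=t_out, mc_wb=mc, temp_seed_K=temp)


def gen_air_schedule(
    T_set: float = 298.15,
    RH_set: float = 0.30,
    U: float = 0.235,
    t_end: float = 86400.0,
    n_samples: int = 97,
    T_wobble: float = 1.0,
    RH_wobble: float = 0.03,
    seed: int = 0,
) -> AirSchedule:
    """Measured-like inlet series: set points plus smooth sensor wobble.

    Emulates an industrial dryer whose inlet conditions fluctuate around
    the set point; wobble amplitudes are in K and humidity fraction.
    """
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, t_end, n_samples)
    # smooth wobble: random walk low-pass filtered
    def wobble(amp):
        w = rng.standard_normal(n_samples).cumsum()
        w = (w - w.mean()) / max(np.abs(w - w.mean()).max(), 1e-12)
        return amp * w

    T_series = T_set + wobble(T_wobble)
    RH_series = np.clip(RH_set + wobble(RH_wobble), 0.01, 0.99)
    return AirSchedule(times=t, T_air=T_series, RH_air=RH_series, U=np.full(n_samples, U))


def analytic_sphere_mc(t: float, D: float, R: float, terms: int = 200) -> float:
    """Fickian-sphere series: mean concentration fraction remaining.

    For constant diffusivity, fixed radius and zero surface concentration,
    W(t)/W(0) = (6/pi^2) sum_n n^-2 exp(-n^2 pi^2 D t / R^2).
    """
    if t < 0:
        raise ValueError("time must be non-negative")
    if terms < 1:
        raise ValueError("need at least one series term")
    tau = D * t / (R * R)
    n = np.arange(1, terms + 1, dtype=float)
    return float(6.0 / math.pi**2 * np.sum(np.exp(-(n**2) * math.pi**2 * tau) / n**2))


def gen_mixing_images(
    pattern: str,
    size: tuple[int, int] = (200, 200),
    seed: int = 0,
    mixedness: float = 0.5,
    out_dir: str | Path | None = None,
    n_images: int = 1,
) -> list[np.ndarray]:
    """Synthetic black/white seed-bed rasters.

    Patterns: ``segregated`` (white block left, black right, with the
    boundary aligned to a 5-cell analysis grid so every cell is pure),
    ``mixed`` (iid Bernoulli(0.5) pixels) and ``intermediate`` (blend
    controlled by ``mixedness`` in [0, 1]: 0 = segregated, 1 = mixed).
    Returns uint8 arrays (0/255); optionally also writes PNG files
    ``frame_000.png`` etc. to ``out_dir``.
    """
    h, w = size
    rng = np.random.default_rng(seed)
    split = 2 * (w // 5)  # cell-boundary column of the default 5x5 grid
    out = []
    for _ in range(n_images):
        if pattern == "segregated":
            img = np.zeros((h, w), dtype=np.uint8)
            img[:, :split] = 255
        elif pattern == "mixed":
            img = (rng.random((h, w)) < 0.5).astype(np.uint8) * 255
        elif pattern == "intermediate":
            if not (0.0 <= mixedness <= 1.0):
                raise ValueError("mixedness must lie in [0, 1]")
            cols = np.arange(w)
            p_seg = (cols < split).astype(float)  # white probability, segregated
            p = (1.0 - mixedness) * p_seg + mixedness * 0.4
            img = (rng.random((h, w)) < p[None, :]).astype(np.uint8) * 255
        else:
            raise ValueError(f"unknown pattern {pattern!r}")
        out.append(img)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for i, img in enumerate(out):
            Image.fromarray(img, mode="L").save(out_dir / f"frame_{i:03d}.png")
    return out
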