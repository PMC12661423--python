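"""Moisture diffusivity of seed material.

Empirical model: a base-10 logarithmic dependence on the water mass
fraction at the 25 degC reference temperature, times an Arrhenius factor,

    D_w = (a log10(y_w) + b) exp(-E_a/R (1/T - 1/298.15)),

clamped below at a glassy floor (the mobility levels off rather than
vanishing at low moisture).  The clamp is applied to the full product, so
the Arrhenius factor cannot lift a clamped value.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize

R_GAS = 8.314462618  # J mol^-1 K^-1

__all__ = ["DiffusivityParams", "diffusivity", "arrhenius_factor", "fit_ab", "fit_ea", "read_diffusivity_csv"]


@dataclass(frozen=True)
class DiffusivityParams:
    """Fitted diffusivity parameters (defaults: whole cabbage seeds)."""

    a: float = 3e-11        # m^2 s^-1 per decade of y_w
    b: float = 9e-11        # m^2 s^-1, value at y_w = 1 and T_ref
    E_a: float = 14.18e3    # J mol^-1
    T_ref: float = 298.15   # K
    floor: float = 1.0e-12  # m^2 s^-1, glassy lower limit
    #: multiplier relating the measured water diffusivity to the mutual
    #: diffusivity used by the transport solver (assumed identical).
    mutual_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.b <= 0:
            raise ValueError("b must be positive")
        if self.floor <= 0:
            raise ValueError("floor must be positive")


def arrhenius_factor(T: float, params: DiffusivityParams) -> float:
    """Temperature factor exp(-E_a/R (1/T - 1/T_ref)); 1 at T_ref."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    return math.exp(-params.E_a / R_GAS * (1.0 / T - 1.0 / params.T_ref))


def diffusivity(y_w, T: float, params: DiffusivityParams):
    """Moisture diffusivity D_w (m^2 s^-1) at mass fraction ``y_w``, ``T``.

    Accepts scalar or array ``y_w``.  Non-positive ``y_w`` is treated as
    fully clamped (with a diagnostic); the result is never below
    ``params.floor``.
    """
    y = np.asarray(y_w, dtype=float)
    scalar = y.ndim == 0
    y = np.atleast_1d(y)
    if np.any(y <= 0.0):
        warnings.warn(
            "non-positive y_w treated as glassy floor diffusivity",
            RuntimeWarning,
            stacklevel=2,
        )
    arr = arrhenius_factor(T, params)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (params.a * np.log10(np.where(y > 0, y, 1.0)) + params.b) * arr
    raw = np.where(y > 0, raw, -np.inf)
    out = np.maximum(raw, params.floor) * params.mutual_multiplier
    return float(out[0]) if scalar else out


def fit_ab(points: np.ndarray, params: DiffusivityParams | None = None) -> tuple[float, float]:
    """Linear least-squares fit of (a, b) from (y_w, D_w) pairs at T_ref.

    Points at or below the clamp floor are excluded (with a warning)
    because they carry no information about the log-linear branch.
    """
    if params is None:
        params = DiffusivityParams()
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[1] != 2:
        raise ValueError("points rows must be (y_w, D_w)")
    clamped = pts[:, 1] <= params.floor
    if clamped.any():
        warnings.warn(
            f"excluding {int(clamped.sum())} clamped point(s) from the (a, b) fit",
            RuntimeWarning,
            stacklevel=2,
        )
        pts = pts[~clamped]
    if len(pts) < 2:
        raise ValueError("need >= 2 unclamped points to fit (a, b)")
    x = np.log10(pts[:, 0])
    if np.ptp(x) == 0.0:
        raise ValueError("degenerate design: all y_w equal")
    design = np.column_stack([x, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(design, pts[:, 1], rcond=None)
    return float(coef[0]), float(coef[1])


def fit_ea(points: np.ndarray, params: DiffusivityParams) -> float:
    """Least-squares fit of the activation energy with (a, b) held fixed.

    ``points`` rows are (y_w, D_w, T_K) with at least one temperature away
    from T_ref.  The fit acts on the ratio of the measured diffusivity to
    the reference-temperature model value; for a single point this reduces
    to the closed form E_a = -R ln(ratio)/(1/T - 1/T_ref).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[1] != 3:
        raise ValueError("points rows must be (y_w, D_w, T_K)")
    off_ref = ~np.isclose(pts[:, 2], params.T_ref)
    pts = pts[off_ref]
    if len(pts) == 0:
        raise ValueError("all points are at T_ref; E_a is unconstrained")
    y, d_obs, temps = pts.T
    d_ref = params.a * np.log10(y) + params.b
    if np.any(d_ref <= 0):
        raise ValueError("reference-model diffusivity non-positive for some y_w")
    ratio = d_obs / d_ref
    x = 1.0 / temps - 1.0 / params.T_ref
    if len(pts) == 1:
        return float(-R_GAS * math.log(ratio[0]) / x[0])

    def model(xv, ea):
        return np.exp(-ea / R_GAS * xv)

    popt, _ = optimize.curve_fit(model, x, ratio, p0=[1e4], xtol=1e-14)
    return float(popt[0])


def read_diffusivity_csv(path: str | Path) -> pd.DataFrame:
    """Read a (y_w, D_w[, T]) table with columns ``yw,Dw[,temp_K]``."""
    df = pd.read_csv(path)
    cols = tuple(df.columns)
    if cols not in (("yw", "Dw"), ("yw", "Dw", "temp_K")):
        raise ValueError(
            f"diffusivity table must have columns (yw, Dw[, temp_K]), got {cols}"
        )
    return df
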