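"""Water-activity (sorption isotherm) models for seed material.

The base model is Flory-Huggins polymer-solution theory,

    a_w = exp( ln(phi_w) + (1 - 1/N_s)(1 - phi_w) + chi_eff (1 - phi_w)^2 + mu_add )

with a composition-dependent interaction parameter chi_eff interpolating
between the concentrated-regime value chi_ws and the semi-dilute value
chi_0 = 0.5.  Below the glass transition (Couchman-Karasz) one of two
glassy-state additions can be switched on:

* ``FH_FV`` — a free-volume term proportional to the solids' Delta C_p and
  the slope of the glass-transition curve; it is negative (water
  plasticizes), lowering a_w in the glassy state.
* ``FH_LS`` — the Leibler-Sekimoto elastic term
  nu_w K_g / (R T) * ln((1 - phi_w,Tg)/(1 - phi_w)), coupling the water
  chemical potential to the elastic bulk modulus K_g of the glassy matrix.
  The default sign lowers a_w in the glassy state, producing the increased
  water retention the theory describes; ``ls_literal_sign`` flips the term
  to the opposite (literal-transcription) sign for comparison runs.  See
  docs/methods.md for why the retention sign is the default.

Both additions vanish continuously at the glass-transition boundary, so
a_w is continuous there by construction.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize

from .material import (
    Composition,
    MaterialConstants,
    water_volume_fraction_oil_excluded,
)

__all__ = [
    "IsothermModel",
    "CouchmanKarasz",
    "IsothermParams",
    "SorptionTable",
    "chi_eff",
    "tg_couchman_karasz",
    "mu_fv",
    "mu_ls",
    "phi_at_tg",
    "water_activity",
    "equilibrium_moisture",
    "fit_chi",
    "fit_kg",
]

CHI_0 = 0.5  # semi-dilute interaction parameter, fixed


class IsothermModel:
    """Model selector labels."""

    FH = "FH"
    FH_FV = "FH_FV"
    FH_LS = "FH_LS"

    ALL = (FH, FH_FV, FH_LS)


@dataclass(frozen=True)
class CouchmanKarasz:
    """Couchman-Karasz glass-transition parameters of a water/solid mix.

    Water values are the literature standard (T_g,w = 136 K,
    Delta C_p,w = 1.94e3 J kg^-1 K^-1); the solid values are material
    configuration (defaults are documented substitutes for seed solids).
    """

    T_g_w: float = 136.0       # K
    T_g_s: float = 420.0       # K
    dC_p_w: float = 1.94e3     # J kg^-1 K^-1
    dC_p_s: float = 450.0      # J kg^-1 K^-1

    def __post_init__(self) -> None:
        if self.T_g_w >= self.T_g_s:
            raise ValueError("T_g,w must be below T_g,s")
        if self.dC_p_w <= 0 or self.dC_p_s <= 0:
            raise ValueError("Delta C_p values must be positive")


@dataclass(frozen=True)
class IsothermParams:
    """Everything the water-activity model needs.

    N_s is the solute/solvent molar-volume ratio; its default is large so
    that (1 - 1/N_s) ~ 1 (polymeric solids).  ``clip_aw_at_unity``
    optionally clips a_w at 1; by default values above 1 only raise a
    diagnostic warning, since clipping would silently change drying fluxes.
    """

    model: str = IsothermModel.FH_LS
    chi_ws: float = 1.244
    N_s: float = 1e3
    K_g: float = 3.3e9          # Pa
    nu_w: float = 1.805e-5      # m^3 mol^-1
    CK: CouchmanKarasz = field(default_factory=CouchmanKarasz)
    clip_aw_at_unity: bool = False
    ls_literal_sign: bool = False

    def __post_init__(self) -> None:
        if self.model not in IsothermModel.ALL:
            raise ValueError(f"model must be one of {IsothermModel.ALL}")
        if self.N_s <= 1:
            raise ValueError("N_s must exceed 1")
        if self.K_g <= 0:
            raise ValueError("K_g must be positive")

    chi_0: float = CHI_0


def chi_eff(chi_ws: float, phi_w: float) -> float:
    """Effective interaction parameter at water volume fraction phi_w.

    Constant chi_ws when chi_ws <= 0.5; otherwise interpolates
    quadratically toward the semi-dilute value 0.5 as phi_w -> 1.
    """
    if not (0.0 <= phi_w <= 1.0):
        raise ValueError(f"phi_w = {phi_w!r} outside [0, 1]")
    if chi_ws <= CHI_0:
        return chi_ws
    return chi_ws - (chi_ws - CHI_0) * phi_w * phi_w


def tg_couchman_karasz(y_w: float, ck: CouchmanKarasz) -> tuple[float, float]:
    """Glass-transition temperature of the mix and its analytic slope.

    Returns ``(T_g, dT_g/dy_w)``.  The slope is the closed-form derivative
    of the Couchman-Karasz expression (kept analytic so the free-volume
    addition stays smooth for the solver).
    """
    if not (0.0 <= y_w <= 1.0):
        raise ValueError(f"y_w = {y_w!r} outside [0, 1]")
    num = y_w * ck.dC_p_w * ck.T_g_w + (1.0 - y_w) * ck.dC_p_s * ck.T_g_s
    den = y_w * ck.dC_p_w + (1.0 - y_w) * ck.dC_p_s
    tg = num / den
    # d/dy of (A y + B (1-y)) / (a y + b (1-y)) with A = dCpw Tgw etc.
    dnum = ck.dC_p_w * ck.T_g_w - ck.dC_p_s * ck.T_g_s
    dden = ck.dC_p_w - ck.dC_p_s
    dtg = (dnum * den - num * dden) / (den * den)
    return tg, dtg


def mu_fv(
    y_w: float,
    T: float,
    params: IsothermParams,
    constants: MaterialConstants | None = None,
) -> float:
    """Free-volume glassy addition to the water chemical potential (-).

    Zero above the glass transition; below it,
    M_w dC_p,s / (R T) * (1 - y_w)^2 * (1 - T/T_g) * dT_g/dy_w.
    """
    if constants is None:
        constants = MaterialConstants()
    tg, dtg = tg_couchman_karasz(y_w, params.CK)
    if T >= tg:
        return 0.0
    pref = constants.M_w * params.CK.dC_p_s / (constants.R_gas * T)
    return pref * (1.0 - y_w) ** 2 * (1.0 - T / tg) * dtg


def mu_ls(
    phi_w: float,
    T: float,
    phi_w_tg: float,
    params: IsothermParams,
    constants: MaterialConstants | None = None,
) -> float:
    """Leibler-Sekimoto elastic glassy addition (-).

    Active only for phi_w < phi_w,Tg (glassy side) and exactly zero at the
    transition.  Default (retention) sign:
    nu_w K_g / (R T) * ln((1 - phi_w,Tg)/(1 - phi_w)) < 0, which lowers
    a_w in the glassy state and reproduces the elastic water retention the
    theory predicts.  With ``params.ls_literal_sign`` the logarithm's
    argument is inverted (the literal-transcription form, > 0 in the
    glassy state).
    """
    if constants is None:
        constants = MaterialConstants()
    if phi_w_tg >= 1.0:
        raise ValueError("phi_w,Tg = 1 is a degenerate reference state")
    if phi_w >= phi_w_tg:
        return 0.0
    pref = params.nu_w * params.K_g / (constants.R_gas * T)
    val = pref * math.log((1.0 - phi_w_tg) / (1.0 - phi_w))
    return -val if params.ls_literal_sign else val


def phi_at_tg(
    T: float, comp: Composition, params: IsothermParams
) -> float:
    """Water volume fraction at which the glass transition sits at ``T``.

    Solves T_g(y_w) = T by bracketed root finding and converts the root to
    a volume fraction with the oil-excluded mixing rule.
    """
    ck = params.CK
    if not (ck.T_g_w < T < ck.T_g_s):
        raise ValueError(
            f"T = {T!r} K outside the glass-transition window "
            f"({ck.T_g_w}, {ck.T_g_s}) K"
        )
    f = lambda y: tg_couchman_karasz(y, ck)[0] - T
    y_star = optimize.brentq(f, 1e-15, 1.0 - 1e-15, xtol=1e-14, rtol=1e-15)
    # density correlations cover [270, 360] K; the mass->volume conversion
    # is only weakly T-dependent, so clamp T for it outside that window
    T_conv = min(max(T, 270.0), 360.0)
    return water_volume_fraction_oil_excluded(comp.with_water(y_star), T_conv)


def water_activity(
    y_w: float,
    T: float,
    comp: Composition,
    params: IsothermParams,
    constants: MaterialConstants | None = None,
) -> float:
    """Water activity of the seed material at water mass fraction ``y_w``.

    The composition is rebalanced to ``y_w`` (dry-matter ratios fixed)
    before the oil-excluded water volume fraction is computed.  Emits a
    diagnostic warning (not an error) if the model predicts a_w > 1.
    """
    if y_w <= 0.0:
        raise ValueError(f"y_w = {y_w!r} must be positive")
    if constants is None:
        constants = MaterialConstants()
    comp_y = comp.with_water(y_w)
    phi = water_volume_fraction_oil_excluded(comp_y, T)
    if phi >= 1.0:
        return 1.0
    chi = chi_eff(params.chi_ws, phi)
    mu = math.log(phi) + (1.0 - 1.0 / params.N_s) * (1.0 - phi) + chi * (1.0 - phi) ** 2
    if params.model == IsothermModel.FH_FV:
        mu += mu_fv(y_w, T, params, constants)
    elif params.model == IsothermModel.FH_LS:
        ck = params.CK
        if ck.T_g_w < T < ck.T_g_s:
            phi_tg = phi_at_tg(T, comp, params)
            mu += mu_ls(phi, T, phi_tg, params, constants)
        elif T <= ck.T_g_w:
            # everything is glassy; no transition crossing to reference
            pass
    aw = math.exp(mu)
    if aw > 1.0:
        if params.clip_aw_at_unity:
            return 1.0
        warnings.warn(
            f"water activity {aw:.4g} exceeds 1 at y_w={y_w:.4g}, T={T:.2f} K",
            RuntimeWarning,
            stacklevel=2,
        )
    return aw


def equilibrium_moisture(
    RH_air: float,
    T: float,
    comp: Composition,
    params: IsothermParams,
    constants: MaterialConstants | None = None,
    y_max: float = 0.99,
    n_scan: int = 2000,
) -> float:
    """Equilibrium (final) moisture content at air humidity ``RH_air``.

    Returns the smallest y_w in (0, y_max) with a_w(y_w) = RH_air, located
    by a grid scan for the first sign change followed by bracketed root
    finding.  This is the model's predicted final moisture content of a
    drying run at constant air conditions.
    """
    if not (0.0 < RH_air < 1.0):
        raise ValueError(f"RH_air = {RH_air!r} outside (0, 1)")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        f = lambda y: water_activity(y, T, comp, params, constants) - RH_air
        # log-spaced scan resolves the steep region at small y_w
        grid = np.logspace(math.log10(1e-8), math.log10(y_max), n_scan)
        prev_y, prev_f = grid[0], f(grid[0])
        for y in grid[1:]:
            cur = f(y)
            if prev_f == 0.0:
                return prev_y
            if prev_f < 0.0 <= cur or prev_f > 0.0 >= cur:
                return optimize.brentq(f, prev_y, y, xtol=1e-14, rtol=8.9e-16)
            prev_y, prev_f = y, cur
    raise ValueError(
        f"no a_w = RH_air crossing found in (0, {y_max}); scanned a_w range "
        f"did not bracket RH_air = {RH_air}"
    )


@dataclass
class SorptionTable:
    """Measured (or generated) equilibrium sorption data.

    Columns: water activity target, equilibrium moisture content
    (wet basis) and temperature, plus a sorption/desorption direction flag.
    """

    aw: np.ndarray
    mc_wb: np.ndarray
    temp_K: np.ndarray
    direction: str = "desorption"

    COLUMNS = ("aw", "mc_wb", "temp_K", "direction")

    def __post_init__(self) -> None:
        self.aw = np.asarray(self.aw, dtype=float)
        self.mc_wb = np.asarray(self.mc_wb, dtype=float)
        self.temp_K = np.asarray(self.temp_K, dtype=float)
        if not (self.aw.shape == self.mc_wb.shape == self.temp_K.shape):
            raise ValueError("aw, mc_wb and temp_K must have equal length")
        if np.any((self.aw <= 0) | (self.aw >= 1)):
            raise ValueError("a_w values must lie strictly within (0, 1)")
        if np.any(np.diff(self.aw) < 0):
            raise ValueError("rows must be sorted by a_w")
        if self.direction not in ("sorption", "desorption"):
            raise ValueError("direction must be 'sorption' or 'desorption'")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "aw": self.aw,
                "mc_wb": self.mc_wb,
                "temp_K": self.temp_K,
                "direction": self.direction,
            }
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path | io.IOBase) -> "SorptionTable":
        df = pd.read_csv(path)
        if tuple(df.columns) != cls.COLUMNS:
            raise ValueError(
                f"sorption table must have columns {cls.COLUMNS}, got "
                f"{tuple(df.columns)}"
            )
        directions = set(df["direction"])
        if len(directions) != 1:
            raise ValueError("sorption table mixes sorption and desorption rows")
        return cls(
            aw=df["aw"].to_numpy(),
            mc_wb=df["mc_wb"].to_numpy(),
            temp_K=df["temp_K"].to_numpy(),
            direction=directions.pop(),
        )


def _rubbery_mask(table: SorptionTable, ck: CouchmanKarasz) -> np.ndarray:
    """Rows above the glass transition at their own moisture content."""
    tg = np.array([tg_couchman_karasz(mc, ck)[0] for mc in table.mc_wb])
    return table.temp_K > tg


def fit_chi(
    table: SorptionTable,
    comp: Composition,
    params: IsothermParams,
    constants: MaterialConstants | None = None,
) -> tuple[float, float]:
    """Least-squares fit of chi_ws to sorption data above glass transition.

    Residuals are taken in moisture content at the table's a_w values
    (each model evaluation inverts the isotherm), matching how isotherms
    are plotted and judged.  Returns ``(chi_ws, standard_error)``.
    """
    mask = _rubbery_mask(table, params.CK)
    if int(mask.sum()) < 3:
        raise ValueError(
            f"need >= 3 rows above the glass transition, found {int(mask.sum())}"
        )
    aw = table.aw[mask]
    mc = table.mc_wb[mask]
    temps = table.temp_K[mask]

    def model(aw_arr, chi):
        p = replace(params, chi_ws=float(chi))
        return np.array(
            [
                equilibrium_moisture(a, t, comp, p, constants)
                for a, t in zip(aw_arr, temps)
            ]
        )

    popt, pcov = optimize.curve_fit(
        model, aw, mc, p0=[max(params.chi_ws, 0.6)], full_output=False
    )
    stderr = float(np.sqrt(np.diag(pcov))[0]) if np.all(np.isfinite(pcov)) else math.nan
    return float(popt[0]), stderr


def fit_kg(
    final_mc_points: np.ndarray,
    comp: Composition,
    params: IsothermParams,
    constants: MaterialConstants | None = None,
) -> float:
    """Least-squares fit of the elastic modulus K_g to final-MC data.

    ``final_mc_points`` rows are (RH, T_K, observed final MC wet basis);
    all other isotherm parameters are held fixed and the model is FH_LS.
    Only points in the glassy region constrain K_g; if every point is
    rubbery the fit is impossible and an error is raised.
    """
    pts = np.atleast_2d(np.asarray(final_mc_points, dtype=float))
    if pts.shape[1] != 3:
        raise ValueError("final_mc_points rows must be (RH, T_K, final_mc)")
    ck = params.CK
    glassy = np.array(
        [tg_couchman_karasz(mc, ck)[0] > t for _, t, mc in pts]
    )
    pts = pts[glassy]
    if len(pts) < 1:
        raise ValueError("all points are rubbery; K_g is unconstrained")

    rh, temps, mc_obs = pts.T

    def model(rh_arr, log10_kg):
        kg = 10.0 ** float(log10_kg)
        p = replace(params, model=IsothermModel.FH_LS, K_g=kg)
        return np.array(
            [
                equilibrium_moisture(r, t, comp, p, constants)
                for r, t in zip(rh_arr, temps)
            ]
        )

    popt, _ = optimize.curve_fit(
        model, rh, mc_obs, p0=[math.log10(params.K_g)], xtol=1e-12
    )
    kg = 10.0 ** float(popt[0])
    if kg <= 0:
        raise ValueError("fitted K_g is non-positive")
    return kg
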