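"""Single-seed drying solver.

A spherical seed is discretised into N initially equal-volume shells in a
Lagrangian (co-moving) frame: the solid mass of every shell is constant
for the whole run and only water crosses shell boundaries, so the shells
shrink as water leaves (ideal shrinkage: shell volume = solid volume +
water volume at the current temperature).  Water transport is a
cell-centred finite-volume discretisation of Fick diffusion in spherical
symmetry; the seed temperature is a single lumped value (Biot number
below ~0.4) advanced with the surface heat balance; evaporation at the
surface is driven by the gap between the surface water activity and the
air humidity.  Time integration is explicit (forward Euler) with an
adaptive step bounded by diffusive stability, the thermal time scale, a
per-shell water-loss cap and a temperature-change cap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .diffusivity import DiffusivityParams, arrhenius_factor, diffusivity
from .isotherm import (
    IsothermParams,
    equilibrium_moisture,
    water_activity,
)
from .material import (
    DEFAULT_DRY_COMPOSITION,
    HYGROSCOPIC_CLASSES,
    Composition,
    MaterialConstants,
    air_properties,
    component_density,
    component_heat_capacity,
    dry_matter_density,
    saturation_pressure,
)

__all__ = [
    "AirSchedule",
    "SimulationConfig",
    "SeedState",
    "DryingCurve",
    "initialize",
    "transfer_coefficients",
    "evaporative_flux",
    "internal_fluxes",
    "coat_flux",
    "heat_step",
    "step",
    "run",
    "compute_biot",
]


# --------------------------------------------------------------------------
# air schedule

@dataclass
class AirSchedule:
    """Air conditions over time: constant or piecewise-linear series.

    In memory temperatures are K, humidity a fraction, air speed m/s.
    Time series are linearly interpolated and held constant beyond the
    last sample.
    """

    times: np.ndarray
    T_air: np.ndarray
    RH_air: np.ndarray
    U: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.atleast_1d(np.asarray(self.times, dtype=float))
        self.T_air = np.atleast_1d(np.asarray(self.T_air, dtype=float))
        self.RH_air = np.atleast_1d(np.asarray(self.RH_air, dtype=float))
        self.U = np.atleast_1d(np.asarray(self.U, dtype=float))
        n = len(self.times)
        for name in ("T_air", "RH_air", "U"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match times")
        if n > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any((self.RH_air < 0) | (self.RH_air > 1)):
            raise ValueError("RH_air must lie in [0, 1]")
        if np.any(self.U < 0):
            raise ValueError("air speed must be non-negative")

    @classmethod
    def constant(cls, T_air: float, RH_air: float, U: float = 0.235) -> "AirSchedule":
        return cls(times=[0.0], T_air=[T_air], RH_air=[RH_air], U=[U])

    @property
    def is_constant(self) -> bool:
        return len(self.times) == 1

    def at(self, t: float) -> tuple[float, float, float]:
        if self.is_constant:
            return float(self.T_air[0]), float(self.RH_air[0]), float(self.U[0])
        return (
            float(np.interp(t, self.times, self.T_air)),
            float(np.interp(t, self.times, self.RH_air)),
            float(np.interp(t, self.times, self.U)),
        )

    CSV_COLUMNS = ("time_s", "temp_air_C", "rh_air_pct", "air_speed_m_s")

    def write_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "time_s": self.times,
                "temp_air_C": self.T_air - 273.15,
                "rh_air_pct": self.RH_air * 100.0,
                "air_speed_m_s": self.U,
            }
        ).to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, default_U: float = 0.235) -> "AirSchedule":
        df = pd.read_csv(path)
        cols = tuple(df.columns)
        if cols not in (cls.CSV_COLUMNS, cls.CSV_COLUMNS[:3]):
            raise ValueError(
                f"air schedule must have columns {cls.CSV_COLUMNS[:3]} "
                f"[+ air_speed_m_s], got {cols}"
            )
        u = df["air_speed_m_s"].to_numpy() if "air_speed_m_s" in df else np.full(len(df), default_U)
        return cls(
            times=df["time_s"].to_numpy(),
            T_air=df["temp_air_C"].to_numpy() + 273.15,
            RH_air=df["rh_air_pct"].to_numpy() / 100.0,
            U=u,
        )


# --------------------------------------------------------------------------
# configuration

@dataclass
class SimulationConfig:
    """Everything a drying run needs besides the air schedule."""

    N: int = 10
    R0: float = 1.0e-3             # m, initial seed radius (~2 mm diameter)
    MC0: float = 0.367             # wet-basis initial moisture content
    T0_seed: float = 298.15        # K
    material_mode: str = "one_material"   # or "two_material"
    isotherm: IsothermParams = field(default_factory=IsothermParams)
    isotherm_coat: IsothermParams | None = None
    diffusivity: DiffusivityParams = field(default_factory=DiffusivityParams)
    dry_composition: dict = field(default_factory=lambda: dict(DEFAULT_DRY_COMPOSITION))
    constants: MaterialConstants = field(default_factory=MaterialConstants)
    beta_int: float | str = "auto"  # coat-interface coefficient; "auto" restores
                                    # the concentration flux for identical materials
    # numerical policy
    dt_safety: float = 0.25
    max_water_loss_frac: float = 0.10
    max_dT_per_step: float = 0.5    # K
    output_interval: float = 60.0   # s
    # physics switches
    strict_heat_sign: bool = False       # literal h_eff (T - T_air) convective term
    airside_psat_at_Tair: bool = False   # evaluate the air-side vapour term at T_air
    # degenerate linear test mode (constant D, no shrink, isothermal,
    # zero-concentration surface) for comparison with the Fickian series
    linear_mode: bool = False
    linear_D: float = 1.0e-10

    def __post_init__(self) -> None:
        if self.N < 3:
            raise ValueError("N must be at least 3")
        if not (0.0 < self.MC0 < 1.0):
            raise ValueError("MC0 must lie in (0, 1)")
        if self.R0 <= 0:
            raise ValueError("R0 must be positive")
        if self.material_mode not in ("one_material", "two_material"):
            raise ValueError("material_mode must be one_material or two_material")
        if self.material_mode == "two_material" and self.isotherm_coat is None:
            self.isotherm_coat = replace(self.isotherm, chi_ws=0.465)

    @property
    def composition(self) -> Composition:
        return Composition.from_dry_basis(self.MC0, self.dry_composition)

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        """Build a configuration from a plain (YAML/JSON-style) mapping.

        Nested keys ``isotherm``, ``isotherm_coat``, ``diffusivity`` and
        ``isotherm.CK`` map onto the corresponding parameter classes.
        """
        from .isotherm import CouchmanKarasz

        data = dict(data)

        def iso(d):
            if d is None:
                return None
            d = dict(d)
            if "CK" in d:
                d["CK"] = CouchmanKarasz(**d["CK"])
            return IsothermParams(**d)

        if "isotherm" in data:
            data["isotherm"] = iso(data["isotherm"])
        if "isotherm_coat" in data:
            data["isotherm_coat"] = iso(data["isotherm_coat"])
        if "diffusivity" in data:
            data["diffusivity"] = DiffusivityParams(**data["diffusivity"])
        if "constants" in data:
            data["constants"] = MaterialConstants(**data["constants"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


# --------------------------------------------------------------------------
# state and output containers

@dataclass
class SeedState:
    """Per-shell masses plus lumped temperature and clock.

    Shell solid masses are constant over a run (Lagrangian contract);
    geometry (volumes, radii) is derived from the masses and temperature.
    """

    m_solid: np.ndarray      # kg per shell, constant
    m_water: np.ndarray      # kg per shell
    T: float                 # K
    t: float = 0.0           # s
    evaporated: float = 0.0  # kg, cumulative evaporative loss
    config: SimulationConfig | None = None
    # geometry caches, refreshed by update_geometry()
    V: np.ndarray = field(default=None, repr=False)
    r_outer: np.ndarray = field(default=None, repr=False)
    r_centroid: np.ndarray = field(default=None, repr=False)

    def _dry_fractions(self) -> dict[str, float]:
        cache = getattr(self, "_dry_cache", None)
        if cache is None:
            cache = self.config.composition.solid_fractions_dry_basis()
            self._dry_cache = cache
        return cache

    def _rho_dry(self, T: float) -> float:
        dry = self._dry_fractions()
        return 1.0 / sum(y / component_density(k, T) for k, y in dry.items())

    def update_geometry(self, frozen: bool = False) -> None:
        """Recompute shell volumes and radii from masses (ideal shrinkage)."""
        if frozen and self.V is not None:
            return
        rho_dry = self._rho_dry(self.T)
        rho_w = component_density("water", self.T)
        self.V = self.m_solid / rho_dry + self.m_water / rho_w
        r3 = np.cumsum(self.V) * 3.0 / (4.0 * math.pi)
        self.r_outer = np.cbrt(r3)
        r_inner = np.concatenate([[0.0], self.r_outer[:-1]])
        self.r_centroid = 0.75 * (self.r_outer**4 - r_inner**4) / (
            self.r_outer**3 - r_inner**3
        )

    @property
    def c_w(self) -> np.ndarray:
        """Shell-centre water concentration, kg m^-3."""
        return self.m_water / self.V

    @property
    def y_w_shell(self) -> np.ndarray:
        return self.m_water / (self.m_water + self.m_solid)

    @property
    def radius(self) -> float:
        return float(self.r_outer[-1])

    @property
    def surface_area(self) -> float:
        return 4.0 * math.pi * self.radius**2

    @property
    def mc_total(self) -> float:
        mw = float(self.m_water.sum())
        return mw / (mw + float(self.m_solid.sum()))

    @property
    def total_water(self) -> float:
        return float(self.m_water.sum())


@dataclass
class DryingCurve:
    """Time series of moisture content (plus temperature and surface a_w)."""

    time_s: np.ndarray
    mc_wb: np.ndarray
    temp_seed_K: np.ndarray | None = None
    aw_surface: np.ndarray | None = None
    water_mass: np.ndarray | None = None
    final_state: SeedState | None = field(default=None, repr=False)
    audit: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.mc_wb = np.asarray(self.mc_wb, dtype=float)
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any((self.mc_wb < 0) | (self.mc_wb > 1)):
            raise ValueError("moisture content must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        data = {"time_s": self.time_s, "mc_wb": self.mc_wb}
        if self.temp_seed_K is not None:
            data["temp_seed_K"] = self.temp_seed_K
        if self.aw_surface is not None:
            data["aw_surface"] = self.aw_surface
        return pd.DataFrame(data)

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "DryingCurve":
        df = pd.read_csv(path)
        if "time_s" not in df or "mc_wb" not in df:
            raise ValueError("drying curve needs at least columns time_s, mc_wb")
        return cls(
            time_s=df["time_s"].to_numpy(),
            mc_wb=df["mc_wb"].to_numpy(),
            temp_seed_K=df["temp_seed_K"].to_numpy() if "temp_seed_K" in df else None,
            aw_surface=df["aw_surface"].to_numpy() if "aw_surface" in df else None,
        )


# --------------------------------------------------------------------------
# fast surface water activity

class _AwEvaluator:
    """Water activity as a cheap function of (y_w, T) for one material.

    Precomputes the dry-matter volume term of the oil-excluded water
    volume fraction and memoizes the glass-transition volume fraction per
    (rounded) temperature, so per-time-step evaluations stay light.
    Delegation target for the solver only; results agree with
    :func:`seedsim.isotherm.water_activity` (tested).
    """

    def __init__(self, comp: Composition, params: IsothermParams,
                 constants: MaterialConstants):
        self.params = params
        self.constants = constants
        self.dry = comp.solid_fractions_dry_basis()
        self._phi_tg_cache: dict[float, float] = {}
        self._comp = comp

    def _v_hyg(self, T: float) -> float:
        # hygroscopic dry-matter volume per unit dry mass
        return sum(
            self.dry[cls] / component_density(cls, T) for cls in HYGROSCOPIC_CLASSES
        )

    def phi_w(self, y_w: float, T: float) -> float:
        v_w = y_w / component_density("water", T)
        return v_w / ((1.0 - y_w) * self._v_hyg(T) + v_w)

    def phi_tg(self, T: float) -> float | None:
        ck = self.params.CK
        if not (ck.T_g_w < T < ck.T_g_s):
            return None
        key = round(T, 4)
        if key not in self._phi_tg_cache:
            from .isotherm import phi_at_tg

            self._phi_tg_cache[key] = phi_at_tg(T, self._comp, self.params)
        return self._phi_tg_cache[key]

    def __call__(self, y_w: float, T: float) -> float:
        from .isotherm import IsothermModel, chi_eff, mu_fv, mu_ls

        p = self.params
        if y_w <= 0.0:
            return 0.0
        phi = self.phi_w(y_w, T)
        if phi >= 1.0:
            return 1.0
        mu = (
            math.log(phi)
            + (1.0 - 1.0 / p.N_s) * (1.0 - phi)
            + chi_eff(p.chi_ws, phi) * (1.0 - phi) ** 2
        )
        if p.model == IsothermModel.FH_FV:
            mu += mu_fv(y_w, T, p, self.constants)
        elif p.model == IsothermModel.FH_LS:
            ptg = self.phi_tg(T)
            if ptg is not None:
                mu += mu_ls(phi, T, ptg, p, self.constants)
        aw = math.exp(mu)
        return min(aw, 1.0) if p.clip_aw_at_unity else aw


# --------------------------------------------------------------------------
# operations

def initialize(config: SimulationConfig) -> SeedState:
    """Uniform initial state: N equal-volume shells at MC0 and T0."""
    comp = config.composition
    v_spec = comp.y_w / component_density("water", config.T0_seed)
    v_spec += (1.0 - comp.y_w) / dry_matter_density(comp, config.T0_seed)
    V_tot = 4.0 / 3.0 * math.pi * config.R0**3
    m_tot = V_tot / v_spec
    m_water = m_tot * config.MC0
    m_solid = m_tot - m_water
    if m_solid <= 0:
        raise ValueError("initial moisture content leaves no solid mass")
    state = SeedState(
        m_solid=np.full(config.N, m_solid / config.N),
        m_water=np.full(config.N, m_water / config.N),
        T=config.T0_seed,
        config=config,
    )
    state.update_geometry()
    return state


def _mean_composition(state: SeedState) -> Composition:
    return state.config.composition.with_water(state.mc_total)


def _fast_thermal(state: SeedState) -> tuple[float, float, float]:
    """(lambda_eff, rho_eff, c_p_eff) of the current mean state.

    Same mixture rules as :func:`seedsim.material.effective_thermal`, but
    computed from cached dry-matter fractions to keep the time loop light.
    """
    cfg = state.config
    dry = state._dry_fractions()
    T = state.T
    mc = state.mc_total
    rho_w = component_density("water", T)
    v_dry = sum(y / component_density(k, T) for k, y in dry.items())
    cp_dry = sum(y * component_heat_capacity(k, T) for k, y in dry.items())
    v_w = mc / rho_w
    v_d = (1.0 - mc) * v_dry
    phi_w = v_w / (v_w + v_d)
    lam = phi_w * cfg.constants.lambda_w + (1.0 - phi_w) * cfg.constants.lambda_s
    rho_eff = 1.0 / (v_w + v_d)
    cp_eff = mc * component_heat_capacity("water", T) + (1.0 - mc) * cp_dry
    return lam, rho_eff, cp_eff


def transfer_coefficients(
    state: SeedState, air: tuple[float, float, float]
) -> tuple[float, float]:
    """External mass and effective heat transfer coefficients.

    Ranz-Marshall closures for a sphere of the current radius; the
    effective heat transfer coefficient is the series combination of the
    internal conduction term lambda_eff/(R/4) and the external convective
    term Nu lambda_air/(2R).  Air properties are evaluated at the
    boundary-layer average temperature (T_air + 2 T)/3.
    """
    T_air, _, U = air
    cfg = state.config
    R = state.radius
    T_avg = (T_air + 2.0 * state.T) / 3.0
    props = air_properties(T_avg)
    Re = U * 2.0 * R / props.nu_air
    Sc = props.nu_air / props.D_air
    Sh = 2.0 + 0.6 * math.sqrt(Re) * Sc**0.33
    Nu = 2.0 + 0.6 * math.sqrt(Re) * props.Pr**0.33
    beta_ext = Sh * props.D_air / (2.0 * R)
    lam_eff, _, _ = _fast_thermal(state)
    h_int = lam_eff / (0.25 * R)
    h_ext = Nu * props.lambda_air / (2.0 * R)
    h_eff = 1.0 / (1.0 / h_int + 1.0 / h_ext)
    return beta_ext, h_eff


def compute_biot(state: SeedState, air: tuple[float, float, float]) -> float:
    """Biot number h_ext R / lambda_eff of the current state."""
    T_air, _, U = air
    T_avg = (T_air + 2.0 * state.T) / 3.0
    props = air_properties(T_avg)
    R = state.radius
    Re = U * 2.0 * R / props.nu_air
    Nu = 2.0 + 0.6 * math.sqrt(Re) * props.Pr**0.33
    h_ext = Nu * props.lambda_air / (2.0 * R)
    lam_eff, _, _ = _fast_thermal(state)
    return h_ext * R / lam_eff


def _surface_aw(state: SeedState, aw_eval: _AwEvaluator) -> float:
    """Surface water activity from the outer shell's centred moisture."""
    y_surf = float(state.y_w_shell[-1])
    return aw_eval(y_surf, state.T)


def evaporative_flux(
    state: SeedState,
    air: tuple[float, float, float],
    beta_ext: float,
    aw_surface: float,
) -> float:
    """Evaporative mass flux J_evap (kg m^-2 s^-1), may be negative.

    J = beta_ext M_w/(R T_avg) (a_w p_sat(T_seed) - RH p_sat(T_seed)),
    with both saturation pressures at the seed temperature (optionally the
    air-side term at T_air for sensitivity runs).
    """
    T_air, RH_air, _ = air
    cfg = state.config
    c = cfg.constants
    T_avg = (T_air + 2.0 * state.T) / 3.0
    p_seed = saturation_pressure(state.T)
    p_air_side = saturation_pressure(T_air) if cfg.airside_psat_at_Tair else p_seed
    return (
        beta_ext * c.M_w / (c.R_gas * T_avg) * (aw_surface * p_seed - RH_air * p_air_side)
    )


def _interface_diffusivity(state: SeedState) -> np.ndarray:
    """D at each internal interface (arithmetic-mean y_w, current T)."""
    cfg = state.config
    if cfg.linear_mode:
        return np.full(cfg.N - 1, cfg.linear_D)
    y = state.y_w_shell
    y_mid = 0.5 * (y[:-1] + y[1:])
    return diffusivity(y_mid, state.T, cfg.diffusivity)


def internal_fluxes(state: SeedState) -> np.ndarray:
    """Outward water mass flow (kg/s) across each internal interface.

    Central differencing between shell volume-centroids; zero flux at the
    centre is implicit (no interface inside shell 0).  In two-material
    mode the embryo/coat interface flux is replaced by the
    water-activity-driven form.
    """
    cfg = state.config
    c = state.c_w
    d_if = _interface_diffusivity(state)
    dr = np.diff(state.r_centroid)
    area = 4.0 * math.pi * state.r_outer[:-1] ** 2
    flow = -d_if * (c[1:] - c[:-1]) / dr * area
    if cfg.material_mode == "two_material" and not cfg.linear_mode:
        flow[-1] = coat_flux(state)
    return flow


def _beta_int_auto(state: SeedState, aw_emb: _AwEvaluator) -> float:
    """Coat-interface coefficient that restores the concentration-driven flux.

    beta_int = D/(dr) * (a_avg/c_avg) / (da_w/dc), with the water-activity
    slope taken as the secant of the *embryo* isotherm between the two
    interface shells' states.  With identical materials the
    activity-driven flux then equals the concentration-driven one exactly.
    """
    cfg = state.config
    y = state.y_w_shell
    c = state.c_w
    y_avg = 0.5 * float(y[-2] + y[-1])
    c_avg = 0.5 * float(c[-2] + c[-1])
    a_lo = aw_emb(float(y[-2]), state.T)
    a_hi = aw_emb(float(y[-1]), state.T)
    a_avg = 0.5 * (a_lo + a_hi)
    d_if = float(_interface_diffusivity(state)[-1])
    dr = float(state.r_centroid[-1] - state.r_centroid[-2])
    dc = float(c[-1] - c[-2])
    da_dc = (a_hi - a_lo) / dc if dc != 0.0 else 0.0
    if da_dc <= 0.0:
        # degenerate secant (flat or inverted); fall back to a central
        # derivative of the embryo isotherm at the mean state
        h = 1e-7
        da_dy = (aw_emb(y_avg + h, state.T) - aw_emb(max(y_avg - h, 1e-12), state.T)) / (
            2 * h
        )
        rho_w = component_density("water", state.T)
        rho_s = dry_matter_density(cfg.composition, state.T)
        v = y_avg / rho_w + (1.0 - y_avg) / rho_s
        dv = 1.0 / rho_w - 1.0 / rho_s
        dc_dy = (v - y_avg * dv) / (v * v)
        da_dc = da_dy / dc_dy
        if da_dc <= 0.0:
            da_dc = a_avg / max(c_avg, 1e-300)
    return d_if / dr * (a_avg / c_avg) / da_dc


def coat_flux(state: SeedState) -> float:
    """Water flow (kg/s) from the outermost embryo shell into the coat.

    Activity-driven: beta_int A_(N-2) (c_avg/a_avg) (a_(N-2) - a_(N-1)),
    with averages over the two shells either side of the embryo/coat
    interface; the embryo isotherm applies to shell N-2 and the coat
    isotherm to shell N-1.
    """
    cfg = state.config
    aw_emb, aw_coat = _get_aw_evaluators(state)
    y = state.y_w_shell
    a_embryo = aw_emb(float(y[-2]), state.T)
    a_coat = aw_coat(float(y[-1]), state.T)
    a_avg = 0.5 * (a_embryo + a_coat)
    if a_avg == 0.0:
        raise ZeroDivisionError("average water activity at the coat interface is 0")
    c_avg = 0.5 * float(state.c_w[-2] + state.c_w[-1])
    beta = cfg.beta_int
    if beta == "auto":
        beta = _beta_int_auto(state, aw_emb)
    area = 4.0 * math.pi * float(state.r_outer[-2]) ** 2
    return beta * area * (c_avg / a_avg) * (a_embryo - a_coat)


def heat_step(
    state: SeedState,
    air: tuple[float, float, float],
    h_eff: float,
    J_evap: float,
) -> float:
    """Lumped temperature rate dT/dt (K/s).

    Convective gain h_eff (T_air - T) minus the latent-heat sink of the
    evaporative flux, over the seed's heat capacity.  With
    ``strict_heat_sign`` the convective term follows the literal
    h_eff (T - T_air) ordering instead.
    """
    cfg = state.config
    c = cfg.constants
    T_air = air[0]
    _, rho_eff, cp_eff = _fast_thermal(state)
    V = float(state.V.sum())
    A = state.surface_area
    latent = c.dH_evap0 + (c.c_p_v - c.c_p_w) * (state.T - c.T_0)
    conv = h_eff * ((state.T - T_air) if cfg.strict_heat_sign else (T_air - state.T))
    return (conv - latent * J_evap) * A / (rho_eff * cp_eff * V)


def _get_aw_evaluators(state: SeedState) -> tuple[_AwEvaluator, _AwEvaluator]:
    cfg = state.config
    cache = getattr(state, "_aw_cache", None)
    if cache is None:
        comp = cfg.composition
        emb = _AwEvaluator(comp, cfg.isotherm, cfg.constants)
        coat = (
            _AwEvaluator(comp, cfg.isotherm_coat, cfg.constants)
            if cfg.material_mode == "two_material"
            else emb
        )
        cache = (emb, coat)
        state._aw_cache = cache
    return cache


def _rates(state: SeedState, air: tuple[float, float, float]):
    """All instantaneous rates: shell dm_w/dt, dT/dt, J_evap, a_w surf."""
    cfg = state.config
    flow = internal_fluxes(state)  # outward, kg/s, length N-1
    if cfg.linear_mode:
        # zero-concentration surface: half-cell gradient to the boundary
        c_surf_gap = state.radius - float(state.r_centroid[-1])
        d_if = cfg.linear_D
        J_out = d_if * float(state.c_w[-1]) / c_surf_gap * state.surface_area
        J_evap = J_out / state.surface_area
        aw_surf = 0.0
        dTdt = 0.0
        beta_ext = 0.0
    else:
        _, coat_eval = _get_aw_evaluators(state)
        aw_surf = _surface_aw(state, coat_eval)
        beta_ext, h_eff = transfer_coefficients(state, air)
        J_evap = evaporative_flux(state, air, beta_ext, aw_surf)
        J_out = J_evap * state.surface_area
        dTdt = heat_step(state, air, h_eff, J_evap)
    dm = np.empty(cfg.N)
    dm[0] = -flow[0]
    if cfg.N > 2:
        dm[1:-1] = flow[:-1] - flow[1:]
    dm[-1] = flow[-1] - J_out
    return dm, dTdt, J_evap, aw_surf, beta_ext


def _stable_dt(
    state: SeedState,
    air: tuple[float, float, float],
    dm: np.ndarray,
    dTdt: float,
    beta_ext: float = 0.0,
) -> float:
    """Adaptive time step from stability and monotonicity limits.

    Limits: explicit-diffusion stability per shell; a per-shell water-loss
    cap; a temperature-change cap; and a linear-stability bound on the
    surface evaporation term, whose sensitivity d(J A)/d(m_w,surface) can
    dominate where the water-activity curve is steep (glassy pinning).
    """
    cfg = state.config
    r_inner = np.concatenate([[0.0], state.r_outer[:-1]])
    thickness = state.r_outer - r_inner
    if cfg.linear_mode:
        d_loc = np.full(cfg.N, cfg.linear_D)
    else:
        d_loc = np.maximum(
            diffusivity(state.y_w_shell, state.T, cfg.diffusivity), 1e-30
        )
    dt = cfg.dt_safety * float(np.min(thickness**2 / (2.0 * d_loc)))
    losing = dm < 0
    if losing.any():
        m = state.m_water[losing]
        rate = -dm[losing]
        with np.errstate(divide="ignore"):
            dt = min(dt, cfg.max_water_loss_frac * float(np.min(m / rate)))
    if dTdt != 0.0:
        dt = min(dt, cfg.max_dT_per_step / abs(dTdt))
    if not cfg.linear_mode:
        # evaporation stiffness: lambda = d(J A)/dm_w of the surface shell
        _, coat_eval = _get_aw_evaluators(state)
        c = cfg.constants
        T_air = air[0]
        T_avg = (T_air + 2.0 * state.T) / 3.0
        if beta_ext == 0.0:
            beta_ext, _ = transfer_coefficients(state, air)
        y_s = float(state.y_w_shell[-1])
        h = 1e-6
        yp, ym = y_s + h, max(y_s - h, 1e-12)
        da_dy = (coat_eval(yp, state.T) - coat_eval(ym, state.T)) / (yp - ym)
        m_tot_shell = float(state.m_water[-1] + state.m_solid[-1])
        dy_dm = float(state.m_solid[-1]) / m_tot_shell**2
        lam = (
            state.surface_area
            * beta_ext
            * c.M_w
            / (c.R_gas * T_avg)
            * saturation_pressure(state.T)
            * abs(da_dy)
            * dy_dm
        )
        if lam > 0:
            dt = min(dt, 0.5 / lam)
    return max(dt, 1e-9)


def step(state: SeedState, air: tuple[float, float, float], dt: float) -> SeedState:
    """Advance the state by one explicit Euler step of length ``dt``.

    Mutates and returns ``state``.  Raises if any shell's water mass
    would go negative (the step was too large).
    """
    cfg = state.config
    dm, dTdt, J_evap, _, _ = _rates(state, air)
    new_m = state.m_water + dm * dt
    if np.any(new_m < 0):
        k = int(np.argmin(new_m))
        raise RuntimeError(
            f"shell {k} water mass would become negative ({new_m[k]:.3e} kg) "
            f"at t = {state.t:.1f} s; dt = {dt:.3e} s is too large"
        )
    state.m_water = new_m
    state.evaporated += J_evap * state.surface_area * dt
    if not cfg.linear_mode:
        state.T += dTdt * dt
    state.t += dt
    state.update_geometry(frozen=cfg.linear_mode)
    return state


def run(
    config: SimulationConfig,
    schedule: AirSchedule,
    t_end: float = 86400.0,
) -> DryingCurve:
    """Integrate a drying run and sample the curve at the output cadence.

    Returns a :class:`DryingCurve` whose ``audit`` dict carries the global
    water-conservation residual and per-shell solid-mass drift, and whose
    ``final_state`` is the end-of-run :class:`SeedState`.
    """
    state = initialize(config)
    m_solid0 = state.m_solid.copy()
    water0 = state.total_water

    times, mcs, temps, aws, wmass = [], [], [], [], []

    def record(aw_surf=None):
        if aw_surf is None:
            if config.linear_mode:
                aw_surf = 0.0
            else:
                _, coat_eval = _get_aw_evaluators(state)
                aw_surf = _surface_aw(state, coat_eval)
        times.append(state.t)
        mcs.append(state.mc_total)
        temps.append(state.T)
        aws.append(aw_surf)
        wmass.append(state.total_water)

    record()
    next_out = config.output_interval
    while state.t < t_end - 1e-9:
        air = schedule.at(state.t)
        dm, dTdt, J_evap, aw_surf, beta_ext = _rates(state, air)
        dt = _stable_dt(state, air, dm, dTdt, beta_ext)
        dt = min(dt, next_out - state.t, t_end - state.t)
        new_m = state.m_water + dm * dt
        if np.any(new_m < 0):
            # halve until safe (rare; the loss cap normally prevents this)
            while np.any(state.m_water + dm * dt < 0) and dt > 1e-9:
                dt *= 0.5
            new_m = state.m_water + dm * dt
        state.m_water = new_m
        state.evaporated += J_evap * state.surface_area * dt
        if not config.linear_mode:
            state.T += dTdt * dt
        state.t += dt
        state.update_geometry(frozen=config.linear_mode)
        if state.t >= next_out - 1e-9:
            record()
            next_out += config.output_interval

    if times[-1] < state.t:
        record()

    residual = abs(water0 - state.total_water - state.evaporated) / water0
    solid_drift = float(np.max(np.abs(state.m_solid - m_solid0) / m_solid0))
    return DryingCurve(
        time_s=np.array(times),
        mc_wb=np.array(mcs),
        temp_seed_K=np.array(temps),
        aw_surface=np.array(aws),
        water_mass=np.array(wmass),
        final_state=state,
        audit={
            "water_conservation_residual": residual,
            "solid_mass_drift": solid_drift,
            "initial_water": water0,
            "evaporated": state.evaporated,
        },
    )


def predicted_final_mc(config: SimulationConfig, schedule: AirSchedule) -> float:
    """Equilibrium moisture content implied by the isotherm at the air state.

    For two-material mode the whole-seed equilibrium uses the embryo
    isotherm (the dominant mass fraction).
    """
    T_air, RH_air, _ = schedule.at(float(schedule.times[-1]))
    return equilibrium_moisture(
        RH_air, T_air, config.composition, config.isotherm, config.constants
    )
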