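"""Material, air and psychrometric properties of the seed-drying system.

Seed dry matter is described by its proximate composition (protein,
carbohydrate, fibre, sugar, ash and oil mass fractions).  Component
densities and specific heats follow the Choi & Okos (1986) temperature
polynomials; oil is inert with respect to water sorption, so the water
volume fraction that enters the sorption isotherm is computed over the
hygroscopic solids only (oil excluded from both numerator and
denominator).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

__all__ = [
    "Composition",
    "DEFAULT_DRY_COMPOSITION",
    "MaterialConstants",
    "AirProperties",
    "HYGROSCOPIC_CLASSES",
    "component_density",
    "component_heat_capacity",
    "water_volume_fraction_oil_excluded",
    "water_volume_fraction_total",
    "dry_matter_density",
    "effective_thermal",
    "saturation_pressure",
    "air_properties",
]

#: Solid classes that absorb water.  Oil is deliberately absent.
HYGROSCOPIC_CLASSES = ("protein", "carbohydrate", "fibre", "sugar", "ash")

T_MIN, T_MAX = 270.0, 360.0  # validity window for property correlations, K

# Choi & Okos (1986) density polynomials, kg m^-3, T in deg C.
# Fibre and sugar are complex/simple carbohydrates and share the
# carbohydrate coefficients for density.
_DENSITY_POLY = {
    "water": (997.18, 3.1439e-3, -3.7574e-3),
    "protein": (1329.9, -0.5184, 0.0),
    "carbohydrate": (1599.1, -0.31046, 0.0),
    "fibre": (1599.1, -0.31046, 0.0),
    "sugar": (1599.1, -0.31046, 0.0),
    "ash": (2423.8, -0.28063, 0.0),
    "oil": (925.59, -0.41757, 0.0),
}

# Choi & Okos (1986) specific heats, J kg^-1 K^-1, T in deg C (T > 0 branch).
_CP_POLY = {
    "water": (4176.2, -0.090864, 5.4731e-3),
    "protein": (2008.2, 1.2089, -1.3129e-3),
    "carbohydrate": (1548.8, 1.9625, -5.9399e-3),
    "fibre": (1845.9, 1.8306, -4.6509e-3),
    "sugar": (1548.8, 1.9625, -5.9399e-3),
    "ash": (1092.6, 1.8896, -3.6817e-3),
    "oil": (1984.2, 1.4733, -4.8008e-3),
}


def _check_temperature(T: float) -> None:
    if not (T_MIN <= T <= T_MAX):
        raise ValueError(
            f"temperature {T!r} K outside supported range [{T_MIN}, {T_MAX}] K"
        )


def component_density(component: str, T: float) -> float:
    """Density of a pure seed component at temperature ``T`` (K), kg m^-3.

    Valid component labels: water, oil and the hygroscopic classes
    (protein, carbohydrate, fibre, sugar, ash).
    """
    _check_temperature(T)
    try:
        c0, c1, c2 = _DENSITY_POLY[component]
    except KeyError:
        valid = ", ".join(sorted(_DENSITY_POLY))
        raise ValueError(
            f"unknown component {component!r}; valid labels: {valid}"
        ) from None
    tc = T - 273.15
    return c0 + c1 * tc + c2 * tc * tc


def component_heat_capacity(component: str, T: float) -> float:
    """Specific heat of a pure seed component at ``T`` (K), J kg^-1 K^-1."""
    _check_temperature(T)
    try:
        c0, c1, c2 = _CP_POLY[component]
    except KeyError:
        valid = ", ".join(sorted(_CP_POLY))
        raise ValueError(
            f"unknown component {component!r}; valid labels: {valid}"
        ) from None
    tc = T - 273.15
    return c0 + c1 * tc + c2 * tc * tc


@dataclass(frozen=True)
class Composition:
    """Mass fractions of the seed material (wet basis).

    ``y_w`` is water; ``y_oil`` is non-hygroscopic; the remaining classes
    are the hygroscopic solids.  Fractions must sum to one.
    """

    y_w: float
    y_oil: float = 0.0
    y_protein: float = 0.0
    y_carbohydrate: float = 0.0
    y_fibre: float = 0.0
    y_sugar: float = 0.0
    y_ash: float = 0.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (-1e-12 <= v <= 1.0 + 1e-12):
                raise ValueError(f"{f.name} = {v!r} outside [0, 1]")
        total = sum(getattr(self, f.name) for f in fields(self))
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mass fractions sum to {total!r}, expected 1")
        if self.hygroscopic_fraction < -1e-12:
            raise ValueError("hygroscopic solid fraction is negative")

    @property
    def hygroscopic_fraction(self) -> float:
        return 1.0 - self.y_w - self.y_oil

    def fraction(self, component: str) -> float:
        if component == "water":
            return self.y_w
        if component == "oil":
            return self.y_oil
        return getattr(self, f"y_{component}")

    def solid_fractions_dry_basis(self) -> dict[str, float]:
        """Dry-matter mass fractions of oil and the hygroscopic classes."""
        dm = 1.0 - self.y_w
        if dm <= 0.0:
            raise ValueError("composition contains no dry matter")
        out = {"oil": self.y_oil / dm}
        for cls in HYGROSCOPIC_CLASSES:
            out[cls] = self.fraction(cls) / dm
        return out

    def with_water(self, y_w: float) -> "Composition":
        """Rebalance to a new water fraction, keeping dry-matter ratios."""
        if not (0.0 <= y_w < 1.0):
            raise ValueError(f"y_w = {y_w!r} outside [0, 1)")
        dry = self.solid_fractions_dry_basis()
        scale = 1.0 - y_w
        return Composition(
            y_w=y_w,
            y_oil=dry["oil"] * scale,
            y_protein=dry["protein"] * scale,
            y_carbohydrate=dry["carbohydrate"] * scale,
            y_fibre=dry["fibre"] * scale,
            y_sugar=dry["sugar"] * scale,
            y_ash=dry["ash"] * scale,
        )

    @classmethod
    def from_dry_basis(cls, y_w: float, dry_fractions: dict[str, float]) -> "Composition":
        """Build a composition from a water fraction and dry-matter recipe."""
        tot = sum(dry_fractions.values())
        if abs(tot - 1.0) > 1e-9:
            raise ValueError(f"dry fractions sum to {tot!r}, expected 1")
        scale = 1.0 - y_w
        kw = {f"y_{k}" if k != "oil" else "y_oil": v * scale for k, v in dry_fractions.items()}
        return cls(y_w=y_w, **kw)


#: Default dry-matter recipe for primed cabbage seed material.  The oil
#: fraction (~35 % of dry matter) follows the whole-seed measurement; the
#: split of the hygroscopic classes is a documented placeholder typical of
#: Brassica seed proximate analyses.
DEFAULT_DRY_COMPOSITION: dict[str, float] = {
    "oil": 0.35,
    "protein": 0.28,
    "carbohydrate": 0.12,
    "fibre": 0.14,
    "sugar": 0.05,
    "ash": 0.06,
}


@dataclass(frozen=True)
class MaterialConstants:
    """Physical constants of water, vapour and seed solids.

    ``lambda_w``/``lambda_s`` are the thermal conductivities entering the
    volume-fraction mixing rule; their exact values are configuration
    (documented substitutes for unpublished ones).
    """

    M_w: float = 0.018015          # kg mol^-1
    R_gas: float = 8.314462618     # J mol^-1 K^-1
    dH_evap0: float = 2.501e6      # J kg^-1, heat of vaporization at 0 degC
    c_p_v: float = 1880.0          # J kg^-1 K^-1, water vapour
    c_p_w: float = 4187.0          # J kg^-1 K^-1, liquid water
    T_0: float = 273.15            # K, enthalpy reference
    lambda_w: float = 0.60         # W m^-1 K^-1
    lambda_s: float = 0.20         # W m^-1 K^-1
    nu_w: float = 1.805e-5         # m^3 mol^-1, molar volume of water

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) <= 0.0:
                raise ValueError(f"{f.name} must be strictly positive")
        rho_w_ref = component_density("water", 298.15)
        implied = self.M_w / rho_w_ref
        if abs(self.nu_w - implied) / implied > 0.02:
            raise ValueError(
                f"nu_w = {self.nu_w!r} inconsistent with M_w/rho_w = {implied:.4e}"
            )


@dataclass(frozen=True)
class AirProperties:
    """Transport properties of humid air at a film temperature."""

    nu_air: float    # m^2 s^-1, kinematic viscosity
    D_air: float     # m^2 s^-1, vapour-in-air diffusivity
    lambda_air: float  # W m^-1 K^-1
    alpha_air: float   # m^2 s^-1, thermal diffusivity
    Pr: float = field(default=0.0)

    def __post_init__(self) -> None:
        for name in ("nu_air", "D_air", "lambda_air", "alpha_air"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be positive")
        pr = self.nu_air / self.alpha_air
        if self.Pr == 0.0:
            object.__setattr__(self, "Pr", pr)
        elif abs(self.Pr - pr) > 1e-6:
            raise ValueError("Pr inconsistent with nu_air/alpha_air")


def air_properties(T: float, pressure: float = 101325.0) -> AirProperties:
    """Air transport properties at film temperature ``T`` (K).

    Low-order fits to dry-air tabulations, valid 0-80 degC:
    kinematic viscosity and conductivity are quadratic/linear in degC,
    vapour diffusivity follows ``2.262e-5 (T/273.15)^1.81`` and the
    thermal diffusivity comes from lambda/(rho c_p) with ideal-gas density.
    """
    _check_temperature(T)
    tc = T - 273.15
    nu = 1.338e-5 + 8.77e-8 * tc + 1.2e-10 * tc * tc
    lam = 0.02436 + 7.4e-5 * tc
    d_air = 2.262e-5 * (T / 273.15) ** 1.81
    rho = pressure / (287.05 * T)
    alpha = lam / (rho * 1007.0)
    return AirProperties(nu_air=nu, D_air=d_air, lambda_air=lam, alpha_air=alpha)


def water_volume_fraction_oil_excluded(comp: Composition, T: float) -> float:
    """Water volume fraction over water + hygroscopic solids only.

    Oil does not take part in water sorption and is excluded from both
    numerator and denominator.  Returns 0 for a dry material; an all-oil
    dry matter with y_w = 0 returns 0 (degenerate, no sorbing phase).
    """
    if comp.y_w == 0.0:
        return 0.0
    v_w = comp.y_w / component_density("water", T)
    v_solids = sum(
        comp.fraction(cls) / component_density(cls, T) for cls in HYGROSCOPIC_CLASSES
    )
    return v_w / (v_solids + v_w)


def water_volume_fraction_total(comp: Composition, T: float) -> float:
    """Water volume fraction over the whole material (oil included)."""
    v_w = comp.y_w / component_density("water", T)
    v_tot = v_w + comp.y_oil / component_density("oil", T)
    v_tot += sum(
        comp.fraction(cls) / component_density(cls, T) for cls in HYGROSCOPIC_CLASSES
    )
    return v_w / v_tot if v_tot > 0 else 0.0


def dry_matter_density(comp: Composition, T: float) -> float:
    """Density of the dry-matter mixture (oil included), kg m^-3."""
    dry = comp.solid_fractions_dry_basis()
    v = sum(y / component_density(cls, T) for cls, y in dry.items())
    return 1.0 / v


def effective_thermal(
    comp: Composition, T: float, constants: MaterialConstants | None = None
) -> tuple[float, float, float]:
    """Effective (lambda_eff, rho_eff, c_p_eff) of the wet seed material.

    lambda_eff is the volume-fraction weighted mean of the water and solid
    conductivities (total water volume fraction; oil counts as solid);
    rho_eff is total mass over total component volume (ideal mixing);
    c_p_eff is the mass-weighted mixture specific heat.
    """
    if constants is None:
        constants = MaterialConstants()
    phi_w = water_volume_fraction_total(comp, T)
    lam = phi_w * constants.lambda_w + (1.0 - phi_w) * constants.lambda_s
    labels = ("water", "oil") + HYGROSCOPIC_CLASSES
    v = sum(comp.fraction(c) / component_density(c, T) for c in labels)
    rho = 1.0 / v
    cp = sum(comp.fraction(c) * component_heat_capacity(c, T) for c in labels)
    return lam, rho, cp


def saturation_pressure(T: float) -> float:
    """Saturation vapour pressure of water at ``T`` (K), Pa.

    Arden Buck (1981) correlation — a Magnus-type form with a
    temperature-dependent exponent, accurate to ~0.05 % from 0 to 100 degC
    (it reproduces 101325 Pa at the normal boiling point).
    """
    if not (T_MIN <= T <= 380.0):
        raise ValueError(
            f"temperature {T!r} K outside supported range [{T_MIN}, 380.0] K"
        )
    tc = T - 273.15
    return 611.21 * math.exp((18.678 - tc / 234.5) * (tc / (257.14 + tc)))
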