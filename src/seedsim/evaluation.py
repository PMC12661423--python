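"""Model-vs-experiment comparison via the percent-error statistic.

PE = (100/n) * sum_i |MC_exp,i - MC_model,i| / MC_model,i

with the *model* moisture content in the denominator.  The model curve
(dense) is linearly interpolated to the experimental timestamps (sparse).
A PE below 10 % is conventionally read as high accuracy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .solver import AirSchedule, DryingCurve, SimulationConfig, run

__all__ = ["ComparisonResult", "percent_error", "evaluate_scenario", "average_schedules"]


@dataclass
class ComparisonResult:
    """Percent error plus per-point residual detail."""

    PE: float
    n: int
    residuals: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("at least one compared point is required")
        if self.PE < 0:
            raise ValueError("PE cannot be negative")
        recomputed = 100.0 * float(self.residuals["rel_abs_dev"].mean())
        if abs(recomputed - self.PE) > 1e-12 * max(1.0, self.PE):
            raise ValueError("PE inconsistent with per-point residuals")

    def to_json(self, path: str | Path, extra: dict | None = None) -> None:
        payload = {
            "PE_percent": self.PE,
            "n": self.n,
            "residuals": self.residuals.to_dict(orient="records"),
        }
        if extra:
            payload.update(extra)
        Path(path).write_text(json.dumps(payload, indent=2))


def percent_error(
    exp: DryingCurve,
    model: DryingCurve,
    exclude_times: np.ndarray | list | None = None,
) -> ComparisonResult:
    """Percent error of an experimental curve against a model curve.

    Model MC is linearly interpolated to the experimental timestamps,
    which must lie within the model's simulated span.  ``exclude_times``
    drops listed experimental timestamps (exact match) from the
    comparison, e.g. to leave out a distorting end point.
    """
    t_exp = np.asarray(exp.time_s, dtype=float)
    mc_exp = np.asarray(exp.mc_wb, dtype=float)
    if exclude_times is not None and len(exclude_times) > 0:
        keep = ~np.isin(t_exp, np.asarray(exclude_times, dtype=float))
        t_exp, mc_exp = t_exp[keep], mc_exp[keep]
    if len(t_exp) == 0:
        raise ValueError("no experimental points left to compare")
    t_lo, t_hi = model.time_s[0], model.time_s[-1]
    out = (t_exp < t_lo - 1e-9) | (t_exp > t_hi + 1e-9)
    if out.any():
        raise ValueError(
            "experimental times outside the model span "
            f"[{t_lo}, {t_hi}] s: {t_exp[out].tolist()}"
        )
    mc_model = np.interp(t_exp, model.time_s, model.mc_wb)
    if np.any(mc_model == 0.0):
        bad = t_exp[mc_model == 0.0]
        raise ZeroDivisionError(
            f"model MC is zero at compared time(s) {bad.tolist()}; PE undefined"
        )
    rel = np.abs(mc_exp - mc_model) / mc_model
    residuals = pd.DataFrame(
        {
            "time_s": t_exp,
            "mc_exp": mc_exp,
            "mc_model": mc_model,
            "rel_abs_dev": rel,
        }
    )
    return ComparisonResult(PE=100.0 * float(rel.mean()), n=len(t_exp), residuals=residuals)


def average_schedules(inlet: AirSchedule, outlet: AirSchedule) -> AirSchedule:
    """Pointwise average of inlet and outlet sensor series.

    The seeds in the bed see conditions between the two sensors, so their
    average is the representative driving air state.  Series are averaged
    on the union of their time grids (each linearly interpolated first).
    """
    times = np.union1d(inlet.times, outlet.times)

    def avg(attr: str) -> np.ndarray:
        a = np.interp(times, inlet.times, getattr(inlet, attr))
        b = np.interp(times, outlet.times, getattr(outlet, attr))
        return 0.5 * (a + b)

    return AirSchedule(
        times=times, T_air=avg("T_air"), RH_air=avg("RH_air"), U=avg("U")
    )


def evaluate_scenario(
    config: SimulationConfig,
    schedule: AirSchedule,
    exp_curve: DryingCurve,
    exclude_times=None,
    t_end: float | None = None,
) -> tuple[ComparisonResult, DryingCurve]:
    """Run the solver on a schedule and score it against an experiment.

    The simulation span covers the last experimental timestamp unless
    ``t_end`` says otherwise.  Returns the comparison and the model curve.
    """
    if t_end is None:
        t_end = float(np.max(exp_curve.time_s))
        if t_end <= 0:
            raise ValueError("experimental curve has no positive times")
    model = run(config, schedule, t_end=t_end)
    result = percent_error(exp_curve, model, exclude_times=exclude_times)
    return result, model
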