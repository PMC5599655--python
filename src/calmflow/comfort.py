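"""Thermal-comfort indices: PMV, PPD, comfort-zone classification.

PMV (Predicted Mean Vote) is Fanger's steady-state heat-balance index of
mean thermal sensation on the seven-point ASHRAE scale (-3 cold ... +3 hot).
It combines four environmental variables (air temperature, mean radiant
temperature, air velocity, relative humidity) with two personal ones
(clothing insulation in clo, metabolic rate in met).  PPD (Predicted
Percentage of Dissatisfied) is the deterministic even function of PMV

    PPD = 100 - 95 * exp(-(0.03353 PMV^4 + 0.2179 PMV^2))

with a minimum of 5 % at PMV = 0.  The comfort zone is -0.5 <= PMV <= +0.5
(closed interval).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: metabolic unit, W/m^2 of body surface
MET_W_M2 = 58.15
#: clothing insulation unit, m^2 K / W
CLO_M2K_W = 0.155

ASHRAE_LABELS = {
    -3: "cold", -2: "cool", -1: "slightly cool", 0: "neutral",
    +1: "slightly warm", +2: "warm", +3: "hot",
}


class ConvergenceError(RuntimeError):
    """Clothing-surface-temperature iteration failed; carries last iterate."""

    def __init__(self, last_tcl: float):
        super().__init__(f"clothing temperature iteration did not converge "
                         f"(last iterate {last_tcl:.4f} degC)")
        self.last_tcl = last_tcl


@dataclass(frozen=True)
class ThermalInput:
    """Environmental and personal inputs to the PMV model."""

    air_temperature: float          # degC
    air_velocity: float             # m/s
    relative_humidity: float        # %
    clothing: float = 0.7           # clo
    metabolic_rate: float = 1.0     # met
    mean_radiant_temperature: float | None = None  # degC; default = t_air

    def __post_init__(self) -> None:
        vals = (self.air_temperature, self.air_velocity,
                self.relative_humidity, self.clothing, self.metabolic_rate)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("non-finite thermal input")
        if self.air_velocity < 0:
            raise ValueError("air velocity must be >= 0")
        if not 0 <= self.relative_humidity <= 100:
            raise ValueError("relative humidity must be in [0, 100] %")
        if self.clothing <= 0 or self.metabolic_rate <= 0:
            raise ValueError("clothing and metabolic rate must be positive")

    @property
    def t_r(self) -> float:
        t = self.mean_radiant_temperature
        return self.air_temperature if t is None else t

    def in_validity_envelope(self) -> bool:
        """Documented envelope: 10-30 degC, v < 1.5 m/s, <=1.5 clo, 0.8-4 met."""
        return (10.0 <= self.air_temperature <= 30.0
                and self.air_velocity < 1.5
                and self.clothing <= 1.5
                and 0.8 <= self.metabolic_rate <= 4.0)


@dataclass(frozen=True)
class ComfortScore:
    pmv: float
    ppd: float
    inputs: ThermalInput
    in_envelope: bool = True

    @property
    def in_zone(self) -> bool:
        return -0.5 <= self.pmv <= 0.5

    @property
    def label(self) -> str:
        return classify_comfort(self.pmv)[1]


def saturation_vapour_pressure(t_air: float) -> float:
    """Saturation water-vapour pressure in Pa (Antoine-type fit)."""
    return 1000.0 * math.exp(16.6536 - 4030.183 / (t_air + 235.0))


def pmv(inputs: ThermalInput, *, tol: float = 1e-5,
        max_iter: int = 150) -> float:
    """Predicted Mean Vote from the Fanger heat balance.

    Solves the clothing surface temperature by damped fixed-point iteration
    to |delta t_cl| < ``tol`` degC, then evaluates the thermal load L
    (metabolic heat minus evaporative, respiratory, radiative and convective
    losses) and PMV = (0.303 exp(-0.036 M) + 0.028) L.  Inputs outside the
    documented validity envelope are computed anyway with a warning.
    """
    if not inputs.in_validity_envelope():
        warnings.warn("thermal inputs outside the PMV validity envelope; "
                      "computing anyway", stacklevel=2)
    ta = inputs.air_temperature
    tr = inputs.t_r
    vel = inputs.air_velocity
    m = inputs.metabolic_rate * MET_W_M2     # W/m^2, external work = 0
    icl = inputs.clothing * CLO_M2K_W        # m^2 K / W
    pa = inputs.relative_humidity / 100.0 * saturation_vapour_pressure(ta)

    fcl = 1.0 + 1.29 * icl if icl <= 0.078 else 1.05 + 0.645 * icl
    hcf = 12.1 * math.sqrt(vel)              # forced convection
    taa, tra = ta + 273.0, tr + 273.0

    # damped fixed point on x = t_cl_abs / 100
    p1 = icl * fcl
    p2 = p1 * 3.96
    p3 = p1 * 100.0
    p4 = p1 * taa
    p5 = 308.7 - 0.028 * m + p2 * (tra / 100.0) ** 4
    xn = (taa + (35.5 - ta) / (3.5 * icl + 0.1)) / 100.0
    xf = xn
    hc = hcf
    for _ in range(max_iter):
        xf = (xf + xn) / 2.0
        hcn = 2.38 * abs(100.0 * xf - taa) ** 0.25  # natural convection
        hc = max(hcf, hcn)
        xn = (p5 + p4 * hc - p2 * xf ** 4) / (100.0 + p3 * hc)
        if abs(100.0 * (xn - xf)) < tol:
            break
    else:
        raise ConvergenceError(100.0 * xn - 273.0)
    tcl = 100.0 * xn - 273.0

    # heat losses, W/m^2
    hl_skin_diff = 3.05e-3 * (5733.0 - 6.99 * m - pa)
    hl_sweat = 0.42 * (m - MET_W_M2) if m > MET_W_M2 else 0.0
    hl_resp_lat = 1.7e-5 * m * (5867.0 - pa)
    hl_resp_dry = 0.0014 * m * (34.0 - ta)
    hl_rad = 3.96 * fcl * (xn ** 4 - (tra / 100.0) ** 4)
    hl_conv = fcl * hc * (tcl - ta)

    load = (m - hl_skin_diff - hl_sweat - hl_resp_lat
            - hl_resp_dry - hl_rad - hl_conv)
    return (0.303 * math.exp(-0.036 * m) + 0.028) * load


def ppd(pmv_value: float) -> float:
    """Predicted Percentage of Dissatisfied (%), an even function of PMV."""
    if not math.isfinite(pmv_value):
        raise ValueError("PMV must be finite")
    return 100.0 - 95.0 * math.exp(-(0.03353 * pmv_value ** 4
                                     + 0.2179 * pmv_value ** 2))


def comfort_score(inputs: ThermalInput) -> ComfortScore:
    """PMV + PPD bundle for one set of thermal inputs."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        v = pmv(inputs)
    return ComfortScore(pmv=v, ppd=ppd(v), inputs=inputs,
                        in_envelope=inputs.in_validity_envelope())


def classify_comfort(pmv_value: float) -> tuple[str, str]:
    """Comfort-zone membership and nearest ASHRAE scale label.

    Returns ``(zone, label)`` with zone 'in_zone' iff -0.5 <= PMV <= +0.5
    (closed bounds); the label is the nearest integer scale point, ties
    rounded away from zero, clamped to [-3, +3].
    """
    if not math.isfinite(pmv_value):
        raise ValueError("PMV must be finite")
    zone = "in_zone" if -0.5 <= pmv_value <= 0.5 else "out_of_zone"
    point = int(math.floor(abs(pmv_value) + 0.5)) * (1 if pmv_value >= 0 else -1)
    point = max(-3, min(3, point))
    return zone, ASHRAE_LABELS[point]


def summarize_environment(series: pd.DataFrame) -> pd.DataFrame:
    """Median and IQR per environmental variable.

    ``series`` must contain at least one of the columns temperature,
    humidity, velocity.  Quartiles use linear interpolation.  Returns a
    frame indexed by variable with columns ``median`` and ``iqr``.
    """
    cols = [c for c in ("temperature", "humidity", "velocity")
            if c in series.columns]
    if not cols or len(series) == 0:
        raise ValueError("empty environment series")
    rows = {}
    for c in cols:
        v = np.asarray(series[c], dtype=float)
        q25, q50, q75 = np.percentile(v, [25, 50, 75])
        rows[c] = {"median": q50, "iqr": q75 - q25}
    return pd.DataFrame(rows).T[["median", "iqr"]]
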