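"""GPU-energy accounting with exact uncertainty propagation.

Per-sample energy is the product of mean GPU power draw (W) and runtime per
sample (h).  Both carry measurement uncertainty, and the standard deviation
of the product of two independent quantities is propagated with the exact
variance-of-product formula

    sigma_E = sqrt((mu_t * sigma_P)**2 + (mu_P * sigma_t)**2
                   + (sigma_P * sigma_t)**2)

rather than the first-order approximation (which drops the last term).
Facility-scale projections multiply per-sample energy by head count and
days of daily inference, preserving the relative uncertainty.  The
embodied-nitrogen comparison converts wasted fertilizer N (applied N times
one minus the nitrogen use efficiency, NUE) into the electrical energy of
industrial N fixation, giving the offset context for model energy budgets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "EnergyQuantity",
    "FacilityScenario",
    "power_from_log",
    "energy",
    "scale_to_facility",
    "embodied_wasted_n",
    "offset_ratio",
    "energy_report",
]

# NVML reports power averaged over 1 s with +/-5 W accuracy; short runs use
# whichever is larger, the observed SD or this floor.
POWER_SIGMA_FLOOR_W = 5.0

_UNIT_BY_KIND = {"power": {"W"}, "time": {"h"}, "energy": {"Wh", "kWh"}}


@dataclass(frozen=True)
class EnergyQuantity:
    """A mean +/- SD power, time or energy value.

    Parameters
    ----------
    mean, sd : float
        Central value and its standard deviation (same unit).
    unit : str
        One of ``W`` (power), ``h`` (time), ``Wh``/``kWh`` (energy).
    kind : str
        ``power`` | ``time`` | ``energy``; must be consistent with ``unit``.
    """

    mean: float
    sd: float
    unit: str
    kind: str = field(default="")

    def __post_init__(self):
        kind = self.kind or {"W": "power", "h": "time", "Wh": "energy", "kWh": "energy"}.get(self.unit, "")
        object.__setattr__(self, "kind", kind)
        if self.kind not in _UNIT_BY_KIND:
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.unit not in _UNIT_BY_KIND[self.kind]:
            raise ValueError(f"unit {self.unit!r} inconsistent with kind {self.kind!r}")
        if self.mean < 0 or self.sd < 0:
            raise ValueError("mean and sd must be non-negative")

    @property
    def cv_percent(self) -> float:
        """Coefficient of variation in percent."""
        return 100.0 * self.sd / self.mean if self.mean else float("nan")

    def scale(self, factor: float) -> "EnergyQuantity":
        """Multiply by an exact (uncertainty-free) factor; relative SD preserved."""
        if factor < 0:
            raise ValueError("factor must be non-negative")
        return replace(self, mean=self.mean * factor, sd=self.sd * factor)

    def to(self, unit: str) -> "EnergyQuantity":
        if unit == self.unit:
            return self
        conv = {("Wh", "kWh"): 1e-3, ("kWh", "Wh"): 1e3}.get((self.unit, unit))
        if conv is None:
            raise ValueError(f"cannot convert {self.unit} -> {unit}")
        return EnergyQuantity(self.mean * conv, self.sd * conv, unit)

    def __format__(self, spec: str) -> str:
        spec = spec or ".3g"
        return f"{self.mean:{spec}} +/- {self.sd:{spec}} {self.unit}"


def power_from_log(log: pd.DataFrame, sigma_floor: float = POWER_SIGMA_FLOOR_W) -> EnergyQuantity:
    """Summarize a power log (columns ``timestamp``, ``watts``) into mean +/- SD.

    The SD floor mirrors the accuracy of 1-s-averaged NVML readings: when
    the observed SD over a short run is below ``sigma_floor`` (default 5 W),
    the floor is used instead.
    """
    watts = np.asarray(log["watts"], dtype=float)
    if watts.size == 0:
        raise ValueError("empty power log")
    sd = float(watts.std(ddof=0)) if watts.size > 1 else 0.0
    return EnergyQuantity(float(watts.mean()), max(sd, sigma_floor), "W")


def energy(power: EnergyQuantity, time: EnergyQuantity) -> EnergyQuantity:
    """Energy = power x time with exact product-variance propagation.

    ``sd`` is ``sqrt((mu_t sd_P)^2 + (mu_P sd_t)^2 + (sd_P sd_t)^2)``, exact
    for independent power and time (not the first-order approximation).
    """
    if power.kind != "power" or time.kind != "time":
        raise ValueError(f"expected (power, time), got ({power.kind}, {time.kind})")
    mu = power.mean * time.mean
    sd = math.sqrt(
        (time.mean * power.sd) ** 2
        + (power.mean * time.sd) ** 2
        + (power.sd * time.sd) ** 2
    )
    return EnergyQuantity(mu, sd, "Wh")


@dataclass(frozen=True)
class FacilityScenario:
    """A facility-scale projection scenario.

    Defaults describe a facility growing 10,000 lettuce heads over a 28-day
    grow-out, with global average nitrogen use efficiency (NUE) of 46% and
    industrial N-fixation intensity 9.7-13.9 kWh per kg N (average 11.11).
    ``tissue_n_g`` is the per-head accumulated tissue N in grams (mean, sd).
    """

    n_heads: int = 10_000
    n_days: int = 28
    tissue_n_g: tuple[float, float] = (0.383, 0.052)
    nue: float = 0.46
    fixation_kwh_per_kg: tuple[float, float, float] = (9.7, 11.11, 13.9)

    def __post_init__(self):
        if not (0 < self.nue <= 1):
            raise ValueError("NUE must be in (0, 1]")
        lo, avg, hi = self.fixation_kwh_per_kg
        if not (lo <= avg <= hi):
            raise ValueError("fixation intensity must satisfy low <= average <= high")
        if self.n_heads <= 0 or self.n_days <= 0:
            raise ValueError("n_heads and n_days must be positive")


def scale_to_facility(per_sample: EnergyQuantity, scenario: FacilityScenario | None = None) -> EnergyQuantity:
    """Total energy of daily inference on every head: E x n_heads x n_days."""
    scenario = scenario or FacilityScenario()
    if per_sample.kind != "energy":
        raise ValueError("per_sample must be an energy quantity")
    return per_sample.to("Wh").scale(scenario.n_heads * scenario.n_days)


def embodied_wasted_n(scenario: FacilityScenario | None = None) -> dict:
    """Applied and wasted fertilizer N for the scenario, and its embodied energy.

    applied = tissue N per head x n_heads / NUE
    wasted  = applied x (1 - NUE)            (= applied - accumulated tissue N)

    The relative uncertainty of the per-head tissue N carries through both.
    Embodied energy of the wasted N is reported at the low / average / high
    fixation intensities, as ``EnergyQuantity`` values in kWh (uncertainty
    from the wasted-N mass only; the intensity range is spanned explicitly).
    """
    scenario = scenario or FacilityScenario()
    mu_n, sd_n = scenario.tissue_n_g
    if mu_n <= 0:
        raise ValueError("tissue N must be positive")
    rel = sd_n / mu_n
    applied_kg = mu_n * scenario.n_heads / scenario.nue / 1000.0
    wasted_kg = applied_kg * (1.0 - scenario.nue)
    lo, avg, hi = scenario.fixation_kwh_per_kg
    embodied = {
        key: EnergyQuantity(wasted_kg * intensity, wasted_kg * rel * intensity, "kWh")
        for key, intensity in (("low", lo), ("average", avg), ("high", hi))
    }
    return {
        "applied_n_kg": (applied_kg, applied_kg * rel),
        "wasted_n_kg": (wasted_kg, wasted_kg * rel),
        "embodied_kwh": embodied,
    }


def offset_ratio(model_total: EnergyQuantity, embodied: EnergyQuantity) -> dict:
    """Compare model GPU energy with the embodied energy of wasted N.

    Returns the embodied/GPU ratio and GPU energy as a percentage of the
    embodied energy (both from unrounded means).
    """
    gpu = model_total.to("kWh").mean
    emb = embodied.to("kWh").mean
    if gpu <= 0 or emb <= 0:
        raise ValueError("energies must be positive")
    return {"embodied_over_gpu": emb / gpu, "gpu_percent_of_embodied": 100.0 * gpu / emb}


def energy_report(
    per_sample: dict[str, EnergyQuantity],
    scenario: FacilityScenario | None = None,
) -> pd.DataFrame:
    """Facility projection table for named models' per-sample inference energies.

    One row per model: per-sample Wh, monthly total Wh, and the share of the
    average-intensity embodied energy of wasted N that the total represents.
    """
    scenario = scenario or FacilityScenario()
    nitrogen = embodied_wasted_n(scenario)
    emb_avg = nitrogen["embodied_kwh"]["average"]
    rows = []
    for name, eq in per_sample.items():
        total = scale_to_facility(eq, scenario)
        ratio = offset_ratio(total, emb_avg)
        rows.append(
            {
                "model": name,
                "per_sample_Wh": eq.to("Wh").mean,
                "per_sample_sd_Wh": eq.to("Wh").sd,
                "total_Wh": total.mean,
                "total_sd_Wh": total.sd,
                "gpu_percent_of_embodied": ratio["gpu_percent_of_embodied"],
            }
        )
    return pd.DataFrame(rows).set_index("model")
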