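"""Synthetic depletion-experiment generator.

Emulates a pilot-scale hydroponic lettuce experiment: three fertilizer
treatments (100/50/25% solution strength) x three tanks each, nightly
overhead 10-channel multispectral imaging from 4 days after transplanting
(DAT), and destructive sampling of a fixed number of heads per tank on a
schedule of sampling days.  Fresh weight follows a logistic curve in DAT;
the treatment scales the asymptote and tissue nutrient concentrations
multiplicatively, tanks-within-treatment and plants-within-tank carry
lognormal random effects, and rendered pixels add Gaussian noise.  The
generated tables, image cubes and masks have the statistical structure the
downstream anomaly-detection and state-estimation tiers assume, so the
whole pipeline is testable without any real greenhouse data.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .vi import CHANNEL_NAMES, MSICube

__all__ = [
    "NUTRIENTS",
    "RESPONSE_VARIABLES",
    "STATE_COLUMNS",
    "ExperimentDesign",
    "GrowthModel",
    "Capture",
    "simulate_experiment",
    "channel_reflectance",
    "render_cube",
    "render_experiment",
    "Trajectories",
    "make_trajectories",
    "anova_ss",
    "logistic",
    "fit_logistic",
]

NUTRIENTS = ["N", "P", "K", "Ca", "Mg", "S"]
RESPONSE_VARIABLES = ["FW", "DM"] + NUTRIENTS
STATE_COLUMNS = [
    "plant_id", "tank_id", "treatment", "DAT",
    "FW_g", "DM_g", "N_pct", "P_pct", "K_pct", "Ca_pct", "Mg_pct", "S_pct",
]

RV_COLUMN = {rv: (f"{rv}_g" if rv in ("FW", "DM") else f"{rv}_pct") for rv in RESPONSE_VARIABLES}


@dataclass(frozen=True)
class ExperimentDesign:
    """Layout and schedule of the depletion experiment.

    Defaults mirror the pilot study: treatments T1/T2/T3 at 100/50/25%
    nutrient-solution strength in triplicate tanks, nightly imaging from
    4 to 26 DAT, and 5 heads per tank destructively sampled on DAT
    11, 14, 18, 21, 23, 25 and 26.
    """

    treatments: tuple[tuple[str, float], ...] = (("T1", 1.0), ("T2", 0.5), ("T3", 0.25))
    tanks_per_treatment: int = 3
    plants_per_tank: int = 40
    imaging_start: int = 4
    imaging_end: int = 26
    sampling_days: tuple[int, ...] = (11, 14, 18, 21, 23, 25, 26)
    samples_per_tank_per_day: int = 5
    seed: int = 0

    def __post_init__(self):
        for name, frac in self.treatments:
            if not (0 < frac <= 1):
                raise ValueError(f"fertilizer fraction for {name} must be in (0, 1]")
        bad = [d for d in self.sampling_days
               if not (self.imaging_start < d <= self.imaging_end)]
        if bad:
            raise ValueError(f"sampling days {bad} outside (imaging_start, imaging_end]")
        n_sampled = len(self.sampling_days) * self.samples_per_tank_per_day
        if n_sampled > self.plants_per_tank:
            raise ValueError(
                f"design infeasible: {n_sampled} destructive samples requested per tank "
                f"but only {self.plants_per_tank} plants available"
            )

    @property
    def dats(self) -> np.ndarray:
        return np.arange(self.imaging_start, self.imaging_end + 1)

    @property
    def tank_roster(self) -> pd.DataFrame:
        """One row per tank: tank_id, treatment, fertilizer_fraction."""
        rows = [
            {"tank_id": f"{name}-K{k + 1}", "treatment": name, "fertilizer_fraction": frac}
            for name, frac in self.treatments
            for k in range(self.tanks_per_treatment)
        ]
        return pd.DataFrame(rows)


# Per-channel affine reflectance link: value = base + b_n * nutrient_index
# + b_b * biomass_index.  Nutrient status raises NIR and green reflectance
# and deepens red/deep-red absorption (chlorophyll), so normalized
# differences like NDVI separate treatments by construction.
DEFAULT_REFLECTANCE_LINK: dict[str, tuple[float, float, float]] = {
    "blue": (0.06, -0.02, 0.00),
    "cyan": (0.07, -0.02, 0.00),
    "green": (0.12, 0.06, 0.02),
    "amber": (0.10, -0.03, 0.01),
    "red": (0.22, -0.15, -0.01),
    "deep_red": (0.20, -0.14, -0.01),
    "far_red": (0.30, 0.08, 0.04),
    "nir850": (0.35, 0.25, 0.08),
    "nir940": (0.33, 0.18, 0.05),
    "white": (0.20, 0.05, 0.03),
}


@dataclass(frozen=True)
class GrowthModel:
    """Generating model: logistic growth, depletion effects, random effects.

    Fresh weight of a plant in treatment with fertilizer fraction ``f`` is

        FW(t) = A * f**fw_depletion_exponent * u_tank * u_plant
                    / (1 + exp(-r (t - t0)))

    with lognormal tank and plant effects ``u``.  The default depletion
    exponent 0.342 calibrates the half-strength treatment to ~78.9% of
    control fresh weight at the end of the grow-out (an anchor from the
    physical experiment, not a fitted value).  Tissue concentrations start
    at per-nutrient baselines (% of dry matter), are scaled by
    ``f**depletion_exponent`` per nutrient, and dilute linearly over the
    grow-out.  The reflectance link maps (nutrient index, biomass index)
    affinely to each channel's reflectance.
    """

    fw_asymptote_g: float = 250.0
    fw_rate: float = 0.35
    fw_midpoint_dat: float = 16.0
    fw_depletion_exponent: float = 0.342
    dm_fraction: float = 0.05
    nutrient_baseline_pct: dict[str, float] = field(
        default_factory=lambda: {"N": 5.3, "P": 0.6, "K": 7.0, "Ca": 1.2, "Mg": 0.35, "S": 0.25}
    )
    nutrient_depletion_exponent: dict[str, float] = field(
        default_factory=lambda: {"N": 0.10, "P": 0.12, "K": 0.10, "Ca": 0.08, "Mg": 0.05, "S": 0.08}
    )
    nutrient_decline_frac: float = 0.10
    tank_sd: float = 0.03
    residual_sd: float = 0.08
    conc_residual_sd: float = 0.02
    reflectance_link: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_REFLECTANCE_LINK)
    )
    pixel_noise_sd: float = 0.01
    background: float = 0.02

    def __post_init__(self):
        for sd in (self.tank_sd, self.residual_sd, self.conc_residual_sd, self.pixel_noise_sd):
            if sd < 0:
                raise ValueError("standard deviations must be non-negative")
        missing = set(CHANNEL_NAMES) - set(self.reflectance_link)
        if missing:
            raise ValueError(f"reflectance link missing channels: {sorted(missing)}")


def logistic(t, asymptote, rate, midpoint):
    """Logistic growth curve A / (1 + exp(-r (t - t0)))."""
    return asymptote / (1.0 + np.exp(-rate * (np.asarray(t, dtype=float) - midpoint)))


def fit_logistic(dat, fw, p0=(200.0, 0.3, 15.0)):
    """Least-squares fit of the logistic curve; returns (asymptote, rate, midpoint)."""
    popt, _ = curve_fit(logistic, np.asarray(dat, float), np.asarray(fw, float),
                        p0=p0, maxfev=20000)
    return tuple(popt)


# Fixed offsets deriving independent per-stage RNG streams from one master
# seed, so e.g. re-rendering images does not perturb the growth draws.
_STREAM_OFFSETS = {"growth": 0, "sampling": 1, "render": 2, "downstream": 3}


def stream_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng((seed * 8 + _STREAM_OFFSETS[stage]) % (2**31))


def simulate_experiment(
    design: ExperimentDesign, model: GrowthModel | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate plant states and the destructive-sampling ground truth.

    Returns
    -------
    states : DataFrame
        One row per living plant per DAT (``STATE_COLUMNS``).  A sampled
        plant emits no states after its sampling day.
    ground_truth : DataFrame
        One row per destructively sampled plant (same columns), exactly
        ``samples_per_tank_per_day`` per (tank, sampling day).
    """
    model = model or GrowthModel()
    rng = stream_rng(design.seed, "growth")
    samp_rng = stream_rng(design.seed, "sampling")

    roster = design.tank_roster
    dats = design.dats
    progress = (dats - design.imaging_start) / max(design.imaging_end - design.imaging_start, 1)

    records = []
    gt_records = []
    for _, tank in roster.iterrows():
        frac = tank["fertilizer_fraction"]
        u_tank = math.exp(rng.normal(0.0, model.tank_sd))
        plant_ids = [f"{tank['tank_id']}-P{p + 1:02d}" for p in range(design.plants_per_tank)]
        u_plants = np.exp(rng.normal(0.0, model.residual_sd, size=len(plant_ids)))
        conc_noise = np.exp(
            rng.normal(0.0, model.conc_residual_sd, size=(len(plant_ids), len(NUTRIENTS)))
        )
        # destructive sampling schedule: without replacement over the tank
        order = samp_rng.permutation(len(plant_ids))
        sample_day = np.full(len(plant_ids), np.iinfo(np.int64).max)
        k = 0
        for day in design.sampling_days:
            for _ in range(design.samples_per_tank_per_day):
                sample_day[order[k]] = day
                k += 1

        asym = model.fw_asymptote_g * frac**model.fw_depletion_exponent * u_tank
        for i, pid in enumerate(plant_ids):
            fw = logistic(dats, asym * u_plants[i], model.fw_rate, model.fw_midpoint_dat)
            dm = model.dm_fraction * fw
            conc = {}
            for j, nut in enumerate(NUTRIENTS):
                base = model.nutrient_baseline_pct[nut]
                mult = frac ** model.nutrient_depletion_exponent[nut]
                conc[nut] = base * mult * (1.0 - model.nutrient_decline_frac * progress) * conc_noise[i, j]
            alive = dats <= sample_day[i]
            for t_idx in np.flatnonzero(alive):
                row = {
                    "plant_id": pid, "tank_id": tank["tank_id"],
                    "treatment": tank["treatment"], "DAT": int(dats[t_idx]),
                    "FW_g": float(fw[t_idx]), "DM_g": float(dm[t_idx]),
                }
                for nut in NUTRIENTS:
                    row[f"{nut}_pct"] = float(conc[nut][t_idx])
                records.append(row)
                if dats[t_idx] == sample_day[i]:
                    gt_records.append(dict(row))

    states = pd.DataFrame(records, columns=STATE_COLUMNS)
    ground_truth = pd.DataFrame(gt_records, columns=STATE_COLUMNS)
    return states, ground_truth


def channel_reflectance(model: GrowthModel, state: pd.Series | dict) -> dict[str, float]:
    """Noise-free link-predicted reflectance per channel for one plant state."""
    nidx = float(state["N_pct"]) / model.nutrient_baseline_pct["N"]
    bidx = float(state["FW_g"]) / model.fw_asymptote_g
    out = {}
    for ch in CHANNEL_NAMES:
        base, b_n, b_b = model.reflectance_link[ch]
        out[ch] = max(base + b_n * nidx + b_b * bidx, 0.0)
    return out


@dataclass
class Capture:
    """One rendered overhead capture: the cube plus per-plant masks and metadata."""

    dat: int
    capture_index: int
    cube: MSICube
    masks: dict[str, np.ndarray]
    plant_meta: pd.DataFrame  # plant_id, tank_id, treatment


def render_cube(
    states_at_dat: pd.DataFrame,
    model: GrowthModel | None = None,
    size: tuple[int, int] = (200, 320),
    rng: np.random.Generator | None = None,
) -> tuple[MSICube, dict[str, np.ndarray]]:
    """Render one multispectral capture of the given plants at one DAT.

    Plants are placed on a regular grid as quasi-circular rosettes whose
    radius grows with the square root of fresh weight (area ~ FW); channel
    intensities inside each mask follow the reflectance link plus Gaussian
    pixel noise; masks are disjoint boolean regions.
    """
    model = model or GrowthModel()
    rng = rng or np.random.default_rng(0)
    n = len(states_at_dat)
    if n == 0:
        raise ValueError("need at least one visible plant")
    h, w = size
    cols = max(1, math.ceil(math.sqrt(n * w / h)))
    rows = math.ceil(n / cols)
    cell_h, cell_w = h // rows, w // cols
    r_max = min(cell_h, cell_w) // 2 - 1
    if r_max < 2:
        raise ValueError(f"image size {size} too small to place {n} plants")

    cube = np.full((len(CHANNEL_NAMES), h, w), model.background, dtype=np.float64)
    if model.pixel_noise_sd > 0:
        cube += rng.normal(0.0, model.pixel_noise_sd, size=cube.shape)
    yy, xx = np.mgrid[0:h, 0:w]
    masks: dict[str, np.ndarray] = {}
    for i, (_, state) in enumerate(states_at_dat.iterrows()):
        cy = (i // cols) * cell_h + cell_h // 2
        cx = (i % cols) * cell_w + cell_w // 2
        bidx = float(state["FW_g"]) / model.fw_asymptote_g
        radius = int(np.clip(round(r_max * math.sqrt(max(bidx, 0.0))), 2, r_max))
        mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
        refl = channel_reflectance(model, state)
        for c, ch in enumerate(CHANNEL_NAMES):
            noise = rng.normal(0.0, model.pixel_noise_sd, size=int(mask.sum())) \
                if model.pixel_noise_sd > 0 else 0.0
            cube[c][mask] = refl[ch] + noise
        masks[str(state["plant_id"])] = mask
    msi = MSICube(data=cube, metadata={"dat": int(states_at_dat["DAT"].iloc[0])})
    return msi, masks


def render_experiment(
    states: pd.DataFrame,
    model: GrowthModel | None = None,
    size: tuple[int, int] = (200, 320),
    captures_per_night: int = 8,
    seed: int = 0,
    tanks: list[str] | None = None,
):
    """Yield one :class:`Capture` per (tank, night, capture index).

    Eight captures per night mirror the hourly acquisition schedule
    beginning at 10 pm; reduce ``captures_per_night`` for desk-scale runs.
    """
    model = model or GrowthModel()
    rng = stream_rng(seed, "render")
    tank_ids = tanks or sorted(states["tank_id"].unique())
    for tank_id in tank_ids:
        tank_states = states[states["tank_id"] == tank_id]
        for dat in sorted(tank_states["DAT"].unique()):
            night = tank_states[tank_states["DAT"] == dat]
            for cap in range(captures_per_night):
                cube, masks = render_cube(night, model, size, rng)
                cube.metadata.update({"tank_id": tank_id, "capture_index": cap})
                yield Capture(
                    dat=int(dat), capture_index=cap, cube=cube, masks=masks,
                    plant_meta=night[["plant_id", "tank_id", "treatment"]].reset_index(drop=True),
                )


class Trajectories:
    """Per-plant dense time series of every feature column, with truncation.

    Built from a table indexed by (plant, DAT).  A destructively sampled
    plant's trajectory ends at its sampling day; interior missing days are
    filled by linear interpolation (leading/trailing gaps are not), and
    plants with fewer than two observations are dropped with a warning.
    """

    def __init__(self, table: pd.DataFrame, feature_columns: list[str] | None = None):
        meta_cols = {"plant_id", "tank_id", "treatment", "DAT"}
        self.feature_columns = feature_columns or [
            c for c in table.columns if c not in meta_cols
        ]
        self.treatment: dict[str, str] = {}
        self.series: dict[str, pd.DataFrame] = {}
        for pid, grp in table.groupby("plant_id", sort=True):
            grp = grp.sort_values("DAT")
            if len(grp) < 2:
                warnings.warn(f"plant {pid} has fewer than 2 observations; excluded")
                continue
            lo, hi = int(grp["DAT"].min()), int(grp["DAT"].max())
            dense = (
                grp.set_index("DAT")[self.feature_columns]
                .reindex(range(lo, hi + 1))
                .interpolate(method="linear", limit_area="inside")
            )
            self.series[str(pid)] = dense
            self.treatment[str(pid)] = str(grp["treatment"].iloc[0])

    @property
    def plant_ids(self) -> list[str]:
        return sorted(self.series)

    def windows(self, feature: str, length: int, start_dat: int = 4):
        """Fixed-length windows of one feature, for plants that fully cover it.

        Returns (values array of shape (n, length), plant_ids, treatments);
        plants whose trajectory does not span [start_dat, start_dat+length-1]
        (e.g. sampled too early) are excluded.  Plant order is ascending id.
        """
        if length < 2:
            raise ValueError("window length must be >= 2")
        span = range(start_dat, start_dat + length)
        vals, pids, treats = [], [], []
        for pid in self.plant_ids:
            s = self.series[pid]
            if span[0] in s.index and span[-1] in s.index:
                window = s.loc[list(span), feature].to_numpy()
                if not np.isnan(window).any():
                    vals.append(window)
                    pids.append(pid)
                    treats.append(self.treatment[pid])
        if not vals:
            return np.empty((0, length)), [], []
        return np.vstack(vals), pids, treats


def make_trajectories(table: pd.DataFrame, feature_columns: list[str] | None = None) -> Trajectories:
    """Build per-plant trajectories with destructive truncation from a feature table."""
    return Trajectories(table, feature_columns)


def anova_ss(values, groups) -> tuple[float, float]:
    """One-way ANOVA sum-of-squares decomposition: (between, within).

    Plain arithmetic over group means; used to verify that the generator's
    treatment effect dominates the variance of simulated fresh weight.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    grand = values.mean()
    between = within = 0.0
    for g in np.unique(groups):
        sub = values[groups == g]
        between += len(sub) * (sub.mean() - grand) ** 2
        within += ((sub - sub.mean()) ** 2).sum()
    return float(between), float(within)
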