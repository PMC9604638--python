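"""Synthetic asthma-cohort generator.

The study data this package targets — indoor air-quality streams, twice-daily
peak-flow diaries and 30-minute activity diaries for a small adult asthma
cohort — are not publicly shareable, so every downstream stage is exercised
on synthetic patients with the same statistical structure:

* pollutant dynamics: per-space mean-reverting (Ornstein–Uhlenbeck-style)
  fluctuations around a slowly drifting daily base level, with
  activity-linked additive pulses (cooking raises kitchen PM2.5, occupancy
  raises CO2), sampled on a 60 s or 120 s sensor grid;
* activity diaries tiling each day in 30-minute slots over three home
  spaces (bedroom, living room, kitchen);
* morning PEFR with a patient-specific baseline, an AR(1) persistence term,
  a linear response to the previous 24 h aggregated exposures, and Gaussian
  noise — so classification and quantile models have recoverable signal;
* cohort calibration matching the study population: 19 patients, 118–212
  diary days (mean ≈ 154), median morning PEFR ≈ 373 L/min, median daily
  PM2.5 ≈ 36 µg/m³ and CO2 ≈ 890 ppm.

Everything is driven by one integer seed; identical configuration and seed
reproduce bit-identical streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import json

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .exposure import EXERTION_ACTIVITIES, DEFAULT_REST_RATE

__all__ = ["CohortConfig", "SyntheticPatient", "simulate_patient", "simulate_cohort", "write_cohort"]

SPACES = ("bedroom", "living", "kitchen")
SLOT_MIN = 30
SLOTS_PER_DAY = 48
AM_SLOT = 14  # 07:00, the morning PEFR measurement time
STUDY_START = pd.Timestamp("2017-11-01")

#: long-run daily-mean targets per variable (µg/m³, ppm, °C, %RH)
_BASE_LEVELS = {"pm25": 34.0, "co2": 800.0, "temperature": 22.4, "humidity": 32.7}
_DAY_AR = {"pm25": 0.55, "co2": 0.5, "temperature": 0.7, "humidity": 0.6}
_DAY_SD = {"pm25": 14.0, "co2": 60.0, "temperature": 1.2, "humidity": 4.5}
_OU_SD = {"pm25": 6.0, "co2": 40.0, "temperature": 0.5, "humidity": 2.0}
_SPACE_OFFSET = {
    "pm25": {"bedroom": -3.0, "living": 0.0, "kitchen": 5.0},
    "co2": {"bedroom": 20.0, "living": 0.0, "kitchen": -10.0},
    "temperature": {"bedroom": -0.5, "living": 0.0, "kitchen": 0.5},
    "humidity": {"bedroom": 1.0, "living": 0.0, "kitchen": 2.0},
}
#: fraction of a kitchen cooking pulse carried into other rooms
_PM_SPILL = {"kitchen": 1.0, "living": 0.5, "bedroom": 0.25}


class ConfigurationError(ValueError):
    pass


def _default_effects() -> Dict[str, float]:
    # ΔPEFR (L/min) per unit of centered daily exposure
    return {
        "pm25_exposure": -1.5,  # per µg inhaled-equivalent dose unit
        "co2_mean": -0.05,  # per ppm
        "temp_mean": 1.5,  # per °C (warmer indoor air is protective here)
        "rh_mean": -0.5,  # per % RH
    }


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition knobs for the synthetic cohort."""

    n_patients: int = 19
    days_range: Tuple[int, int] = (118, 212)
    mean_days: float = 154.0
    sensor_interval: int = 120  # seconds; the deployed units logged at 60–120 s
    pefr_baseline_median: float = 373.3
    pefr_between_sd: float = 50.0
    ar_coef: float = 0.3
    exposure_effect_sizes: Mapping[str, float] = field(default_factory=_default_effects)
    noise_sd: float = 20.0
    #: dose-response convexity: the PM2.5 effect slope is multiplied by this
    #: factor above the reference dose (threshold-like response shared by the
    #: whole cohort; 1.0 makes the response purely linear); the hinge term is
    #: centered so it does not shift the patient's median PEFR
    pm25_hinge_factor: float = 2.0
    #: humid-air potentiation of the particulate effect: the PM2.5 effect is
    #: scaled by (1 + synergy * (RH - ref)/5), a multiplicative interaction
    #: shared by the whole cohort; 0.0 disables it
    pm25_rh_synergy: float = 4.0
    risk_quantile: float = 0.2
    missing_sensor_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        if self.days_range[0] < 2 or self.days_range[1] < self.days_range[0]:
            raise ConfigurationError("days_range must be increasing with min >= 2")
        if self.sensor_interval not in (60, 120):
            raise ConfigurationError("sensor_interval must be 60 or 120 seconds")
        if not 0 < self.risk_quantile < 1:
            raise ConfigurationError("risk_quantile must be in (0, 1)")
        if not 0 <= self.missing_sensor_fraction < 1:
            raise ConfigurationError("missing_sensor_fraction must be in [0, 1)")
        if not self.days_range[0] <= self.mean_days <= self.days_range[1]:
            raise ConfigurationError("mean_days must lie inside days_range")


@dataclass
class SyntheticPatient:
    """One patient's generated streams, in the package's CSV schemas."""

    patient_id: str
    air_quality: pd.DataFrame  # timestamp, space_id, pm25, co2, temperature, humidity
    pefr_diary: pd.DataFrame  # date, am_pefr, pm_pefr
    activity_diary: pd.DataFrame  # start, end, activity_type, space_id
    covariates: Dict[str, float]


def _draw_n_days(cfg: CohortConfig, rng: np.random.Generator) -> int:
    """Day count from a Beta law scaled to days_range with mean ``mean_days``."""
    lo, hi = cfg.days_range
    if hi == lo:
        return int(lo)
    mu = (cfg.mean_days - lo) / (hi - lo)
    a = 2.0
    b = a * (1 - mu) / mu
    return int(round(lo + (hi - lo) * rng.beta(a, b)))


def _draw_covariates(rng: np.random.Generator) -> Dict[str, float]:
    return {
        "age": int(rng.integers(34, 84)),
        "sex": int(rng.integers(0, 2)),  # 0 = female, 1 = male
        "bmi": float(np.round(rng.normal(24.0, 3.0), 1)),
        "cooking_level": int(rng.integers(1, 8)),  # 1 = every day .. 7 = none
        "road_level": int(rng.integers(1, 6)),
        "income_level": int(rng.integers(1, 10)),
    }


def _daily_activity_slots(
    rng: np.random.Generator, cook_prob: float
) -> Tuple[List[str], List[str], np.ndarray]:
    """One day's 48 slot assignments: (activity, space) per slot.

    Returns (activities, spaces, cooking-slot indicator).
    """
    act = ["rest"] * SLOTS_PER_DAY
    spc = ["living"] * SLOTS_PER_DAY
    for s in range(0, 14):  # 00:00–07:00 sleep in bedroom
        act[s], spc[s] = "sleep", "bedroom"
    for s in range(45, SLOTS_PER_DAY):  # 22:30–24:00
        act[s], spc[s] = "sleep", "bedroom"
    # candidate meal slots: breakfast 07:30, lunch ~12:00, dinner ~18:00
    meals = [15, int(rng.integers(24, 26)), int(rng.integers(36, 38))]
    cooking = np.zeros(SLOTS_PER_DAY, dtype=bool)
    for s in meals:
        if rng.random() < cook_prob:
            act[s], spc[s] = "cooking", "kitchen"
            cooking[s] = True
    # a couple of housework slots at random daytime positions
    for s in rng.choice(np.arange(16, 44), size=rng.integers(1, 4), replace=False):
        if act[s] == "rest":
            act[s], spc[s] = "housework", "living"
    return act, spc, cooking


def _ou(noise: np.ndarray, phi: float) -> np.ndarray:
    """Mean-zero AR(1)/discretised OU path driven by ``noise``."""
    return lfilter([1.0], [1.0, -phi], noise)


def _simulate_sensor_streams(
    cfg: CohortConfig,
    rng: np.random.Generator,
    n_days: int,
    act_space: np.ndarray,
    cooking: np.ndarray,
) -> Dict[str, Dict[str, np.ndarray]]:
    """Per-space sensor traces on the sensor grid.

    ``act_space`` gives the occupied space per 30-min slot (length 48*n_days);
    ``cooking`` flags cooking slots.
    """
    per_day = 86400 // cfg.sensor_interval
    n = n_days * per_day
    steps_per_slot = per_day // SLOTS_PER_DAY
    t_frac = (np.arange(n) % per_day) / per_day  # time of day in [0,1)
    slot_of_step = (np.arange(n) // steps_per_slot).astype(int)

    phi_step = np.exp(-cfg.sensor_interval / 3600.0)  # 1 h relaxation
    out: Dict[str, Dict[str, np.ndarray]] = {v: {} for v in _BASE_LEVELS}

    # day-level base drift, shared across spaces
    base_day: Dict[str, np.ndarray] = {}
    for var in _BASE_LEVELS:
        innov = rng.normal(0.0, _DAY_SD[var] * np.sqrt(1 - _DAY_AR[var] ** 2), n_days)
        base_day[var] = _BASE_LEVELS[var] + _ou(innov, _DAY_AR[var])
    day_of_step = np.arange(n) // per_day

    # cooking pulse input on the sensor grid (kitchen-origin PM2.5)
    pulse_in = np.zeros(n)
    cook_steps = np.flatnonzero(cooking[slot_of_step] & (np.arange(n) % steps_per_slot == 0))
    if cook_steps.size:
        pulse_in[cook_steps] = rng.uniform(60.0, 140.0, cook_steps.size)
    decay = np.exp(-cfg.sensor_interval / (20 * 60.0))  # ~20 min decay
    pm_pulse = lfilter([1.0], [1.0, -decay], pulse_in)

    # occupancy-driven CO2 forcing per space
    co2_decay = np.exp(-cfg.sensor_interval / (40 * 60.0))
    occupied_space = act_space[slot_of_step]

    diurnal = {
        "pm25": 3.0 * np.sin(2 * np.pi * (t_frac - 0.3)),
        "co2": 30.0 * np.sin(2 * np.pi * (t_frac - 0.05)),
        "temperature": 1.0 * np.sin(2 * np.pi * (t_frac - 0.35)),
        "humidity": 2.0 * np.sin(2 * np.pi * (t_frac + 0.2)),
    }

    for space in SPACES:
        occ = (occupied_space == space).astype(float)
        co2_forcing = lfilter([1.0], [1.0, -co2_decay], occ)
        co2_occup = co2_forcing * 220.0 * (1 - co2_decay)
        for var in _BASE_LEVELS:
            ou_noise = rng.normal(0.0, _OU_SD[var] * np.sqrt(1 - phi_step**2), n)
            x = (
                base_day[var][day_of_step]
                + _SPACE_OFFSET[var][space]
                + diurnal[var]
                + _ou(ou_noise, phi_step)
            )
            if var == "pm25":
                x = x + _PM_SPILL[space] * pm_pulse
                x = np.clip(x, 0.5, None)
            elif var == "co2":
                x = x + co2_occup
                x = np.clip(x, 400.0, None)
            elif var == "humidity":
                x = np.clip(x, 3.0, 97.0)
            out[var][space] = x
    return out


def _window_features(
    cfg: CohortConfig,
    streams: Dict[str, Dict[str, np.ndarray]],
    act_space: np.ndarray,
    activities: List[str],
    n_days: int,
) -> pd.DataFrame:
    """Generator-internal daily exposures over [07:00 d, 07:00 d+1).

    Row d here feeds PEFR on day d+1; slot-level means stand in for the
    minute-level aggregation the exposure module performs on the emitted
    streams (the two agree closely because within-slot variation is smooth).
    """
    per_day = 86400 // cfg.sensor_interval
    steps_per_slot = per_day // SLOTS_PER_DAY
    n_slots = n_days * SLOTS_PER_DAY

    # slot means per variable/space
    slot_mean = {
        var: {
            s: streams[var][s].reshape(n_slots, steps_per_slot).mean(axis=1)
            for s in SPACES
        }
        for var in streams
    }
    space_idx = act_space  # occupied space per slot
    rates = np.array(
        [
            DEFAULT_REST_RATE * (2.0 if a in EXERTION_ACTIVITIES else 1.0)
            for a in activities
        ]
    )
    pm_occ = np.empty(n_slots)
    for s in SPACES:
        mask = space_idx == s
        pm_occ[mask] = slot_mean["pm25"][s][mask]
    dose_slot = pm_occ * rates / 60.0 * SLOT_MIN

    rows = []
    for d in range(n_days - 1):
        sl = slice(d * SLOTS_PER_DAY + AM_SLOT, (d + 1) * SLOTS_PER_DAY + AM_SLOT)
        rows.append(
            {
                "pm25_exposure": float(dose_slot[sl].sum()),
                "co2_mean": float(np.mean([slot_mean["co2"][s][sl].mean() for s in SPACES])),
                "temp_mean": float(
                    np.mean([slot_mean["temperature"][s][sl].mean() for s in SPACES])
                ),
                "rh_mean": float(np.mean([slot_mean["humidity"][s][sl].mean() for s in SPACES])),
            }
        )
    return pd.DataFrame(rows)


#: exposure reference points; effects are applied to (X - reference)
_EFFECT_REF = {"pm25_exposure": 10.0, "co2_mean": 900.0, "temp_mean": 22.4, "rh_mean": 33.0}


def simulate_patient(
    config: CohortConfig,
    patient_id: str,
    *,
    rng: Optional[np.random.Generator] = None,
    baseline: Optional[float] = None,
) -> SyntheticPatient:
    """Generate one patient's sensor, diary and PEFR streams.

    Next-day morning PEFR is baseline + AR(1) persistence + a linear
    response to the previous 24 h aggregated exposures + Gaussian noise;
    the exposures derive from the same sensor streams the patient emits, so
    the downstream feature builder recovers the generating signal.
    """
    if not isinstance(config, CohortConfig):
        raise ConfigurationError("config must be a CohortConfig")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, _pid_key(patient_id)]))
    n_days = _draw_n_days(config, rng)
    cov = _draw_covariates(rng)
    if baseline is None:
        baseline = config.pefr_baseline_median + config.pefr_between_sd * rng.standard_normal()

    # activity diary: 48 slots/day; cooking probability from the covariate level
    cook_prob = float(np.clip(1.05 - 0.15 * cov["cooking_level"], 0.05, 0.95))
    acts: List[str] = []
    spcs: List[str] = []
    cooking = np.zeros(n_days * SLOTS_PER_DAY, dtype=bool)
    for d in range(n_days):
        a, s, c = _daily_activity_slots(rng, cook_prob)
        acts.extend(a)
        spcs.extend(s)
        cooking[d * SLOTS_PER_DAY : (d + 1) * SLOTS_PER_DAY] = c
    act_space = np.array(spcs)

    streams = _simulate_sensor_streams(config, rng, n_days, act_space, cooking)
    feats = _window_features(config, streams, act_space, acts, n_days)

    # PEFR: baseline + random effect already folded into `baseline`
    am = np.empty(n_days)
    am[0] = baseline + rng.normal(0.0, config.noise_sd)
    # centering the convex hinge term keeps the median PEFR at baseline
    hinge_gain = config.exposure_effect_sizes.get("pm25_exposure", 0.0) * (
        config.pm25_hinge_factor - 1.0
    )
    if n_days > 1:
        pm_excess = np.maximum(feats["pm25_exposure"] - _EFFECT_REF["pm25_exposure"], 0.0)
        pm_excess = pm_excess - pm_excess.mean()
    beta_pm = config.exposure_effect_sizes.get("pm25_exposure", 0.0)
    for d in range(1, n_days):
        x = feats.iloc[d - 1]
        effect = sum(
            beta * (x[var] - _EFFECT_REF[var])
            for var, beta in config.exposure_effect_sizes.items()
        )
        effect += hinge_gain * pm_excess.iloc[d - 1]
        # humid days potentiate the particulate response (multiplicative)
        effect += (
            beta_pm
            * (x["pm25_exposure"] - _EFFECT_REF["pm25_exposure"])
            * config.pm25_rh_synergy
            * (x["rh_mean"] - _EFFECT_REF["rh_mean"])
            / 5.0
        )
        am[d] = (
            baseline
            + config.ar_coef * (am[d - 1] - baseline)
            + effect
            + rng.normal(0.0, config.noise_sd)
        )
    pm = am + rng.normal(8.0, config.noise_sd / 2, n_days)
    am = np.round(np.clip(am, 60.0, None), 1)
    pm = np.round(np.clip(pm, 60.0, None), 1)

    dates = STUDY_START + pd.to_timedelta(np.arange(n_days), unit="D")
    pefr_diary = pd.DataFrame({"date": dates.normalize(), "am_pefr": am, "pm_pefr": pm})

    slot_starts = STUDY_START + pd.to_timedelta(np.arange(n_days * SLOTS_PER_DAY) * SLOT_MIN, "m")
    activity_diary = pd.DataFrame(
        {
            "start": slot_starts,
            "end": slot_starts + pd.Timedelta(minutes=SLOT_MIN),
            "activity_type": acts,
            "space_id": spcs,
        }
    )

    per_day = 86400 // config.sensor_interval
    ts = STUDY_START + pd.to_timedelta(np.arange(n_days * per_day) * config.sensor_interval, "s")
    parts = []
    for space in SPACES:
        parts.append(
            pd.DataFrame(
                {
                    "timestamp": ts,
                    "space_id": space,
                    "pm25": np.round(streams["pm25"][space], 2),
                    "co2": np.round(streams["co2"][space], 1),
                    "temperature": np.round(streams["temperature"][space], 2),
                    "humidity": np.round(streams["humidity"][space], 2),
                }
            )
        )
    air_quality = pd.concat(parts, ignore_index=True)
    if config.missing_sensor_fraction > 0:
        keep = rng.random(len(air_quality)) >= config.missing_sensor_fraction
        air_quality = air_quality.loc[keep].reset_index(drop=True)
    air_quality = air_quality.sort_values(["timestamp", "space_id"], kind="stable").reset_index(
        drop=True
    )

    return SyntheticPatient(
        patient_id=patient_id,
        air_quality=air_quality,
        pefr_diary=pefr_diary,
        activity_diary=activity_diary,
        covariates=cov,
    )


def _pid_key(patient_id: str) -> int:
    return abs(hash_str(patient_id)) % (2**31)


def hash_str(s: str) -> int:
    """Deterministic (non-salted) string hash for seed derivation."""
    h = 2166136261
    for ch in s.encode():
        h = (h ^ ch) * 16777619 % (2**32)
    return h


def simulate_cohort(config: CohortConfig) -> List[SyntheticPatient]:
    """Generate ``config.n_patients`` patients sharing population structure.

    Effect directions and magnitudes are shared across the cohort (so
    pooling other patients' data carries transferable signal) while each
    patient gets an independent PEFR baseline, covariates and streams.
    A single-patient cohort is valid but leaves nothing to pool from.
    """
    if config.n_patients == 1:
        import warnings

        warnings.warn("cohort of one: pooled data excluding the target is empty")
    patients = []
    for i in range(config.n_patients):
        pid = f"SP-{i + 1:03d}"
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, i]))
        patients.append(simulate_patient(config, pid, rng=rng))
    return patients


def write_cohort(patients: Sequence[SyntheticPatient], out_dir: str | Path) -> Path:
    """Write per-patient CSVs plus a cohort manifest; returns the root dir."""
    root = Path(out_dir)
    root.mkdir(parents=True, exist_ok=True)
    manifest = {"patients": []}
    cov_rows = []
    for p in patients:
        pdir = root / p.patient_id
        pdir.mkdir(exist_ok=True)
        p.air_quality.to_csv(pdir / "air_quality.csv", index=False)
        p.pefr_diary.to_csv(pdir / "pefr.csv", index=False)
        p.activity_diary.to_csv(pdir / "activities.csv", index=False)
        cov_rows.append({"patient_id": p.patient_id, **p.covariates})
        manifest["patients"].append(
            {"patient_id": p.patient_id, "n_days": int(len(p.pefr_diary))}
        )
    pd.DataFrame(cov_rows).to_csv(root / "covariates.csv", index=False)
    (root / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return root
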