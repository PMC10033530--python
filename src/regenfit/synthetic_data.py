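"""Seeded synthetic cohorts emulating the sex-by-diet resection study.

No per-animal measurement tables are publicly deposited for the rat study
this package models, so every downstream stage is exercised on synthetic
cohorts that reproduce the study design: male and female rats on chronic
ethanol, isocaloric carbohydrate control, or chow diets, measured at -24, 0,
10, 24, 48, 72, 96 h, 1 week and 2 weeks around a 70% PHx, with per-animal
missingness and an at-least-five-volume-measurements eligibility floor.

Group-level 1-week volume recovery and the 10 h portal-flow anchors use the
study's printed means and standard deviations (e.g. ethanol-fed males
recover to 65.93% +- 5.91% of the pre-surgery volume at 1 week, controls to
~90-97%).  Each animal draws a recovery plateau from its group distribution
and follows a single-exponential rise from the 30% remnant, anchored so the
1-week value equals the drawn plateau and held flat to 2 weeks; observation
noise is added on top.  Ancillary measures (portal and hepatic-artery flow,
stiffness, oxygen saturation, body mass) are drawn around anchor curves
interpolated between printed group statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .likelihood_fit import AnimalRecord, MEASURES, MIN_MEASUREMENTS

__all__ = [
    "GroupProfile",
    "CohortSpec",
    "CohortError",
    "default_profiles",
    "default_cohort_spec",
    "recovery_curve",
    "generate_cohort",
    "write_cohort",
]

logger = logging.getLogger(__name__)

#: the study's measurement schedule (hours relative to PHx)
STUDY_TIMES = (-24.0, 0.0, 10.0, 24.0, 48.0, 72.0, 96.0, 168.0, 336.0)
REMNANT_VOLUME = 0.30
PLATEAU_BOUNDS = (0.30, 1.20)


class CohortError(ValueError):
    """Raised when a cohort cannot satisfy its own specification."""


@dataclass
class GroupProfile:
    """Recovery and ancillary-measure statistics for one sex-by-diet group.

    ``plateau_mean``/``plateau_sd`` describe the 1-week relative volume;
    ``tau_hours`` is the recovery time constant of the exponential rise.
    ``anchors`` maps a measure name to a list of (t_hours, mean, sd) anchor
    points; between anchors both the mean and the sd are linearly
    interpolated in time.
    """

    sex: str
    diet: str
    n_animals: int
    plateau_mean: float
    plateau_sd: float
    tau_hours: float
    anchors: dict[str, list[tuple[float, float, float]]] = field(
        default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.plateau_mean <= 1.2:
            raise CohortError(f"plateau_mean {self.plateau_mean} out of "
                              "(0, 1.2]")
        if self.plateau_sd < 0:
            raise CohortError("plateau_sd must be >= 0")
        if self.tau_hours <= 0:
            raise CohortError("tau_hours must be positive")
        for measure in self.anchors:
            if measure not in MEASURES:
                raise CohortError(f"unknown anchored measure {measure!r}")


def _flow_anchors(baseline, peak10, peak_sd):
    # transient rise in normalised flow that resolves by one week
    return [(-24.0, baseline, 0.25), (0.0, (baseline + peak10) / 2, 0.30),
            (10.0, peak10, peak_sd), (96.0, (baseline + peak10) / 2, 0.30),
            (168.0, baseline, 0.25), (336.0, baseline, 0.25)]


def _ha_anchors():
    # hepatic-artery flow: transient increase to 10 h, back by one week; the
    # study prints no group-level values, so one synthetic profile is shared
    return [(-24.0, 0.12, 0.04), (10.0, 0.20, 0.06), (96.0, 0.15, 0.05),
            (168.0, 0.12, 0.04), (336.0, 0.12, 0.04)]


def _stiffness_anchors(pre, pre_sd, peak, peak_sd, week, week_sd):
    return [(-24.0, pre, pre_sd), (10.0, peak, peak_sd),
            (96.0, (peak + week) / 2, peak_sd), (168.0, week, week_sd),
            (336.0, week, week_sd)]


def _spo2_anchors(h48, h48_sd, h72, h72_sd, wk, wk_sd):
    return [(-24.0, 57.0, 3.0), (0.0, 54.0, 3.0), (48.0, h48, h48_sd),
            (72.0, h72, h72_sd), (168.0, wk, wk_sd), (336.0, wk, wk_sd)]


def _mass_anchors(base, sd):
    return [(-24.0, base, sd), (24.0, 0.95 * base, sd),
            (336.0, 1.05 * base, sd)]


def default_profiles() -> list[GroupProfile]:
    """The shipped study design: printed group statistics where available.

    Volume plateaus (1-week relative volume, mean +- sd): ethanol males
    0.6593 +- 0.0591, control males 0.9004 +- 0.0868, control females
    0.9154 +- 0.1039, ethanol females 0.9713 +- 0.0837.  Portal-flow 10 h
    peaks (ml/min/cm^3): ethanol males 1.92 +- 0.44, control males
    1.31 +- 0.22, ethanol females 2.09 +- 0.48, control females
    2.27 +- 0.16.  Stiffness (m/s) and oxygen-saturation (%) anchors use the
    printed ethanol-group values; the study reports no significant diet
    differences in stiffness, so control and chow groups share the same-sex
    ethanol anchors.  Chow volume statistics are not printed and default to
    a full-recovery profile.  Group sizes total 43 (23 male, 20 female).
    """
    em = GroupProfile(
        sex="male", diet="ethanol", n_animals=8,
        plateau_mean=0.6593, plateau_sd=0.0591, tau_hours=72.0,
        anchors={
            "pv_flow": _flow_anchors(0.90, 1.92, 0.44),
            "ha_flow": _ha_anchors(),
            "stiffness": _stiffness_anchors(1.75, 0.06, 2.07, 0.15,
                                            1.82, 0.10),
            "spo2": _spo2_anchors(53.53, 3.26, 55.08, 2.65, 55.42, 1.78),
            "body_mass_g": _mass_anchors(420.0, 25.0),
        })
    cm = GroupProfile(
        sex="male", diet="control", n_animals=8,
        plateau_mean=0.9004, plateau_sd=0.0868, tau_hours=48.0,
        anchors={
            "pv_flow": _flow_anchors(0.90, 1.31, 0.22),
            "ha_flow": _ha_anchors(),
            "stiffness": _stiffness_anchors(1.75, 0.08, 2.07, 0.15,
                                            1.82, 0.10),
            "spo2": _spo2_anchors(55.91, 1.57, 57.0, 2.5, 57.0, 2.5),
            "body_mass_g": _mass_anchors(420.0, 25.0),
        })
    ef = GroupProfile(
        sex="female", diet="ethanol", n_animals=7,
        plateau_mean=0.9713, plateau_sd=0.0837, tau_hours=48.0,
        anchors={
            "pv_flow": _flow_anchors(0.90, 2.09, 0.48),
            "ha_flow": _ha_anchors(),
            "stiffness": _stiffness_anchors(1.93, 0.09, 2.35, 0.04,
                                            2.08, 0.18),
            "spo2": _spo2_anchors(56.0, 2.5, 58.34, 2.06, 59.74, 1.70),
            "body_mass_g": _mass_anchors(270.0, 20.0),
        })
    cf = GroupProfile(
        sex="female", diet="control", n_animals=7,
        plateau_mean=0.9154, plateau_sd=0.1039, tau_hours=48.0,
        anchors={
            "pv_flow": _flow_anchors(0.90, 2.27, 0.16),
            "ha_flow": _ha_anchors(),
            "stiffness": _stiffness_anchors(1.93, 0.09, 2.35, 0.08,
                                            2.08, 0.18),
            "spo2": _spo2_anchors(56.0, 2.5, 57.0, 2.5, 57.0, 2.5),
            "body_mass_g": _mass_anchors(270.0, 20.0),
        })
    chow_m = GroupProfile(
        sex="male", diet="chow", n_animals=7,
        plateau_mean=0.95, plateau_sd=0.09, tau_hours=48.0,
        anchors={
            "pv_flow": _flow_anchors(0.90, 1.31, 0.22),
            "ha_flow": _ha_anchors(),
            "stiffness": _stiffness_anchors(1.75, 0.08, 2.07, 0.15,
                                            1.82, 0.10),
            "spo2": _spo2_anchors(55.91, 1.57, 57.0, 2.5, 57.0, 2.5),
            "body_mass_g": _mass_anchors(420.0, 25.0),
        })
    chow_f = GroupProfile(
        sex="female", diet="chow", n_animals=6,
        plateau_mean=0.95, plateau_sd=0.09, tau_hours=48.0,
        anchors={
            "pv_flow": _flow_anchors(0.90, 2.27, 0.16),
            "ha_flow": _ha_anchors(),
            "stiffness": _stiffness_anchors(1.93, 0.09, 2.35, 0.08,
                                            2.08, 0.18),
            "spo2": _spo2_anchors(56.0, 2.5, 57.0, 2.5, 57.0, 2.5),
            "body_mass_g": _mass_anchors(270.0, 20.0),
        })
    return [em, cm, ef, cf, chow_m, chow_f]


@dataclass
class CohortSpec:
    """Design of a synthetic cohort: groups, schedule, noise, missingness."""

    profiles: list[GroupProfile] = field(default_factory=default_profiles)
    times: tuple[float, ...] = STUDY_TIMES
    noise_sd: float = 0.03
    missingness: dict[str, float] = field(default_factory=lambda: {
        "rel_volume": 0.08,
        "body_mass_g": 0.05,
        "pv_flow": 0.15,
        "ha_flow": 0.30,  # the small hepatic artery is often not visualised
        "stiffness": 0.15,
        "spo2": 0.15,
    })
    min_measurements: int = MIN_MEASUREMENTS
    enforce_eligibility: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.times)
        if any(b <= a for a, b in zip(times, times[1:])):
            raise CohortError("times must be strictly increasing")
        if self.noise_sd < 0:
            raise CohortError("noise_sd must be >= 0")
        for m, rate in self.missingness.items():
            if m not in MEASURES or not 0.0 <= rate < 1.0:
                raise CohortError(f"bad missingness entry {m!r}: {rate!r}")
        n_post = sum(t >= 0 for t in times)
        if self.enforce_eligibility and n_post < self.min_measurements:
            raise CohortError(
                f"schedule has only {n_post} post-PHx times but eligibility "
                f"requires {self.min_measurements}")
        self.times = times

    def to_yaml(self, path: str | Path) -> None:
        raw = asdict(self)
        raw["times"] = list(self.times)
        for prof in raw["profiles"]:
            prof["anchors"] = {k: [list(a) for a in v]
                               for k, v in prof["anchors"].items()}
        Path(path).write_text(yaml.safe_dump(raw, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortSpec":
        raw = yaml.safe_load(Path(path).read_text())
        profiles = [GroupProfile(**{
            **p, "anchors": {k: [tuple(a) for a in v]
                             for k, v in p.get("anchors", {}).items()}})
            for p in raw.pop("profiles")]
        return cls(profiles=profiles, **raw)


def default_cohort_spec(seed: int = 0) -> CohortSpec:
    return CohortSpec(seed=seed)


def recovery_curve(plateau: float, tau_hours: float,
                   t: np.ndarray) -> np.ndarray:
    """Noiseless relative-volume curve for one animal.

    Single-exponential rise from the 30% remnant with time constant ``tau``,
    anchored so the value at one week equals ``plateau`` exactly, and held
    flat from one to two weeks.  The -24 h reference value is 1 by
    definition of the normalisation.
    """
    t = np.asarray(t, dtype=float)
    ec = np.exp(-168.0 / tau_hours)
    asymptote = (plateau - REMNANT_VOLUME * ec) / (1.0 - ec)
    v = asymptote + (REMNANT_VOLUME - asymptote) * np.exp(
        -np.clip(t, 0.0, None) / tau_hours)
    v = np.where(t >= 168.0, plateau, v)
    return np.where(t < 0, 1.0, v)


def _truncated_normal(rng, mean, sd, bounds, max_tries=1000):
    if sd == 0:
        return float(np.clip(mean, *bounds))
    for _ in range(max_tries):
        draw = rng.normal(mean, sd)
        if bounds[0] < draw < bounds[1]:
            return float(draw)
    raise CohortError(f"could not draw a plateau in {bounds} around "
                      f"{mean} +- {sd}")


def _keep_mask(rng, n, rate, keep_first):
    mask = rng.random(n) >= rate
    if keep_first:
        mask[0] = True  # the -24 h reference defines the normalisation
    return mask


def generate_cohort(spec: CohortSpec,
                    seed: int | None = None) -> list[AnimalRecord]:
    """Draw a reproducible cohort of animal records from a cohort spec.

    Per animal: a recovery plateau ~ Normal(group mean, group sd) truncated
    to (0.3, 1.2); the anchored exponential recovery curve; observation
    noise on every post-PHx volume; ancillary measures drawn around the
    interpolated anchor curves; missingness applied per measure, re-drawn
    for the volume series (up to 100 attempts) when eligibility is
    enforced.  The same seed yields a byte-identical cohort.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    times = np.asarray(spec.times)
    post = times >= 0
    animals: list[AnimalRecord] = []
    prefix_counts: dict[str, int] = {}
    for profile in spec.profiles:
        prefix = (profile.sex[0] + profile.diet[:2]).upper()
        for _ in range(profile.n_animals):
            prefix_counts[prefix] = prefix_counts.get(prefix, 0) + 1
            animal_id = f"{prefix}{prefix_counts[prefix]:02d}"
            plateau = _truncated_normal(
                rng, profile.plateau_mean, profile.plateau_sd,
                PLATEAU_BOUNDS)
            clean = recovery_curve(plateau, profile.tau_hours, times)
            values = clean.copy()
            values[post] = np.maximum(
                clean[post] + rng.normal(0.0, spec.noise_sd, post.sum()),
                1e-3)
            vol_rate = spec.missingness.get("rel_volume", 0.0)
            for attempt in range(100):
                keep = _keep_mask(rng, times.size, vol_rate, keep_first=True)
                if not spec.enforce_eligibility or \
                        (keep & post).sum() >= spec.min_measurements:
                    break
            else:
                raise CohortError(
                    f"animal {animal_id}: could not satisfy the "
                    f"{spec.min_measurements}-measurement eligibility floor")
            extras: dict[str, tuple[np.ndarray, np.ndarray]] = {}
            for measure, anchors in profile.anchors.items():
                at = np.asarray([a[0] for a in anchors])
                mean = np.interp(times, at, [a[1] for a in anchors])
                sd = np.interp(times, at, [a[2] for a in anchors])
                draws = rng.normal(mean, sd)
                rate = spec.missingness.get(measure, 0.0)
                mkeep = _keep_mask(rng, times.size, rate, keep_first=False)
                if mkeep.any():
                    extras[measure] = (times[mkeep].copy(), draws[mkeep])
            animals.append(AnimalRecord(
                animal_id=animal_id, sex=profile.sex, diet=profile.diet,
                t_hours=times[keep].copy(), rel_volume=values[keep],
                extras=extras))
    logger.info("generated %d synthetic animals in %d groups",
                len(animals), len(spec.profiles))
    return animals


def write_cohort(animals: Sequence[AnimalRecord], path: str | Path) -> None:
    """Write animal records as the long-format measurement CSV.

    One row per (animal, time, measure); round-trips losslessly through
    :func:`regenfit.likelihood_fit.read_animals`.
    """
    if not animals:
        raise ValueError("refusing to write an empty cohort")
    rows = []
    for a in animals:
        for t, v in zip(a.t_hours, a.rel_volume):
            rows.append((a.animal_id, a.sex, a.diet, t, "rel_volume", v))
        for measure, (ts, vs) in sorted(a.extras.items()):
            for t, v in zip(ts, vs):
                rows.append((a.animal_id, a.sex, a.diet, t, measure, v))
    frame = pd.DataFrame(
        rows, columns=["animal_id", "sex", "diet", "t_hours", "measure",
                       "value"])
    # shortest round-trip float form so read(write(x)) == x bit-for-bit
    frame["value"] = [repr(float(v)) for v in frame["value"]]
    frame["t_hours"] = [repr(float(t)) for t in frame["t_hours"]]
    frame.to_csv(path, index=False)
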