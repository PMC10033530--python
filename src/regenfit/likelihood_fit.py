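"""Grid-scan maximum-likelihood fit of measured volume recovery.

Each animal's longitudinal relative-volume series (normalised to its own
pre-surgery, -24 h, liver-volume-to-body-mass ratio) is compared against all
simulated trajectories of the (M, Kcd) sweep.  Residuals are simulated minus
measured volume at each post-PHx observation time; with sigma the sample
standard deviation of those residuals, a zero-mean Gaussian log-likelihood
is summed over time points:

    log L = sum_i log p(x_i),   p(x) = exp(-x^2 / (2 sigma^2)) / (sigma sqrt(2 pi))

The weighted variant inflates the final residual five-fold inside the
density, log p(5 x_n) + sum_{i<n} log p(x_i), so the end-of-series recovery
dominates the fit; sigma is not recomputed from the inflated residual.
Animals need at least five post-PHx volume measurements to be fitted.  The
95th-percentile set of an animal's weighted log-likelihoods over the 10,000
cells is reported as its credible region.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .param_sweep import ModeMap, SweepResult, MODE_LABELS, build_grid

__all__ = [
    "AnimalRecord",
    "ResidualSet",
    "LikelihoodSurface",
    "EligibilityError",
    "AlignmentError",
    "MIN_MEASUREMENTS",
    "SIGMA_FLOOR",
    "DEFAULT_LAST_WEIGHT",
    "read_animals",
    "residuals",
    "loglik_unweighted",
    "loglik_weighted",
    "fit_animal",
    "fit_cohort",
    "summarize_cohort",
    "group_mode_composition",
]

logger = logging.getLogger(__name__)

MIN_MEASUREMENTS = 5
SIGMA_FLOOR = 1e-6
DEFAULT_LAST_WEIGHT = 5.0
CREDIBLE_PERCENTILE = 95.0

SEXES = ("male", "female")
DIETS = ("ethanol", "control", "chow")
MEASURES = ("rel_volume", "body_mass_g", "pv_flow", "ha_flow",
            "stiffness", "spo2")
_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


class EligibilityError(ValueError):
    """Animal lacks the minimum number of post-PHx volume measurements."""


class AlignmentError(ValueError):
    """Simulation times do not match the animal's observation times."""


@dataclass
class AnimalRecord:
    """One animal's metadata and longitudinal measurement series.

    ``t_hours``/``rel_volume`` hold the volume series (time strictly
    increasing, volumes positive, -24 h reference equal to 1 when present).
    Ancillary series (portal/hepatic-artery flow, stiffness, oxygen
    saturation, body mass) live in ``extras`` keyed by measure name, each a
    ``(times, values)`` pair.
    """

    animal_id: str
    sex: str
    diet: str
    t_hours: np.ndarray
    rel_volume: np.ndarray
    extras: dict[str, tuple[np.ndarray, np.ndarray]] = field(
        default_factory=dict)

    def __post_init__(self) -> None:
        self.t_hours = np.asarray(self.t_hours, dtype=float)
        self.rel_volume = np.asarray(self.rel_volume, dtype=float)
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.diet not in DIETS:
            raise ValueError(f"unknown diet {self.diet!r}")
        if self.t_hours.shape != self.rel_volume.shape:
            raise ValueError("time and volume series differ in length")
        if np.any(np.diff(self.t_hours) <= 0):
            raise ValueError(f"animal {self.animal_id}: t_hours must be "
                             "strictly increasing")
        if np.any(self.rel_volume <= 0):
            raise ValueError(f"animal {self.animal_id}: rel_volume must be "
                             "positive")
        ref = np.flatnonzero(self.t_hours < 0)
        if ref.size and not np.allclose(self.rel_volume[ref], 1.0):
            raise ValueError(f"animal {self.animal_id}: pre-surgery "
                             "reference volume must equal 1.0")

    @property
    def post_phx_times(self) -> np.ndarray:
        return self.t_hours[self.t_hours >= 0]

    @property
    def post_phx_volumes(self) -> np.ndarray:
        return self.rel_volume[self.t_hours >= 0]

    @property
    def eligible(self) -> bool:
        return self.post_phx_times.size >= MIN_MEASUREMENTS

    def pre_phx_value(self, measure: str) -> float:
        """Baseline (-24 h) value of an ancillary measure, NaN if absent."""
        if measure not in self.extras:
            return float("nan")
        t, v = self.extras[measure]
        hit = np.flatnonzero(t < 0)
        return float(v[hit[0]]) if hit.size else float("nan")


def read_animals(path: str | Path) -> list[AnimalRecord]:
    """Read a long-format measurement CSV into animal records.

    Expected columns: animal_id, sex, diet, t_hours, measure, value, with
    ``measure`` one of rel_volume, body_mass_g, pv_flow, ha_flow, stiffness,
    spo2.
    """
    frame = pd.read_csv(path, float_precision="round_trip")
    required = {"animal_id", "sex", "diet", "t_hours", "measure", "value"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    bad = set(frame["measure"].unique()) - set(MEASURES)
    if bad:
        raise ValueError(f"{path}: unknown measures {sorted(bad)}")
    animals = []
    for animal_id, sub in frame.groupby("animal_id", sort=True):
        sex = sub["sex"].iloc[0]
        diet = sub["diet"].iloc[0]
        vol = sub[sub["measure"] == "rel_volume"].sort_values("t_hours")
        extras = {}
        for measure, block in sub[sub["measure"] != "rel_volume"].groupby(
                "measure"):
            block = block.sort_values("t_hours")
            extras[measure] = (block["t_hours"].to_numpy(dtype=float),
                               block["value"].to_numpy(dtype=float))
        animals.append(AnimalRecord(
            animal_id=str(animal_id), sex=sex, diet=diet,
            t_hours=vol["t_hours"].to_numpy(dtype=float),
            rel_volume=vol["value"].to_numpy(dtype=float),
            extras=extras))
    return animals


@dataclass(frozen=True)
class ResidualSet:
    """Residuals (simulated - measured) at the post-PHx observation times."""

    x: np.ndarray
    sigma: float
    weight_last: float = DEFAULT_LAST_WEIGHT
    times: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.x.size


def _sigma(x: np.ndarray, mode: str) -> float:
    if mode == "sample":
        s = float(np.std(x, ddof=1))
    elif mode == "rms0":
        s = float(np.sqrt(np.mean(x**2)))
    else:
        raise ValueError(f"unknown sigma mode {mode!r}")
    return max(s, SIGMA_FLOOR)


def residuals(
    animal: AnimalRecord,
    sim_volumes: Sequence[float],
    *,
    sim_times: Sequence[float] | None = None,
    weight_last: float = DEFAULT_LAST_WEIGHT,
    sigma_mode: str = "sample",
) -> ResidualSet:
    """Residual set for one animal against one simulated trajectory.

    ``sim_volumes`` must be evaluated exactly at the animal's post-PHx
    observation times (pass ``sim_times`` to have this checked).  sigma is
    the sample standard deviation of the residuals about their own mean
    (n-1 denominator), floored at 1e-6; ``sigma_mode='rms0'`` switches to
    the root-mean-square about zero.
    """
    obs_t = animal.post_phx_times
    obs_v = animal.post_phx_volumes
    if obs_t.size < MIN_MEASUREMENTS:
        raise EligibilityError(
            f"animal {animal.animal_id} has only {obs_t.size} post-PHx "
            f"volume measurements (minimum {MIN_MEASUREMENTS})")
    sim = np.asarray(sim_volumes, dtype=float)
    if sim.shape != obs_v.shape:
        raise AlignmentError(
            f"animal {animal.animal_id}: {sim.size} simulated values for "
            f"{obs_v.size} observations")
    if sim_times is not None and not np.allclose(
            np.asarray(sim_times, dtype=float), obs_t, atol=1e-6):
        raise AlignmentError(
            f"animal {animal.animal_id}: simulation times do not match "
            "observation times")
    x = sim - obs_v
    return ResidualSet(x=x, sigma=_sigma(x, sigma_mode),
                       weight_last=weight_last, times=obs_t.copy())


def _logp(x, sigma):
    return -(x * x) / (2.0 * sigma * sigma) - math.log(sigma) - _LOG_SQRT_2PI


def loglik_unweighted(res: ResidualSet) -> float:
    """Sum over residuals of the zero-mean Gaussian log-density."""
    return float(np.sum(_logp(res.x, res.sigma)))


def loglik_weighted(res: ResidualSet) -> float:
    """As the unweighted sum, but the final residual enters as ``5 x_n``."""
    head = float(np.sum(_logp(res.x[:-1], res.sigma)))
    return head + float(_logp(res.weight_last * res.x[-1], res.sigma))


@dataclass(frozen=True)
class LikelihoodSurface:
    """Per-animal log-likelihoods over the (M, Kcd) grid plus summaries."""

    animal_id: str
    sex: str
    diet: str
    grid_M: np.ndarray
    grid_Kcd: np.ndarray
    loglik_weighted: np.ndarray  # shape (n_M, n_Kcd)
    loglik_unweighted: np.ndarray
    best_fit_weighted: tuple[float, float]
    best_fit_unweighted: tuple[float, float]
    credible_mask: np.ndarray  # bool, >= 95th pct of weighted log-likelihood
    mode_map: ModeMap | None = None

    @property
    def best_region_modes(self) -> dict[str, float] | None:
        """Share of credible-region cells in each regeneration mode."""
        if self.mode_map is None:
            return None
        sel = self.mode_map.modes[self.credible_mask]
        total = max(sel.size, 1)
        return {lab: float((sel == code).sum() / total)
                for code, lab in enumerate(MODE_LABELS)}

    def to_frame(self) -> pd.DataFrame:
        mm, kk = np.meshgrid(self.grid_M, self.grid_Kcd, indexing="ij")
        out = pd.DataFrame({
            "M": mm.ravel(),
            "Kcd": kk.ravel(),
            "loglik_weighted": self.loglik_weighted.ravel(),
            "loglik_unweighted": self.loglik_unweighted.ravel(),
            "in_credible_mask": self.credible_mask.ravel(),
        })
        if self.mode_map is not None:
            out["mode"] = self.mode_map.labels().ravel()
        return out


def _argmax_low_first(ll: np.ndarray) -> tuple[int, int]:
    # np.argmax returns the first maximum in C order, i.e. ties break toward
    # lower M first, then lower Kcd
    return tuple(np.unravel_index(int(np.argmax(ll)), ll.shape))


def fit_animal(
    animal: AnimalRecord,
    sweep: SweepResult,
    mode_map: ModeMap | None = None,
    *,
    weight_last: float = DEFAULT_LAST_WEIGHT,
    sigma_mode: str = "sample",
) -> LikelihoodSurface:
    """Likelihood of every sweep cell for one animal's volume series.

    Vectorised over the whole grid: residual cube = simulated volumes at the
    animal's post-PHx times minus observations, per-cell sigma from the
    residual spread, then both likelihood variants.  Argmax ties break
    toward lower M, then lower Kcd; the credible mask keeps cells at or
    above the 95th percentile of the weighted log-likelihood (ties
    included).
    """
    obs_t = animal.post_phx_times
    obs_v = animal.post_phx_volumes
    if obs_t.size < MIN_MEASUREMENTS:
        raise EligibilityError(
            f"animal {animal.animal_id} has only {obs_t.size} post-PHx "
            f"volume measurements (minimum {MIN_MEASUREMENTS})")
    try:
        sim = sweep.volumes_at(obs_t)  # (n_M, n_Kcd, n_obs)
    except KeyError as err:
        raise AlignmentError(
            f"animal {animal.animal_id}: {err.args[0]}") from None
    x = sim - obs_v[None, None, :]
    n = obs_t.size
    if sigma_mode == "sample":
        sigma = np.maximum(x.std(axis=2, ddof=1), SIGMA_FLOOR)
    elif sigma_mode == "rms0":
        sigma = np.maximum(np.sqrt((x**2).mean(axis=2)), SIGMA_FLOOR)
    else:
        raise ValueError(f"unknown sigma mode {sigma_mode!r}")
    inv2s2 = 1.0 / (2.0 * sigma**2)
    norm = -n * (np.log(sigma) + _LOG_SQRT_2PI)
    ssq = (x**2).sum(axis=2)
    ll_unw = -ssq * inv2s2 + norm
    last = x[:, :, -1]
    ll_w = ll_unw + (last**2 - (weight_last * last)**2) * inv2s2

    iw, jw = _argmax_low_first(ll_w)
    iu, ju = _argmax_low_first(ll_unw)
    m_values = sweep.grid.m_values()
    kcd_values = sweep.grid.kcd_values()
    threshold = np.percentile(ll_w, CREDIBLE_PERCENTILE)
    mask = ll_w >= threshold
    return LikelihoodSurface(
        animal_id=animal.animal_id, sex=animal.sex, diet=animal.diet,
        grid_M=m_values, grid_Kcd=kcd_values,
        loglik_weighted=ll_w, loglik_unweighted=ll_unw,
        best_fit_weighted=(float(m_values[iw]), float(kcd_values[jw])),
        best_fit_unweighted=(float(m_values[iu]), float(kcd_values[ju])),
        credible_mask=mask, mode_map=mode_map)


def fit_cohort(
    animals: Iterable[AnimalRecord],
    sweep: SweepResult,
    mode_map: ModeMap | None = None,
    **kwargs,
) -> list[LikelihoodSurface]:
    """Fit every eligible animal; ineligible ones are skipped with a log."""
    surfaces = []
    for animal in animals:
        try:
            surfaces.append(fit_animal(animal, sweep, mode_map, **kwargs))
        except EligibilityError as err:
            logger.warning("skipping animal: %s", err)
    return surfaces


def summarize_cohort(
    surfaces: Sequence[LikelihoodSurface],
) -> pd.DataFrame:
    """Tidy per-animal table of best fits and credible-region composition."""
    if not surfaces:
        logger.warning("summarize_cohort called with no fitted animals")
        return pd.DataFrame(columns=[
            "animal_id", "sex", "diet", "best_M_weighted",
            "best_Kcd_weighted", "best_M_unweighted", "best_Kcd_unweighted",
            "credible_cells",
            *(f"credible_frac_{lab}" for lab in MODE_LABELS)])
    rows = []
    for s in surfaces:
        row = {
            "animal_id": s.animal_id,
            "sex": s.sex,
            "diet": s.diet,
            "best_M_weighted": s.best_fit_weighted[0],
            "best_Kcd_weighted": s.best_fit_weighted[1],
            "best_M_unweighted": s.best_fit_unweighted[0],
            "best_Kcd_unweighted": s.best_fit_unweighted[1],
            "credible_cells": int(s.credible_mask.sum()),
        }
        comp = s.best_region_modes
        for lab in MODE_LABELS:
            row[f"credible_frac_{lab}"] = (
                comp[lab] if comp is not None else float("nan"))
        rows.append(row)
    return pd.DataFrame(rows)


def group_mode_composition(summary: pd.DataFrame) -> pd.DataFrame:
    """Per sex-by-diet group, mean share of credible cells in each mode."""
    cols = [f"credible_frac_{lab}" for lab in MODE_LABELS]
    return summary.groupby(["sex", "diet"])[cols].mean().reset_index()
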