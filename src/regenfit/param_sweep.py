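"""Grid sweep over (M, Kcd) and classification into regeneration modes.

The metabolic load M is scanned over 100 linearly spaced values in [5, 30]
and the cell-death constant Kcd over 100 log-spaced values in [5e-4, 0.5]
(endpoints included), giving 10,000 simulations.  Each grid cell is labelled
from its relative liver volume at one week post-PHx: healthy (>85% of the
original volume), suppressed (40-85%, boundaries included) or failure (<40%
or collapsed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .regen_model import (
    ModelParameters,
    SimulationError,
    T_WEEK,
    T_MAX,
    simulate,
)

__all__ = [
    "GridSpec",
    "SweepResult",
    "ModeMap",
    "GridSpecError",
    "MODE_LABELS",
    "HEALTHY_THRESHOLD",
    "FAILURE_THRESHOLD",
    "build_grid",
    "run_sweep",
    "classify",
    "save_sweep",
    "load_sweep",
]

logger = logging.getLogger(__name__)

HEALTHY_THRESHOLD = 0.85
FAILURE_THRESHOLD = 0.40

#: integer codes used in the mode array
HEALTHY, SUPPRESSED, FAILURE = 0, 1, 2
MODE_LABELS = ("healthy", "suppressed", "failure")


class GridSpecError(ValueError):
    """Raised for invalid grid specifications."""


@dataclass(frozen=True)
class GridSpec:
    """The (M, Kcd) scan: M linear, Kcd logarithmic, endpoints inclusive."""

    M_min: float = 5.0
    M_max: float = 30.0
    n_M: int = 100
    Kcd_min: float = 5e-4
    Kcd_max: float = 0.5
    n_Kcd: int = 100

    def __post_init__(self) -> None:
        if self.n_M < 1 or self.n_Kcd < 1:
            raise GridSpecError("grid counts must be positive")
        if not self.M_min < self.M_max:
            raise GridSpecError("require M_min < M_max")
        if not 0 < self.Kcd_min < self.Kcd_max:
            raise GridSpecError("require 0 < Kcd_min < Kcd_max")

    def m_values(self) -> np.ndarray:
        return np.linspace(self.M_min, self.M_max, self.n_M)

    def kcd_values(self) -> np.ndarray:
        return np.geomspace(self.Kcd_min, self.Kcd_max, self.n_Kcd)

    @property
    def n_cells(self) -> int:
        return self.n_M * self.n_Kcd

    def nearest_index(self, M: float, Kcd: float) -> tuple[int, int]:
        """Indices of the grid cell closest to (M, Kcd); Kcd in log distance."""
        i = int(np.argmin(np.abs(self.m_values() - M)))
        j = int(np.argmin(np.abs(np.log(self.kcd_values()) - np.log(Kcd))))
        return i, j


def build_grid(spec: GridSpec) -> np.ndarray:
    """All (M, Kcd) pairs, M ascending-major and Kcd ascending-minor."""
    m = spec.m_values()
    k = spec.kcd_values()
    mm, kk = np.meshgrid(m, k, indexing="ij")
    return np.column_stack([mm.ravel(), kk.ravel()])


@dataclass(frozen=True)
class SweepResult:
    """Cached relative-volume cube for every grid cell and evaluation time."""

    grid: GridSpec
    eval_times: np.ndarray
    rel_volume: np.ndarray  # shape (n_M, n_Kcd, n_times)
    collapsed: np.ndarray  # shape (n_M, n_Kcd), bool
    base_params: ModelParameters

    def time_indices(self, times: Sequence[float]) -> np.ndarray:
        """Indices into ``eval_times`` for the requested times (exact)."""
        idx = []
        for t in times:
            hits = np.flatnonzero(np.isclose(self.eval_times, t, atol=1e-6))
            if hits.size == 0:
                raise KeyError(f"time {t} h was not evaluated in this sweep")
            idx.append(hits[0])
        return np.asarray(idx, dtype=int)

    def volumes_at(self, times: Sequence[float]) -> np.ndarray:
        return self.rel_volume[:, :, self.time_indices(times)]


@dataclass(frozen=True)
class ModeMap:
    """Per-cell regeneration-mode labels derived from the 1-week volume."""

    grid: GridSpec
    modes: np.ndarray  # shape (n_M, n_Kcd), int codes

    def counts(self) -> dict[str, int]:
        return {lab: int((self.modes == code).sum())
                for code, lab in enumerate(MODE_LABELS)}

    def labels(self) -> np.ndarray:
        return np.asarray(MODE_LABELS, dtype=object)[self.modes]

    def to_frame(self) -> pd.DataFrame:
        pairs = build_grid(self.grid)
        return pd.DataFrame({
            "M": pairs[:, 0],
            "Kcd": pairs[:, 1],
            "mode": self.labels().ravel(),
        })


def _params_hash(params: ModelParameters) -> str:
    blob = json.dumps(params.to_dict(), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()


def run_sweep(
    spec: GridSpec,
    params: ModelParameters,
    eval_times: Sequence[float] = (0.0, 10.0, 24.0, 48.0, 72.0, 96.0,
                                   T_WEEK, T_MAX),
    *,
    progress: bool = False,
) -> SweepResult:
    """Simulate every grid cell once, deterministically.

    ``eval_times`` must include the 1-week endpoint (168 h) used for mode
    classification.  Integrator failures in single cells are recorded as
    collapsed rather than aborting the sweep.
    """
    times = np.asarray(sorted(set(float(t) for t in eval_times)))
    if times[0] < 0 or times[-1] > T_MAX:
        raise ValueError(f"eval_times must lie within [0, {T_MAX}] h")
    if not np.any(np.isclose(times, T_WEEK)):
        raise ValueError("eval_times must include the 1-week endpoint (168 h)")

    m_values = spec.m_values()
    kcd_values = spec.kcd_values()
    cube = np.empty((spec.n_M, spec.n_Kcd, times.size))
    collapsed = np.zeros((spec.n_M, spec.n_Kcd), dtype=bool)
    floor = params.epsilon / (1.0 + params.epsilon)
    for i, M in enumerate(m_values):
        if progress and i % 10 == 0:
            logger.info("sweep: M column %d/%d", i + 1, spec.n_M)
        for j, Kcd in enumerate(kcd_values):
            cell = params.replace(M=float(M), Kcd=float(Kcd))
            try:
                traj = simulate(cell, times)
            except SimulationError as err:
                logger.warning("cell (M=%.4g, Kcd=%.4g) failed: %s",
                               M, Kcd, err)
                cube[i, j] = floor
                collapsed[i, j] = True
                continue
            cube[i, j] = traj.rel_volume
            collapsed[i, j] = traj.collapsed
    return SweepResult(grid=spec, eval_times=times, rel_volume=cube,
                       collapsed=collapsed, base_params=params)


def classify(sweep: SweepResult) -> ModeMap:
    """Label every cell from its relative volume at 168 h.

    Boundary values (exactly 0.40 or 0.85) are assigned to the suppressed
    mode so the three conditions form a true partition.
    """
    v = sweep.volumes_at([T_WEEK])[:, :, 0]
    modes = np.full(v.shape, SUPPRESSED, dtype=int)
    modes[v > HEALTHY_THRESHOLD] = HEALTHY
    modes[(v < FAILURE_THRESHOLD) | sweep.collapsed] = FAILURE
    return ModeMap(grid=sweep.grid, modes=modes)


def save_sweep(sweep: SweepResult, outdir: str | Path) -> None:
    """Write the sweep cube as a long CSV plus a JSON sidecar.

    The sidecar stores the grid spec, the evaluation times and a hash of the
    base parameters; :func:`load_sweep` refuses a cache whose hash does not
    match the parameters it is asked to trust.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pairs = build_grid(sweep.grid)
    n_t = sweep.eval_times.size
    frame = pd.DataFrame({
        "M": np.repeat(pairs[:, 0], n_t),
        "Kcd": np.repeat(pairs[:, 1], n_t),
        "t_hours": np.tile(sweep.eval_times, len(pairs)),
        "rel_volume": sweep.rel_volume.reshape(-1),
        "collapsed": np.repeat(sweep.collapsed.reshape(-1), n_t),
    })
    # shortest round-trip float form so the cube reloads bit-for-bit
    for col in ("M", "Kcd", "t_hours", "rel_volume"):
        frame[col] = [repr(float(v)) for v in frame[col]]
    frame.to_csv(outdir / "sweep_cube.csv", index=False)
    sidecar = {
        "grid": asdict(sweep.grid),
        "eval_times": sweep.eval_times.tolist(),
        "params": sweep.base_params.to_dict(),
        "params_hash": _params_hash(sweep.base_params),
    }
    (outdir / "sweep_meta.json").write_text(json.dumps(sidecar, indent=2))


def load_sweep(outdir: str | Path,
               expected_params: ModelParameters | None = None) -> SweepResult:
    """Load a cached sweep; validate the parameter hash if one is expected."""
    outdir = Path(outdir)
    sidecar = json.loads((outdir / "sweep_meta.json").read_text())
    params = ModelParameters(**sidecar["params"])
    if sidecar.get("params_hash") != _params_hash(params):
        raise ValueError(f"corrupt sweep cache in {outdir}: hash mismatch")
    if expected_params is not None and \
            _params_hash(expected_params) != sidecar["params_hash"]:
        raise ValueError(
            f"sweep cache in {outdir} was built with different parameters")
    spec = GridSpec(**sidecar["grid"])
    times = np.asarray(sidecar["eval_times"], dtype=float)
    frame = pd.read_csv(outdir / "sweep_cube.csv",
                        float_precision="round_trip")
    if len(frame) != spec.n_cells * times.size:
        raise ValueError(f"sweep cache in {outdir} has wrong row count")
    cube = frame["rel_volume"].to_numpy().reshape(
        spec.n_M, spec.n_Kcd, times.size)
    collapsed = frame["collapsed"].to_numpy().reshape(
        spec.n_M, spec.n_Kcd, times.size)[:, :, 0].astype(bool)
    return SweepResult(grid=spec, eval_times=times, rel_volume=cube,
                       collapsed=collapsed, base_params=params)
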