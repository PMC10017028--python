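"""Dewetting-temperature hydropathy analysis.

The underlying protocol: take an equilibrated structure at simulation
temperature T_MD with its first hydration shell, restrain the solute, and
heat the box over a grid of "dewetting temperatures" T_dw (250-400 K at
1 K / 20 ps, i.e. 3 ns).  A residue that keeps its shell water to high
T_dw interacts strongly with water (hydrophilic); one that loses it early
is hydrophobic.  This module turns per-(T_dw) trajectories into:

* an :class:`OccupancyMatrix` of per-residue mean shell counts, normalized
  row-wise to the lowest-T_dw baseline;
* per-residue dewetting temperatures (first grid crossing of a fraction
  ``theta`` of baseline occupancy, linearly interpolated);
* percent-dehydrated curves and the (T_MD, T_dw) :class:`DewettingMap`;
* hydropathy scores in [0, 1] (higher = more hydrophilic).

Residues that are essentially dry at baseline (fewer than ``min_baseline``
waters) cannot meaningfully dewet and are flagged out of all percentages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import LabeledSystem, Trajectory
from .proximity import ShellParams, average_residue_profile

#: sentinel returned when a residue stays hydrated over the whole grid
NEVER_DEWETS = float("inf")


@dataclass(frozen=True)
class AnnealingSchedule:
    """Linear heating schedule of the dewetting protocol.

    Defaults encode the reference protocol: 250 -> 400 K at 1 K per 20 ps,
    which takes (400 - 250) * 20 ps = 3 ns.
    """

    t_initial: float = 250.0
    t_final: float = 400.0
    rate: float = 1.0 / 20.0  # K / ps
    duration: float = 3000.0  # ps

    def __post_init__(self) -> None:
        if self.t_final <= self.t_initial:
            raise ValueError("t_final must exceed t_initial")
        if self.rate <= 0:
            raise ValueError("heating rate must be positive")


def validate_schedule(schedule: AnnealingSchedule, rtol: float = 1e-9) -> bool:
    """True iff (t_final - t_initial) / rate equals the stated duration."""
    implied = (schedule.t_final - schedule.t_initial) / schedule.rate
    return bool(math.isclose(implied, schedule.duration, rel_tol=rtol))


@dataclass
class OccupancyMatrix:
    """Per-residue mean shell counts over an ascending T_dw grid."""

    residue_indices: np.ndarray       # internal 0-based indices
    tdw_grid: np.ndarray
    raw: np.ndarray                   # residues x grid, mean counts
    normalized: np.ndarray            # raw / baseline column
    baseline_flags: np.ndarray        # True where baseline < min_baseline
    min_baseline: float

    @property
    def n_unflagged(self) -> int:
        return int(np.count_nonzero(~self.baseline_flags))


@dataclass
class DewettingMap:
    """Percent-dehydrated grid over (T_MD rows, T_dw columns)."""

    tmd_grid: np.ndarray
    tdw_grid: np.ndarray
    percent_dehydrated: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.percent_dehydrated, dtype=float)
        if np.any((p < 0) | (p > 100)):
            raise ValueError("percentages must lie in [0, 100]")
        self.percent_dehydrated = p


def occupancy_matrix(
    series: list[tuple[float, Trajectory]],
    system: LabeledSystem | None = None,
    params: ShellParams = ShellParams(),
    window: float = 1.0,
    min_baseline: float = 1.0,
) -> OccupancyMatrix:
    """Build the residue x T_dw occupancy matrix from an annealing series.

    For each grid temperature the per-residue water counts are averaged
    over the trailing ``window`` fraction of frames, then each row is
    normalized by its count at the lowest (baseline) temperature.
    """
    if len(series) < 2:
        raise ValueError("need at least 2 dewetting-temperature grid points")
    grid = np.array([T for T, _ in series], dtype=float)
    if np.any(np.diff(grid) <= 0):
        if len(np.unique(grid)) != len(grid):
            raise ValueError("duplicate T_dw grid temperatures")
        raise ValueError("T_dw grid must be sorted ascending")
    profiles = []
    for _, traj in series:
        if len(traj) == 0:
            raise ValueError("empty trajectory in annealing series")
        profiles.append(average_residue_profile(traj, params, window))
    residue_indices = profiles[0].residue_indices
    for p in profiles:
        if not np.array_equal(p.residue_indices, residue_indices):
            raise ValueError("annealing series mixes different systems")
    raw = np.stack([p.per_residue_counts for p in profiles], axis=1)
    baseline = raw[:, 0]
    flags = baseline < min_baseline
    with np.errstate(divide="ignore", invalid="ignore"):
        normalized = np.where(baseline[:, None] > 0, raw / baseline[:, None], 0.0)
    return OccupancyMatrix(
        residue_indices=residue_indices,
        tdw_grid=grid,
        raw=raw,
        normalized=normalized,
        baseline_flags=flags,
        min_baseline=min_baseline,
    )


def residue_dewetting_temperature(
    matrix: OccupancyMatrix, residue: int, theta: float = 0.5
) -> float:
    """Temperature at which a residue's normalized occupancy drops below
    ``theta``.

    Returns the smallest grid T_dw whose occupancy is below ``theta``,
    refined by linear interpolation between the bracketing grid points;
    :data:`NEVER_DEWETS` if occupancy stays at or above ``theta`` across
    the whole grid.  ``residue`` is the internal residue index.
    """
    pos = np.nonzero(matrix.residue_indices == residue)[0]
    if len(pos) != 1:
        raise KeyError(f"residue {residue} not in occupancy matrix")
    k = int(pos[0])
    if matrix.baseline_flags[k]:
        raise ValueError(
            f"residue {residue} is not hydrated at baseline "
            f"(< {matrix.min_baseline} waters); dewetting is undefined"
        )
    row = matrix.normalized[k]
    below = np.nonzero(row < theta)[0]
    if len(below) == 0:
        return NEVER_DEWETS
    j = int(below[0])
    if j == 0:
        # cannot happen for normalized rows with theta <= 1, but a custom
        # absolute-mode matrix may start below threshold
        return float(matrix.tdw_grid[0])
    t0, t1 = matrix.tdw_grid[j - 1], matrix.tdw_grid[j]
    y0, y1 = row[j - 1], row[j]
    return float(t0 + (y0 - theta) / (y0 - y1) * (t1 - t0))


def percent_dehydrated_curve(
    matrix: OccupancyMatrix, theta: float = 0.5
) -> np.ndarray:
    """Percent of unflagged residues below ``theta`` occupancy at each T_dw."""
    keep = ~matrix.baseline_flags
    n = int(np.count_nonzero(keep))
    if n == 0:
        raise ValueError("all residues are flagged non-hydrated")
    below = matrix.normalized[keep] < theta
    return 100.0 * below.sum(axis=0) / n


def assemble_dewetting_map(
    curves: list[tuple[float, np.ndarray]], tdw_grid: np.ndarray
) -> DewettingMap:
    """Stack per-T_MD percent-dehydrated curves into a (T_MD, T_dw) map."""
    if not curves:
        raise ValueError("no curves to assemble")
    tdw_grid = np.asarray(tdw_grid, dtype=float)
    rows = []
    tmds = []
    for tmd, curve in curves:
        curve = np.asarray(curve, dtype=float)
        if curve.shape != tdw_grid.shape:
            raise ValueError(
                f"curve at T_MD={tmd} has {curve.shape} points for a "
                f"{tdw_grid.shape} T_dw grid"
            )
        tmds.append(float(tmd))
        rows.append(curve)
    return DewettingMap(
        tmd_grid=np.array(tmds),
        tdw_grid=tdw_grid,
        percent_dehydrated=np.stack(rows),
    )


def hydropathy_scores(
    dewetting_temperatures: dict[int, float],
    schedule: AnnealingSchedule = AnnealingSchedule(),
) -> dict[int, float]:
    """Map per-residue dewetting temperatures onto a [0, 1] hydropathy scale.

    ``score = (T_dw,res - t_initial) / (t_final - t_initial)`` clipped to
    [0, 1]; the never-dewets sentinel scores 1.0.  Higher scores mean the
    residue holds its hydration water longer, i.e. is more hydrophilic.
    """
    if len(dewetting_temperatures) < 2:
        raise ValueError("need dewetting temperatures for at least 2 residues")
    span = schedule.t_final - schedule.t_initial
    scores = {}
    for res, t in dewetting_temperatures.items():
        if t == NEVER_DEWETS:
            scores[res] = 1.0
        else:
            scores[res] = float(np.clip((t - schedule.t_initial) / span, 0.0, 1.0))
    if all(s == 1.0 for s in scores.values()):
        import warnings

        warnings.warn("degenerate hydropathy scale: no residue dewets", stacklevel=2)
    return scores
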