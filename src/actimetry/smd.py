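"""Simplified steered-dynamics restraint schedules with work accounting.

A subset of atoms is dragged from its starting position to a destination
r* by a harmonic restraint U = k |r - r0|^2 / 2 whose center r0 is moved
in N discrete stages.  After stage i the center is updated from the
stage-averaged atom position <r>^(i) by

    r0^(i+1) = <r>^(i) - (<r>^(i) - r*) / (N - i),      i = 1 .. N-1,

so each update closes 1/(N-i) of the remaining gap and the final center
is r* exactly.  Basing the update on the *measured* mean rather than on a
pre-computed linear path lets the pulled atoms detour around barriers.
The remaining protein core is held by weaker fixed-center restraints.
Work is accounted stepwise: every center jump changes the restraint
energy at the instantaneous coordinates, and the sum of those jumps is
the external switching work — in the quasi-static limit, the free-energy
change of the transformation.

Defaults follow the published protocol: N = 21 stages, k = 500
kcal/(mol A^2) on the pulled atoms, k = 80 kcal/(mol A^2) on the core.

The dynamics backend is pluggable; it must provide::

    labels                              -> sequence of atom labels
    get_positions()                     -> (M, 3) array, Angstrom
    run(n_steps, restraints, rng)       -> advance under its own potential
                                           plus the given HarmonicRestraints
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Protocol, Sequence, runtime_checkable

import numpy as np
import pandas as pd

__all__ = [
    "HarmonicRestraint",
    "SteeringSchedule",
    "SteeringRunState",
    "DynamicsBackend",
    "next_center",
    "restraint_energy_force",
    "stage_work_increment",
    "run_steering",
    "N_STAGES_DEFAULT",
    "K_PULL_DEFAULT",
    "K_CORE_DEFAULT",
]

N_STAGES_DEFAULT = 21
K_PULL_DEFAULT = 500.0  # kcal/(mol A^2), pulled atoms
K_CORE_DEFAULT = 80.0  # kcal/(mol A^2), retained core


@dataclass(frozen=True, eq=False)
class HarmonicRestraint:
    """U(r) = k |r - r0|^2 / 2 acting on one atom."""

    atom: Hashable
    center: np.ndarray  # (3,) Angstrom
    k: float  # kcal/(mol A^2)

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        if self.k <= 0:
            raise ValueError("force constant must be positive")


def restraint_energy_force(
    r: np.ndarray, restraint: HarmonicRestraint
) -> tuple[float, np.ndarray]:
    """Energy (kcal/mol) and force (kcal/mol/A) of a harmonic restraint."""
    d = np.asarray(r, dtype=float) - restraint.center
    return float(0.5 * restraint.k * np.dot(d, d)), -restraint.k * d


def next_center(
    mean_pos: np.ndarray, destination: np.ndarray, i: int, n_stages: int
) -> np.ndarray:
    """Center for stage i+1 from the stage-i mean position.

    Advances 1/(N-i) of the remaining gap toward the destination; at
    i = N-1 the destination is returned exactly (bitwise), which pins the
    schedule endpoint regardless of rounding along the way.
    """
    if not 1 <= i <= n_stages - 1:
        raise IndexError(f"stage index {i} outside 1..{n_stages - 1}")
    destination = np.asarray(destination, dtype=float)
    if i == n_stages - 1:
        return destination.copy()
    mean_pos = np.asarray(mean_pos, dtype=float)
    return mean_pos - (mean_pos - destination) / (n_stages - i)


@dataclass(eq=False)
class SteeringSchedule:
    """What to pull, where to, and how hard."""

    moved_atoms: list
    destinations: np.ndarray  # (n_moved, 3)
    n_stages: int = N_STAGES_DEFAULT
    k_pull: float = K_PULL_DEFAULT
    k_core: float = K_CORE_DEFAULT
    core_atoms: list = field(default_factory=list)
    stage_steps: int = 1000
    averaging_window: float = 0.5  # fraction of each stage averaged for <r>
    decorrelation_fraction: float = 0.25  # run after the window, before the jump

    def __post_init__(self) -> None:
        self.destinations = np.atleast_2d(np.asarray(self.destinations, dtype=float))
        if self.destinations.shape != (len(self.moved_atoms), 3):
            raise ValueError("destinations must be (n_moved, 3)")
        if self.n_stages < 2:
            raise ValueError("a schedule needs at least 2 stages")
        if self.k_pull <= 0 or self.k_core <= 0:
            raise ValueError("force constants must be positive")
        if set(self.moved_atoms) & set(self.core_atoms):
            raise ValueError("moved and core atom sets overlap")
        if not 0.0 < self.averaging_window <= 1.0:
            raise ValueError("averaging window must be in (0, 1]")
        if not 0.0 <= self.decorrelation_fraction < 1.0:
            raise ValueError("decorrelation fraction must be in [0, 1)")
        if self.averaging_window + self.decorrelation_fraction > 1.0:
            raise ValueError("averaging window plus decorrelation exceed the stage")
        if self.stage_steps < 1:
            raise ValueError("stage_steps must be >= 1")


@dataclass(eq=False)
class SteeringRunState:
    """Bookkeeping of one steering run."""

    stage: int = 0
    centers: np.ndarray | None = None  # pulled-atom centers r0^(i)
    stage_means: np.ndarray | None = None  # <r>^(i)
    work: float = 0.0  # accumulated switching work, kcal/mol
    work_increments: list[float] = field(default_factory=list)


def stage_work_increment(
    coords: np.ndarray,
    old_centers: np.ndarray,
    new_centers: np.ndarray,
    k: float,
) -> float:
    """Work done on the system by a center jump at fixed coordinates.

    dW = sum_atoms [ U(r; r0_new) - U(r; r0_old) ] evaluated at the
    instantaneous positions when the centers switch.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    old_centers = np.atleast_2d(np.asarray(old_centers, dtype=float))
    new_centers = np.atleast_2d(np.asarray(new_centers, dtype=float))
    if coords.shape != old_centers.shape or coords.shape != new_centers.shape:
        raise ValueError("coords and center arrays must share one shape")
    u_old = 0.5 * k * np.sum((coords - old_centers) ** 2)
    u_new = 0.5 * k * np.sum((coords - new_centers) ** 2)
    return float(u_new - u_old)


@runtime_checkable
class DynamicsBackend(Protocol):
    labels: Sequence

    def get_positions(self) -> np.ndarray: ...

    def run(
        self,
        n_steps: int,
        restraints: Sequence[HarmonicRestraint],
        rng: np.random.Generator,
    ) -> None: ...


def _restraints(
    atoms: Sequence, centers: np.ndarray, k: float
) -> list[HarmonicRestraint]:
    return [HarmonicRestraint(a, c, k) for a, c in zip(atoms, centers)]


def run_steering(
    backend: DynamicsBackend,
    schedule: SteeringSchedule,
    seed: int = 0,
    samples_per_window: int = 100,
) -> tuple[SteeringRunState, pd.DataFrame]:
    """Execute a full steering schedule on a dynamics backend.

    Each of the N stages runs ``stage_steps`` backend steps with fixed
    restraint centers; the pulled-atom mean over a mid-stage averaging
    window feeds the center update, and the restraint-energy jump at the
    switch is added to the accumulated work.  A trailing
    ``decorrelation_fraction`` of each stage runs after the window so the
    coordinates at the jump are not the very samples that set the new
    center (that correlation acts as a feedback bias on the work
    estimate).  Core atoms are restrained at their initial positions with
    ``k_core`` throughout.

    Returns the final run state and a trace with one row per
    (stage, pulled atom): centers, stage means and work increments.
    """
    rng = np.random.default_rng(seed)
    labels = list(backend.labels)
    index = {lab: i for i, lab in enumerate(labels)}
    try:
        moved_idx = np.array([index[a] for a in schedule.moved_atoms], dtype=int)
        core_idx = np.array([index[a] for a in schedule.core_atoms], dtype=int)
    except KeyError as exc:
        raise KeyError(f"schedule names atom {exc.args[0]!r} unknown to backend") from exc

    pos0 = np.asarray(backend.get_positions(), dtype=float)
    centers = pos0[moved_idx].copy()
    core_centers = pos0[core_idx].copy()
    core_restraints = _restraints(schedule.core_atoms, core_centers, schedule.k_core)

    state = SteeringRunState(centers=centers.copy())
    rows: list[dict] = []
    n_stage = schedule.stage_steps
    window_steps = max(1, int(round(schedule.averaging_window * n_stage)))
    guard_steps = int(round(schedule.decorrelation_fraction * n_stage))
    pre_steps = max(0, n_stage - window_steps - guard_steps)
    n_samples = min(samples_per_window, window_steps)
    chunks = np.diff(np.round(np.linspace(0, window_steps, n_samples + 1))).astype(int)

    for i in range(1, schedule.n_stages + 1):
        restraints = (
            _restraints(schedule.moved_atoms, centers, schedule.k_pull)
            + core_restraints
        )
        try:
            if pre_steps:
                backend.run(pre_steps, restraints, rng)
            acc = np.zeros_like(centers)
            n_acc = 0
            for c in chunks:
                if c:
                    backend.run(int(c), restraints, rng)
                acc += np.asarray(backend.get_positions())[moved_idx]
                n_acc += 1
            mean = acc / n_acc
            if guard_steps:
                backend.run(guard_steps, restraints, rng)
        except Exception as exc:
            raise RuntimeError(f"dynamics backend failed in stage {i}") from exc

        state.stage = i
        state.stage_means = mean
        increment = 0.0
        if i < schedule.n_stages:
            new_centers = np.vstack(
                [
                    next_center(mean[j], schedule.destinations[j], i, schedule.n_stages)
                    for j in range(len(moved_idx))
                ]
            )
            coords_now = np.asarray(backend.get_positions())[moved_idx]
            increment = stage_work_increment(
                coords_now, centers, new_centers, schedule.k_pull
            )
            state.work += increment
            state.work_increments.append(increment)
            centers_next = new_centers
        else:
            centers_next = centers
        for j, atom in enumerate(schedule.moved_atoms):
            rows.append(
                {
                    "stage": i,
                    "atom": atom,
                    "center_x": centers[j, 0],
                    "center_y": centers[j, 1],
                    "center_z": centers[j, 2],
                    "mean_x": mean[j, 0],
                    "mean_y": mean[j, 1],
                    "mean_z": mean[j, 2],
                    "work_increment": increment if j == 0 else 0.0,
                }
            )
        centers = centers_next
        state.centers = centers.copy()

    return state, pd.DataFrame(rows)
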