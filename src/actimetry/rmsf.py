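"""Per-residue RMSF and stiff-core detection.

RMSF_i = sqrt( <|r_i(t) - <r_i>|^2> ) over frames of a trajectory that has
been rigid-fitted to its mean structure, so that only internal motion is
counted.  The stiff core of a helical bundle shows up as contiguous runs
of residues whose fluctuation sits well below the rest of the chain;
``detect_stiff_core`` extracts such runs with a quantile cut.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import kabsch_fit
from .structure_io import (
    AtomLabel,
    ResidueRangeSelection,
    StructureModel,
    read_models,
    resolve_selection,
)

__all__ = [
    "Trajectory",
    "RMSFProfile",
    "align_trajectory",
    "rmsf_profile",
    "detect_stiff_core",
    "trajectory_from_models",
    "read_trajectory_table",
    "write_trajectory_table",
]


@dataclass(eq=False)
class Trajectory:
    """Frames (T, M, 3) over a fixed ordered atom list."""

    frames: np.ndarray
    labels: list[AtomLabel]
    frame_spacing_ps: float = 1.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must be a (T, M, 3) array")
        if self.frames.shape[1] != len(self.labels):
            raise ValueError("label count does not match atoms per frame")
        if self.frames.shape[0] < 2:
            raise ValueError("a trajectory needs at least 2 frames")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    def selection_indices(self, sel: ResidueRangeSelection) -> np.ndarray:
        wanted = []
        index = {lab: i for i, lab in enumerate(self.labels)}
        for chain, resnum in sel.residues():
            for name in sel.atom_names:
                for icode in ("",):
                    i = index.get((chain, resnum, icode, name))
                    if i is not None:
                        wanted.append(i)
        if len(wanted) < 3:
            raise ValueError("fit selection resolves to fewer than 3 trajectory atoms")
        return np.array(wanted, dtype=int)


@dataclass(eq=False)
class RMSFProfile:
    labels: list[AtomLabel]
    rmsf: np.ndarray  # (M,) Angstrom
    reference: str = "mean-structure"

    def __post_init__(self) -> None:
        self.rmsf = np.asarray(self.rmsf, dtype=float)
        if np.any(self.rmsf < 0):
            raise ValueError("RMSF values must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chain": [lab[0] for lab in self.labels],
                "resnum": [lab[1] for lab in self.labels],
                "atom": [lab[3] for lab in self.labels],
                "rmsf_A": self.rmsf,
            }
        )


def align_trajectory(
    traj: Trajectory, fit_selection: ResidueRangeSelection | None = None
) -> Trajectory:
    """Rigid-fit every frame to the trajectory mean structure.

    Two-pass: frames are first fitted to the raw mean, the mean is
    recomputed from the fitted frames, and each frame is refitted to the
    refined mean.  The fit uses only ``fit_selection`` atoms (all atoms if
    None); the resulting transform is applied to the whole frame.
    """
    idx = (
        np.arange(traj.n_atoms)
        if fit_selection is None
        else traj.selection_indices(fit_selection)
    )
    frames = traj.frames.copy()
    for _ in range(2):
        mean = frames.mean(axis=0)
        for t in range(frames.shape[0]):
            fit = kabsch_fit(frames[t, idx], mean[idx])
            frames[t] = fit.transform.apply(frames[t])
    return Trajectory(frames, list(traj.labels), traj.frame_spacing_ps)


def rmsf_profile(traj: Trajectory) -> RMSFProfile:
    """RMSF of each atom about its time-mean position (frame-order invariant)."""
    mean = traj.frames.mean(axis=0)
    dev2 = np.sum((traj.frames - mean) ** 2, axis=2)  # (T, M)
    return RMSFProfile(list(traj.labels), np.sqrt(dev2.mean(axis=0)))


def detect_stiff_core(
    profile: RMSFProfile, quantile: float = 0.25, min_run: int = 4
) -> list[tuple[str, int, int]]:
    """Contiguous low-fluctuation residue runs.

    A residue belongs to the core when its RMSF is strictly below the
    given quantile of the profile; runs of consecutive residue numbers
    (within one chain) of length >= ``min_run`` are returned as
    ``(chain, start, end)`` ranges, compatible with
    :class:`ResidueRangeSelection`.
    """
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must be in (0, 1)")
    if len(profile.labels) == 0:
        raise ValueError("empty RMSF profile")
    cut = float(np.quantile(profile.rmsf, quantile))
    # residue-level rmsf: mean over that residue's atoms
    res_vals: dict[tuple[str, int], list[float]] = {}
    order: list[tuple[str, int]] = []
    for lab, v in zip(profile.labels, profile.rmsf):
        key = (lab[0], lab[1])
        if key not in res_vals:
            order.append(key)
        res_vals.setdefault(key, []).append(float(v))
    low = [key for key in order if float(np.mean(res_vals[key])) < cut]
    runs: list[tuple[str, int, int]] = []
    for chain, resnum in low:
        if runs and runs[-1][0] == chain and resnum == runs[-1][2] + 1:
            runs[-1] = (chain, runs[-1][1], resnum)
        else:
            runs.append((chain, resnum, resnum))
    return [r for r in runs if r[2] - r[1] + 1 >= min_run]


def trajectory_from_models(
    models: Sequence[StructureModel],
    sel: ResidueRangeSelection | None = None,
    frame_spacing_ps: float = 1.0,
) -> Trajectory:
    """Stack per-frame structures (e.g. multi-MODEL PDB) into a Trajectory."""
    if len(models) < 2:
        raise ValueError("a trajectory needs at least 2 frames")
    if sel is not None:
        first_atoms, _ = resolve_selection(models[0], sel)
        labels = [a.label for a in first_atoms]
    else:
        labels = [a.label for a in models[0].atoms]
    frames = np.empty((len(models), len(labels), 3))
    for t, m in enumerate(models):
        index = m.index()
        try:
            frames[t] = np.vstack([index[lab].pos for lab in labels])
        except KeyError as exc:
            raise ValueError(f"frame {t} is missing atom {exc.args[0]}") from exc
    return Trajectory(frames, labels, frame_spacing_ps)


def read_trajectory_pdb(
    path: str | Path, sel: ResidueRangeSelection | None = None
) -> Trajectory:
    return trajectory_from_models(read_models(path), sel)


def read_trajectory_table(path: str | Path) -> Trajectory:
    """Read a whitespace table (frame chain resnum x y z) of Calpha positions."""
    df = pd.read_csv(
        path,
        sep=r"\s+",
        comment="#",
        names=["frame", "chain", "resnum", "x", "y", "z"],
        dtype={"frame": int, "chain": str, "resnum": int},
    )
    frames_ids = sorted(df["frame"].unique())
    first = df[df["frame"] == frames_ids[0]]
    labels: list[AtomLabel] = [
        (str(c), int(r), "", "CA") for c, r in zip(first["chain"], first["resnum"])
    ]
    frames = np.empty((len(frames_ids), len(labels), 3))
    for t, fid in enumerate(frames_ids):
        sub = df[df["frame"] == fid]
        if len(sub) != len(labels):
            raise ValueError(f"frame {fid} has {len(sub)} atoms, expected {len(labels)}")
        frames[t] = sub[["x", "y", "z"]].to_numpy()
    return Trajectory(frames, labels)


def write_trajectory_table(traj: Trajectory, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# frame chain resnum x y z\n")
        for t in range(traj.n_frames):
            for (chain, resnum, _icode, _name), pos in zip(
                traj.labels, traj.frames[t]
            ):
                fh.write(
                    f"{t} {chain} {resnum} "
                    f"{pos[0]:.4f} {pos[1]:.4f} {pos[2]:.4f}\n"
                )
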