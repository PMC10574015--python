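"""Synthetic helical-bundle structures and trajectories with ground truth.

Three generator families feed the test surface of the whole package:

* ideal Calpha alpha-helices (rise 1.5 A, twist 100 deg, radius 2.3 A per
  residue) assembled into a seven-helix bundle whose residue numbering
  mimics a class-A GPCR, so the CB1 stiff-core and indicator selections
  resolve on it;
* "conformational change" pairs in which a chosen sub-helix is rigidly
  displaced by a known amount while the stiff core stays put — the
  activation metric must then read back the displacement exactly;
* Gaussian-jitter trajectories with prescribed per-residue amplitudes,
  for which the expected RMSF is known in closed form (sqrt(3) sigma).

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rmsf import Trajectory
from .structure_io import Atom, ResidueRangeSelection, StructureModel

__all__ = [
    "HelixSpec",
    "build_helix",
    "build_cb1_like_bundle",
    "make_conformational_pair",
    "make_jitter_trajectory",
    "BUNDLE_HELICES",
]

RISE_PER_RESIDUE = 1.5  # A
TWIST_PER_RESIDUE = 100.0  # degrees
HELIX_RADIUS = 2.3  # A

#: (name, first residue, last residue) of the seven bundle helices.
#: Numbering covers the selections cited for CB1: stiff core 195-199 /
#: 243-249 / 275-289, indicator 351-361 / 381-391, plus the CV anchor
#: residues (V179 on TM2, F381 on TM7, and loop stubs for T125/P113/F102).
BUNDLE_HELICES = (
    ("TM1", 100, 140),
    ("TM2", 150, 188),
    ("TM3", 189, 224),
    ("TM4", 234, 252),
    ("TM5", 270, 296),
    ("TM6", 339, 367),
    ("TM7", 374, 400),
)


@dataclass(frozen=True)
class HelixSpec:
    """Geometry of one ideal Calpha helix."""

    chain: str = "A"
    first_residue: int = 1
    length: int = 10
    axis_origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    phase_deg: float = 0.0
    rise: float = RISE_PER_RESIDUE
    twist_deg: float = TWIST_PER_RESIDUE
    radius: float = HELIX_RADIUS

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("helix length must be >= 1")
        n = np.linalg.norm(self.axis_direction)
        if abs(n - 1.0) > 1e-6:
            object.__setattr__(
                self,
                "axis_direction",
                tuple(np.asarray(self.axis_direction, dtype=float) / n),
            )


def _axis_frame(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors orthogonal to the axis (deterministic choice)."""
    d = np.asarray(direction, dtype=float)
    seedvec = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(seedvec, d)) > 0.9:
        seedvec = np.array([0.0, 1.0, 0.0])
    u = seedvec - np.dot(seedvec, d) * d
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    return u, v


def build_helix(spec: HelixSpec) -> tuple[np.ndarray, list[tuple[str, int]]]:
    """Calpha coordinates and (chain, resnum) labels of an ideal helix."""
    d = np.asarray(spec.axis_direction, dtype=float)
    origin = np.asarray(spec.axis_origin, dtype=float)
    u, v = _axis_frame(d)
    j = np.arange(spec.length)
    ang = np.radians(spec.phase_deg + j * spec.twist_deg)
    coords = (
        origin[None, :]
        + np.outer(j * spec.rise, d)
        + spec.radius * (np.outer(np.cos(ang), u) + np.outer(np.sin(ang), v))
    )
    labels = [(spec.chain, spec.first_residue + int(k)) for k in j]
    return coords, labels


def _atoms_from_helix(spec: HelixSpec) -> list[Atom]:
    coords, labels = build_helix(spec)
    return [
        Atom(
            chain=chain,
            resnum=resnum,
            icode="",
            resname="ALA",
            name="CA",
            altloc="",
            occupancy=1.0,
            pos=coords[i],
        )
        for i, (chain, resnum) in enumerate(labels)
    ]


def build_cb1_like_bundle(seed: int = 0, chain: str = "A") -> StructureModel:
    """Seven ideal helices on a ring, numbered like a CB1 7TM domain.

    Helices alternate direction around a ring of radius 11 A; the seed
    only randomises helix phases, so the topology and numbering are
    always the same and every default selection resolves completely.
    A short three-residue stub (resnums 102, 113, 125) is added near TM1
    so the angle collective variable has its anchor atoms.
    """
    rng = np.random.default_rng(seed)
    phases = rng.uniform(0.0, 360.0, size=len(BUNDLE_HELICES))
    ring_radius = 11.0
    atoms: list[Atom] = []
    used: set[int] = set()
    for h, (name, first, last) in enumerate(BUNDLE_HELICES):
        theta = 2.0 * np.pi * h / len(BUNDLE_HELICES)
        length = last - first + 1
        up = h % 2 == 0
        origin = np.array(
            [
                ring_radius * np.cos(theta),
                ring_radius * np.sin(theta),
                0.0 if up else (length - 1) * RISE_PER_RESIDUE,
            ]
        )
        spec = HelixSpec(
            chain=chain,
            first_residue=first,
            length=length,
            axis_origin=tuple(origin),
            axis_direction=(0.0, 0.0, 1.0) if up else (0.0, 0.0, -1.0),
            phase_deg=float(phases[h]),
        )
        for a in _atoms_from_helix(spec):
            if a.resnum not in used:
                atoms.append(a)
                used.add(a.resnum)
    # N-terminal loop stub anchoring the angle CV (F102, P113, T125).
    stub = {102: (16.0, 4.0, 65.0), 113: (13.0, -3.0, 68.0), 125: (9.0, 2.0, 63.0)}
    for resnum, pos in stub.items():
        if resnum not in used:
            atoms.append(
                Atom(chain, resnum, "", "GLY", "CA", "", 1.0, np.array(pos, float))
            )
            used.add(resnum)
    atoms.sort(key=lambda a: a.resnum)
    return StructureModel(atoms, title="synthetic 7TM bundle", source_id=f"bundle-{seed}")


def _rotation_matrix(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    a = np.radians(angle_deg)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * (K @ K)


def make_conformational_pair(
    bundle: StructureModel,
    moved: ResidueRangeSelection,
    translation: np.ndarray = (0.0, 0.0, 0.0),
    rotation_axis: np.ndarray | None = None,
    rotation_angle_deg: float = 0.0,
    rotation_origin: np.ndarray | None = None,
    protected: ResidueRangeSelection | None = None,
) -> tuple[StructureModel, StructureModel, pd.DataFrame]:
    """Reference/displaced pair with exact per-atom ground truth.

    Atoms in ``moved`` are rigidly displaced (optional rotation about
    ``rotation_origin``, then translation); everything else is untouched.
    If ``protected`` (e.g. the stiff-core selection) overlaps the moved
    residues the call is refused, because the exactness guarantees of the
    activation metric rest on an unperturbed fitting core.

    Returns (reference, displaced, table of per-atom displacements).
    """
    translation = np.asarray(translation, dtype=float)
    moved_set = set(moved.residues())
    if protected is not None:
        overlap = moved_set & set(protected.residues())
        if overlap:
            raise ValueError(
                f"moved selection overlaps protected core residues: {sorted(overlap)}"
            )
    R = (
        _rotation_matrix(rotation_axis, rotation_angle_deg)
        if rotation_axis is not None and rotation_angle_deg != 0.0
        else None
    )
    displaced_atoms: list[Atom] = []
    rows = []
    moved_names = set(moved.atom_names)
    for a in bundle.atoms:
        if (a.chain, a.resnum) in moved_set and a.name in moved_names:
            pos = a.pos
            if R is not None:
                origin = (
                    np.zeros(3)
                    if rotation_origin is None
                    else np.asarray(rotation_origin, dtype=float)
                )
                pos = origin + R @ (pos - origin)
            pos = pos + translation
            displaced_atoms.append(
                Atom(a.chain, a.resnum, a.icode, a.resname, a.name, a.altloc, a.occupancy, pos)
            )
            rows.append(
                {
                    "chain": a.chain,
                    "resnum": a.resnum,
                    "atom": a.name,
                    "displacement_A": float(np.linalg.norm(pos - a.pos)),
                }
            )
        else:
            displaced_atoms.append(a)
    reference = StructureModel(
        list(bundle.atoms), list(bundle.hetero), bundle.title, bundle.source_id
    )
    displaced = StructureModel(
        displaced_atoms, list(bundle.hetero), bundle.title, bundle.source_id + "-displaced"
    )
    return reference, displaced, pd.DataFrame(rows)


def make_jitter_trajectory(
    reference: StructureModel,
    sigma: float | dict[int, float] | np.ndarray,
    n_frames: int,
    seed: int = 0,
    frame_spacing_ps: float = 1.0,
) -> Trajectory:
    """Frames = reference + isotropic Gaussian noise, per-coordinate std
    sigma_i for residue i.

    ``sigma`` may be a scalar, a {resnum: sigma} mapping (unlisted
    residues get the mapping's default key ``-1`` or 0), or an array
    aligned with the reference atoms.  Expected RMSF per atom is
    sqrt(3) * sigma_i.
    """
    if n_frames < 2:
        raise ValueError("a trajectory needs at least 2 frames")
    atoms = reference.atoms
    m = len(atoms)
    if isinstance(sigma, dict):
        default = float(sigma.get(-1, 0.0))
        sig = np.array([float(sigma.get(a.resnum, default)) for a in atoms])
    else:
        sig = np.broadcast_to(np.asarray(sigma, dtype=float), (m,)).copy()
    if np.any(sig < 0):
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng(seed)
    base = reference.coords()
    noise = rng.standard_normal((n_frames, m, 3)) * sig[None, :, None]
    return Trajectory(base[None, :, :] + noise, [a.label for a in atoms], frame_spacing_ps)
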