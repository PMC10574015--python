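"""Rigid-body superposition and distance metrics.

The superposition is the classic least-squares (Kabsch) fit on a chosen
atom subset: here typically the stiff transmembrane core used as the
common reference frame of all activation comparisons.  Metrics (RMSD, max
pairwise distance, collective-variable distance/angle) deliberately do NO
fitting of their own — they are evaluated in whatever frame a prior fit
produced, so that "RMSD after core superposition" means exactly that.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .structure_io import AtomLookupError, StructureModel

__all__ = [
    "RigidTransform",
    "FitResult",
    "kabsch_fit",
    "rmsd",
    "max_pair_distance",
    "cv_distance",
    "cv_angle",
]


@dataclass(frozen=True, eq=False)
class RigidTransform:
    """Proper rotation followed by translation: x -> R x + t."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if abs(np.linalg.det(R) - 1.0) > 1e-8:
            raise ValueError("rotation must be proper (det = +1)")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


@dataclass(frozen=True, eq=False)
class FitResult:
    transform: RigidTransform
    fit_rmsd: float
    n_atoms: int


def kabsch_fit(mobile: np.ndarray, reference: np.ndarray) -> FitResult:
    """Least-squares rigid superposition of *mobile* onto *reference*.

    Rows of the two (M, 3) arrays correspond.  Returns the proper-rotation
    transform minimising the RMSD of ``transform.apply(mobile)`` to
    *reference*, with reflections excluded via the sign of the smallest
    singular value.  Degenerate (rank-deficient, e.g. collinear) inputs
    emit a warning but still yield a proper rotation.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("mobile and reference must be matching (M, 3) arrays")
    m = P.shape[0]
    if m < 3:
        raise ValueError(f"superposition needs at least 3 atoms, got {m}")
    pc = P.mean(axis=0)
    qc = Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-10 * max(S[0], 1.0):
        warnings.warn(
            "rank-deficient (collinear or coincident) point set; "
            "superposition is not unique",
            RuntimeWarning,
            stacklevel=2,
        )
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d if d != 0 else 1.0])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    tr = RigidTransform(R, t)
    return FitResult(transform=tr, fit_rmsd=rmsd(tr.apply(P), Q), n_atoms=m)


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Root-mean-square deviation between row-matched coordinates (no fit)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("coordinate arrays must have equal shape")
    if a.shape[0] == 0:
        raise ValueError("RMSD of an empty atom set is undefined")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def max_pair_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Largest per-row displacement between row-matched coordinates."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("coordinate arrays must have equal shape")
    if a.shape[0] == 0:
        raise ValueError("max distance of an empty atom set is undefined")
    return float(np.max(np.linalg.norm(a - b, axis=1)))


def _atom_pos(structure: StructureModel, label: str | tuple) -> np.ndarray:
    """Resolve 'A:381:CA' or (chain, resnum, name) to a position."""
    if isinstance(label, str):
        parts = label.split(":")
        if len(parts) == 2:
            chain, res = parts
            name = "CA"
        elif len(parts) == 3:
            chain, res, name = parts
        else:
            raise AtomLookupError(f"cannot parse atom label {label!r}")
        try:
            resnum = int(res)
        except ValueError as exc:
            raise AtomLookupError(f"bad residue number in {label!r}") from exc
    else:
        chain, resnum, name = label[0], int(label[1]), label[2]
    return structure.get_atom(chain, resnum, name).pos


def cv_distance(structure: StructureModel, a: str | tuple, b: str | tuple) -> float:
    """Distance collective variable: |r_a - r_b| in Angstrom.

    Used e.g. as the Calpha(F381)-Calpha(V179) separation tracking the
    approach of TM7 to its active-state position.
    """
    return float(np.linalg.norm(_atom_pos(structure, a) - _atom_pos(structure, b)))


def cv_angle(
    structure: StructureModel, a: str | tuple, b: str | tuple, c: str | tuple
) -> float:
    """Angle collective variable a-b-c (b the vertex), in degrees [0, 180].

    Used e.g. as the Calpha T125-P113-F102 angle describing the lift of
    the N-terminal loop.
    """
    ra = _atom_pos(structure, a)
    rb = _atom_pos(structure, b)
    rc = _atom_pos(structure, c)
    v1 = ra - rb
    v2 = rc - rb
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 < 1e-12 or n2 < 1e-12:
        raise ValueError("undefined angle: zero-length arm")
    cosang = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))
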