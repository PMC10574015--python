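"""Overdamped Langevin (Brownian) toy dynamics with analytic oracles.

A desk-scale stand-in for a solvated MD system, used to exercise the
steering scheduler end to end.  Particles move in a potential assembled
from harmonic wells and pairwise harmonic bonds, integrated with the
Euler-Maruyama scheme

    r <- r + (F/gamma) dt + sqrt(2 kBT dt / gamma) xi,

which has the Boltzmann distribution exp(-U/kBT) as its stationary law
for small dt.  Temperature enters directly as kB*T in kcal/mol so all
energies share one unit.  For a particle in a harmonic well steered by a
harmonic restraint the free-energy change of moving the restraint center
is known in closed form, giving an exact target for the accumulated
switching work in the quasi-static limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Sequence

import numpy as np

from .smd import HarmonicRestraint

__all__ = [
    "HarmonicWell",
    "HarmonicBond",
    "ToySystem",
    "BrownianBackend",
    "brownian_step",
    "analytic_steering_dF",
]


@dataclass(frozen=True, eq=False)
class HarmonicWell:
    """U = k_s |r - center|^2 / 2 on one particle."""

    atom: Hashable
    center: np.ndarray
    k: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        if self.k <= 0:
            raise ValueError("well constant must be positive")


@dataclass(frozen=True, eq=False)
class HarmonicBond:
    """U = k_b (|r_a - r_b| - r0)^2 / 2 between two particles."""

    atom_a: Hashable
    atom_b: Hashable
    k: float
    rest_length: float = 0.0

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("bond constant must be positive")
        if self.rest_length < 0:
            raise ValueError("rest length must be non-negative")


@dataclass(eq=False)
class ToySystem:
    """Potential terms plus thermodynamic and integrator parameters."""

    labels: list
    wells: list[HarmonicWell] = field(default_factory=list)
    bonds: list[HarmonicBond] = field(default_factory=list)
    kBT: float = 0.593  # kcal/mol, ~298 K
    gamma: float = 1.0  # friction, mass/time
    dt: float = 0.01  # time step

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.gamma <= 0 or self.kBT < 0:
            raise ValueError("dt and gamma must be positive, kBT non-negative")
        known = set(self.labels)
        for w in self.wells:
            if w.atom not in known:
                raise ValueError(f"well references unknown particle {w.atom!r}")
        for b in self.bonds:
            if b.atom_a not in known or b.atom_b not in known:
                raise ValueError("bond references unknown particle")
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    @property
    def n(self) -> int:
        return len(self.labels)

    def forces(
        self,
        positions: np.ndarray,
        restraints: Sequence[HarmonicRestraint] = (),
    ) -> np.ndarray:
        pos = np.asarray(positions, dtype=float)
        F = np.zeros_like(pos)
        for w in self.wells:
            i = self._index[w.atom]
            F[i] -= w.k * (pos[i] - w.center)
        for b in self.bonds:
            i, j = self._index[b.atom_a], self._index[b.atom_b]
            dv = pos[i] - pos[j]
            r = np.linalg.norm(dv)
            if r > 1e-12:
                f = -b.k * (r - b.rest_length) * dv / r
            else:
                f = np.zeros(3)
            F[i] += f
            F[j] -= f
        for rs in restraints:
            i = self._index[rs.atom]
            F[i] -= rs.k * (pos[i] - rs.center)
        return F


def brownian_step(
    positions: np.ndarray,
    system: ToySystem,
    restraints: Sequence[HarmonicRestraint],
    rng: np.random.Generator,
) -> np.ndarray:
    """One Euler-Maruyama step of overdamped Langevin dynamics."""
    pos = np.asarray(positions, dtype=float)
    F = system.forces(pos, restraints)
    if not np.all(np.isfinite(F)):
        raise FloatingPointError(
            f"non-finite force encountered; positions:\n{pos!r}"
        )
    new = pos + (F / system.gamma) * system.dt
    if system.kBT > 0:
        sigma = np.sqrt(2.0 * system.kBT * system.dt / system.gamma)
        new = new + sigma * rng.standard_normal(pos.shape)
    if not np.all(np.isfinite(new)):
        raise FloatingPointError(
            f"numerical blow-up after step; positions:\n{pos!r}"
        )
    return new


class BrownianBackend:
    """Dynamics-backend adapter over :func:`brownian_step`.

    Satisfies the steering contract: ``labels``, ``get_positions()`` and
    ``run(n_steps, restraints, rng)``.
    """

    def __init__(self, system: ToySystem, initial_positions: np.ndarray):
        self.system = system
        pos = np.atleast_2d(np.asarray(initial_positions, dtype=float))
        if pos.shape != (system.n, 3):
            raise ValueError("initial positions must be (n_particles, 3)")
        self._pos = pos.copy()

    @property
    def labels(self) -> list:
        return list(self.system.labels)

    def get_positions(self) -> np.ndarray:
        return self._pos.copy()

    def run(
        self,
        n_steps: int,
        restraints: Sequence[HarmonicRestraint],
        rng: np.random.Generator,
    ) -> None:
        pos = self._pos
        for _ in range(n_steps):
            pos = brownian_step(pos, self.system, restraints, rng)
        self._pos = pos


def analytic_steering_dF(k_s: float, k: float, displacement: float) -> float:
    """Free-energy change of dragging a restrained particle in a well.

    For U = k_s x^2 / 2 plus restraint k (x - r0)^2 / 2 with the center
    moved from 0 to d, the configurational free energy is quadratic in
    r0 and

        dF = (1/2) * (k * k_s / (k + k_s)) * d^2 .

    In the stiff-restraint limit (k >> k_s) this tends to k_s d^2 / 2,
    the bare cost of carrying the particle up its well.
    """
    if k_s <= 0 or k <= 0:
        raise ValueError("force constants must be positive")
    return 0.5 * (k * k_s / (k + k_s)) * displacement**2
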