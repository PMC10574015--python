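"""Coordinate I/O and residue-range selections.

Structures are held as flat atom lists in author (PDB) residue numbering,
which is how class-A GPCR residues are cited in the structural literature
(e.g. Ser383 of CB1).  Parsing and serialisation of the PDB format are
delegated to :mod:`gemmi`; this module adds deterministic altloc
resolution, receptor-chain inference for fusion constructs, and ordered
expansion of residue-range selections into atom subsets.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "AtomLabel",
    "StructureModel",
    "ResidueRangeSelection",
    "PairedCoordinates",
    "StructureParseError",
    "EmptyStructureError",
    "InsufficientAtomsError",
    "AtomLookupError",
    "read_structure",
    "write_structure",
    "resolve_selection",
    "pair_structures",
    "parse_selection",
]

#: (chain id, author residue number, insertion code, atom name)
AtomLabel = tuple[str, int, str, str]

# Standard amino-acid residue names treated as protein even when a
# deposition tags them HETATM (e.g. MSE in some entries).
_AMINO3 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "SEC", "PYL",
}


class StructureParseError(ValueError):
    """Raised when a coordinate file cannot be parsed."""


class EmptyStructureError(ValueError):
    """Raised when a file contains no protein atoms."""


class InsufficientAtomsError(ValueError):
    """Raised when a selection or pairing resolves to fewer than 3 atoms."""


class AtomLookupError(KeyError):
    """Raised when a named atom cannot be found in a structure."""


@dataclass(frozen=True, eq=False)
class Atom:
    chain: str
    resnum: int
    icode: str
    resname: str
    name: str
    altloc: str
    occupancy: float
    pos: np.ndarray  # shape (3,), Angstrom

    @property
    def label(self) -> AtomLabel:
        return (self.chain, self.resnum, self.icode, self.name)


@dataclass(eq=False)
class StructureModel:
    """One coordinate model: protein atoms plus ligand/solvent kept aside."""

    atoms: list[Atom]
    hetero: list[Atom] = field(default_factory=list)
    title: str = ""
    source_id: str = ""

    def __post_init__(self) -> None:
        for a in self.atoms:
            if not np.all(np.isfinite(a.pos)):
                raise ValueError(f"non-finite coordinates for atom {a.label}")

    def __len__(self) -> int:
        return len(self.atoms)

    def index(self) -> dict[AtomLabel, Atom]:
        return {a.label: a for a in self.atoms}

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain, None)
        return list(seen)

    def receptor_chain(self, lo: int = 100, hi: int = 420) -> str:
        """Chain with the most residues numbered in [lo, hi].

        Crystal constructs of GPCRs carry fusion partners and antibody
        chains; the receptor chain is recognised as the one dominating the
        receptor numbering range.
        """
        counts: dict[str, set[tuple[int, str]]] = {}
        for a in self.atoms:
            if lo <= a.resnum <= hi:
                counts.setdefault(a.chain, set()).add((a.resnum, a.icode))
        if not counts:
            raise EmptyStructureError(
                f"no residues numbered {lo}-{hi} in any chain"
            )
        return max(sorted(counts), key=lambda c: len(counts[c]))

    def get_atom(self, chain: str, resnum: int, name: str, icode: str = "") -> Atom:
        for a in self.atoms:
            if (a.chain, a.resnum, a.icode, a.name) == (chain, resnum, icode, name):
                return a
        raise AtomLookupError(f"atom {chain}:{resnum}{icode}:{name} not found")

    def coords(self, atoms: Sequence[Atom] | None = None) -> np.ndarray:
        src = self.atoms if atoms is None else atoms
        if not src:
            return np.zeros((0, 3))
        return np.vstack([a.pos for a in src])

    def with_coords(self, coords: np.ndarray) -> "StructureModel":
        """Copy of the model with protein coordinates replaced row-for-row."""
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = [
            dataclasses.replace(a, pos=np.asarray(coords[i], dtype=float))
            for i, a in enumerate(self.atoms)
        ]
        return StructureModel(atoms, list(self.hetero), self.title, self.source_id)


@dataclass(frozen=True)
class ResidueRangeSelection:
    """Ordered residue intervals plus an atom-name filter (default Calpha)."""

    ranges: tuple[tuple[str, int, int], ...]
    atom_names: tuple[str, ...] = ("CA",)

    def __post_init__(self) -> None:
        for chain, start, end in self.ranges:
            if start > end:
                raise ValueError(f"range {chain}:{start}-{end} has start > end")
        if not self.atom_names:
            raise ValueError("atom name filter must not be empty")

    @classmethod
    def from_ranges(
        cls,
        ranges: Iterable[tuple[str, int, int]],
        atom_names: Iterable[str] = ("CA",),
    ) -> "ResidueRangeSelection":
        return cls(tuple((c, int(s), int(e)) for c, s, e in ranges), tuple(atom_names))

    def n_residues(self) -> int:
        return sum(end - start + 1 for _, start, end in self.ranges)

    def residues(self) -> list[tuple[str, int]]:
        out = []
        for chain, start, end in self.ranges:
            out.extend((chain, r) for r in range(start, end + 1))
        return out

    def with_chain(self, chain: str) -> "ResidueRangeSelection":
        return ResidueRangeSelection(
            tuple((chain, s, e) for _, s, e in self.ranges), self.atom_names
        )

    def to_string(self) -> str:
        body = ",".join(f"{c}:{s}-{e}" for c, s, e in self.ranges)
        return f"{body}@{','.join(self.atom_names)}"


_RANGE_RE = re.compile(r"^([A-Za-z0-9]):(-?\d+)(?:-(-?\d+))?$")


def parse_selection(text: str) -> ResidueRangeSelection:
    """Parse ``"A:195-199,A:243-249,A:275-289@CA"`` into a selection."""
    text = text.strip()
    if "@" in text:
        body, _, names = text.rpartition("@")
        atom_names = tuple(n.strip() for n in names.split(",") if n.strip())
    else:
        body, atom_names = text, ("CA",)
    ranges = []
    for token in body.split(","):
        token = token.strip()
        if not token:
            continue
        m = _RANGE_RE.match(token)
        if m is None:
            raise ValueError(f"cannot parse selection token {token!r}")
        chain, start, end = m.group(1), int(m.group(2)), m.group(3)
        ranges.append((chain, start, int(end) if end is not None else start))
    if not ranges:
        raise ValueError(f"empty selection {text!r}")
    return ResidueRangeSelection.from_ranges(ranges, atom_names)


@dataclass(eq=False)
class PairedCoordinates:
    """Row-matched coordinates of two structures over a common selection."""

    labels: list[AtomLabel]
    coords_a: np.ndarray
    coords_b: np.ndarray
    dropped: list[AtomLabel] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.coords_a.shape != self.coords_b.shape:
            raise ValueError("paired coordinate arrays must have equal shape")
        if len(self.labels) != self.coords_a.shape[0]:
            raise ValueError("label count does not match coordinate rows")

    @property
    def n(self) -> int:
        return len(self.labels)


def _resolve_altlocs(atoms: list[Atom], policy: str) -> list[Atom]:
    if policy not in ("first", "highest-occupancy"):
        raise ValueError(f"unknown altloc policy {policy!r}")
    groups: dict[AtomLabel, list[Atom]] = {}
    order: list[AtomLabel] = []
    for a in atoms:
        if a.label not in groups:
            order.append(a.label)
        groups.setdefault(a.label, []).append(a)
    resolved = []
    for lab in order:
        cands = groups[lab]
        if len(cands) == 1:
            resolved.append(cands[0])
        elif policy == "first":
            resolved.append(cands[0])
        else:
            # highest occupancy, ties broken by lexicographically first altloc
            resolved.append(
                min(cands, key=lambda a: (-a.occupancy, a.altloc))
            )
    return resolved


def read_structure(
    path: str | Path,
    altloc_policy: str = "highest-occupancy",
    model_index: int = 0,
) -> StructureModel:
    """Read one model from a PDB file.

    HETATM ligand/solvent records are excluded from the protein atom list
    but retained on ``StructureModel.hetero``.  Author residue numbering and
    insertion codes are preserved verbatim.
    """
    path = Path(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path} contains no coordinate model")
    model = st[model_index]
    protein: list[Atom] = []
    hetero: list[Atom] = []
    for chain in model:
        for res in chain:
            is_protein = res.het_flag == "A" or res.name in _AMINO3
            for at in res:
                rec = Atom(
                    chain=chain.name,
                    resnum=res.seqid.num,
                    icode=(res.seqid.icode or "").strip(),
                    resname=res.name,
                    name=at.name,
                    altloc=at.altloc or "",
                    occupancy=float(at.occ),
                    pos=np.array([at.pos.x, at.pos.y, at.pos.z], dtype=float),
                )
                (protein if is_protein else hetero).append(rec)
    if not protein:
        raise EmptyStructureError(f"{path} contains no protein atoms")
    return StructureModel(
        atoms=_resolve_altlocs(protein, altloc_policy),
        hetero=hetero,
        title=st.name or "",
        source_id=path.stem,
    )


def read_models(path: str | Path, altloc_policy: str = "highest-occupancy") -> list[StructureModel]:
    """Read every MODEL of a multi-model PDB file (trajectory storage)."""
    path = Path(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path} contains no coordinate model")
    return [read_structure(path, altloc_policy, model_index=i) for i in range(len(st))]


def write_structure(model: StructureModel, path: str | Path, models: Sequence[StructureModel] | None = None) -> None:
    """Write a model (or a list of models as MODEL/ENDMDL frames) to PDB."""
    st = gemmi.Structure()
    st.name = model.title or model.source_id or "actimetry"
    frames = [model] if models is None else list(models)
    for i, frame in enumerate(frames, start=1):
        gm = gemmi.Model(i)
        chain_map: dict[str, gemmi.Chain] = {}
        for group, het in ((frame.atoms, False), (frame.hetero, True)):
            for a in group:
                ch = chain_map.get(a.chain)
                if ch is None:
                    ch = gemmi.Chain(a.chain)
                    chain_map[a.chain] = ch
                    gm.add_chain(ch)
                    ch = gm[len(gm) - 1]
                    chain_map[a.chain] = ch
                res = None
                if len(ch) > 0:
                    last = ch[len(ch) - 1]
                    if (last.seqid.num, last.seqid.icode.strip(), last.name) == (
                        a.resnum,
                        a.icode,
                        a.resname,
                    ):
                        res = last
                if res is None:
                    res = gemmi.Residue()
                    res.name = a.resname
                    res.seqid = gemmi.SeqId(a.resnum, a.icode or " ")
                    res.het_flag = "H" if het else "A"
                    ch.add_residue(res)
                    res = ch[len(ch) - 1]
                ga = gemmi.Atom()
                ga.name = a.name
                ga.altloc = a.altloc or "\0"
                ga.occ = a.occupancy
                ga.element = gemmi.Element(a.name[:1] if a.name[:1].isalpha() else "C")
                ga.pos = gemmi.Position(*a.pos)
                res.add_atom(ga)
        st.add_model(gm)
    st.setup_entities()
    doc_path = str(Path(path))
    st.write_pdb(doc_path)


def resolve_selection(
    structure: StructureModel, sel: ResidueRangeSelection
) -> tuple[list[Atom], list[tuple[str, int]]]:
    """Expand a selection into an ordered atom list.

    Returns ``(atoms, missing)`` where *missing* lists (chain, resnum)
    pairs named by the selection but absent from the structure.  Ordering
    is (range order, residue order, atom-name order) and is deterministic.
    """
    by_residue: dict[tuple[str, int], dict[str, Atom]] = {}
    for a in structure.atoms:
        by_residue.setdefault((a.chain, a.resnum), {}).setdefault(a.name, a)
    atoms: list[Atom] = []
    missing: list[tuple[str, int]] = []
    for chain, resnum in sel.residues():
        res_atoms = by_residue.get((chain, resnum))
        found = False
        if res_atoms:
            for name in sel.atom_names:
                if name in res_atoms:
                    atoms.append(res_atoms[name])
                    found = True
        if not found:
            missing.append((chain, resnum))
    if len(atoms) < 3:
        raise InsufficientAtomsError(
            f"selection {sel.to_string()} resolves to {len(atoms)} atoms (< 3)"
        )
    return atoms, missing


def pair_structures(
    a: StructureModel, b: StructureModel, sel: ResidueRangeSelection
) -> PairedCoordinates:
    """Pair atoms of two structures over a selection by shared labels.

    Labels present in only one structure are reported in ``dropped``,
    never interpolated.
    """
    atoms_a, missing_a = resolve_selection(a, sel)
    atoms_b, missing_b = resolve_selection(b, sel)
    index_b = {at.label: at for at in atoms_b}
    labels: list[AtomLabel] = []
    rows_a: list[np.ndarray] = []
    rows_b: list[np.ndarray] = []
    dropped: list[AtomLabel] = []
    for at in atoms_a:
        mate = index_b.get(at.label)
        if mate is None:
            dropped.append(at.label)
        else:
            labels.append(at.label)
            rows_a.append(at.pos)
            rows_b.append(mate.pos)
    labels_a = {at.label for at in atoms_a}
    dropped.extend(at.label for at in atoms_b if at.label not in labels_a)
    if len(labels) < 3:
        raise InsufficientAtomsError(
            f"only {len(labels)} atoms paired on {sel.to_string()} (< 3)"
        )
    return PairedCoordinates(
        labels=labels,
        coords_a=np.vstack(rows_a),
        coords_b=np.vstack(rows_b),
        dropped=dropped,
    )
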