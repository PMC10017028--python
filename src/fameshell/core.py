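"""Core domain containers: atoms, role-labeled systems, frames, trajectories.

Conventions used throughout the package:

* coordinates are always in Angstrom internally,
* residue indices are 0-based internally; every emitted table is 1-based,
* boxes are orthorhombic, given as three edge lengths in Angstrom.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np


class Role(str, enum.Enum):
    """Structural role of an atom/residue in a lipidated-peptide system."""

    LIPID = "lipid"
    LIPIDATION_SITE = "lipidation_site"
    ELP = "elp"
    WATER = "water"
    OTHER = "other"


#: roles that make up the peptide chain proper
PEPTIDE_ROLES = frozenset({Role.LIPIDATION_SITE, Role.ELP})


@dataclass(frozen=True)
class AtomRecord:
    """A single atom with its residue membership and role label.

    ``position`` holds the reference coordinates of the system topology;
    per-frame coordinates live in :class:`Frame`.
    """

    serial: int
    name: str
    element: str
    residue_index: int
    residue_name: str
    role: Role
    position: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"


@dataclass(frozen=True)
class Residue:
    """A residue: contiguous atom span ``[start, stop)`` in the atom list."""

    index: int
    name: str
    role: Role
    start: int
    stop: int

    @property
    def n_atoms(self) -> int:
        return self.stop - self.start


class LabeledSystem:
    """An ordered collection of atoms grouped into role-labeled residues.

    Validates on construction that

    * atom serials are unique,
    * residue atom spans are contiguous and non-overlapping (atoms of one
      residue are adjacent in the atom list),
    * water residues contain either 3 atoms (O, H, H) or a single oxygen
      (the O-only dialect used by the synthetic generator).
    """

    def __init__(self, atoms: Sequence[AtomRecord]):
        atoms = tuple(atoms)
        if not atoms:
            raise ValueError("a LabeledSystem needs at least one atom")
        serials = [a.serial for a in atoms]
        if len(set(serials)) != len(serials):
            raise ValueError("atom serials must be unique within a system")
        self.atoms: tuple[AtomRecord, ...] = atoms

        # group into residues; spans must be contiguous
        residues: list[Residue] = []
        seen: set[int] = set()
        start = 0
        for i, atom in enumerate(atoms):
            nxt = atoms[i + 1] if i + 1 < len(atoms) else None
            if nxt is None or nxt.residue_index != atom.residue_index:
                ridx = atom.residue_index
                if ridx in seen:
                    raise ValueError(
                        f"residue {ridx} has a non-contiguous atom span"
                    )
                seen.add(ridx)
                block = atoms[start : i + 1]
                if any(a.residue_name != atom.residue_name for a in block) or any(
                    a.role != atom.role for a in block
                ):
                    raise ValueError(
                        f"residue {ridx} mixes names or roles across its atoms"
                    )
                residues.append(
                    Residue(ridx, atom.residue_name, atom.role, start, i + 1)
                )
                start = i + 1
        self.residues: tuple[Residue, ...] = tuple(residues)

        for res in self.residues:
            if res.role is Role.WATER and res.n_atoms not in (1, 3):
                raise ValueError(
                    f"water residue {res.index} has {res.n_atoms} atoms; "
                    "expected 3 (O,H,H) or 1 (O-only)"
                )

        # cached numpy views used by the distance machinery
        self._reference = np.array([a.position for a in atoms], dtype=float)
        self._heavy = np.array([a.is_heavy for a in atoms], dtype=bool)
        self._atom_residue = np.array([a.residue_index for a in atoms], dtype=int)
        self._roles = np.array([a.role.value for a in atoms], dtype=object)

    # ------------------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def reference_positions(self) -> np.ndarray:
        """(N, 3) reference coordinates in Angstrom (copy)."""
        return self._reference.copy()

    @property
    def heavy_mask(self) -> np.ndarray:
        return self._heavy.copy()

    @property
    def atom_residue_indices(self) -> np.ndarray:
        return self._atom_residue.copy()

    @property
    def peptide_residues(self) -> tuple[Residue, ...]:
        return tuple(r for r in self.residues if r.role in PEPTIDE_ROLES)

    @property
    def water_residues(self) -> tuple[Residue, ...]:
        return tuple(r for r in self.residues if r.role is Role.WATER)

    @property
    def peptide_length(self) -> int:
        """Number of peptide residues (lipidation site + ELP)."""
        return len(self.peptide_residues)

    def atoms_of(self, residue: Residue) -> tuple[AtomRecord, ...]:
        return self.atoms[residue.start : residue.stop]

    def atom_indices(
        self,
        roles: Iterable[Role] = PEPTIDE_ROLES,
        heavy_only: bool = True,
    ) -> np.ndarray:
        """Indices of atoms whose residue role is in ``roles``."""
        roleset = {Role(r).value for r in roles}
        mask = np.isin(self._roles, list(roleset))
        if heavy_only:
            mask &= self._heavy
        return np.nonzero(mask)[0]

    def water_counting_atoms(self, which: str = "water_oxygen") -> np.ndarray:
        """Atom indices used to decide water-shell membership.

        ``water_oxygen``: one oxygen per water molecule (errors if a water
        has none); ``any_water_atom``: every water atom.
        """
        idx: list[int] = []
        for res in self.water_residues:
            if which == "any_water_atom":
                idx.extend(range(res.start, res.stop))
            elif which == "water_oxygen":
                oxy = [
                    i
                    for i in range(res.start, res.stop)
                    if self.atoms[i].element.upper() == "O"
                ]
                if not oxy:
                    raise ValueError(
                        f"water residue {res.index} has no oxygen atom"
                    )
                idx.extend(oxy)
            else:
                raise ValueError(f"unknown counting-atom mode {which!r}")
        return np.asarray(idx, dtype=int)


@dataclass
class Frame:
    """One trajectory snapshot: coordinates plus optional metadata."""

    positions: np.ndarray
    box: np.ndarray | None = None
    temperature: float | None = None
    time: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be an (N, 3) array")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float).reshape(3)
            if np.any(self.box <= 0):
                raise ValueError("box edge lengths must be strictly positive")


@dataclass
class Trajectory:
    """An ordered list of frames sharing one :class:`LabeledSystem`."""

    system: LabeledSystem
    frames: list[Frame]

    def __post_init__(self) -> None:
        for k, fr in enumerate(self.frames):
            if fr.positions.shape[0] != self.system.n_atoms:
                raise ValueError(
                    f"frame {k} has {fr.positions.shape[0]} positions for a "
                    f"{self.system.n_atoms}-atom system"
                )
        times = [fr.time for fr in self.frames if fr.time is not None]
        if len(times) > 1 and any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("frame times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)
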