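"""Reading/writing coordinate files and result tables.

PDB (multi-MODEL) and GRO are handled through biotite; XYZ is an extended
dialect whose per-frame comment line carries ``T=<K> t=<ps>`` metadata.
Because none of these formats can store role labels or (for PDB/GRO)
per-frame temperature, :func:`write_trajectory` emits a JSON sidecar
(``<path>.meta.json``) that :func:`read_structure` picks up when present.

Internal coordinates are Angstrom (GRO nm are converted on read/write) and
residue indices are 0-based; emitted tables are 1-based.
"""

from __future__ import annotations

import json
import os
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import AtomRecord, Frame, LabeledSystem, Role, Trajectory

#: residue names recognized as water by default
DEFAULT_WATER_NAMES = frozenset({"HOH", "SOL", "TIP3", "TIP3P", "TIP4", "SPC", "WAT"})
#: residue names recognized as the myristoyl lipid by default
DEFAULT_LIPID_NAMES = frozenset({"MYR"})

AMINO_ACIDS_3 = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP "
    "TYR VAL HSD HSE HSP".split()
)

_FORMATS = ("pdb", "gro", "xyz")


class FormatError(ValueError):
    """Raised when a coordinate file cannot be parsed."""


def _infer_format(path: str | os.PathLike) -> str:
    suffix = Path(path).suffix.lower().lstrip(".")
    if suffix in _FORMATS:
        return suffix
    raise FormatError(f"cannot infer format from suffix of {path!r}")


def _guess_element(atom_name: str) -> str:
    for ch in atom_name:
        if ch.isalpha():
            return ch.upper()
    return "X"


def _check_orthorhombic(box_matrix: np.ndarray, path) -> np.ndarray | None:
    """Extract edge lengths from a 3x3 box matrix; reject triclinic cells."""
    if box_matrix is None:
        return None
    m = np.asarray(box_matrix, dtype=float)
    off = m - np.diag(np.diag(m))
    if np.any(np.abs(off) > 1e-4):
        raise FormatError(f"{path}: triclinic boxes are not supported")
    edges = np.diag(m)
    if np.all(edges == 0):
        return None
    return edges


# ----------------------------------------------------------------------
# readers
# ----------------------------------------------------------------------

def read_structure(path: str | os.PathLike, fmt: str | None = None) -> Trajectory:
    """Read a multi-frame coordinate file into a :class:`Trajectory`.

    Atoms keep their file order; all frames share one topology.  Roles are
    restored from the JSON sidecar when present, otherwise every residue is
    labeled ``other`` and :func:`assign_roles` should be applied.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = fmt or _infer_format(path)
    if fmt == "pdb":
        traj = _read_pdb_or_gro(path, "pdb")
    elif fmt == "gro":
        traj = _read_pdb_or_gro(path, "gro")
    elif fmt == "xyz":
        traj = _read_xyz(path)
    else:
        raise FormatError(f"unknown format {fmt!r}")
    if not traj.frames:
        raise FormatError(f"{path}: file contains zero frames")
    _apply_sidecar(traj, path)
    return traj


def _read_pdb_or_gro(path: Path, fmt: str) -> Trajectory:
    try:
        if fmt == "pdb":
            from biotite.structure.io.pdb import PDBFile

            f = PDBFile.read(str(path))
            stack = f.get_structure(model=None)
        else:
            from biotite.structure.io.gro import GROFile

            f = GROFile.read(str(path))
            stack = f.get_structure(model=None)
    except Exception as exc:  # biotite raises various parse errors
        raise FormatError(f"{path}: parse failure ({exc})") from exc

    n_models = stack.stack_depth()
    if n_models == 0 or stack.array_length() == 0:
        raise FormatError(f"{path}: file contains zero frames")

    elements = getattr(stack, "element", None)
    names = stack.atom_name
    res_ids = stack.res_id
    res_names = stack.res_name

    # map file residue ids (which may restart) to sequential 0-based indices
    internal = np.zeros(stack.array_length(), dtype=int)
    current = -1
    prev = None
    for i in range(stack.array_length()):
        key = (stack.chain_id[i], res_ids[i], res_names[i])
        if key != prev:
            current += 1
            prev = key
        internal[i] = current

    atoms = []
    coords0 = stack.coord[0]
    for i in range(stack.array_length()):
        elem = ""
        if elements is not None:
            elem = str(elements[i]).strip()
        if not elem:
            elem = _guess_element(str(names[i]))
        atoms.append(
            AtomRecord(
                serial=i + 1,
                name=str(names[i]),
                element=elem.capitalize(),
                residue_index=int(internal[i]),
                residue_name=str(res_names[i]),
                role=Role.OTHER,
                position=tuple(coords0[i]),
            )
        )
    system = LabeledSystem(atoms)

    boxes = stack.box  # (m, 3, 3) or None
    frames = []
    for m in range(n_models):
        edges = _check_orthorhombic(boxes[m], path) if boxes is not None else None
        frames.append(Frame(positions=np.array(stack.coord[m]), box=edges))
    return Trajectory(system, frames)


def _read_xyz(path: Path) -> Trajectory:
    """Extended XYZ: ``T=<K> t=<ps>`` in the comment line; one residue per
    atom (topology information is carried by the sidecar, if any)."""
    frames_raw: list[tuple[list[str], np.ndarray, float | None, float | None]] = []
    with open(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            lineno += 1
            if not header.strip():
                break
            try:
                n = int(header)
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: expected atom count, got {header!r}"
                ) from exc
            comment = fh.readline()
            lineno += 1
            temperature = time = None
            for token in comment.split():
                if token.startswith("T="):
                    temperature = float(token[2:])
                elif token.startswith("t="):
                    time = float(token[2:])
            symbols: list[str] = []
            coords = np.empty((n, 3))
            for i in range(n):
                line = fh.readline()
                lineno += 1
                parts = line.split()
                if len(parts) < 4:
                    raise FormatError(f"{path}:{lineno}: malformed XYZ atom line")
                symbols.append(parts[0])
                coords[i] = [float(v) for v in parts[1:4]]
            frames_raw.append((symbols, coords, temperature, time))
    if not frames_raw:
        raise FormatError(f"{path}: file contains zero frames")

    symbols, coords0, _, _ = frames_raw[0]
    atoms = [
        AtomRecord(
            serial=i + 1,
            name=sym,
            element=_guess_element(sym),
            residue_index=i,
            residue_name="UNK",
            role=Role.OTHER,
            position=tuple(coords0[i]),
        )
        for i, sym in enumerate(symbols)
    ]
    system = LabeledSystem(atoms)
    frames = [
        Frame(positions=c, temperature=T, time=t) for _, c, T, t in frames_raw
    ]
    return Trajectory(system, frames)


# ----------------------------------------------------------------------
# writers
# ----------------------------------------------------------------------

def write_trajectory(
    trajectory: Trajectory,
    path: str | os.PathLike,
    fmt: str | None = None,
    sidecar: bool = True,
) -> Path:
    """Write a trajectory; optionally emit the JSON metadata sidecar."""
    path = Path(path)
    fmt = fmt or _infer_format(path)
    if fmt in ("pdb", "gro"):
        _write_pdb_or_gro(trajectory, path, fmt)
    elif fmt == "xyz":
        _write_xyz(trajectory, path)
    else:
        raise FormatError(f"unknown format {fmt!r}")
    if sidecar:
        _write_sidecar(trajectory, path)
    return path


def _build_stack(trajectory: Trajectory):
    import biotite.structure as struc

    system = trajectory.system
    n = system.n_atoms
    m = len(trajectory.frames)
    stack = struc.AtomArrayStack(m, n)
    stack.coord = np.stack([fr.positions for fr in trajectory.frames])
    stack.set_annotation("chain_id", np.array(["A"] * n, dtype="U4"))
    stack.set_annotation(
        "res_id", np.array([a.residue_index + 1 for a in system.atoms], dtype=int)
    )
    stack.set_annotation(
        "res_name", np.array([a.residue_name for a in system.atoms], dtype="U5")
    )
    stack.set_annotation(
        "atom_name", np.array([a.name for a in system.atoms], dtype="U6")
    )
    stack.set_annotation(
        "element", np.array([a.element.upper() for a in system.atoms], dtype="U2")
    )
    stack.set_annotation(
        "hetero",
        np.array(
            [a.role in (Role.WATER, Role.LIPID, Role.OTHER) for a in system.atoms]
        ),
    )
    boxes = [fr.box for fr in trajectory.frames]
    if all(b is not None for b in boxes):
        stack.box = np.stack([np.diag(b) for b in boxes])
    return stack


def _write_pdb_or_gro(trajectory: Trajectory, path: Path, fmt: str) -> None:
    stack = _build_stack(trajectory)
    if fmt == "pdb":
        from biotite.structure.io.pdb import PDBFile

        f = PDBFile()
        f.set_structure(stack)
    else:
        from biotite.structure.io.gro import GROFile

        f = GROFile()
        f.set_structure(stack)
    f.write(str(path))


def _write_xyz(trajectory: Trajectory, path: Path) -> None:
    system = trajectory.system
    with open(path, "w") as fh:
        for fr in trajectory.frames:
            fh.write(f"{system.n_atoms}\n")
            tokens = []
            if fr.temperature is not None:
                tokens.append(f"T={fr.temperature:g}")
            if fr.time is not None:
                tokens.append(f"t={fr.time:g}")
            fh.write(" ".join(tokens) + "\n")
            for atom, pos in zip(system.atoms, fr.positions):
                fh.write(
                    f"{atom.element:<2s} {pos[0]:12.6f} {pos[1]:12.6f} "
                    f"{pos[2]:12.6f}\n"
                )


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json")


def _write_sidecar(trajectory: Trajectory, path: Path) -> None:
    system = trajectory.system
    payload = {
        "residue_roles": [r.role.value for r in system.residues],
        "frames": [
            {
                "temperature": fr.temperature,
                "time": fr.time,
                "meta": _jsonable(fr.meta),
            }
            for fr in trajectory.frames
        ],
    }
    with open(_sidecar_path(path), "w") as fh:
        json.dump(payload, fh, sort_keys=True)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def _apply_sidecar(trajectory: Trajectory, path: Path) -> None:
    sc = _sidecar_path(path)
    if not sc.exists():
        return
    with open(sc) as fh:
        payload = json.load(fh)
    roles = payload.get("residue_roles")
    system = trajectory.system
    if roles is not None and len(roles) == len(system.residues):
        atoms = []
        for res, role in zip(system.residues, roles):
            for atom in system.atoms_of(res):
                atoms.append(
                    AtomRecord(
                        serial=atom.serial,
                        name=atom.name,
                        element=atom.element,
                        residue_index=atom.residue_index,
                        residue_name=atom.residue_name,
                        role=Role(role),
                        position=atom.position,
                    )
                )
        trajectory.system = LabeledSystem(atoms)
    metas = payload.get("frames", [])
    for fr, fm in zip(trajectory.frames, metas):
        fr.temperature = fm.get("temperature")
        fr.time = fm.get("time")
        fr.meta = fm.get("meta", {}) or {}


# ----------------------------------------------------------------------
# role assignment
# ----------------------------------------------------------------------

def assign_roles(
    obj: Trajectory | LabeledSystem,
    rules: Mapping[str, str] | None = None,
    default_role: str | Role | None = None,
    lipidation_site_length: int = 20,
) -> LabeledSystem:
    """Label residues as lipid / lipidation_site / elp / water / other.

    ``rules`` maps residue names to a role name or the pseudo-role
    ``"peptide"``; defaults send common water names to ``water``, ``MYR``
    to ``lipid`` and the 20 amino acids to ``peptide``.  Because residue
    names cannot distinguish the lipidation site from the ELP domain, the
    first ``lipidation_site_length`` peptide residues become the lipidation
    site (12 recognition residues + 8 His by default) and the rest ELP.
    """
    system = obj.system if isinstance(obj, Trajectory) else obj
    table: dict[str, str] = {name: "water" for name in DEFAULT_WATER_NAMES}
    table.update({name: "lipid" for name in DEFAULT_LIPID_NAMES})
    table.update({name: "peptide" for name in AMINO_ACIDS_3})
    if rules:
        table.update({k: str(Role(v).value) if v != "peptide" else "peptide"
                      for k, v in rules.items()})

    coarse: list[str] = []
    unmapped: list[str] = []
    for res in system.residues:
        label = table.get(res.name)
        if label is None:
            if default_role is not None:
                label = Role(default_role).value
            else:
                unmapped.append(res.name)
                continue
        coarse.append(label)
    if unmapped:
        raise ValueError(
            "no role rule for residue name(s): " + ", ".join(sorted(set(unmapped)))
        )

    # split peptide residues positionally into lipidation site and ELP
    peptide_seen = 0
    final: list[Role] = []
    for label in coarse:
        if label == "peptide":
            final.append(
                Role.LIPIDATION_SITE
                if peptide_seen < lipidation_site_length
                else Role.ELP
            )
            peptide_seen += 1
        else:
            final.append(Role(label))

    atoms = []
    for res, role in zip(system.residues, final):
        for atom in system.atoms_of(res):
            atoms.append(
                AtomRecord(
                    serial=atom.serial,
                    name=atom.name,
                    element=atom.element,
                    residue_index=atom.residue_index,
                    residue_name=atom.residue_name,
                    role=role,
                    position=atom.position,
                )
            )
    return LabeledSystem(atoms)


# ----------------------------------------------------------------------
# tables
# ----------------------------------------------------------------------

def write_profile_table(
    rows: Sequence[Mapping],
    path: str | os.PathLike,
    columns: Iterable[str] | None = None,
) -> Path:
    """Write keyed records as a TSV table.

    Floats are written at 6 significant digits; any ``residue_index``
    column is converted from the internal 0-based to the emitted 1-based
    convention.
    """
    path = Path(path)
    if rows:
        keysets = {frozenset(r.keys()) for r in rows}
        if len(keysets) != 1:
            raise ValueError("all records must share one key set")
        df = pd.DataFrame(list(rows))
    else:
        if columns is None:
            raise ValueError("empty row list needs explicit columns")
        df = pd.DataFrame(columns=list(columns))
    if "residue_index" in df.columns and len(df):
        df = df.assign(residue_index=df["residue_index"].astype(int) + 1)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path


def read_profile_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a TSV written by :func:`write_profile_table`; restores 0-based
    residue indices."""
    df = pd.read_csv(path, sep="\t")
    if "residue_index" in df.columns and len(df):
        df = df.assign(residue_index=df["residue_index"].astype(int) - 1)
    return df
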