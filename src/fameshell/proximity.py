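"""First-hydration-shell water counts (N_w) and intrachain contacts (N_pp).

Definitions follow the standard shell/contact conventions for a single
solvated peptide chain:

* a water molecule belongs to the chain's first hydration shell when one of
  its counting atoms (its oxygen, by default) lies strictly within
  ``water_cutoff`` (3.15 A) of a peptide solute atom (heavy atoms only, by
  default);
* two peptide residues are in contact when at least one heavy-atom pair is
  strictly within ``contact_cutoff`` (6.0 A) and the residues are at least
  ``min_sequence_separation`` (3) apart in sequence, which excludes the
  bonded neighbors that are trivially close.

All predicates compare *squared* distances so that the strict "<" at the
cutoff behaves deterministically even for exactly-on-boundary input.  A
periodic orthorhombic box triggers minimum-image distances (valid only for
cutoffs below half the smallest edge); the accelerated cell/tree search is
backed by ``scipy.spatial.cKDTree`` and an O(N*M) brute-force path is kept
as an independent oracle (``method="brute"``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.spatial import cKDTree

from .core import Frame, LabeledSystem, Role, Trajectory, PEPTIDE_ROLES


@dataclass(frozen=True)
class ShellParams:
    """Cutoffs and conventions for shell/contact counting."""

    water_cutoff: float = 3.15
    contact_cutoff: float = 6.0
    min_sequence_separation: int = 3
    counting_atom: str = "water_oxygen"  # or "any_water_atom"
    solute_atoms: str = "heavy"  # or "all"
    include_lipid: bool = False
    contact_mode: str = "residue_pairs"  # or "atom_pairs"

    def __post_init__(self) -> None:
        if self.water_cutoff <= 0 or self.contact_cutoff <= 0:
            raise ValueError("cutoffs must be positive")
        if self.min_sequence_separation < 1:
            raise ValueError("min_sequence_separation must be >= 1")
        if self.counting_atom not in ("water_oxygen", "any_water_atom"):
            raise ValueError(f"unknown counting_atom {self.counting_atom!r}")
        if self.solute_atoms not in ("heavy", "all"):
            raise ValueError(f"unknown solute_atoms {self.solute_atoms!r}")
        if self.contact_mode not in ("residue_pairs", "atom_pairs"):
            raise ValueError(f"unknown contact_mode {self.contact_mode!r}")


@dataclass
class HydrationProfile:
    """Per-residue first-shell water counts (single frame or time average)."""

    residue_indices: np.ndarray
    per_residue_counts: np.ndarray
    per_residue_sd: np.ndarray
    n_frames: int


# ----------------------------------------------------------------------
# distance helpers
# ----------------------------------------------------------------------

def minimum_image_displacement(d: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors."""
    if box is None:
        return d
    return d - box * np.round(d / box)


def _check_box(box: np.ndarray | None, cutoff: float) -> None:
    if box is not None and cutoff >= float(np.min(box)) / 2.0:
        raise ValueError(
            f"cutoff {cutoff} A is not below half the smallest box edge "
            f"({np.min(box)} A); minimum-image distances would be ambiguous"
        )


def _wrap(points: np.ndarray, box: np.ndarray) -> np.ndarray:
    wrapped = np.mod(points, box)
    # np.mod can return exactly box for tiny negative inputs
    wrapped[wrapped == box] = 0.0
    return wrapped


def pair_distances_sq(a: np.ndarray, b: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """All-pairs squared distances (len(a) x len(b)), minimum image if boxed."""
    d = a[:, None, :] - b[None, :, :]
    d = minimum_image_displacement(d, box)
    return np.einsum("ijk,ijk->ij", d, d)


def _solute_indices(system: LabeledSystem, params: ShellParams) -> np.ndarray:
    roles = set(PEPTIDE_ROLES)
    if params.include_lipid:
        roles.add(Role.LIPID)
    return system.atom_indices(roles=roles, heavy_only=params.solute_atoms == "heavy")


# ----------------------------------------------------------------------
# water counting
# ----------------------------------------------------------------------

def _water_atom_tables(system: LabeledSystem, params: ShellParams):
    """Counting-atom indices and the water residue index of each."""
    atom_idx = system.water_counting_atoms(params.counting_atom)
    water_of_atom = system.atom_residue_indices[atom_idx] if len(atom_idx) else np.empty(0, int)
    return atom_idx, water_of_atom


def count_chain_waters(
    frame: Frame,
    system: LabeledSystem,
    params: ShellParams = ShellParams(),
    method: str = "auto",
) -> int:
    """Number of distinct water molecules in the chain's first shell."""
    if system.peptide_length < 1:
        raise ValueError("system has no peptide residues")
    atom_idx, water_of_atom = _water_atom_tables(system, params)
    if len(atom_idx) == 0:
        return 0
    solute = _solute_indices(system, params)
    _check_box(frame.box, params.water_cutoff)
    w = frame.positions[atom_idx]
    s = frame.positions[solute]
    cut2 = params.water_cutoff ** 2
    if method == "brute" or (method == "auto" and len(w) * len(s) < 20_000):
        within = (pair_distances_sq(w, s, frame.box) < cut2).any(axis=1)
    else:
        within = _tree_within(w, s, params.water_cutoff, frame.box)
    return int(np.unique(water_of_atom[within]).size)


def _tree_within(
    points: np.ndarray, targets: np.ndarray, cutoff: float, box: np.ndarray | None
) -> np.ndarray:
    """Boolean mask: which ``points`` lie strictly within ``cutoff`` of any
    target, using a KD-tree (periodic when boxed) plus a strict squared-
    distance confirmation."""
    if box is not None:
        points_q = _wrap(points, box)
        targets_q = _wrap(targets, box)
        tree = cKDTree(targets_q, boxsize=box)
    else:
        points_q = points
        targets_q = targets
        tree = cKDTree(targets_q)
    cut2 = cutoff ** 2
    mask = np.zeros(len(points), dtype=bool)
    neighbor_lists = tree.query_ball_point(points_q, r=cutoff)
    for i, neigh in enumerate(neighbor_lists):
        if not neigh:
            continue
        d = points_q[i] - targets_q[neigh]
        d = minimum_image_displacement(d, box)
        if np.any(np.einsum("ij,ij->i", d, d) < cut2):
            mask[i] = True
    return mask


def residue_water_counts(
    frame: Frame,
    system: LabeledSystem,
    params: ShellParams = ShellParams(),
    method: str = "auto",
) -> HydrationProfile:
    """Distinct-water count in each peptide residue's first shell.

    Per-residue shells overlap: one water may be counted for several
    residues (once per residue), so the per-residue sum is an upper bound
    on the chain-level count.
    """
    residues = system.peptide_residues
    if params.include_lipid:
        residues = tuple(
            r for r in system.residues if r.role in PEPTIDE_ROLES or r.role is Role.LIPID
        )
    if not residues:
        raise ValueError("system has no peptide residues")
    atom_idx, water_of_atom = _water_atom_tables(system, params)
    _check_box(frame.box, params.water_cutoff)
    heavy_only = params.solute_atoms == "heavy"
    cut2 = params.water_cutoff ** 2
    counts = np.zeros(len(residues), dtype=float)
    if len(atom_idx):
        w = frame.positions[atom_idx]
        use_tree = method == "kdtree" or (
            method == "auto" and len(atom_idx) * len(residues) >= 2_000
        )
        tree = None
        if use_tree:
            if frame.box is not None:
                w_q = _wrap(w, frame.box)
                tree = cKDTree(w_q, boxsize=frame.box)
            else:
                w_q = w
                tree = cKDTree(w_q)
        for k, res in enumerate(residues):
            sol = [
                i
                for i in range(res.start, res.stop)
                if not heavy_only or system.atoms[i].is_heavy
            ]
            if not sol:
                continue
            s = frame.positions[sol]
            if tree is None:
                d2 = pair_distances_sq(w, s, frame.box)
                hit = (d2 < cut2).any(axis=1)
                waters = water_of_atom[hit]
            else:
                s_q = _wrap(s, frame.box) if frame.box is not None else s
                cand = set()
                for lst in tree.query_ball_point(s_q, r=params.water_cutoff):
                    cand.update(lst)
                cand = np.array(sorted(cand), dtype=int)
                if cand.size:
                    d2 = pair_distances_sq(w[cand], s, frame.box)
                    hit = (d2 < cut2).any(axis=1)
                    waters = water_of_atom[cand[hit]]
                else:
                    waters = np.empty(0, int)
            counts[k] = np.unique(waters).size
    return HydrationProfile(
        residue_indices=np.array([r.index for r in residues], dtype=int),
        per_residue_counts=counts,
        per_residue_sd=np.zeros_like(counts),
        n_frames=1,
    )


# ----------------------------------------------------------------------
# contacts
# ----------------------------------------------------------------------

def count_intrachain_contacts(
    frame: Frame,
    system: LabeledSystem,
    params: ShellParams = ShellParams(),
    method: str = "auto",
) -> int:
    """Number of peptide residue pairs (or heavy-atom pairs) in contact.

    Lipid atoms are excluded; use :func:`count_role_contacts` for
    lipid-peptide contacts.
    """
    residues = system.peptide_residues
    if len(residues) < params.min_sequence_separation + 1:
        warnings.warn(
            "fewer residues than min_sequence_separation + 1; no pair can "
            "qualify, returning 0",
            stacklevel=2,
        )
        return 0
    sol = system.atom_indices(roles=PEPTIDE_ROLES, heavy_only=True)
    _check_box(frame.box, params.contact_cutoff)
    pos = frame.positions[sol]
    res_of = system.atom_residue_indices[sol]
    # residue rank in peptide order defines sequence separation
    rank = {r.index: k for k, r in enumerate(residues)}
    rank_of = np.array([rank[i] for i in res_of], dtype=int)
    cut2 = params.contact_cutoff ** 2

    if method == "brute" or (method == "auto" and len(sol) < 400):
        d2 = pair_distances_sq(pos, pos, frame.box)
        iu, ju = np.triu_indices(len(sol), k=1)
        hit = d2[iu, ju] < cut2
        ai, aj = iu[hit], ju[hit]
    else:
        if frame.box is not None:
            tree = cKDTree(_wrap(pos, frame.box), boxsize=frame.box)
        else:
            tree = cKDTree(pos)
        pairs = tree.query_pairs(r=params.contact_cutoff, output_type="ndarray")
        if len(pairs):
            d = pos[pairs[:, 0]] - pos[pairs[:, 1]]
            d = minimum_image_displacement(d, frame.box)
            strict = np.einsum("ij,ij->i", d, d) < cut2
            pairs = pairs[strict]
        ai, aj = (pairs[:, 0], pairs[:, 1]) if len(pairs) else (np.empty(0, int),) * 2

    sep = np.abs(rank_of[ai] - rank_of[aj])
    ok = sep >= params.min_sequence_separation
    if params.contact_mode == "atom_pairs":
        return int(np.count_nonzero(ok))
    pairs_r = {
        (min(a, b), max(a, b))
        for a, b in zip(rank_of[ai[ok]], rank_of[aj[ok]])
    }
    return len(pairs_r)


def count_role_contacts(
    frame: Frame,
    system: LabeledSystem,
    params: ShellParams = ShellParams(),
    roles_a=(Role.LIPID,),
    roles_b=PEPTIDE_ROLES,
) -> int:
    """Residue pairs in contact between two role groups (e.g. lipid vs
    peptide); no sequence-separation filter applies across groups."""
    ia = system.atom_indices(roles=roles_a, heavy_only=True)
    ib = system.atom_indices(roles=roles_b, heavy_only=True)
    if len(ia) == 0 or len(ib) == 0:
        return 0
    _check_box(frame.box, params.contact_cutoff)
    d2 = pair_distances_sq(frame.positions[ia], frame.positions[ib], frame.box)
    hit = d2 < params.contact_cutoff ** 2
    ra = system.atom_residue_indices[ia]
    rb = system.atom_residue_indices[ib]
    pairs = {
        (ra[i], rb[j])
        for i, j in zip(*np.nonzero(hit))
        if ra[i] != rb[j]
    }
    return len(pairs)


# ----------------------------------------------------------------------
# per-trajectory statistics
# ----------------------------------------------------------------------

def series_statistics(
    trajectory: Trajectory, metric: Callable[[Frame], float]
) -> tuple[float, float, int]:
    """Mean, population SD and count of a per-frame metric over all frames."""
    if len(trajectory) == 0:
        raise ValueError("trajectory has no frames")
    values = np.array([metric(fr) for fr in trajectory.frames], dtype=float)
    return float(values.mean()), float(values.std(ddof=0)), len(values)


def average_residue_profile(
    trajectory: Trajectory,
    params: ShellParams = ShellParams(),
    window: float = 1.0,
) -> HydrationProfile:
    """Time-averaged per-residue water counts over the trailing ``window``
    fraction of frames."""
    if not 0 < window <= 1:
        raise ValueError("window must be in (0, 1]")
    n = len(trajectory)
    if n == 0:
        raise ValueError("trajectory has no frames")
    take = max(1, int(round(window * n)))
    frames = trajectory.frames[-take:]
    profiles = [residue_water_counts(fr, trajectory.system, params) for fr in frames]
    stackc = np.stack([p.per_residue_counts for p in profiles])
    return HydrationProfile(
        residue_indices=profiles[0].residue_indices,
        per_residue_counts=stackc.mean(axis=0),
        per_residue_sd=stackc.std(axis=0, ddof=0) if len(frames) > 1 else np.zeros(stackc.shape[1]),
        n_frames=len(frames),
    )
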