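"""Synthetic fixture generators for lipidated-ELP hydration analysis.

These generators produce coordinate data with the *statistical* structure
the downstream analysis assumes — they are not a force field and make no
attempt at physical dynamics:

* :func:`build_fame_topology` builds a coarse single-chain topology
  (backbone N/CA/C/O from ideal internal coordinates, one pseudo-CB per
  non-Gly residue, an optional 14-bead myristoyl chain);
* :func:`simulate_hydration_frames` populates first hydration shells with
  Poisson-distributed water counts whose expectation decays logistically
  with temperature (residue-specific dewetting midpoint T50, width w);
* :func:`simulate_temperature_scan` realizes chain-level water counts and
  residue contacts that follow linear-in-temperature models with Gaussian
  noise;
* :func:`simulate_dihedral_ensemble` draws backbone (phi, psi) from
  von Mises distributions centered in chosen Ramachandran regions and
  rebuilds coordinates so the angles are exactly recoverable.

Every placement records its ground truth in ``Frame.meta``, and placements
are validated with the same minimum-image geometry the counting module
uses, so an independent recount reproduces the ground truth exactly.
All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import AtomRecord, Frame, LabeledSystem, Role, Trajectory
from .proximity import ShellParams, pair_distances_sq, count_intrachain_contacts

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

#: default lipidation-site sequence: recognition peptide + octahistidine tag
DEFAULT_LS_SEQUENCE = "GLYASKLFSNLG" + "HHHHHHHH"

# ideal backbone internal coordinates (Angstrom / degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_CA_CB = 1.530
ANGLE_N_CA_C = 111.0
ANGLE_CA_C_N = 117.0
ANGLE_C_N_CA = 121.0
ANGLE_CA_C_O = 120.5
ANGLE_C_CA_CB = 110.5
OMEGA = 180.0

#: Ramachandran region centers used by the dihedral generator (degrees)
REGION_CENTERS = {
    "alpha_R": (-75.0, -50.0),
    "beta": (-120.0, 130.0),
    "alpha_L": (60.0, 40.0),
}


class GenerationError(RuntimeError):
    """Raised when bounded-retry placement cannot satisfy its constraints."""


# ----------------------------------------------------------------------
# internal-coordinate chain construction
# ----------------------------------------------------------------------

def place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond: float, angle_deg: float, torsion_deg: float,
) -> np.ndarray:
    """Place atom D bonded to c with angle(b,c,D) and torsion(a,b,c,D)."""
    theta = np.deg2rad(angle_deg)
    chi = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [
            -bond * np.cos(theta),
            bond * np.sin(theta) * np.cos(chi),
            bond * np.sin(theta) * np.sin(chi),
        ]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def measure_dihedral(p0, p1, p2, p3) -> float:
    """Torsion angle in degrees, IUPAC sign convention, range (-180, 180]."""
    b0 = np.asarray(p0) - np.asarray(p1)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    ang = np.degrees(np.arctan2(y, x))
    return float(ang if ang != -180.0 else 180.0)


def build_backbone(
    sequence: str, phi: np.ndarray, psi: np.ndarray
) -> tuple[np.ndarray, list[tuple[int, str, str]]]:
    """Build backbone coordinates for a one-letter ``sequence``.

    ``phi[i]`` / ``psi[i]`` are per-residue torsions in degrees (``phi[0]``
    is unused; ``psi[-1]`` only orients the final carbonyl oxygen).
    Returns coordinates plus a (residue_number, atom_name, element) list in
    the order N, CA, C, O[, CB] per residue.
    """
    n_res = len(sequence)
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    if phi.shape != (n_res,) or psi.shape != (n_res,):
        raise ValueError("phi/psi must have one value per residue")
    N = np.zeros((n_res, 3))
    CA = np.zeros((n_res, 3))
    C = np.zeros((n_res, 3))
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (BOND_N_CA, 0.0, 0.0)
    theta = np.deg2rad(ANGLE_N_CA_C)
    C[0] = CA[0] + BOND_CA_C * np.array([-np.cos(theta), np.sin(theta), 0.0])
    for i in range(1, n_res):
        N[i] = place_atom(N[i - 1], CA[i - 1], C[i - 1], BOND_C_N, ANGLE_CA_C_N, psi[i - 1])
        CA[i] = place_atom(CA[i - 1], C[i - 1], N[i], BOND_N_CA, ANGLE_C_N_CA, OMEGA)
        C[i] = place_atom(C[i - 1], N[i], CA[i], BOND_CA_C, ANGLE_N_CA_C, phi[i])

    coords: list[np.ndarray] = []
    spec: list[tuple[int, str, str]] = []
    for i, aa in enumerate(sequence):
        O = place_atom(N[i], CA[i], C[i], BOND_C_O, ANGLE_CA_C_O, psi[i] + 180.0)
        coords += [N[i], CA[i], C[i], O]
        spec += [(i, "N", "N"), (i, "CA", "C"), (i, "C", "C"), (i, "O", "O")]
        if aa != "G":
            CB = place_atom(N[i], C[i], CA[i], BOND_CA_CB, ANGLE_C_CA_CB, -122.5)
            coords.append(CB)
            spec.append((i, "CB", "C"))
    return np.array(coords), spec


def build_peptide(
    sequence: str,
    phi: np.ndarray,
    psi: np.ndarray,
    lipidation_site_length: int = 0,
    include_lipid: bool = False,
    first_residue_index: int = 0,
) -> LabeledSystem:
    """Assemble a :class:`LabeledSystem` peptide (optionally lipidated)."""
    coords, spec = build_backbone(sequence, phi, psi)
    atoms: list[AtomRecord] = []
    serial = 1
    res_offset = first_residue_index

    if include_lipid:
        # 14-bead zigzag acyl chain grown away from the N terminus
        n0 = coords[0]          # N of residue 0
        ca0 = coords[1]         # CA of residue 0
        beads = [n0 + np.array([-1.45, 0.6, 0.0])]
        a, b = ca0, n0
        for _ in range(13):
            new = place_atom(a, b, beads[-1], 1.53, 111.0, 180.0)
            a, b = b, beads[-1]
            beads.append(new)
        for k, pos in enumerate(beads):
            atoms.append(
                AtomRecord(serial, f"C{k + 1}", "C", res_offset, "MYR",
                           Role.LIPID, tuple(pos))
            )
            serial += 1
        res_offset += 1

    for (ires, name, elem), pos in zip(spec, coords):
        aa = sequence[ires]
        role = (
            Role.LIPIDATION_SITE
            if ires < lipidation_site_length
            else Role.ELP
        )
        atoms.append(
            AtomRecord(serial, name, elem, res_offset + ires,
                       ONE_TO_THREE[aa], role, tuple(pos))
        )
        serial += 1
    return LabeledSystem(atoms)


def build_fame_topology(
    n_pentads: int,
    ls_sequence: str = DEFAULT_LS_SEQUENCE,
    include_lipid: bool = True,
    seed: int = 0,
) -> LabeledSystem:
    """Coarse topology of a myristoylated ELP construct.

    The peptide is ``ls_sequence`` followed by ``n_pentads`` GVGVP repeats
    in a jittered extended conformation (deterministic in ``seed``); the
    lipidation-site/ELP boundary is positional at ``len(ls_sequence)``.
    """
    if n_pentads < 0:
        raise ValueError("n_pentads must be >= 0")
    sequence = ls_sequence + "GVGVP" * n_pentads
    if not sequence:
        raise ValueError("empty construct: no residues to build")
    rng = np.random.default_rng(seed)
    n = len(sequence)
    phi = -140.0 + rng.normal(0.0, 10.0, n)
    psi = 140.0 + rng.normal(0.0, 10.0, n)
    return build_peptide(
        sequence, phi, psi,
        lipidation_site_length=len(ls_sequence),
        include_lipid=include_lipid,
    )


# ----------------------------------------------------------------------
# hydration models
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class HydrationModel:
    """Logistic dewetting model of per-residue first-shell occupancy.

    Expected shell count of residue *r* at temperature *T* is
    ``baseline[r] / (1 + exp((T - T50[r]) / w))`` — full occupancy well
    below the dewetting midpoint ``T50``, none well above it.
    """

    baseline_counts: np.ndarray
    midpoints: np.ndarray
    width: float = 5.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "baseline_counts",
                           np.asarray(self.baseline_counts, dtype=float))
        object.__setattr__(self, "midpoints",
                           np.asarray(self.midpoints, dtype=float))
        if self.width <= 0:
            raise ValueError("logistic width must be positive")
        if np.any(self.baseline_counts < 0):
            raise ValueError("baseline counts must be non-negative")
        if self.baseline_counts.shape != self.midpoints.shape:
            raise ValueError("baseline_counts and midpoints must align")

    def expected_occupancy(self, temperature: float) -> np.ndarray:
        z = (temperature - self.midpoints) / self.width
        return self.baseline_counts / (1.0 + np.exp(z))


@dataclass(frozen=True)
class ScanModel:
    """Linear-in-temperature model for chain-level N_w and N_pp."""

    nw_intercept: float
    nw_slope: float
    npp_intercept: float
    npp_slope: float
    noise_sd: float = 0.0

    def expected_nw(self, T: float) -> float:
        return self.nw_intercept + self.nw_slope * T

    def expected_npp(self, T: float) -> float:
        return self.npp_intercept + self.npp_slope * T


# ----------------------------------------------------------------------
# water placement machinery
# ----------------------------------------------------------------------

_SHELL_INNER = 2.4  # A; keeps placed waters off the solute atom itself


def _random_shell_points(
    rng: np.random.Generator, centers: np.ndarray, outer: float
) -> np.ndarray:
    """Uniform-direction points in the spherical shell [_SHELL_INNER, outer)."""
    n = len(centers)
    direction = rng.normal(size=(n, 3))
    direction /= np.linalg.norm(direction, axis=1, keepdims=True)
    radius = rng.uniform(_SHELL_INNER, np.nextafter(outer, 0.0), size=n)
    return centers + direction * radius[:, None]


def _water_atoms_for(
    count: int, first_serial: int, first_residue: int, water_atoms: int
) -> list[AtomRecord]:
    atoms = []
    serial = first_serial
    for k in range(count):
        ridx = first_residue + k
        atoms.append(AtomRecord(serial, "OW", "O", ridx, "SOL", Role.WATER))
        serial += 1
        for hname in ("HW1", "HW2")[: max(0, water_atoms - 1)]:
            atoms.append(AtomRecord(serial, hname, "H", ridx, "SOL", Role.WATER))
            serial += 1
    return atoms


def _default_box(solute_xyz: np.ndarray, margin: float = 12.0) -> np.ndarray:
    span = solute_xyz.max(axis=0) - solute_xyz.min(axis=0)
    return span + 2 * margin


def _place_bulk(
    rng: np.random.Generator,
    n: int,
    box: np.ndarray,
    solute_xyz: np.ndarray,
    exclusion: float,
    max_rounds: int = 200,
) -> np.ndarray:
    """Uniform waters at min-image distance >= exclusion from all solute."""
    if n == 0:
        return np.empty((0, 3))
    placed = np.empty((n, 3))
    need = np.arange(n)
    excl2 = exclusion ** 2
    for _ in range(max_rounds):
        cand = rng.uniform(0.0, box, size=(len(need), 3))
        d2 = pair_distances_sq(cand, solute_xyz, box)
        ok = (d2 >= excl2).all(axis=1)
        placed[need[ok]] = cand[ok]
        need = need[~ok]
        if len(need) == 0:
            return placed
    raise GenerationError("could not place bulk waters after bounded retries")


def simulate_hydration_frames(
    system: LabeledSystem,
    model: HydrationModel,
    temperature: float,
    n_frames: int,
    box: np.ndarray | None = None,
    n_bulk_waters: int = 30,
    seed: int = 0,
    water_atoms: int = 1,
    max_rounds: int = 200,
) -> Trajectory:
    """Frames with Poisson-occupied first shells around each peptide residue.

    Each shell water is placed strictly within the 3.15 A shell of one
    heavy atom of its residue and at least the cutoff away from every other
    peptide residue's heavy atoms, so the drawn counts (stored per frame in
    ``meta['true_residue_waters']`` / ``meta['true_chain_waters']``) are
    exactly recoverable by proximity recounting.  The solute is rigid
    across frames (mirroring position-restrained annealing).
    """
    rng = np.random.default_rng(seed)
    residues = system.peptide_residues
    if len(residues) != len(model.baseline_counts):
        raise ValueError(
            f"model has {len(model.baseline_counts)} residues; system has "
            f"{len(residues)} peptide residues"
        )
    params = ShellParams()
    cutoff = params.water_cutoff
    cut2 = cutoff ** 2

    solute_ref = system.reference_positions
    box = np.asarray(box, dtype=float) if box is not None else _default_box(solute_ref)
    # center the rigid solute in the box
    shift = box / 2.0 - (solute_ref.max(axis=0) + solute_ref.min(axis=0)) / 2.0
    solute_xyz = solute_ref + shift

    heavy = system.heavy_mask
    res_heavy = [
        [i for i in range(r.start, r.stop) if heavy[i]] for r in residues
    ]
    pep_heavy = np.concatenate([np.array(h, int) for h in res_heavy])
    pep_heavy_xyz = solute_xyz[pep_heavy]
    # residue id per peptide heavy atom, for own-residue masking
    owner = np.concatenate(
        [np.full(len(h), k, int) for k, h in enumerate(res_heavy)]
    )
    all_heavy_xyz = solute_xyz[heavy]

    lam = model.expected_occupancy(temperature)
    counts = rng.poisson(lam, size=(n_frames, len(residues)))
    capacity = int(counts.sum(axis=1).max(initial=0)) + n_bulk_waters

    n_solute_res = len(system.residues)
    atoms = list(system.atoms) + _water_atoms_for(
        capacity, system.atoms[-1].serial + 1, n_solute_res, water_atoms
    )
    full_system = LabeledSystem(atoms)
    stride = max(1, water_atoms)

    frames: list[Frame] = []
    for f in range(n_frames):
        c = counts[f]
        shell = np.empty((int(c.sum()), 3))
        res_of_shell = np.repeat(np.arange(len(residues)), c)
        need = np.arange(len(shell))
        for _ in range(max_rounds):
            if len(need) == 0:
                break
            ridx = res_of_shell[need]
            anchors = np.array(
                [res_heavy[r][rng.integers(len(res_heavy[r]))] for r in ridx]
            )
            cand = _random_shell_points(rng, solute_xyz[anchors], cutoff)
            d2 = pair_distances_sq(cand, pep_heavy_xyz, box)
            own = owner[None, :] == ridx[:, None]
            ok = np.all((d2 >= cut2) | own, axis=1)
            # anchor distance < cutoff is guaranteed by the shell radius
            shell[need[ok]] = cand[ok]
            need = need[~ok]
        if len(need):
            raise GenerationError(
                f"frame {f}: could not place {len(need)} shell waters"
            )
        bulk = _place_bulk(
            rng, capacity - len(shell), box, all_heavy_xyz,
            cutoff + 1.0, max_rounds,
        )
        water_o = np.vstack([shell, bulk]) if capacity else np.empty((0, 3))

        pos = np.empty((full_system.n_atoms, 3))
        pos[: system.n_atoms] = solute_xyz
        base = system.n_atoms
        for k in range(capacity):
            pos[base + k * stride] = water_o[k]
            if water_atoms == 3:
                pos[base + k * stride + 1] = water_o[k] + (0.96, 0.0, 0.0)
                pos[base + k * stride + 2] = water_o[k] + (-0.24, 0.93, 0.0)
        frames.append(
            Frame(
                positions=pos,
                box=box.copy(),
                temperature=float(temperature),
                time=float(f),
                meta={
                    "true_residue_waters": c.tolist(),
                    "true_chain_waters": int(c.sum()),
                },
            )
        )
    return Trajectory(full_system, frames)


def simulate_annealing_series(
    system: LabeledSystem,
    model: HydrationModel,
    tdw_grid: np.ndarray,
    n_frames: int,
    seed: int = 0,
    t_range: tuple[float, float] = (250.0, 400.0),
    **kwargs,
) -> list[tuple[float, Trajectory]]:
    """One rigid-solute hydration trajectory per dewetting temperature.

    Emulates a restrained-solute annealing series sampled at stationary
    occupancy for each grid temperature in ``tdw_grid`` (ascending,
    within ``t_range``).
    """
    grid = np.asarray(tdw_grid, dtype=float)
    if grid.ndim != 1 or len(grid) == 0:
        raise ValueError("tdw_grid must be a non-empty 1-D sequence")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("tdw_grid must be strictly ascending")
    if grid[0] < t_range[0] or grid[-1] > t_range[1]:
        raise ValueError(f"tdw_grid must lie within {t_range}")
    children = np.random.SeedSequence(seed).spawn(len(grid))
    out = []
    for T, child in zip(grid, children):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        out.append(
            (
                float(T),
                simulate_hydration_frames(
                    system, model, float(T), n_frames, seed=sub_seed, **kwargs
                ),
            )
        )
    return out


# ----------------------------------------------------------------------
# temperature scan (N_w / N_pp linear trends)
# ----------------------------------------------------------------------

def _lattice_sites(n: int, spacing: float) -> np.ndarray:
    side = int(np.ceil(n ** (1.0 / 3.0)))
    grid = np.array(
        [(i, j, k) for i in range(side) for j in range(side) for k in range(side)],
        dtype=float,
    )
    return grid[:n] * spacing + spacing  # keep off the box faces


def simulate_temperature_scan(
    system: LabeledSystem,
    model: ScanModel,
    temps: np.ndarray,
    n_frames: int,
    seed: int = 0,
    n_bulk_waters: int = 20,
    max_rounds: int = 200,
) -> list[tuple[float, Trajectory]]:
    """Trajectories whose recounted N_w and N_pp follow the linear model.

    Residues are scattered on a dilated lattice (no baseline contacts);
    per frame, the target contact count is realized by translating one
    member of each of that many disjoint residue pairs to ~4.5 A from its
    partner, with rejection so no incidental contact appears.  Water counts
    are realized by shell/bulk placement as in the hydration generator.
    Ground truth per frame: ``meta['true_nw']`` and ``meta['true_npp']``.
    """
    temps = np.asarray(temps, dtype=float)
    residues = system.peptide_residues
    n_res = len(residues)
    params = ShellParams()
    min_sep = params.min_sequence_separation
    capacity_pairs = n_res // 2
    for T in temps:
        if model.expected_nw(T) < 0 or model.expected_npp(T) < 0:
            raise ValueError(f"scan model yields negative expected count at {T} K")
        if model.expected_npp(T) + 5 * model.noise_sd > capacity_pairs:
            raise ValueError(
                "expected contact count exceeds the disjoint-pair capacity "
                f"({capacity_pairs}) of a {n_res}-residue chain"
            )

    heavy = system.heavy_mask
    spacing = 14.0
    ref = system.reference_positions
    all_res = system.residues
    sites = _lattice_sites(len(all_res), spacing)
    base = np.empty_like(ref)
    for k, res in enumerate(all_res):
        blk = ref[res.start : res.stop]
        base[res.start : res.stop] = blk - blk.mean(axis=0) + sites[k]
    box = sites.max(axis=0) + spacing

    pep_rank = {r.index: k for k, r in enumerate(residues)}
    res_heavy = [
        np.array([i for i in range(r.start, r.stop) if heavy[i]], int)
        for r in residues
    ]
    cut = params.contact_cutoff
    cut2 = cut ** 2

    rng_master = np.random.SeedSequence(seed).spawn(len(temps))
    out: list[tuple[float, Trajectory]] = []
    wcut = params.water_cutoff

    for T, child in zip(temps, rng_master):
        rng = np.random.default_rng(child)
        nw_t = np.maximum(
            0, np.rint(model.expected_nw(T) + rng.normal(0, model.noise_sd, n_frames))
        ).astype(int)
        npp_t = np.clip(
            np.rint(model.expected_npp(T) + rng.normal(0, model.noise_sd, n_frames)),
            0, capacity_pairs,
        ).astype(int)
        capacity = int(nw_t.max(initial=0)) + n_bulk_waters

        n_solute_res = len(all_res)
        atoms = list(system.atoms) + _water_atoms_for(
            capacity, system.atoms[-1].serial + 1, n_solute_res, 1
        )
        full_system = LabeledSystem(atoms)

        frames: list[Frame] = []
        for f in range(n_frames):
            pos = None
            for _attempt in range(max_rounds):
                pos = base.copy()
                if _realize_contacts(
                    rng, pos, residues, res_heavy, npp_t[f], min_sep, cut, box
                ):
                    break
                pos = None
            if pos is None:
                raise GenerationError(
                    f"could not realize {npp_t[f]} contacts at {T} K"
                )
            # verify by construction-independent brute recount
            probe = Frame(positions=pos, box=box.copy())
            realized = count_intrachain_contacts(probe, system, params, method="brute")
            if realized != npp_t[f]:
                raise GenerationError(
                    f"contact realization mismatch: wanted {npp_t[f]}, got {realized}"
                )

            pep_heavy_xyz = pos[np.concatenate(res_heavy)]
            anchors = pep_heavy_xyz[
                rng.integers(len(pep_heavy_xyz), size=nw_t[f])
            ]
            shell = _random_shell_points(rng, anchors, wcut)
            bulk = _place_bulk(
                rng, capacity - nw_t[f], box, pos[heavy], wcut + 1.0, max_rounds
            )
            water_o = np.vstack([shell, bulk])
            allpos = np.vstack([pos, water_o])
            frames.append(
                Frame(
                    positions=allpos,
                    box=box.copy(),
                    temperature=float(T),
                    time=float(f),
                    meta={"true_nw": int(nw_t[f]), "true_npp": int(npp_t[f])},
                )
            )
        out.append((float(T), Trajectory(full_system, frames)))
    return out


def _realize_contacts(
    rng, pos, residues, res_heavy, k, min_sep, cut, box
) -> bool:
    """Move one residue of each of ``k`` disjoint pairs into contact."""
    n_res = len(residues)
    if k == 0:
        return True
    order = rng.permutation(n_res)
    pairs = []
    used: set[int] = set()
    for a in order:
        if a in used:
            continue
        partners = [
            b for b in order
            if b not in used and b != a and abs(int(a) - int(b)) >= min_sep
        ]
        if not partners:
            continue
        b = partners[rng.integers(len(partners))]
        pairs.append((int(a), int(b)))
        used.update((int(a), int(b)))
        if len(pairs) == k:
            break
    if len(pairs) < k:
        return False

    cut2 = cut ** 2
    for a, b in pairs:
        ra, rb = residues[a], residues[b]
        target_atom = pos[res_heavy[a][rng.integers(len(res_heavy[a]))]]
        moved = None
        for _ in range(50):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            anchor_b = res_heavy[b][rng.integers(len(res_heavy[b]))]
            new_anchor = target_atom + direction * 4.5
            delta = new_anchor - pos[anchor_b]
            cand = pos[rb.start : rb.stop] + delta
            cand_heavy = pos[res_heavy[b]] + delta
            # no incidental contact: b's heavy atoms must stay >= cut from
            # every countable residue except its partner a
            ok = True
            for c, rc in enumerate(residues):
                if c in (a, b) or abs(c - b) < min_sep:
                    continue
                d2 = pair_distances_sq(cand_heavy, pos[res_heavy[c]], box)
                if np.any(d2 < cut2):
                    ok = False
                    break
            if ok:
                moved = (rb, cand)
                break
        if moved is None:
            return False
        rb, cand = moved
        pos[rb.start : rb.stop] = cand
    return True


# ----------------------------------------------------------------------
# dihedral ensembles
# ----------------------------------------------------------------------

def simulate_dihedral_ensemble(
    class_map: list[str],
    kappa: float,
    n_frames: int,
    seed: int = 0,
    sequence: str | None = None,
) -> Trajectory:
    """Backbone ensemble with (phi, psi) drawn per residue per frame.

    ``class_map[i]`` selects the circular distribution for residue *i*:
    a von Mises of concentration ``kappa`` centered in the named
    Ramachandran region (``alpha_R`` at (-75, -50), ``beta`` at
    (-120, 130), ``alpha_L`` at (60, 40)) or ``coil`` (uniform).  Chains
    are rebuilt from ideal internal coordinates each frame, so the drawn
    angles (stored in ``meta['true_phi'/'true_psi']``, degrees) are exactly
    recoverable from the coordinates.
    """
    n_res = len(class_map)
    if n_res < 3:
        raise ValueError("need at least 3 residues for interior dihedrals")
    for label in class_map:
        if label != "coil" and label not in REGION_CENTERS:
            raise ValueError(f"unknown region label {label!r}")
    if sequence is None:
        sequence = "A" * n_res
    if len(sequence) != n_res:
        raise ValueError("sequence length must match class_map")
    rng = np.random.default_rng(seed)

    def draw(label: str, n: int) -> tuple[np.ndarray, np.ndarray]:
        if label == "coil":
            phi = rng.uniform(-180.0, 180.0, n)
            psi = rng.uniform(-180.0, 180.0, n)
        else:
            c_phi, c_psi = REGION_CENTERS[label]
            phi = np.degrees(rng.vonmises(np.radians(c_phi), kappa, n))
            psi = np.degrees(rng.vonmises(np.radians(c_psi), kappa, n))
        phi[phi == -180.0] = 180.0
        psi[psi == -180.0] = 180.0
        return phi, psi

    phis = np.empty((n_frames, n_res))
    psis = np.empty((n_frames, n_res))
    for i, label in enumerate(class_map):
        phis[:, i], psis[:, i] = draw(label, n_frames)

    system = None
    frames = []
    for f in range(n_frames):
        coords, spec = build_backbone(sequence, phis[f], psis[f])
        if system is None:
            atoms = [
                AtomRecord(s + 1, name, elem, ires, ONE_TO_THREE[sequence[ires]],
                           Role.ELP, tuple(coords[s]))
                for s, (ires, name, elem) in enumerate(spec)
            ]
            system = LabeledSystem(atoms)
        frames.append(
            Frame(
                positions=coords,
                time=float(f),
                meta={"true_phi": phis[f].tolist(), "true_psi": psis[f].tolist()},
            )
        )
    return Trajectory(system, frames)
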