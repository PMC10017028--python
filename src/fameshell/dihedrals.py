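"""Backbone dihedral extraction and Ramachandran-region classification.

Phi(i) is the torsion C(i-1)-N(i)-CA(i)-C(i) and Psi(i) the torsion
N(i)-CA(i)-C(i)-N(i+1), IUPAC sign convention, degrees in (-180, 180].
Only interior peptide residues (which have both angles) enter the series.

The default region set places the right-handed alpha helix at
Phi in [-100, -50], Psi in [-70, -30]; the beta and left-handed-alpha
boxes follow common Ramachandran conventions and all boxes are
user-overridable (disjointness of interiors is enforced).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import LabeledSystem, Trajectory


@dataclass(frozen=True)
class RamachandranRegion:
    label: str
    phi_range: tuple[float, float]
    psi_range: tuple[float, float]

    def __post_init__(self) -> None:
        for lo, hi in (self.phi_range, self.psi_range):
            if not (-180.0 <= lo < hi <= 180.0):
                raise ValueError(
                    f"region {self.label!r}: interval ({lo}, {hi}) must be "
                    "ordered and within (-180, 180]"
                )

    def contains(self, phi: float, psi: float) -> bool:
        return (
            self.phi_range[0] <= phi <= self.phi_range[1]
            and self.psi_range[0] <= psi <= self.psi_range[1]
        )


DEFAULT_REGIONS: tuple[RamachandranRegion, ...] = (
    RamachandranRegion("alpha_R", (-100.0, -50.0), (-70.0, -30.0)),
    RamachandranRegion("beta", (-180.0, -90.0), (90.0, 180.0)),
    RamachandranRegion("alpha_L", (30.0, 100.0), (0.0, 80.0)),
)


def _check_disjoint(regions: tuple[RamachandranRegion, ...]) -> None:
    for i, a in enumerate(regions):
        for b in regions[i + 1 :]:
            phi_overlap = min(a.phi_range[1], b.phi_range[1]) > max(
                a.phi_range[0], b.phi_range[0]
            )
            psi_overlap = min(a.psi_range[1], b.psi_range[1]) > max(
                a.psi_range[0], b.psi_range[0]
            )
            if phi_overlap and psi_overlap:
                raise ValueError(
                    f"regions {a.label!r} and {b.label!r} overlap"
                )


@dataclass
class DihedralSeries:
    """Per-residue (phi, psi) time series in degrees.

    ``angles[residue_index]`` is an (n_frames, 2) array; terminal residues
    that lack one of the two angles are absent.
    """

    angles: dict[int, np.ndarray]
    n_frames: int

    @property
    def residues(self) -> list[int]:
        return sorted(self.angles)


def _dihedrals_vectorized(p0, p1, p2, p3) -> np.ndarray:
    """Torsions for stacked point arrays; IUPAC sign, (-180, 180] degrees."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1 = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    v = b0 - np.sum(b0 * b1, axis=-1, keepdims=True) * b1
    w = b2 - np.sum(b2 * b1, axis=-1, keepdims=True) * b1
    x = np.sum(v * w, axis=-1)
    y = np.sum(np.cross(b1, v) * w, axis=-1)
    ang = np.degrees(np.arctan2(y, x))
    return np.where(ang == -180.0, 180.0, ang)


def backbone_dihedrals(
    trajectory: Trajectory, system: LabeledSystem | None = None
) -> DihedralSeries:
    """Extract (phi, psi) for every interior peptide residue of a trajectory."""
    system = system or trajectory.system
    residues = system.peptide_residues
    if len(residues) < 3:
        raise ValueError("need at least 3 peptide residues for interior dihedrals")

    def backbone_index(res, name: str) -> int:
        for i in range(res.start, res.stop):
            if system.atoms[i].name == name:
                return i
        raise ValueError(
            f"residue {res.index} ({res.name}) is missing backbone atom {name}"
        )

    idx_N = np.array([backbone_index(r, "N") for r in residues])
    idx_CA = np.array([backbone_index(r, "CA") for r in residues])
    idx_C = np.array([backbone_index(r, "C") for r in residues])

    pos = np.stack([fr.positions for fr in trajectory.frames])  # (F, A, 3)
    interior = range(1, len(residues) - 1)
    angles: dict[int, np.ndarray] = {}
    for k in interior:
        phi = _dihedrals_vectorized(
            pos[:, idx_C[k - 1]], pos[:, idx_N[k]], pos[:, idx_CA[k]], pos[:, idx_C[k]]
        )
        psi = _dihedrals_vectorized(
            pos[:, idx_N[k]], pos[:, idx_CA[k]], pos[:, idx_C[k]], pos[:, idx_N[k + 1]]
        )
        angles[residues[k].index] = np.column_stack([phi, psi])
    return DihedralSeries(angles=angles, n_frames=len(trajectory.frames))


def classify_conformation(
    phi: float,
    psi: float,
    regions: tuple[RamachandranRegion, ...] = DEFAULT_REGIONS,
) -> str:
    """Label a (phi, psi) pair by the first matching region, else 'other'."""
    _check_disjoint(regions)
    for region in regions:
        if region.contains(phi, psi):
            return region.label
    return "other"


def region_occupancy(
    series: DihedralSeries,
    window: float = 0.25,
    regions: tuple[RamachandranRegion, ...] = DEFAULT_REGIONS,
) -> pd.DataFrame:
    """Fraction of windowed frames each residue spends in each region.

    ``window`` is the trailing fraction of frames analyzed (0.25 mirrors
    analyzing the last quarter of an equilibrium run).  Rows are residues,
    columns region labels plus 'other'; each row sums to 1.
    """
    _check_disjoint(regions)
    if not 0 < window <= 1:
        raise ValueError("window must be in (0, 1]")
    take = max(1, int(round(window * series.n_frames)))
    if series.n_frames == 0:
        raise ValueError("empty dihedral series")
    labels = [r.label for r in regions] + ["other"]
    rows = {}
    for res, arr in series.angles.items():
        sub = arr[-take:]
        counts = dict.fromkeys(labels, 0)
        in_any = np.zeros(len(sub), dtype=bool)
        for region in regions:
            hit = (
                (sub[:, 0] >= region.phi_range[0])
                & (sub[:, 0] <= region.phi_range[1])
                & (sub[:, 1] >= region.psi_range[0])
                & (sub[:, 1] <= region.psi_range[1])
            ) & ~in_any
            counts[region.label] = int(hit.sum())
            in_any |= hit
        counts["other"] = int((~in_any).sum())
        rows[res] = {k: v / len(sub) for k, v in counts.items()}
    return pd.DataFrame.from_dict(rows, orient="index", columns=labels).sort_index()


def ramachandran_histogram(
    series: DihedralSeries, bins: int = 36, window: float = 1.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """2-D (phi, psi) histogram over all residues and windowed frames."""
    take = max(1, int(round(window * series.n_frames)))
    allang = np.concatenate([arr[-take:] for arr in series.angles.values()])
    edges = np.linspace(-180.0, 180.0, bins + 1)
    hist, xe, ye = np.histogram2d(allang[:, 0], allang[:, 1], bins=[edges, edges])
    return hist, xe, ye
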