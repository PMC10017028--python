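"""Shared fixtures: small synthetic systems and random-system factories."""

from __future__ import annotations

import numpy as np
import pytest

from fameshell.core import AtomRecord, Frame, LabeledSystem, Role
from fameshell.synth import HydrationModel, build_fame_topology


@pytest.fixture(scope="session")
def small_construct() -> LabeledSystem:
    """Lipidated 25-residue construct (12 LS + 8 His + 1 pentad)."""
    return build_fame_topology(1, seed=0)


@pytest.fixture(scope="session")
def flat_hydration_model(small_construct) -> HydrationModel:
    n = small_construct.peptide_length
    return HydrationModel(
        baseline_counts=np.full(n, 6.0),
        midpoints=np.full(n, 325.0),
        width=5.0,
    )


def make_random_system(
    rng: np.random.Generator,
    n_peptide_res: int,
    n_waters: int,
    box: np.ndarray | None,
    water_atoms: int = 1,
) -> tuple[LabeledSystem, Frame]:
    """A random labeled system with scattered peptide residues and waters.

    Coordinates are uniform in the box (or a 30 A cube without PBC), so
    shell membership and contacts are nontrivial.
    """
    extent = box if box is not None else np.array([30.0, 30.0, 30.0])
    atoms: list[AtomRecord] = []
    serial = 1
    ridx = 0
    for _ in range(n_peptide_res):
        n_heavy = int(rng.integers(1, 5))
        center = rng.uniform(0, extent)
        for a in range(n_heavy):
            pos = center + rng.normal(0, 1.0, 3)
            atoms.append(
                AtomRecord(serial, f"A{a}", "C", ridx, "ALA", Role.ELP, tuple(pos))
            )
            serial += 1
        if rng.random() < 0.5:  # some hydrogens, which counting must ignore
            pos = center + rng.normal(0, 1.0, 3)
            atoms.append(
                AtomRecord(serial, "H1", "H", ridx, "ALA", Role.ELP, tuple(pos))
            )
            serial += 1
        ridx += 1
    for _ in range(n_waters):
        opos = rng.uniform(0, extent)
        atoms.append(
            AtomRecord(serial, "OW", "O", ridx, "SOL", Role.WATER, tuple(opos))
        )
        serial += 1
        if water_atoms == 3:
            for name in ("HW1", "HW2"):
                atoms.append(
                    AtomRecord(
                        serial, name, "H", ridx, "SOL", Role.WATER,
                        tuple(opos + rng.normal(0, 0.5, 3)),
                    )
                )
                serial += 1
        ridx += 1
    system = LabeledSystem(atoms)
    frame = Frame(positions=system.reference_positions, box=box)
    return system, frame
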