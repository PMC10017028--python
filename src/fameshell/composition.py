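"""Sequence-level mass and amphiphilicity metrics for lipidated ELPs.

A myristoylated construct is an amphiphile: a C14 acyl tail (the
hydrophobic block) attached to the peptide head (lipidation site +
His tag + ELP repeats).  The hydrophilic fraction

    f = m_peptide / (m_peptide + m_lipid)

is operationalized on a mass basis; the default lipid contribution is the
myristoyl acyl group C14H26O (myristic acid minus the water lost on amide
formation).  The N-terminal Met of the expression construct is excluded,
as it is removed upon myristoylation of the following Gly.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.SeqUtils import molecular_weight
from pyteomics import mass as pmass

VALID_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")

#: one-letter sequences of the reference constructs (after Met removal)
_LS = "GLYASKLFSNLG" + "H" * 8
PRESETS = {
    f"myr-V{n}": _LS + "GVGVP" * n for n in (20, 30, 40, 50, 60)
}

MYRISTOYL_FORMULA = "C14H26O"


@dataclass(frozen=True)
class ConjugateSpec:
    """A peptide-lipid conjugate: sequence plus lipid molecular formula."""

    sequence: str
    lipid_formula: str = MYRISTOYL_FORMULA
    mass_mode: str = "average"

    def __post_init__(self) -> None:
        if self.mass_mode not in ("average", "monoisotopic"):
            raise ValueError(f"unknown mass_mode {self.mass_mode!r}")
        _validate_sequence(self.sequence)


def _validate_sequence(sequence: str) -> None:
    if not sequence:
        raise ValueError("peptide sequence must be non-empty")
    for i, ch in enumerate(sequence):
        if ch not in VALID_RESIDUES:
            raise ValueError(
                f"invalid residue {ch!r} at position {i + 1} (1-based)"
            )


def peptide_mass(sequence: str, mass_mode: str = "average") -> float:
    """Mass of a peptide in Da: residue masses plus one water."""
    _validate_sequence(sequence)
    return float(
        molecular_weight(
            sequence, seq_type="protein", monoisotopic=mass_mode == "monoisotopic"
        )
    )


def lipid_mass(formula: str, mass_mode: str = "average") -> float:
    """Mass of a molecular formula in Da (empty formula -> 0)."""
    if not formula:
        return 0.0
    return float(pmass.calculate_mass(formula=formula, average=mass_mode == "average"))


def hydrophilic_fraction(spec: ConjugateSpec) -> float:
    """Mass fraction of the conjugate belonging to the peptide head."""
    pm = peptide_mass(spec.sequence, spec.mass_mode)
    lm = lipid_mass(spec.lipid_formula, spec.mass_mode)
    return pm / (pm + lm)


def preset_spec(name: str, mass_mode: str = "average") -> ConjugateSpec:
    """ConjugateSpec for a named construct (myr-V20 ... myr-V60)."""
    if name not in PRESETS:
        raise KeyError(
            f"unknown preset {name!r}; choose from {sorted(PRESETS)}"
        )
    return ConjugateSpec(sequence=PRESETS[name], mass_mode=mass_mode)
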