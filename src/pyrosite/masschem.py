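"""Monoisotopic mass chemistry.

Element and residue tables, modification deltas, the phosphate neutral-loss
species and m/z arithmetic. Everything downstream (digestion, fragment
generation, the neutral-loss trigger, the spectral validator) derives its
masses from the element table in this module, so the exact-isobar identity

    mass(pyrophospho at residue i) == mass(phospho at i) + mass(phospho at j)

holds to machine precision by construction: the pyrophospho delta is defined
as 2 x mass(HPO3), never typed as a literal.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "MONOISOTOPIC_ELEMENTS",
    "PROTON_MASS",
    "WATER_MASS",
    "NH3_MASS",
    "H_MASS",
    "RESIDUE_FORMULAS",
    "RESIDUE_MASSES",
    "Modification",
    "MODIFICATIONS",
    "PHOSPHATE_EQUIVALENTS",
    "NeutralLossSpecies",
    "NEUTRAL_LOSSES",
    "ModifiedPeptide",
    "monoisotopic_mass",
    "peptide_neutral_mass",
    "mz",
]

#: Monoisotopic atomic masses in Da (NIST/IUPAC 2021 values).
MONOISOTOPIC_ELEMENTS: dict[str, float] = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "P": 30.97376151,
    "S": 31.97207069,
}

#: Mass of a proton in Da -- the charge carrier for m/z arithmetic
#: (deliberately the bare proton, not the hydrogen atom).
PROTON_MASS: float = 1.0072765

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def monoisotopic_mass(formula: str) -> float:
    """Monoisotopic mass in Da of an elemental formula such as ``"H4P2O7"``.

    The empty formula has mass 0. Raises :class:`ValueError` for an element
    symbol missing from the table, naming the offending symbol.
    """
    pos = 0
    total = 0.0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise ValueError(f"malformed formula {formula!r} at offset {pos}")
        symbol, count = match.group(1), match.group(2)
        if symbol not in MONOISOTOPIC_ELEMENTS:
            raise ValueError(f"unknown element symbol {symbol!r} in formula {formula!r}")
        total += MONOISOTOPIC_ELEMENTS[symbol] * (int(count) if count else 1)
        pos = match.end()
    if pos != len(formula):
        raise ValueError(f"malformed formula {formula!r} at offset {pos}")
    return total


WATER_MASS: float = monoisotopic_mass("H2O")
NH3_MASS: float = monoisotopic_mass("NH3")
H_MASS: float = MONOISOTOPIC_ELEMENTS["H"]

#: Elemental composition of amino-acid residues (peptide-bond residues,
#: i.e. the free amino acid minus water).
RESIDUE_FORMULAS: dict[str, str] = {
    "G": "C2H3NO",
    "A": "C3H5NO",
    "S": "C3H5NO2",
    "P": "C5H7NO",
    "V": "C5H9NO",
    "T": "C4H7NO2",
    "C": "C3H5NOS",
    "L": "C6H11NO",
    "I": "C6H11NO",
    "N": "C4H6N2O2",
    "D": "C4H5NO3",
    "Q": "C5H8N2O2",
    "K": "C6H12N2O",
    "E": "C5H7NO3",
    "M": "C5H9NOS",
    "H": "C6H7N3O",
    "F": "C9H9NO",
    "R": "C6H12N4O",
    "Y": "C9H9NO2",
    "W": "C11H10N2O",
}

RESIDUE_MASSES: dict[str, float] = {
    aa: monoisotopic_mass(f) for aa, f in RESIDUE_FORMULAS.items()
}


@dataclass(frozen=True)
class Modification:
    """A residue modification: mass delta, eligible residues, fixed/variable."""

    name: str
    delta: float
    targets: frozenset[str]
    fixed: bool = False


_HPO3 = monoisotopic_mass("HPO3")

#: The modification set used throughout: phospho (S/T/Y), pyrophospho (S/T)
#: and oxidation (M) variable; carbamidomethyl (C) fixed.
MODIFICATIONS: dict[str, Modification] = {
    "phospho": Modification("phospho", _HPO3, frozenset("STY")),
    "pyrophospho": Modification("pyrophospho", 2 * _HPO3, frozenset("ST")),
    "oxidation": Modification("oxidation", monoisotopic_mass("O"), frozenset("M")),
    "carbamidomethyl": Modification(
        "carbamidomethyl", monoisotopic_mass("C2H3NO"), frozenset("C"), fixed=True
    ),
}

#: Phosphate-group equivalents carried by each modification (pyrophospho
#: places a diphosphate on one side chain and counts as 2).
PHOSPHATE_EQUIVALENTS: dict[str, int] = {
    "phospho": 1,
    "pyrophospho": 2,
    "oxidation": 0,
    "carbamidomethyl": 0,
}


@dataclass(frozen=True)
class NeutralLossSpecies:
    """A neutral molecule lost from a precursor ion during CID."""

    label: str
    formula: str
    mass: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "mass", monoisotopic_mass(self.formula))

    @property
    def nominal(self) -> int:
        return round(self.mass)


#: The three diagnostic precursor losses. H4P2O7 (pyrophosphoric acid,
#: nominal -178) is produced only by pyrophosphopeptides; mono- and
#: bisphosphopeptides produce only the -98 / -196 channels.
NEUTRAL_LOSSES: dict[str, NeutralLossSpecies] = {
    "H3PO4": NeutralLossSpecies("H3PO4", "H3PO4"),
    "H4P2O7": NeutralLossSpecies("H4P2O7", "H4P2O7"),
    "H6P2O8": NeutralLossSpecies("H6P2O8", "H6P2O8"),
}


@dataclass(frozen=True)
class ModifiedPeptide:
    """A peptide sequence with positioned modifications.

    ``mods`` is a frozenset of ``(position, modification_name)`` with 1-based
    positions. ``protein_id``/``start`` record provenance when the peptide
    came from a digest (start is the 1-based offset of residue 1 in the
    protein).
    """

    sequence: str
    mods: frozenset[tuple[int, str]] = frozenset()
    protein_id: str | None = None
    start: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "mods", frozenset(self.mods))

    def validate(self) -> None:
        for aa in self.sequence:
            if aa not in RESIDUE_MASSES:
                raise ValueError(f"unknown residue {aa!r} in {self.sequence!r}")
        seen: set[int] = set()
        for pos, name in self.mods:
            if not 1 <= pos <= len(self.sequence):
                raise ValueError(
                    f"modification position {pos} outside peptide {self.sequence!r}"
                )
            if name not in MODIFICATIONS:
                raise ValueError(f"unknown modification {name!r}")
            residue = self.sequence[pos - 1]
            if residue not in MODIFICATIONS[name].targets:
                raise ValueError(
                    f"{name} not allowed on residue {residue!r} at position {pos}"
                )
            if pos in seen:
                raise ValueError(f"residue {pos} carries more than one modification")
            seen.add(pos)

    def mod_at(self, pos: int) -> str | None:
        for p, name in self.mods:
            if p == pos:
                return name
        return None

    def phosphate_equivalents(self, pos: int) -> int:
        name = self.mod_at(pos)
        return PHOSPHATE_EQUIVALENTS.get(name, 0) if name else 0

    @property
    def pyro_sites(self) -> tuple[int, ...]:
        return tuple(sorted(p for p, n in self.mods if n == "pyrophospho"))

    @property
    def form_key(self) -> str:
        """Deterministic string key, e.g. ``"ASSK[pyrophospho@3]"``."""
        tags = "".join(
            f"[{name}@{pos}]" for pos, name in sorted(self.mods)
        )
        return self.sequence + tags


def peptide_neutral_mass(peptide: ModifiedPeptide) -> float:
    """Neutral monoisotopic mass: residue sum + H2O + modification deltas."""
    peptide.validate()
    total = WATER_MASS
    for aa in peptide.sequence:
        total += RESIDUE_MASSES[aa]
    for _pos, name in peptide.mods:
        total += MODIFICATIONS[name].delta
    return total


def mz(mass: float, z: int) -> float:
    """m/z of a species of neutral ``mass`` carrying ``z`` protons."""
    if z < 1:
        raise ValueError(f"charge must be a positive integer, got {z}")
    return (mass + z * PROTON_MASS) / z
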