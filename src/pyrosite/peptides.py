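"""In-silico tryptic digestion and modified-peptide candidate enumeration.

Digestion follows the full-trypsin rule (cleave after K/R, not before P) with
a configurable number of missed cleavages; candidate generation enumerates
every placement of the variable modifications (phospho, pyrophospho,
oxidation) under the search caps and filters against an observed precursor
at a ppm tolerance, mirroring a standard database-search configuration
(trypsin, 2 missed cleavages, 10 ppm precursor / 0.02 Da fragment,
precursor mass 350-5,000 Da, charge 2-4).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from pyteomics import fasta as _fasta

from .masschem import (
    MODIFICATIONS,
    RESIDUE_MASSES,
    ModifiedPeptide,
    mz,
    peptide_neutral_mass,
)

__all__ = [
    "DigestParams",
    "DigestedPeptide",
    "digest",
    "enumerate_modforms",
    "read_fasta",
    "candidates_for_precursor",
]

DEFAULT_VARIABLE_MODS = ("phospho", "pyrophospho", "oxidation")


@dataclass(frozen=True)
class DigestParams:
    enzyme: str = "trypsin"
    max_missed: int = 2
    min_len: int = 7
    mass_range: tuple[float, float] = (350.0, 5000.0)
    charge_range: tuple[int, int] = (2, 4)


@dataclass(frozen=True)
class DigestedPeptide:
    sequence: str
    start: int  # 1-based, inclusive
    end: int  # 1-based, inclusive
    missed: int


def _cleavage_sites(protein: str) -> list[int]:
    """0-based indices i such that trypsin cuts between i and i+1."""
    sites = []
    for i in range(len(protein) - 1):
        if protein[i] in "KR" and protein[i + 1] != "P":
            sites.append(i)
    return sites


def digest(protein: str, params: DigestParams | None = None) -> list[DigestedPeptide]:
    """Tryptic peptides of ``protein`` with up to ``max_missed`` missed cleavages.

    Cuts after K/R except before P. Offsets are 1-based inclusive. The
    ``min_len`` filter is *not* applied here (it belongs to candidate
    generation); an empty protein yields an empty list.
    """
    params = params or DigestParams()
    if params.enzyme != "trypsin":
        raise ValueError(f"unsupported enzyme {params.enzyme!r}")
    if not protein:
        return []
    cuts = _cleavage_sites(protein)
    # boundaries: start indices of fully-cleaved fragments
    starts = [0] + [c + 1 for c in cuts]
    ends = [c for c in cuts] + [len(protein) - 1]
    out: list[DigestedPeptide] = []
    for i, s in enumerate(starts):
        for skip in range(params.max_missed + 1):
            j = i + skip
            if j >= len(ends):
                break
            e = ends[j]
            out.append(
                DigestedPeptide(protein[s : e + 1], s + 1, e + 1, missed=skip)
            )
    return out


def enumerate_modforms(
    sequence: str,
    max_var_mods: int = 4,
    max_pyro: int = 1,
    variable_mods: tuple[str, ...] = DEFAULT_VARIABLE_MODS,
) -> list[ModifiedPeptide]:
    """All distinct variable-modification placements of ``sequence``.

    Every form carries the fixed carbamidomethyl on each Cys; no residue
    carries two modifications; at most ``max_var_mods`` variable mods and
    ``max_pyro`` pyrophospho groups per form. Forms are returned in
    deterministic (form-key sorted) order, the unmodified form first.
    """
    fixed = frozenset(
        (i + 1, "carbamidomethyl") for i, aa in enumerate(sequence) if aa == "C"
    )
    options: list[tuple[int, list[str]]] = []
    for i, aa in enumerate(sequence):
        if aa == "C":
            continue  # occupied by the fixed mod
        applicable = [m for m in variable_mods if aa in MODIFICATIONS[m].targets]
        if applicable:
            options.append((i + 1, applicable))

    forms: list[ModifiedPeptide] = []

    def recurse(idx: int, placed: list[tuple[int, str]], n_var: int, n_pyro: int) -> None:
        if idx == len(options):
            forms.append(ModifiedPeptide(sequence, fixed | frozenset(placed)))
            return
        pos, mods = options[idx]
        recurse(idx + 1, placed, n_var, n_pyro)  # leave unmodified
        if n_var < max_var_mods:
            for m in mods:
                if m == "pyrophospho" and n_pyro >= max_pyro:
                    continue
                placed.append((pos, m))
                recurse(idx + 1, placed, n_var + 1, n_pyro + (m == "pyrophospho"))
                placed.pop()

    recurse(0, [], 0, 0)
    return sorted(forms, key=lambda p: (len(p.mods), p.form_key))


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (possibly wrapped) multi-record FASTA into ``{id: sequence}``.

    The record id is the first whitespace-delimited token of the header.
    """
    proteins: dict[str, str] = {}
    with _fasta.read(str(path)) as reader:
        for record in reader:
            header = record.description
            if not header:
                raise ValueError(f"FASTA record with empty header in {path}")
            proteins[header.split()[0]] = record.sequence.upper()
    if not proteins:
        raise ValueError(f"no FASTA records found in {path}")
    return proteins


def candidates_for_precursor(
    proteins: dict[str, str],
    mz_obs: float,
    z: int,
    tol_ppm: float = 10.0,
    params: DigestParams | None = None,
    max_var_mods: int = 4,
    max_pyro: int = 1,
) -> list[ModifiedPeptide]:
    """Modified peptides from the digested ``proteins`` matching a precursor.

    Returns every form whose theoretical m/z at charge ``z`` lies within
    ``tol_ppm`` of ``mz_obs`` and whose neutral mass is inside the accepted
    precursor mass range, ranked by (number of modifications, form key).
    Peptides containing non-standard letters are skipped.
    """
    params = params or DigestParams()
    lo_z, hi_z = params.charge_range
    if not lo_z <= z <= hi_z:
        raise ValueError(f"precursor charge {z} outside configured range {params.charge_range}")
    lo, hi = params.mass_range
    out: list[ModifiedPeptide] = []
    seen: set[str] = set()
    for pid, seq in proteins.items():
        for pep in digest(seq, params):
            if len(pep.sequence) < params.min_len:
                continue
            if any(aa not in RESIDUE_MASSES for aa in pep.sequence):
                continue
            for form in enumerate_modforms(pep.sequence, max_var_mods, max_pyro):
                mass = peptide_neutral_mass(form)
                if not lo <= mass <= hi:
                    continue
                theo = mz(mass, z)
                if abs(theo - mz_obs) / mz_obs * 1e6 > tol_ppm:
                    continue
                key = f"{pid}:{pep.start}:{form.form_key}"
                if key in seen:
                    continue
                seen.add(key)
                out.append(
                    ModifiedPeptide(form.sequence, form.mods, protein_id=pid, start=pep.start)
                )
    return sorted(out, key=lambda p: (len(p.mods), p.form_key, p.protein_id or "", p.start or 0))
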