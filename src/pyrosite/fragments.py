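"""Theoretical backbone fragments and tolerance-based peak matching.

CID spectra are annotated with b/y ions, EThcD spectra with c/z ions (plus
b/y from the HCD component). z ions come in three common variants whose
naming differs between tools; all three are generated and whichever matched
is reported:

    b_i  = sum(residues 1..i)                  (+ proton per charge)
    y_j  = sum(residues L-j+1..L) + H2O
    c_i  = b_i + NH3
    z*_j = y_j - NH3 + H      (z radical; series label "z")
    z+1  = z* + H
    z-1  = z* - H

Modifications are included in the residue sums, so a c ion crossing a
pyrophosphorylated residue carries the full diphosphate. ``phospho_count``
records the phosphate-group equivalents inside the fragment -- the quantity
the spectral validator reasons on.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass

from .masschem import (
    H_MASS,
    MODIFICATIONS,
    NH3_MASS,
    PROTON_MASS,
    RESIDUE_MASSES,
    WATER_MASS,
    ModifiedPeptide,
    PHOSPHATE_EQUIVALENTS,
)

__all__ = [
    "SERIES",
    "FragmentIon",
    "PeakMatch",
    "theoretical_ions",
    "match_peaks",
    "phospho_signature",
]

#: Supported series labels. "z" denotes the z radical (z-dot).
SERIES = ("b", "y", "c", "z", "z+1", "z-1")

_NTERM_SERIES = frozenset({"b", "c"})
_CTERM_SERIES = frozenset({"y", "z", "z+1", "z-1"})

# neutral-mass offset of each series relative to the bare residue sum
_SERIES_OFFSET = {
    "b": 0.0,
    "c": NH3_MASS,
    "y": WATER_MASS,
    "z": WATER_MASS - NH3_MASS + H_MASS,
    "z+1": WATER_MASS - NH3_MASS + 2 * H_MASS,
    "z-1": WATER_MASS - NH3_MASS,
}


@dataclass(frozen=True)
class FragmentIon:
    series: str
    index: int  # 1..L-1; counted from the N-terminus for b/c, C-terminus for y/z
    charge: int
    phospho_count: int
    mz: float


@dataclass(frozen=True)
class PeakMatch:
    ion: FragmentIon
    peak_mz: float
    intensity: float
    error_da: float

    @property
    def error_ppm(self) -> float:
        return self.error_da / self.ion.mz * 1e6


def _residue_masses_with_mods(p: ModifiedPeptide) -> list[float]:
    masses = []
    for i, aa in enumerate(p.sequence, start=1):
        m = RESIDUE_MASSES[aa]
        name = p.mod_at(i)
        if name:
            m += MODIFICATIONS[name].delta
        masses.append(m)
    return masses


def phospho_signature(p: ModifiedPeptide, series: str, index: int) -> int:
    """Phosphate-group equivalents carried by fragment ``series``/``index``.

    A pyrophosphorylated residue inside the fragment contributes 2; a
    monophosphorylated residue contributes 1. For a pure pyrophospho form the
    result is always 0 or 2, never 1 -- a fragment carrying exactly one
    phosphate is possible only for a bisphosphorylated peptide.
    """
    L = len(p.sequence)
    if not 1 <= index <= L - 1:
        raise ValueError(f"fragment index {index} invalid for length {L}")
    if series in _NTERM_SERIES:
        positions = range(1, index + 1)
    elif series in _CTERM_SERIES:
        positions = range(L - index + 1, L + 1)
    else:
        raise ValueError(f"unsupported series {series!r}")
    return sum(p.phosphate_equivalents(i) for i in positions)


def theoretical_ions(
    p: ModifiedPeptide,
    series: tuple[str, ...] = ("c", "z"),
    max_charge: int = 2,
) -> list[FragmentIon]:
    """All fragment ions of ``p`` for the requested series and charges.

    Per series and charge there are exactly L-1 ions (indices 1..L-1).
    """
    p.validate()
    L = len(p.sequence)
    if L < 2:
        raise ValueError("peptide must have length >= 2 to fragment")
    for s in series:
        if s not in SERIES:
            raise ValueError(f"unsupported series {s!r}")
    res = _residue_masses_with_mods(p)
    prefix = [0.0]
    for m in res:
        prefix.append(prefix[-1] + m)
    total = prefix[-1]
    ions: list[FragmentIon] = []
    for s in series:
        offset = _SERIES_OFFSET[s]
        for idx in range(1, L):
            if s in _NTERM_SERIES:
                neutral = prefix[idx] + offset
            else:
                neutral = (total - prefix[L - idx]) + offset
            count = phospho_signature(p, s, idx)
            for z in range(1, max_charge + 1):
                ions.append(
                    FragmentIon(s, idx, z, count, (neutral + z * PROTON_MASS) / z)
                )
    return ions


def match_peaks(
    peaks: list[tuple[float, float]],
    ions: list[FragmentIon],
    tol: float = 0.02,
    tol_unit: str = "Da",
) -> list[PeakMatch]:
    """Match each theoretical ion to the nearest peak within tolerance.

    One peak may satisfy several isomeric ions; the ambiguity is preserved.
    When two peaks are equidistant from an ion the more intense one wins.
    Ions without a peak within tolerance are absent from the output.
    """
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    if tol_unit not in ("Da", "ppm"):
        raise ValueError(f"unsupported tolerance unit {tol_unit!r}")
    peaks = sorted(peaks)
    mzs = [p[0] for p in peaks]
    out: list[PeakMatch] = []
    for ion in ions:
        limit = tol if tol_unit == "Da" else tol * ion.mz / 1e6
        i = bisect_left(mzs, ion.mz)
        best: tuple[float, float, float] | None = None  # (|err|, -intensity, mz)
        for j in (i - 1, i):
            if 0 <= j < len(peaks):
                err = abs(mzs[j] - ion.mz)
                if err <= limit:
                    cand = (err, -peaks[j][1], mzs[j])
                    if best is None or cand < best:
                        best = cand
        if best is not None:
            peak_mz = best[2]
            intensity = -best[1]
            out.append(PeakMatch(ion, peak_mz, intensity, peak_mz - ion.mz))
    return out
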