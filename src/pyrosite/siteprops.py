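"""Sequence-property analyses of validated pyrophosphorylation sites.

Covers the downstream characterization of a site cohort: a sliding-window
local isoelectric point profile (pyrophosphosites concentrate in acidic
stretches), the CK2-consensus partition (acidophilic kinase motif: E/D/S/T
at position +3), the disorder-stretch rule (a site counts as disordered if
it lies inside a run of >= 20 consecutive residues with disorder score
>= 0.5), the Ser/Thr tally and the position frequency matrix underlying a
sequence logo.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PKA_SIDE_CHAINS",
    "SiteRecord",
    "extract_sites",
    "read_site_list",
    "read_disorder_track",
    "local_pi_profile",
    "window_pi",
    "ck2_partition",
    "disorder_stretch_flag",
    "disorder_cohort_fraction",
    "residue_tally_and_pfm",
]

#: Side-chain pKa values (Lehninger set). Only side chains ionize in the
#: windowed profile; the backbone termini of an interior window are peptide
#: bonds, not free termini, and are excluded.
PKA_SIDE_CHAINS: dict[str, tuple[float, int]] = {
    # residue: (pKa, charge sign when protonated side is left: -1 acid, +1 base)
    "D": (3.65, -1),
    "E": (4.25, -1),
    "C": (8.30, -1),
    "Y": (10.07, -1),
    "H": (6.00, +1),
    "K": (10.53, +1),
    "R": (12.48, +1),
}

PAD = "-"


@dataclass(frozen=True)
class SiteRecord:
    """A pyrophosphosite in protein coordinates with its flanking window."""

    protein_id: str
    position: int  # 1-based
    residue: str  # S or T
    window: str  # length 2w+1, '-' padded at the termini

    def __post_init__(self) -> None:
        if self.residue not in ("S", "T"):
            raise ValueError(
                f"pyrophosphorylation occurs on S/T only, got {self.residue!r} "
                f"at {self.protein_id}:{self.position}"
            )
        if len(self.window) % 2 != 1:
            raise ValueError("window length must be odd (2w+1)")

    def flank(self, offset: int) -> str:
        """Residue at the given offset from the site (PAD beyond the window)."""
        w = len(self.window) // 2
        if abs(offset) > w:
            return PAD
        return self.window[w + offset]


def extract_sites(
    proteins: dict[str, str], sites: list[tuple[str, int]], w: int = 7
) -> list[SiteRecord]:
    """Build site records with +/-w flanking windows from protein sequences."""
    out = []
    for pid, pos in sites:
        seq = proteins[pid]
        if not 1 <= pos <= len(seq):
            raise ValueError(f"site {pid}:{pos} outside protein of length {len(seq)}")
        chars = []
        for off in range(-w, w + 1):
            i = pos - 1 + off
            chars.append(seq[i] if 0 <= i < len(seq) else PAD)
        out.append(SiteRecord(pid, pos, seq[pos - 1], "".join(chars)))
    return out


def read_site_list(path) -> list[tuple[str, int]]:
    """Read a site-list TSV with columns ``protein_id`` and ``position``."""
    df = pd.read_csv(path, sep="\t")
    missing = {"protein_id", "position"} - set(df.columns)
    if missing:
        raise ValueError(f"site list is missing columns: {sorted(missing)}")
    return [(str(r.protein_id), int(r.position)) for r in df.itertuples()]


def read_disorder_track(path, length: int | None = None) -> np.ndarray:
    """Read a two-column (position, score) TSV into a per-residue array.

    Positions are 1-based; scores must lie in [0, 1]. If ``length`` is given
    the track must cover exactly that many residues.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=["position", "score"], comment="#")
    positions = df["position"].to_numpy(dtype=int)
    scores = df["score"].to_numpy(dtype=float)
    if np.any((scores < 0) | (scores > 1)):
        raise ValueError("disorder scores must lie in [0, 1]")
    n = positions.max()
    if length is not None and n != length:
        raise ValueError(f"disorder track covers {n} residues, expected {length}")
    track = np.full(n, np.nan)
    track[positions - 1] = scores
    if np.isnan(track).any():
        raise ValueError("disorder track has gaps")
    return track


def _net_charge(window: str, ph: float) -> float:
    q = 0.0
    for aa in window:
        entry = PKA_SIDE_CHAINS.get(aa)
        if entry is None:
            continue
        pka, sign = entry
        if sign > 0:  # base: protonated (charged) fraction
            q += 1.0 / (1.0 + 10 ** (ph - pka))
        else:  # acid: deprotonated (charged) fraction
            q -= 1.0 / (1.0 + 10 ** (pka - ph))
    return q


def window_pi(window: str, tol: float = 1e-4) -> tuple[float, bool]:
    """pI of one sequence window by bisection of the net-charge equation.

    Returns ``(pI, ionizable)``. A window without ionizable side chains has
    no defined pI and reports the neutral sentinel 7.0 with ``ionizable``
    False. Windows whose charge never crosses zero inside pH 0-14 (pure
    acids / pure bases) report the clamped boundary.
    """
    if not any(aa in PKA_SIDE_CHAINS for aa in window):
        return 7.0, False
    lo, hi = 0.0, 14.0
    qlo, qhi = _net_charge(window, lo), _net_charge(window, hi)
    if qlo <= 0:  # all-acid window: negative across the whole range
        return lo, True
    if qhi >= 0:  # all-base window
        return hi, True
    while True:
        mid = 0.5 * (lo + hi)
        q = _net_charge(window, mid)
        if abs(q) < tol or hi - lo < 1e-12:
            return mid, True
        if q > 0:
            lo = mid
        else:
            hi = mid


def local_pi_profile(sequence: str, w: int = 10) -> pd.DataFrame:
    """Sliding-window local pI along a protein (window 2w+1, truncated at termini).

    Returns a DataFrame with 1-based ``position``, ``pi`` and ``ionizable``.
    """
    if w < 1:
        raise ValueError("window half-width must be >= 1")
    rows = []
    n = len(sequence)
    for i in range(n):
        window = sequence[max(0, i - w) : min(n, i + w + 1)]
        pi, ionizable = window_pi(window)
        rows.append((i + 1, pi, ionizable))
    return pd.DataFrame(rows, columns=["position", "pi", "ionizable"])


CK2_PLUS3 = frozenset("EDST")


def ck2_partition(sites: list[SiteRecord]) -> tuple[list[SiteRecord], list[SiteRecord]]:
    """Split sites into (CK2-consensus, remainder) by the +3 rule.

    A site matches the acidophilic CK2 consensus iff the residue at position
    +3 is Glu/Asp/Ser/Thr; a padded +3 (site within 3 residues of the
    C-terminus) cannot fire the rule and goes to the remainder.
    """
    ck2, rest = [], []
    for s in sites:
        (ck2 if s.flank(+3) in CK2_PLUS3 else rest).append(s)
    return ck2, rest


def disorder_stretch_flag(
    track: np.ndarray, position: int, min_len: int = 20, cutoff: float = 0.5
) -> bool:
    """Whether a site lies in a disordered stretch of >= ``min_len`` residues.

    True iff the maximal run of consecutive residues with score >= cutoff
    containing ``position`` has length >= min_len; a site whose own score is
    below the cutoff is never flagged.
    """
    n = len(track)
    if not 1 <= position <= n:
        raise ValueError(f"position {position} outside track of length {n}")
    i = position - 1
    if track[i] < cutoff:
        return False
    lo = i
    while lo > 0 and track[lo - 1] >= cutoff:
        lo -= 1
    hi = i
    while hi < n - 1 and track[hi + 1] >= cutoff:
        hi += 1
    return hi - lo + 1 >= min_len


def disorder_cohort_fraction(
    tracks: dict[str, np.ndarray],
    sites: list[tuple[str, int]],
    min_len: int = 20,
    cutoff: float = 0.5,
) -> float:
    """Fraction of sites lying within a qualifying disordered stretch."""
    if not sites:
        raise ValueError("empty site list")
    flags = [
        disorder_stretch_flag(tracks[pid], pos, min_len, cutoff) for pid, pos in sites
    ]
    return float(np.mean(flags))


AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def residue_tally_and_pfm(
    sites: list[SiteRecord],
) -> tuple[int, int, pd.DataFrame]:
    """Ser/Thr counts of the cohort and the window position frequency matrix.

    The PFM has one row per amino acid and one column per window offset
    (-w..+w); padding characters are not counted, so each column sums to the
    number of sites whose window covers that offset.
    """
    if not sites:
        raise ValueError("empty site list")
    widths = {len(s.window) for s in sites}
    if len(widths) > 1:
        raise ValueError("site windows have differing widths")
    w = widths.pop() // 2
    offsets = list(range(-w, w + 1))
    pfm = pd.DataFrame(0, index=list(AMINO_ACIDS), columns=offsets)
    s_count = t_count = 0
    for s in sites:
        if s.residue == "S":
            s_count += 1
        else:
            t_count += 1
        for off in offsets:
            aa = s.flank(off)
            if aa != PAD:
                pfm.loc[aa, off] += 1
    return s_count, t_count, pfm
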