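"""The three-step protocol confirming pyrophosphorylation site assignments.

A candidate (peptide with a single putative pyrophospho site) is assessed
against its paired CID/EThcD spectra with a strict precedence of outcomes:

1. ``NOT_TRIGGERED`` -- the CID scan shows no qualifying -178 neutral loss.
2. ``STEP1_FAIL`` -- the -178 loss is present but ranks outside the top
   three CID peaks (typical of bisphospho/pyrophospho mixtures).
3. ``BISPHOSPHO_EVIDENCE`` -- the EThcD spectrum contains a fragment that
   can only be explained with exactly one phosphate group; such a fragment
   exists only if bisphosphorylated species contribute to the spectrum.
   This step rejects the co-fragmentation hazard: two bisphosphopeptides
   with overlapping phosphorylation pairs jointly supply every ion needed
   to (mis)assign a pyrophospho site to the shared residue, but their
   single-phosphate fragments betray them.
4. ``INSUFFICIENT_COVERAGE`` -- no site-bridging couplet (sequential
   fragments: index k-1 with zero phosphates and index k with two) was
   matched; spectra with the key fragments missing are discarded.
5. ``CONFIRMED`` -- couplet evidence present and no counter-evidence.

Before steps 3-4 the EThcD peak list is stripped of non-fragment signals
(residual precursor, charge-reduced precursors and their phosphate neutral
losses), mirroring a standard non-fragment filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .fragments import PeakMatch, match_peaks, theoretical_ions
from .masschem import NEUTRAL_LOSSES, ModifiedPeptide
from .spectra_io import SpectrumRecord
from .trigger import TriggerConfig, detect_neutral_losses, should_trigger, step1_rank_filter

__all__ = [
    "ValidatorConfig",
    "CoupletEvidence",
    "ValidationVerdict",
    "strip_nonfragment_peaks",
    "find_monophospho_evidence",
    "find_site_couplets",
    "classify",
]

_N_SERIES = ("b", "c")
_C_SERIES = ("y", "z", "z+1", "z-1")


@dataclass(frozen=True)
class ValidatorConfig:
    trigger: TriggerConfig = field(default_factory=TriggerConfig)
    fragment_tol: float = 0.02  # Da
    series: tuple[str, ...] = ("c", "z", "z+1", "z-1", "b", "y")
    max_fragment_charge: int = 2
    couplet_policy: str = "ONE_SIDE"  # or "BOTH_SIDES"
    precursor_window: float = 1.0  # Da, non-fragment filter around the precursor
    reduced_window: float = 0.5  # Da, around charge-reduced precursors and losses

    def __post_init__(self) -> None:
        if self.couplet_policy not in ("ONE_SIDE", "BOTH_SIDES"):
            raise ValueError(f"unknown couplet policy {self.couplet_policy!r}")


@dataclass(frozen=True)
class CoupletEvidence:
    """Sequential lower/upper fragments bridging a putative pyro site.

    ``lower`` matches the fragment just short of the site with zero
    phosphates; ``upper`` the next fragment carrying both phosphates --
    detected simultaneously, they place the diphosphate on the bridged
    residue.
    """

    side: str  # "N" or "C"
    series: str
    lower: PeakMatch
    upper: PeakMatch

    def describe(self) -> str:
        s = self.series
        return f"{self.side}:{s}{self.lower.ion.index}/{s}{self.upper.ion.index}"


@dataclass(frozen=True)
class ValidationVerdict:
    spectrum_id: str
    candidate: ModifiedPeptide
    site: int
    verdict: str
    couplets: tuple[CoupletEvidence, ...] = ()
    counter_evidence: tuple[PeakMatch, ...] = ()
    nl_rank: int | None = None


def strip_nonfragment_peaks(
    ethcd: SpectrumRecord, cfg: ValidatorConfig | None = None
) -> SpectrumRecord:
    """Remove residual precursor signals from an EThcD peak list.

    Peaks within +/-1 Da of the precursor m/z are removed; peaks within
    +/-0.5 Da of each charge-reduced precursor (charges z-1..1) or of any
    phosphate neutral-loss position of the precursor species are removed.
    All other peaks are untouched.
    """
    cfg = cfg or ValidatorConfig()
    if ethcd.activation != "EThcD":
        raise ValueError(f"non-fragment stripping expects an EThcD scan, got {ethcd.activation}")
    z = ethcd.precursor_charge
    mh = ethcd.precursor_mz * z  # mass of [M + zH], protons included
    windows: list[tuple[float, float]] = [(ethcd.precursor_mz, cfg.precursor_window)]
    loss_masses = [sp.mass for sp in NEUTRAL_LOSSES.values()]
    for loss in loss_masses:  # precursor neutral losses at the original charge
        windows.append((ethcd.precursor_mz - loss / z, cfg.reduced_window))
    for r in range(z - 1, 0, -1):  # charge-reduced species keep all protons
        reduced = mh / r
        windows.append((reduced, cfg.reduced_window))
        for loss in loss_masses:
            windows.append((reduced - loss / r, cfg.reduced_window))
    kept = tuple(
        (m, i)
        for m, i in ethcd.peaks
        if all(abs(m - center) > half for center, half in windows)
    )
    return replace(ethcd, peaks=kept)


def _backbone_without_phospho(candidate: ModifiedPeptide) -> ModifiedPeptide:
    """The candidate with its phosphate modifications removed (others kept)."""
    mods = frozenset(
        (p, n) for p, n in candidate.mods if n not in ("phospho", "pyrophospho")
    )
    return ModifiedPeptide(candidate.sequence, mods)


def find_monophospho_evidence(
    ethcd: SpectrumRecord,
    candidate: ModifiedPeptide,
    cfg: ValidatorConfig | None = None,
) -> list[PeakMatch]:
    """Step 2: matched fragments explainable only with exactly one phosphate.

    The spectrum is matched against the union of (a) the pyrophospho
    hypothesis and (b) every single-phospho placement on the same backbone.
    A matched single-phosphate fragment counts as counter-evidence only if
    its m/z is not within tolerance of any 0- or 2-phosphate ion of the
    pyro hypothesis (coincident masses are ambiguous and, conservatively,
    not held against the candidate).
    """
    cfg = cfg or ValidatorConfig()
    backbone = _backbone_without_phospho(candidate)
    pyro_ions = theoretical_ions(candidate, cfg.series, cfg.max_fragment_charge)
    pyro_mzs = sorted(ion.mz for ion in pyro_ions)

    phosphorylatable = [
        i + 1
        for i, aa in enumerate(backbone.sequence)
        if aa in "STY" and backbone.mod_at(i + 1) is None
    ]
    mono_ions = []
    seen: set[tuple[str, int, int]] = set()
    for pos in phosphorylatable:
        form = ModifiedPeptide(
            backbone.sequence, backbone.mods | {(pos, "phospho")}
        )
        for ion in theoretical_ions(form, cfg.series, cfg.max_fragment_charge):
            if ion.phospho_count != 1:
                continue
            key = (ion.series, ion.index, ion.charge)
            if key in seen:  # same m/z regardless of which inside residue carries it
                continue
            seen.add(key)
            mono_ions.append(ion)

    matches = match_peaks(list(ethcd.peaks), mono_ions, cfg.fragment_tol)

    from bisect import bisect_left

    def coincident(mz_val: float) -> bool:
        i = bisect_left(pyro_mzs, mz_val)
        for j in (i - 1, i):
            if 0 <= j < len(pyro_mzs) and abs(pyro_mzs[j] - mz_val) <= cfg.fragment_tol:
                return True
        return False

    return [m for m in matches if not coincident(m.ion.mz)]


def find_site_couplets(
    ethcd: SpectrumRecord,
    candidate: ModifiedPeptide,
    site: int,
    cfg: ValidatorConfig | None = None,
) -> list[CoupletEvidence]:
    """Step 3 evidence: sequential ion pairs bridging the putative site.

    N-side couplet: indices (site-1, site) in a b or c series, the lower ion
    with zero phosphates and the upper carrying both. C-side couplet:
    indices (L-site, L-site+1) in a y or z series. A site at position 1 (or
    L) has no N-side (C-side) couplet -- reported as absence, not an error.
    Couplet ions must share series label and charge state.
    """
    cfg = cfg or ValidatorConfig()
    L = len(candidate.sequence)
    if not 1 <= site <= L:
        raise ValueError(f"site {site} outside peptide of length {L}")
    ions = theoretical_ions(candidate, cfg.series, cfg.max_fragment_charge)
    matches = match_peaks(list(ethcd.peaks), ions, cfg.fragment_tol)
    by_key = {(m.ion.series, m.ion.index, m.ion.charge): m for m in matches}

    couplets: list[CoupletEvidence] = []

    def probe(side: str, series_set: tuple[str, ...], lo_idx: int, hi_idx: int) -> None:
        if lo_idx < 1 or hi_idx > L - 1:
            return
        for s in series_set:
            if s not in cfg.series:
                continue
            for z in range(1, cfg.max_fragment_charge + 1):
                lower = by_key.get((s, lo_idx, z))
                upper = by_key.get((s, hi_idx, z))
                if (
                    lower
                    and upper
                    and lower.ion.phospho_count == 0
                    and upper.ion.phospho_count == 2
                ):
                    couplets.append(CoupletEvidence(side, s, lower, upper))

    probe("N", _N_SERIES, site - 1, site)
    probe("C", _C_SERIES, L - site, L - site + 1)
    return couplets


def classify(
    cid: SpectrumRecord,
    ethcd: SpectrumRecord,
    candidate: ModifiedPeptide,
    cfg: ValidatorConfig | None = None,
) -> ValidationVerdict:
    """Run the full three-step protocol on a paired CID/EThcD spectrum.

    The candidate must carry exactly one pyrophospho site. Raises if the
    EThcD scan is not linked to (or consistent with) the given CID scan.
    """
    cfg = cfg or ValidatorConfig()
    sites = candidate.pyro_sites
    if len(sites) != 1:
        raise ValueError("candidate must carry exactly one pyrophospho site")
    site = sites[0]
    if ethcd.triggered_by is not None and ethcd.triggered_by != cid.scan_id:
        raise ValueError(
            f"EThcD scan {ethcd.scan_id} is paired with {ethcd.triggered_by}, not {cid.scan_id}"
        )
    if abs(cid.precursor_mz - ethcd.precursor_mz) / cid.precursor_mz * 1e6 > 20:
        raise ValueError("CID and EThcD precursor m/z disagree; spectra are not a pair")

    report = detect_neutral_losses(cid, cfg.trigger)
    obs = report.losses.get(cfg.trigger.trigger_loss)
    nl_rank = obs.rank if obs and obs.observed else None

    def verdict(name: str, couplets=(), counter=()) -> ValidationVerdict:
        return ValidationVerdict(
            spectrum_id=ethcd.scan_id,
            candidate=candidate,
            site=site,
            verdict=name,
            couplets=tuple(couplets),
            counter_evidence=tuple(counter),
            nl_rank=nl_rank,
        )

    if not should_trigger(report, cfg.trigger):
        return verdict("NOT_TRIGGERED")
    if not step1_rank_filter(report, cfg.trigger):
        return verdict("STEP1_FAIL")

    stripped = strip_nonfragment_peaks(ethcd, cfg)
    counter = find_monophospho_evidence(stripped, candidate, cfg)
    if counter:
        return verdict("BISPHOSPHO_EVIDENCE", counter=counter)

    couplets = find_site_couplets(stripped, candidate, site, cfg)
    if cfg.couplet_policy == "BOTH_SIDES":
        ok = any(c.side == "N" for c in couplets) and any(c.side == "C" for c in couplets)
        # a terminal site has only one defined side; require the defined one
        if site == 1:
            ok = any(c.side == "C" for c in couplets)
        elif site == len(candidate.sequence):
            ok = any(c.side == "N" for c in couplets)
    else:
        ok = bool(couplets)
    if not ok:
        return verdict("INSUFFICIENT_COVERAGE", couplets=couplets)
    return verdict("CONFIRMED", couplets=couplets)
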