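"""CID neutral-loss trigger emulation and the intensity-rank filter.

During acquisition each precursor is first fragmented by CID; if a neutral
loss of pyrophosphoric acid (H4P2O7, 177.9432 Da) from the precursor is seen
above 15% relative intensity and the precursor charge is 2-4, an EThcD scan
of the same precursor is acquired. Offline, assessment step 1 additionally
requires the -178 channel to be among the three most intense peaks of the
CID scan: in pyrophosphopeptide standards it consistently ranks in the top
three, whereas bisphosphopeptide co-fragmentation inflates the -98/-196
channels and pushes -178 down the ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .masschem import NEUTRAL_LOSSES
from .spectra_io import SpectrumRecord

__all__ = [
    "TriggerConfig",
    "NeutralLossObservation",
    "NeutralLossReport",
    "detect_neutral_losses",
    "should_trigger",
    "step1_rank_filter",
]


@dataclass(frozen=True)
class TriggerConfig:
    losses: tuple[str, ...] = ("H3PO4", "H4P2O7", "H6P2O8")
    trigger_loss: str = "H4P2O7"
    rel_intensity_threshold: float = 0.15  # fraction of the base peak
    rank_cutoff: int = 3
    charge_range: tuple[int, int] = (2, 4)
    peak_tol: float = 0.02  # Da
    isolation_window: float = 1.6  # m/z
    exclude_isolation_window_from_rank: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.rel_intensity_threshold <= 1:
            raise ValueError("rel_intensity_threshold must be in (0, 1]")
        if self.rank_cutoff < 1:
            raise ValueError("rank_cutoff must be >= 1")


@dataclass(frozen=True)
class NeutralLossObservation:
    label: str
    target_mz: float
    observed: bool
    peak_mz: float | None = None
    rel_intensity: float | None = None  # fraction of base peak
    rank: int | None = None


@dataclass(frozen=True)
class NeutralLossReport:
    precursor_charge: int
    losses: dict[str, NeutralLossObservation] = field(default_factory=dict)


def detect_neutral_losses(cid: SpectrumRecord, cfg: TriggerConfig | None = None) -> NeutralLossReport:
    """Locate the precursor neutral-loss peaks in a CID spectrum.

    For each loss species L the peak nearest to ``precursor_mz - mass(L)/z``
    within the tolerance is recorded with its intensity relative to the base
    peak and its intensity rank within the spectrum (equal intensities share
    the best rank). The loss is searched at the precursor's own charge.
    """
    cfg = cfg or TriggerConfig()
    if cid.activation != "CID":
        raise ValueError(f"neutral-loss detection requires a CID scan, got {cid.activation}")
    z = cid.precursor_charge
    if z < 1:
        raise ValueError("precursor charge unknown; trigger undefined")
    peaks = list(cid.peaks)
    if cfg.exclude_isolation_window_from_rank:
        half = cfg.isolation_window / 2
        rank_peaks = [p for p in peaks if abs(p[0] - cid.precursor_mz) > half]
    else:
        rank_peaks = peaks
    base = cid.base_peak_intensity
    report: dict[str, NeutralLossObservation] = {}
    for label in cfg.losses:
        species = NEUTRAL_LOSSES[label]
        target = cid.precursor_mz - species.mass / z
        best = None
        for m, i in peaks:
            err = abs(m - target)
            if err <= cfg.peak_tol and (best is None or (err, -i) < (best[0], -best[1][1])):
                best = (err, (m, i))
        if best is None or base == 0:
            report[label] = NeutralLossObservation(label, target, observed=False)
        else:
            m, i = best[1]
            rank = 1 + sum(1 for _m, other in rank_peaks if other > i)
            report[label] = NeutralLossObservation(
                label, target, observed=True, peak_mz=m, rel_intensity=i / base, rank=rank
            )
    return NeutralLossReport(precursor_charge=z, losses=report)


def should_trigger(report: NeutralLossReport, cfg: TriggerConfig | None = None) -> bool:
    """True iff the acquisition would take an EThcD scan of this precursor.

    Requires the H4P2O7 loss observed at >= the relative-intensity threshold
    and a precursor charge inside the configured range.
    """
    cfg = cfg or TriggerConfig()
    lo, hi = cfg.charge_range
    if not lo <= report.precursor_charge <= hi:
        return False
    obs = report.losses.get(cfg.trigger_loss)
    return bool(obs and obs.observed and obs.rel_intensity >= cfg.rel_intensity_threshold)


def step1_rank_filter(report: NeutralLossReport, cfg: TriggerConfig | None = None) -> bool:
    """Assessment step 1: the -178 loss must rank in the top ``rank_cutoff`` peaks."""
    cfg = cfg or TriggerConfig()
    obs = report.losses.get(cfg.trigger_loss)
    if not obs or not obs.observed:
        return False
    return obs.rank <= cfg.rank_cutoff
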