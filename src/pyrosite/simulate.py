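"""Synthetic paired CID/EThcD spectra with labeled ground truth.

The generator emulates the acquisition the validator was designed for:

* CID scans carry the diagnostic precursor neutral-loss channels.
  Pyrophosphopeptides lose H3PO4 (-98), H4P2O7 (-178) and H6P2O8 (-196);
  mono- and bisphosphopeptides can produce only the -98 and -196 channels,
  so a pure bisphosphopeptide CID scan never contains a -178 peak. The
  -178 channel of a pyrophosphopeptide is placed among the top three peaks,
  reflecting its consistently high rank in synthetic standards.
* EThcD scans contain a configurable fraction of the theoretical c/z ions
  (plus b/y if requested) with seeded log-uniform intensities, optional
  residual-precursor artifacts and optional uniform noise peaks that avoid
  the immediate neighborhood of any theoretical fragment.
* ``simulate_mixture`` reproduces the co-fragmentation hazard: two
  bisphosphopeptide isomers sharing one phospho site jointly supply every
  couplet ion needed to misassign a pyrophospho site to the shared residue.
  Because the hazard only matters for spectra the acquisition actually
  triggered, the mixture CID scan includes a -178 interference channel
  scaled by the degree of mixing (it vanishes for a degenerate 1:0
  mixture, which is then byte-identical to the pure component pair).

Intensities are arbitrary units; only relative ranks matter downstream.
All randomness flows through a single ``numpy`` Generator, so a fixed seed
gives byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fragments import theoretical_ions
from .masschem import NEUTRAL_LOSSES, ModifiedPeptide, mz, peptide_neutral_mass
from .spectra_io import SpectrumRecord

__all__ = [
    "SimConfig",
    "GroundTruthLabel",
    "simulate_pair",
    "simulate_mixture",
    "make_standard_fixtures",
    "random_pyro_peptide",
    "random_bis_peptide",
    "random_mixture_isomers",
    "label_blind_benchmark",
]

#: Relative intensity (fraction of the CID base peak) of each neutral-loss
#: channel per ground-truth class.
CID_NL_PROFILES: dict[str, dict[str, float]] = {
    "PYRO": {"H3PO4": 0.8, "H4P2O7": 1.0, "H6P2O8": 0.7},
    "MONO": {"H3PO4": 1.0, "H6P2O8": 0.6},
    "BIS": {"H3PO4": 1.0, "H6P2O8": 0.6},
}
#: -178 interference intensity of a 1:1 bisphosphopeptide mixture (scaled
#: down linearly as the mixture becomes uneven).
MIXTURE_TRIGGER_REL = 0.5


@dataclass(frozen=True)
class SimConfig:
    series: tuple[str, ...] = ("c", "z")
    fragment_charges: tuple[int, ...] = (1, 2)
    coverage: float = 1.0  # fraction of theoretical ions emitted
    precursor_charge: int = 2
    noise_peaks: int = 0
    noise_mz_range: tuple[float, float] = (150.0, 1800.0)
    noise_exclusion: float = 0.05  # Da guard band around theoretical ions
    cid_base_intensity: float = 1.0e4
    cid_backbone_rel: tuple[float, float] = (0.05, 0.35)  # below the NL channels
    ethcd_intensity_log10: tuple[float, float] = (3.0, 5.0)
    noise_intensity_log10: tuple[float, float] = (2.0, 3.3)
    add_precursor_artifacts: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.coverage <= 1.0:
            raise ValueError("coverage must be in [0, 1]")


@dataclass(frozen=True)
class GroundTruthLabel:
    cls: str  # PYRO, MONO, BIS or MIXTURE
    sites: tuple[int, ...]
    components: tuple[str, ...]  # form keys of the contributing peptides


def _classify_form(p: ModifiedPeptide) -> tuple[str, tuple[int, ...]]:
    pyro = p.pyro_sites
    phos = tuple(sorted(pos for pos, n in p.mods if n == "phospho"))
    if len(pyro) == 1 and not phos:
        return "PYRO", pyro
    if len(phos) == 2 and not pyro:
        return "BIS", phos
    if len(phos) == 1 and not pyro:
        return "MONO", phos
    raise ValueError(f"unsupported ground-truth class for form {p.form_key}")


def _merge(peaks: list[tuple[float, float]]) -> tuple[tuple[float, float], ...]:
    """Sum intensities of coincident peaks, drop non-positive ones."""
    merged: dict[float, float] = {}
    for m, i in peaks:
        if i > 0:
            key = round(m, 9)
            merged[key] = merged.get(key, 0.0) + i
    return tuple(sorted(merged.items()))


def _cid_spectrum(
    p: ModifiedPeptide,
    profile: dict[str, float],
    cfg: SimConfig,
    rng: np.random.Generator,
    scan_id: str,
    extra: dict,
) -> SpectrumRecord:
    z = cfg.precursor_charge
    pmz = mz(peptide_neutral_mass(p), z)
    nl_targets = {lab: pmz - sp.mass / z for lab, sp in NEUTRAL_LOSSES.items()}
    peaks: list[tuple[float, float]] = []
    base = cfg.cid_base_intensity
    for lab, rel in profile.items():
        if rel > 0:
            peaks.append((nl_targets[lab], rel * base))
    # low-lying b/y backbone signal so intensity ranks are meaningful;
    # kept clear of every NL channel so absent channels stay truly absent
    lo, hi = cfg.cid_backbone_rel
    for ion in theoretical_ions(p, ("b", "y"), max_charge=1):
        if any(abs(ion.mz - t) < cfg.noise_exclusion for t in nl_targets.values()):
            continue
        peaks.append((ion.mz, float(rng.uniform(lo, hi)) * base))
    peaks.append((pmz, 0.3 * base))  # residual precursor
    return SpectrumRecord(scan_id, pmz, z, "CID", _merge(peaks), extra=extra)


def _ethcd_fragment_peaks(
    p: ModifiedPeptide, cfg: SimConfig, rng: np.random.Generator
) -> list[tuple[float, float]]:
    ions = theoretical_ions(p, cfg.series, max(cfg.fragment_charges))
    ions = [ion for ion in ions if ion.charge in cfg.fragment_charges]
    n_keep = int(round(cfg.coverage * len(ions)))
    idx = rng.choice(len(ions), size=n_keep, replace=False) if n_keep else []
    lo, hi = cfg.ethcd_intensity_log10
    return [
        (ions[i].mz, float(10 ** rng.uniform(lo, hi))) for i in sorted(np.asarray(idx))
    ]


def _ethcd_extras(
    p: ModifiedPeptide, cfg: SimConfig, rng: np.random.Generator
) -> list[tuple[float, float]]:
    """Residual-precursor artifacts and noise peaks for an EThcD scan."""
    z = cfg.precursor_charge
    mass = peptide_neutral_mass(p)
    pmz = mz(mass, z)
    peaks: list[tuple[float, float]] = []
    if cfg.add_precursor_artifacts:
        peaks.append((pmz, 5.0e4))
        mh = pmz * z
        for r in range(z - 1, 0, -1):
            peaks.append((mh / r, 3.0e4))
    if cfg.noise_peaks:
        exclusion = [ion.mz for ion in theoretical_ions(p, cfg.series, max(cfg.fragment_charges))]
        # avoid fabricating single-phosphate counter-evidence as well
        guard = sorted(exclusion)
        lo, hi = cfg.noise_mz_range
        ilo, ihi = cfg.noise_intensity_log10
        placed = 0
        while placed < cfg.noise_peaks:
            m = float(rng.uniform(lo, hi))
            if all(abs(m - g) > cfg.noise_exclusion for g in guard):
                peaks.append((m, float(10 ** rng.uniform(ilo, ihi))))
                placed += 1
    return peaks


def simulate_pair(
    p: ModifiedPeptide,
    cfg: SimConfig | None = None,
    rng: np.random.Generator | int | None = None,
    scan_prefix: str | None = None,
) -> tuple[SpectrumRecord, SpectrumRecord, GroundTruthLabel]:
    """Paired CID/EThcD spectra of a single modified peptide.

    The class (PYRO/MONO/BIS) is inferred from the modifications and selects
    the CID neutral-loss profile. Deterministic for a fixed seed.
    """
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(rng)
    cls, sites = _classify_form(p)
    label = GroundTruthLabel(cls, sites, (p.form_key,))
    prefix = scan_prefix or p.form_key
    extra = {
        "label": cls,
        "truesites": ",".join(map(str, sites)),
        "components": p.form_key,
    }
    cid = _cid_spectrum(p, CID_NL_PROFILES[cls], cfg, rng, f"{prefix}|CID", extra)
    frag = _ethcd_fragment_peaks(p, cfg, rng)
    ext = _ethcd_extras(p, cfg, rng)
    ethcd = SpectrumRecord(
        f"{prefix}|EThcD",
        cid.precursor_mz,
        cfg.precursor_charge,
        "EThcD",
        _merge(frag + ext),
        triggered_by=cid.scan_id,
        extra=extra,
    )
    return cid, ethcd, label


def simulate_mixture(
    pA: ModifiedPeptide,
    pB: ModifiedPeptide,
    ratio: float = 0.5,
    cfg: SimConfig | None = None,
    rng: np.random.Generator | int | None = None,
    scan_prefix: str | None = None,
) -> tuple[SpectrumRecord, SpectrumRecord, GroundTruthLabel]:
    """Co-fragmented pair of bisphosphopeptide isomers sharing the backbone.

    ``ratio`` is the fraction contributed by ``pA``. The EThcD peaks are the
    intensity-scaled union of both components' fragments; the CID scan is
    the scaled union of the components' (-98/-196) channels plus a -178
    interference peak proportional to the degree of mixing.
    """
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(rng)
    if pA.sequence != pB.sequence:
        raise ValueError("mixture components must share the same backbone sequence")
    if not 0.0 <= ratio <= 1.0:
        raise ValueError("ratio must be in [0, 1]")
    clsA, sitesA = _classify_form(pA)
    clsB, sitesB = _classify_form(pB)
    if clsA != "BIS" or clsB != "BIS":
        raise ValueError("mixture components must both be bisphosphopeptides")
    shared = tuple(sorted(set(sitesA) & set(sitesB)))
    label = GroundTruthLabel("MIXTURE", shared, (pA.form_key, pB.form_key))
    prefix = scan_prefix or f"MIX[{pA.form_key}+{pB.form_key}]"
    extra = {
        "label": "MIXTURE",
        "truesites": ",".join(map(str, shared)),
        "components": f"{pA.form_key}+{pB.form_key}",
    }

    z = cfg.precursor_charge
    pmz = mz(peptide_neutral_mass(pA), z)  # isomers: identical mass
    # component A is drawn in exactly the order simulate_pair uses, so a
    # degenerate 1:0 mixture reproduces the pure-component pair bit for bit
    cidA = _cid_spectrum(pA, CID_NL_PROFILES["BIS"], cfg, rng, "a", extra)
    fragA = [(m, ratio * i) for m, i in _ethcd_fragment_peaks(pA, cfg, rng)]
    ext = _ethcd_extras(pA, cfg, rng)
    cidB = _cid_spectrum(pB, CID_NL_PROFILES["BIS"], cfg, rng, "b", extra)
    fragB = [(m, (1.0 - ratio) * i) for m, i in _ethcd_fragment_peaks(pB, cfg, rng)]

    cid_peaks = [(m, ratio * i) for m, i in cidA.peaks]
    cid_peaks += [(m, (1.0 - ratio) * i) for m, i in cidB.peaks]
    trigger_rel = MIXTURE_TRIGGER_REL * 2.0 * min(ratio, 1.0 - ratio)
    if trigger_rel > 0:
        target = pmz - NEUTRAL_LOSSES["H4P2O7"].mass / z
        cid_peaks.append((target, trigger_rel * cfg.cid_base_intensity))
    cid = SpectrumRecord(f"{prefix}|CID", pmz, z, "CID", _merge(cid_peaks), extra=extra)
    ethcd = SpectrumRecord(
        f"{prefix}|EThcD",
        pmz,
        z,
        "EThcD",
        _merge(fragA + fragB + ext),
        triggered_by=cid.scan_id,
        extra=extra,
    )
    return cid, ethcd, label


#: The five synthetic pyrophosphopeptide standards, written with the
#: modified residue spelled out (e.g. "LD-ppS-EEDSAWPTNEK" = pyrophospho-Ser
#: at position 3 of LDSEEDSAWPTNEK).
STANDARD_SEQUENCES: dict[str, str] = {
    "ppT-1": "DAVTY-ppT-EHAK",
    "ppS-2": "SQYHVDG-ppS-LEK",
    "ppS-3": "LD-ppS-EEDSAWPTNEK",
    "ppS-4": "NEEDEGH-ppS-NSSPR",
    "ppS-5": "AQWTQE-ppS-FQSNNTR",
}


def make_standard_fixtures() -> dict[str, ModifiedPeptide]:
    """The five standard pyrophosphopeptides as modified-peptide objects."""
    out: dict[str, ModifiedPeptide] = {}
    for name, spec_str in STANDARD_SEQUENCES.items():
        sequence = ""
        site = None
        for segment in spec_str.split("-"):
            if segment.startswith("pp"):
                site = len(sequence) + 1
                sequence += segment[2:]
            else:
                sequence += segment
        assert site is not None
        pep = ModifiedPeptide(sequence, frozenset({(site, "pyrophospho")}))
        pep.validate()
        out[name] = pep
    return out


_FILLER = "ADEFGHILNQVW"  # no S/T (sites are placed explicitly), no C/M/K/R/P


def _random_backbone(rng: np.random.Generator, length: int) -> list[str]:
    body = [str(_FILLER[i]) for i in rng.integers(0, len(_FILLER), size=length - 1)]
    body.append("K" if rng.random() < 0.5 else "R")
    return body


def random_pyro_peptide(rng: np.random.Generator) -> ModifiedPeptide:
    """A tryptic-like peptide with one interior pyrophospho-Ser/Thr site."""
    L = int(rng.integers(9, 15))
    site = int(rng.integers(3, L - 1))
    body = _random_backbone(rng, L)
    body[site - 1] = "S" if rng.random() < 0.8 else "T"
    return ModifiedPeptide("".join(body), frozenset({(site, "pyrophospho")}))


def random_bis_peptide(rng: np.random.Generator) -> ModifiedPeptide:
    """A peptide monophosphorylated at two distinct Ser positions."""
    L = int(rng.integers(10, 15))
    i = int(rng.integers(2, L - 4))
    j = int(rng.integers(i + 2, L - 1))
    body = _random_backbone(rng, L)
    body[i - 1] = "S"
    body[j - 1] = "S"
    return ModifiedPeptide(
        "".join(body), frozenset({(i, "phospho"), (j, "phospho")})
    )


def _distinguishable_from_pyro(
    components: tuple[ModifiedPeptide, ...],
    site: int,
    tol: float = 0.025,
    min_unambiguous: int = 2,
) -> bool:
    """Whether single-phosphate fragments can betray a bisphospho origin.

    A component set is fragment-mass distinguishable if at least
    ``min_unambiguous`` of the single-phosphate c/z ions its members produce
    lie further than ``tol`` from every ion of the pyrophospho hypothesis at
    ``site``. Rare backbones violate this -- chance isobars between a
    prefix+HPO3 and a suffix fragment can propagate through a whole series
    -- and for those no fragment-mass protocol can separate the isobaric
    explanations, so the benchmark sampler rejects them as ill-posed.
    """
    seq = components[0].sequence
    cand = ModifiedPeptide(seq, frozenset({(site, "pyrophospho")}))
    pyro_mzs = sorted(
        ion.mz for ion in theoretical_ions(cand, ("c", "z", "z+1", "z-1", "b", "y"), 2)
    )

    def coincident(v: float) -> bool:
        from bisect import bisect_left

        i = bisect_left(pyro_mzs, v)
        return any(
            0 <= j < len(pyro_mzs) and abs(pyro_mzs[j] - v) <= tol for j in (i - 1, i)
        )

    n_clear = 0
    for form in components:
        for ion in theoretical_ions(form, ("c", "z"), 2):
            if ion.phospho_count == 1 and not coincident(ion.mz):
                n_clear += 1
                if n_clear >= min_unambiguous:
                    return True
    return False


def random_mixture_isomers(
    rng: np.random.Generator,
) -> tuple[ModifiedPeptide, ModifiedPeptide, int]:
    """Two bisphospho isomers pS(k-2)+pS(k) and pS(k)+pS(k+3) on one backbone.

    Their co-fragmentation supplies all couplet ions for a bogus pyrophospho
    assignment at the shared central site ``k``. Backbones whose
    single-phosphate fragments are all mass-coincident with pyrophospho
    hypothesis ions are resampled (see ``_distinguishable_from_pyro``).
    """
    while True:
        L = int(rng.integers(12, 16))
        k = int(rng.integers(4, L - 3))
        body = _random_backbone(rng, L)
        for pos in (k - 2, k, k + 3):
            body[pos - 1] = "S"
        seq = "".join(body)
        pA = ModifiedPeptide(seq, frozenset({(k - 2, "phospho"), (k, "phospho")}))
        pB = ModifiedPeptide(seq, frozenset({(k, "phospho"), (k + 3, "phospho")}))
        if _distinguishable_from_pyro((pA, pB), k):
            return pA, pB, k


def label_blind_benchmark(
    n_per_class: int = 50,
    seed: int = 0,
    cfg: SimConfig | None = None,
    validator_cfg=None,
):
    """Simulate a labeled batch and run the full protocol on every pair.

    Returns a DataFrame with one row per spectrum pair: ground-truth label,
    candidate form, putative site and the validator's verdict. The candidate
    offered to the validator is always the pyrophospho hypothesis -- the
    true form for PYRO pairs, the misassignment hypothesis for BIS (pyro at
    the first phosphosite) and MIXTURE (pyro at the shared site) pairs.
    """
    import pandas as pd

    from .validator import ValidatorConfig, classify

    cfg = cfg or SimConfig()
    validator_cfg = validator_cfg or ValidatorConfig()
    rng = np.random.default_rng(seed)
    rows = []
    for n in range(n_per_class):
        p = random_pyro_peptide(rng)
        cid, ethcd, label = simulate_pair(p, cfg, rng, scan_prefix=f"PYRO{n}")
        v = classify(cid, ethcd, p, validator_cfg)
        rows.append(("PYRO", p.form_key, v.site, v.verdict))
    for n in range(n_per_class):
        p = random_bis_peptide(rng)
        cid, ethcd, label = simulate_pair(p, cfg, rng, scan_prefix=f"BIS{n}")
        site = min(pos for pos, _ in p.mods)
        cand = ModifiedPeptide(p.sequence, frozenset({(site, "pyrophospho")}))
        v = classify(cid, ethcd, cand, validator_cfg)
        rows.append(("BIS", cand.form_key, v.site, v.verdict))
    for n in range(n_per_class):
        pA, pB, k = random_mixture_isomers(rng)
        cid, ethcd, label = simulate_mixture(pA, pB, 0.5, cfg, rng, scan_prefix=f"MIX{n}")
        cand = ModifiedPeptide(pA.sequence, frozenset({(k, "pyrophospho")}))
        v = classify(cid, ethcd, cand, validator_cfg)
        rows.append(("MIXTURE", cand.form_key, v.site, v.verdict))
    return pd.DataFrame(rows, columns=["label", "candidate", "site", "verdict"])
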