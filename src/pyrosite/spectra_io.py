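"""Reading and writing paired CID/EThcD peak lists and validation reports.

MGF is the primary interchange format (read and written through pyteomics);
mzML is supported read-only for converted vendor data. After loading, every
spectrum's peaks are sorted ascending by m/z and an EThcD scan is linked to
the CID scan that triggered it: the nearest preceding CID scan whose
precursor m/z agrees within 5 ppm, matching an acquisition scheme in which
the EThcD spectrum of the same precursor is taken immediately after the
triggering CID scan.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

from pyteomics import mgf as _mgf

logger = logging.getLogger(__name__)

__all__ = ["SpectrumRecord", "read_mgf", "read_mzml", "write_mgf", "write_results", "pair_scans"]

PAIRING_TOL_PPM = 5.0


@dataclass(frozen=True)
class SpectrumRecord:
    """One MS2 peak list with precursor and activation metadata."""

    scan_id: str
    precursor_mz: float
    precursor_charge: int
    activation: str  # "CID", "EThcD" or "other"
    peaks: tuple[tuple[float, float], ...]
    triggered_by: str | None = None  # scan id of the CID scan that triggered this one
    extra: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "peaks", tuple(sorted(self.peaks)))
        if not 1 <= self.precursor_charge <= 8:
            raise ValueError(
                f"precursor charge {self.precursor_charge} outside 1..8 for scan {self.scan_id}"
            )
        if any(i < 0 for _m, i in self.peaks):
            raise ValueError(f"negative intensity in scan {self.scan_id}")

    @property
    def base_peak_intensity(self) -> float:
        return max((i for _m, i in self.peaks), default=0.0)


def _parse_activation(text: str) -> str:
    text = text.upper()
    if "ETHCD" in text or "ETD" in text:
        return "EThcD"
    if "CID" in text or "COLLISION" in text:
        return "CID"
    return "other"


def pair_scans(records: list[SpectrumRecord]) -> list[SpectrumRecord]:
    """Link each EThcD scan to its triggering CID scan.

    The trigger is the nearest preceding CID record whose precursor m/z
    matches within 5 ppm; records are assumed to be in acquisition order.
    """
    out: list[SpectrumRecord] = []
    for i, rec in enumerate(records):
        link = None
        if rec.activation == "EThcD":
            for prev in reversed(records[:i]):
                if (
                    prev.activation == "CID"
                    and abs(prev.precursor_mz - rec.precursor_mz)
                    / rec.precursor_mz
                    * 1e6
                    <= PAIRING_TOL_PPM
                ):
                    link = prev.scan_id
                    break
        out.append(replace(rec, triggered_by=link) if link else rec)
    return out


def read_mgf(path: str | Path) -> list[SpectrumRecord]:
    """Read an MGF file into spectrum records with CID/EThcD pairing applied.

    Activation is taken from an ``ACTIVATION`` block key or an
    ``ACTIVATION=...`` token inside the TITLE, defaulting to ``other``. A
    block missing PEPMASS or CHARGE raises, naming the block index.
    """
    records: list[SpectrumRecord] = []
    with _mgf.read(str(path), use_index=False, convert_arrays=1) as reader:
        for idx, block in enumerate(reader):
            params = block["params"]
            title = str(params.get("title", f"index={idx}"))
            if "pepmass" not in params:
                raise ValueError(f"MGF block {idx} ({title!r}) is missing PEPMASS")
            if "charge" not in params:
                raise ValueError(f"MGF block {idx} ({title!r}) is missing CHARGE")
            activation = "other"
            if "activation" in params:
                activation = _parse_activation(str(params["activation"]))
            else:
                for token in title.replace(",", " ").split():
                    if token.upper().startswith("ACTIVATION="):
                        activation = _parse_activation(token.split("=", 1)[1])
            extra = {
                k: str(v)
                for k, v in params.items()
                if k not in ("pepmass", "charge", "title", "activation")
            }
            records.append(
                SpectrumRecord(
                    scan_id=title,
                    precursor_mz=float(params["pepmass"][0]),
                    precursor_charge=int(params["charge"][0]),
                    activation=activation,
                    peaks=tuple(
                        zip(block["m/z array"].tolist(), block["intensity array"].tolist())
                    ),
                    extra=extra,
                )
            )
    return pair_scans(records)


def _decode_binary_array(elem) -> list[float]:
    import base64
    import zlib

    import numpy as np

    ns = "{http://psi.hupo.org/ms/mzml}"
    accessions = {
        cv.get("accession"): cv.get("name", "")
        for cv in elem.findall(f"{ns}cvParam") + elem.findall("cvParam")
    }
    dtype = np.float32 if "MS:1000521" in accessions else np.float64
    binary = elem.find(f"{ns}binary")
    if binary is None:
        binary = elem.find("binary")
    raw = base64.b64decode(binary.text or "")
    if "MS:1000574" in accessions:  # zlib compression
        raw = zlib.decompress(raw)
    return np.frombuffer(raw, dtype=dtype).astype(float).tolist()


def read_mzml(path: str | Path) -> list[SpectrumRecord]:
    """Read MS2 spectra from an mzML file; same record contract as MGF.

    A minimal reader (lxml + base64) for the subset the pipeline needs:
    MS2 ``<spectrum>`` elements with a selected ion, a charge state and
    32/64-bit uncompressed or zlib-compressed peak arrays. Activation is
    mapped from the dissociation-method CV terms (electron transfer ->
    EThcD, collision-induced -> CID, otherwise "other"); spectra with
    missing precursor metadata are skipped with a logged warning.
    """
    from lxml import etree

    ns = "{http://psi.hupo.org/ms/mzml}"

    def findall(elem, tag):
        return elem.findall(f".//{ns}{tag}") or elem.findall(f".//{tag}")

    records: list[SpectrumRecord] = []
    tags = (f"{ns}spectrum", "spectrum")
    for _event, spec in etree.iterparse(str(path), events=("end",)):
        if spec.tag not in tags:
            continue
        sid = spec.get("id", "?")
        try:
            cv_names = {cv.get("name"): cv.get("value") for cv in findall(spec, "cvParam")}
            if cv_names.get("ms level") != "2":
                spec.clear()
                continue
            sel = findall(spec, "selectedIon")[0]
            sel_cv = {cv.get("name"): cv.get("value") for cv in findall(sel, "cvParam")}
            pmz = float(sel_cv["selected ion m/z"])
            z = int(sel_cv["charge state"])
            act_elem = findall(spec, "activation")
            activation = "other"
            if act_elem:
                act_names = " ".join(
                    cv.get("name", "") for cv in findall(act_elem[0], "cvParam")
                )
                if "electron transfer" in act_names:
                    activation = "EThcD"
                elif "collision-induced" in act_names or "CID" in act_names:
                    activation = "CID"
            arrays: dict[str, list[float]] = {}
            for bda in findall(spec, "binaryDataArray"):
                names = {cv.get("name") for cv in findall(bda, "cvParam")}
                values = _decode_binary_array(bda)
                if "m/z array" in names:
                    arrays["mz"] = values
                elif "intensity array" in names:
                    arrays["intensity"] = values
            records.append(
                SpectrumRecord(
                    scan_id=str(sid),
                    precursor_mz=pmz,
                    precursor_charge=z,
                    activation=activation,
                    peaks=tuple(zip(arrays["mz"], arrays["intensity"])),
                )
            )
        except (KeyError, IndexError, TypeError, ValueError) as exc:
            logger.warning("skipping mzML spectrum %s: missing metadata (%s)", sid, exc)
        spec.clear()
    return pair_scans(records)


def write_mgf(records: list[SpectrumRecord], path: str | Path) -> None:
    """Write spectrum records as MGF; m/z with 6 decimals (sub-ppm at m/z 1000)."""
    blocks = []
    for rec in records:
        params = {
            "title": rec.scan_id,
            "pepmass": rec.precursor_mz,
            "charge": rec.precursor_charge,
            "activation": rec.activation,
        }
        params.update(rec.extra)
        import numpy as np

        blocks.append(
            {
                "params": params,
                "m/z array": np.array([m for m, _i in rec.peaks]),
                "intensity array": np.array([i for _m, i in rec.peaks]),
            }
        )
    _mgf.write(
        blocks, str(path), fragment_format="%.6f %.6g", use_numpy=True, file_mode="w"
    )


def write_results(verdicts, path: str | Path) -> None:
    """Write validation verdicts as a TSV (one row per spectrum/candidate site)."""
    import pandas as pd

    rows = []
    for v in verdicts:
        site = v.site
        protein_site = (
            site + v.candidate.start - 1 if v.candidate.start is not None else ""
        )
        rows.append(
            {
                "scan_id": v.spectrum_id,
                "peptide": v.candidate.form_key,
                "site_in_peptide": site,
                "site_in_protein": protein_site,
                "protein_id": v.candidate.protein_id or "",
                "verdict": v.verdict,
                "nl_rank": v.nl_rank if v.nl_rank is not None else "",
                "couplets": ";".join(c.describe() for c in v.couplets),
                "counter_evidence": ";".join(
                    f"{m.ion.series}{m.ion.index}^{m.ion.charge}+@{m.peak_mz:.4f}"
                    for m in v.counter_evidence
                ),
            }
        )
    columns = [
        "scan_id",
        "peptide",
        "site_in_peptide",
        "site_in_protein",
        "protein_id",
        "verdict",
        "nl_rank",
        "couplets",
        "counter_evidence",
    ]
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False, encoding="utf-8")
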