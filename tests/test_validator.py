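"""Non-fragment stripping, counter-evidence, couplets and the verdict chain."""

import dataclasses

import numpy as np
import pytest

from pyrosite.fragments import theoretical_ions
from pyrosite.masschem import (
    MODIFICATIONS,
    ModifiedPeptide,
    mz,
    peptide_neutral_mass,
)
from pyrosite.simulate import (
    SimConfig,
    random_mixture_isomers,
    random_pyro_peptide,
    simulate_mixture,
    simulate_pair,
)
from pyrosite.spectra_io import SpectrumRecord
from pyrosite.validator import (
    ValidatorConfig,
    classify,
    find_monophospho_evidence,
    find_site_couplets,
    strip_nonfragment_peaks,
)

CFG = ValidatorConfig()


def ethcd(peptide, peaks, z=2, scan_id="e"):
    return SpectrumRecord(
        scan_id, mz(peptide_neutral_mass(peptide), z), z, "EThcD", tuple(peaks)
    )


class TestStripNonfragmentPeaks:
    PEP = ModifiedPeptide("LDSEEDSAWPTNEK", frozenset({(3, "pyrophospho")}))

    def test_lone_precursor_peak_removed(self):
        spec = ethcd(self.PEP, [(mz(peptide_neutral_mass(self.PEP), 2), 1e4)])
        assert strip_nonfragment_peaks(spec, CFG).peaks == ()

    def test_peak_outside_reduced_window_retained(self):
        pmz = mz(peptide_neutral_mass(self.PEP), 2)
        reduced = pmz * 2  # [M+2H]+ after one electron transfer
        spec = ethcd(self.PEP, [(reduced + 0.7, 5e3)])
        assert strip_nonfragment_peaks(spec, CFG).peaks == ((reduced + 0.7, 5e3),)

    def test_charge_reduced_precursor_removed(self):
        pmz = mz(peptide_neutral_mass(self.PEP), 2)
        spec = ethcd(self.PEP, [(pmz * 2 + 0.3, 5e3)])
        assert strip_nonfragment_peaks(spec, CFG).peaks == ()

    def test_injected_artifacts_strip_back_to_clean_simulation(self, standards):
        pep = standards["ppS-4"]
        with_art = SimConfig(add_precursor_artifacts=True)
        without = SimConfig(add_precursor_artifacts=False)
        _c1, dirty, _l1 = simulate_pair(pep, with_art, rng=21)
        _c2, clean, _l2 = simulate_pair(pep, without, rng=21)
        assert strip_nonfragment_peaks(dirty, CFG).peaks == strip_nonfragment_peaks(
            clean, CFG
        ).peaks

    def test_requires_ethcd(self):
        spec = SpectrumRecord("c", 600.0, 2, "CID", ((100.0, 1.0),))
        with pytest.raises(ValueError):
            strip_nonfragment_peaks(spec, CFG)


class TestMonophosphoEvidence:
    def test_hand_built_single_phosphate_ion_is_returned(self):
        cand = ModifiedPeptide("AGSGGLK", frozenset({(3, "pyrophospho")}))
        mono = ModifiedPeptide("AGSGGLK", frozenset({(3, "phospho")}))
        c3_1p = next(
            i
            for i in theoretical_ions(mono, ("c",), 1)
            if i.index == 3 and i.phospho_count == 1
        )
        spec = ethcd(cand, [(c3_1p.mz, 1e3)])
        found = find_monophospho_evidence(spec, cand, CFG)
        assert found and all(m.ion.phospho_count == 1 for m in found)

    def test_noise_free_pyro_yields_none(self, standards):
        cfg = SimConfig(add_precursor_artifacts=False)
        for i, pep in enumerate(standards.values()):
            _cid, spec, _lab = simulate_pair(pep, cfg, rng=i)
            assert find_monophospho_evidence(spec, pep, CFG) == []

    def test_overlapping_bisphospho_union_is_caught(self):
        rng = np.random.default_rng(5)
        pA, pB, k = random_mixture_isomers(rng)
        _cid, spec, _lab = simulate_mixture(pA, pB, 0.5, SimConfig(), rng)
        cand = ModifiedPeptide(pA.sequence, frozenset({(k, "pyrophospho")}))
        stripped = strip_nonfragment_peaks(spec, CFG)
        assert find_monophospho_evidence(stripped, cand, CFG)


class TestSiteCouplets:
    def test_pps3_couplets_at_both_termini(self, standards):
        pep = standards["ppS-3"]  # site 3 of a 14-mer
        _cid, spec, _lab = simulate_pair(pep, SimConfig(), rng=9)
        couplets = find_site_couplets(
            strip_nonfragment_peaks(spec, CFG), pep, 3, CFG
        )
        described = {c.describe() for c in couplets}
        assert "N:c2/c3" in described
        assert "C:z11/z12" in described

    def test_missing_lower_ion_breaks_n_couplet(self, standards):
        pep = standards["ppS-3"]
        _cid, spec, _lab = simulate_pair(
            pep, SimConfig(add_precursor_artifacts=False), rng=9
        )
        c2 = {
            i.mz
            for i in theoretical_ions(pep, ("c",), 2)
            if i.index == 2
        }
        pruned = dataclasses.replace(
            spec,
            peaks=tuple(
                (m, i)
                for m, i in spec.peaks
                if all(abs(m - v) > 0.001 for v in c2)
            ),
        )
        couplets = find_site_couplets(pruned, pep, 3, CFG)
        assert all(c.side != "N" or c.series != "c" for c in couplets)

    def test_site_at_position_one_cannot_be_bridged(self):
        """A terminal site has no defined N-side couplet, and its C-side
        upper ion would be the intact peptide (index L), which is not a
        backbone fragment -- reported as absence, not an exception."""
        pep = ModifiedPeptide("SAGAGLK", frozenset({(1, "pyrophospho")}))
        cid, spec, _lab = simulate_pair(pep, SimConfig(), rng=2)
        couplets = find_site_couplets(strip_nonfragment_peaks(spec, CFG), pep, 1, CFG)
        assert couplets == []
        assert classify(cid, spec, pep, CFG).verdict == "INSUFFICIENT_COVERAGE"


class TestClassify:
    def test_full_coverage_pyro_confirmed(self, standards):
        for i, pep in enumerate(standards.values()):
            cid, eth, _lab = simulate_pair(pep, SimConfig(), rng=i)
            assert classify(cid, eth, pep, CFG).verdict == "CONFIRMED"

    def test_zero_noise_mixture_is_bisphospho_evidence(self):
        rng = np.random.default_rng(17)
        for _ in range(5):
            pA, pB, k = random_mixture_isomers(rng)
            cid, eth, _lab = simulate_mixture(pA, pB, 0.5, SimConfig(), rng)
            cand = ModifiedPeptide(pA.sequence, frozenset({(k, "pyrophospho")}))
            assert classify(cid, eth, cand, CFG).verdict == "BISPHOSPHO_EVIDENCE"

    def test_deleting_site_fragments_gives_insufficient_coverage(self, standards):
        pep = standards["ppS-3"]
        cid, eth, _lab = simulate_pair(pep, SimConfig(), rng=4)
        site = 3
        L = len(pep.sequence)
        kill = {
            i.mz
            for i in theoretical_ions(pep, CFG.series, CFG.max_fragment_charge)
            if (i.series in ("b", "c") and i.index in (site - 1, site))
            or (i.series in ("y", "z", "z+1", "z-1") and i.index in (L - site, L - site + 1))
        }
        pruned = dataclasses.replace(
            eth,
            peaks=tuple(
                (m, inten)
                for m, inten in eth.peaks
                if all(abs(m - v) > 0.001 for v in kill)
            ),
        )
        assert classify(cid, pruned, pep, CFG).verdict == "INSUFFICIENT_COVERAGE"

    def test_candidate_with_two_pyro_sites_rejected(self, standards):
        pep = standards["ppS-3"]
        cid, eth, _lab = simulate_pair(pep, SimConfig(), rng=4)
        double = ModifiedPeptide(
            pep.sequence, pep.mods | {(7, "pyrophospho")}
        )
        with pytest.raises(ValueError):
            classify(cid, eth, double, CFG)

    def test_deletions_never_fabricate_bisphospho_evidence(self, standards):
        """Removing peaks from a CONFIRMED pyrophospho spectrum can only lose
        evidence -- it never manufactures single-phosphate counter-evidence."""
        pep = standards["ppS-2"]
        cid, eth, _lab = simulate_pair(pep, SimConfig(), rng=6)
        assert classify(cid, eth, pep, CFG).verdict == "CONFIRMED"
        rng = np.random.default_rng(13)
        for _ in range(20):
            keep = rng.random(len(eth.peaks)) > 0.4
            pruned = dataclasses.replace(
                eth, peaks=tuple(p for p, k in zip(eth.peaks, keep) if k)
            )
            verdict = classify(cid, pruned, pep, CFG).verdict
            assert verdict in ("CONFIRMED", "INSUFFICIENT_COVERAGE")

    def test_both_sides_policy_is_stricter(self):
        """Every spectrum CONFIRMED under BOTH_SIDES is CONFIRMED under ONE_SIDE."""
        strict = dataclasses.replace(CFG, couplet_policy="BOTH_SIDES")
        rng = np.random.default_rng(8)
        n_strict = n_lenient = 0
        for _ in range(15):
            p = random_pyro_peptide(rng)
            cid, eth, _lab = simulate_pair(p, SimConfig(coverage=0.6), rng)
            lenient_ok = classify(cid, eth, p, CFG).verdict == "CONFIRMED"
            strict_ok = classify(cid, eth, p, strict).verdict == "CONFIRMED"
            n_lenient += lenient_ok
            n_strict += strict_ok
            if strict_ok:
                assert lenient_ok
        assert n_strict <= n_lenient
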