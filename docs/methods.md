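# Methods

## The assignment problem

Protein pyrophosphorylation places a diphosphate group (two phosphates in an
acid anhydride linkage) on a single Ser/Thr side chain. A tryptic
pyrophosphopeptide is *exactly* isobaric with every bisphosphopeptide of the
same backbone — a peptide carrying two monophosphates on two different
residues — so the molecular ion is uninformative and the default assumption
must be bisphosphorylation. Assignment therefore rests on fragmentation
evidence from a paired acquisition:

* **CID survey scan.** Collisional activation of a pyrophosphopeptide
  precursor releases pyrophosphoric acid, H4P2O7, a neutral loss of
  177.9432 Da (nominal −178 m/z at charge-preserved loss). Mono- and
  bisphosphopeptides can only lose H3PO4 (−98) and, twice over, H6P2O8
  (−196); the −178 channel is unique to the intact diphosphate.
* **EThcD scan.** Electron-transfer dissociation (with HCD supplemental
  activation) produces c/z ions that retain the labile modification, so the
  phosphate content of each backbone fragment can be read off its mass.

## The three-step verdict chain

`pyrosite.validator.classify` assesses one candidate (a peptide with a
single putative pyrophospho site k) against a CID/EThcD pair, with strict
verdict precedence:

1. **Trigger** (`NOT_TRIGGERED`): the CID scan must show the −178 loss at
   the precursor's own charge, at ≥ 15% of the base-peak intensity, with
   precursor charge 2–4.
2. **Rank filter** (`STEP1_FAIL`): the −178 peak must be among the three
   most intense CID peaks. In pyrophosphopeptide standards it consistently
   is; co-fragmenting bisphosphopeptides inflate the −98/−196 channels and
   push −178 down the ranking.
3. **Counter-evidence** (`BISPHOSPHO_EVIDENCE`): after stripping
   non-fragment signals, the EThcD spectrum is matched against the union of
   the pyrophospho hypothesis and every single-phospho placement on the
   same backbone. Any matched fragment explainable *only* with exactly one
   phosphate group discards the spectrum — such a fragment exists only if
   bisphosphorylated species contribute. A single-phosphate fragment whose
   m/z is within tolerance of some 0- or 2-phosphate ion of the pyro
   hypothesis is ambiguous and, conservatively, not held against the
   candidate.
4. **Couplets** (`INSUFFICIENT_COVERAGE` / `CONFIRMED`): the site must be
   bridged by a couplet of sequential ions — index k−1 with zero phosphates
   and index k carrying both (b/c series from the N terminus, or the
   mirrored indices L−k, L−k+1 in y/z from the C terminus). Detected
   simultaneously, they place the diphosphate on residue k. Spectra with
   the key fragments missing are discarded.

The couplet step alone cannot reject co-fragmentation: two bisphosphopeptide
isomers with overlapping phosphorylation pairs — pS(k−2)+pS(k) mixed with
pS(k)+pS(k+3) — jointly supply every couplet ion for a bogus assignment at
the shared residue k. Step 3 exists to catch exactly this hazard: the
mixture's single-phosphate fragments (e.g. c ions spanning only one of the
two sites of one isomer) betray it.

## Parameters and defaults

| parameter | default | unit | note |
|---|---|---|---|
| trigger loss | H4P2O7 | — | 177.9432 Da from the element table |
| relative-intensity threshold | 0.15 | fraction of base peak | trigger gate |
| rank cutoff | 3 | — | step-1 filter |
| precursor charge range | 2–4 | — | low charge gives poor ETD |
| isolation window | 1.6 | m/z | rank-exclusion switch only |
| precursor mass range | 350–5,000 | Da | candidate filter |
| precursor tolerance | 10 | ppm | candidate matching |
| fragment tolerance | 0.02 | Da | peak matching everywhere |
| digestion | trypsin, ≤2 missed | — | cleave after K/R, not before P |
| variable mods | phospho (S/T/Y), pyrophospho (S/T), oxidation (M) | — | ≤4 per form, ≤1 pyrophospho |
| fixed mod | carbamidomethyl (C) | — | applied to every Cys |
| non-fragment filter | ±1 Da precursor, ±0.5 Da charge-reduced + losses | Da | before steps 3–4 |
| couplet policy | ONE_SIDE | — | BOTH_SIDES as strict mode |

Element masses are the NIST/IUPAC monoisotopic values hard-coded to ≥6
decimals; all modification deltas are derived from formulas (HPO3, 2×HPO3,
O, C2H3NO), never typed as literals, which makes the pyro/bisphospho
isobar identity exact to machine precision. Charging uses the bare proton
mass 1.0072765 Da.

Decisions taken where the protocol leaves room (each exposed in
configuration):

* The 15% threshold is referenced to the CID base peak; referencing to
  total ion current is the plausible alternative and would only loosen the
  gate.
* The intensity rank is computed over all peaks, residual precursor
  included; a switch excludes peaks inside the isolation window.
* One bridging couplet in any one series suffices by default
  (`ONE_SIDE`); the validated endogenous examples show couplets on both
  termini, so a `BOTH_SIDES` strict mode is provided (its CONFIRMED set is
  provably a subset of the default's).
* Doubly charged fragments are accepted as couplet evidence.
* z-type ions are generated in all three common variants (z•, z+1, z−1)
  and whichever matched is reported; tools disagree on which variant the
  plain label "z" denotes.
* A terminal site (position 1 or L) cannot be bridged — the would-be upper
  ion is the intact peptide — and is reported as absence of coverage, not
  an error.

## The synthetic-spectrum generator

`pyrosite.simulate` produces labeled paired spectra so the whole protocol
can be exercised without instrument data:

* CID scans carry the class-specific loss channels — pyrophospho:
  −98/−178/−196 at 0.8/1.0/0.7 of the base peak; mono/bis: −98/−196 at
  1.0/0.6 — plus low-lying b/y backbone signal (≤0.35 of base) and a
  residual precursor, so intensity ranks are meaningful. Channels a class
  cannot produce are genuinely absent.
* EThcD scans contain a configurable fraction (default 1.0) of the
  theoretical c/z ions at charges 1–2 with seeded log-uniform intensities,
  optional residual-precursor artifacts (on by default; the non-fragment
  filter must earn its keep) and optional uniform noise that avoids a
  ±0.05 Da guard band around every theoretical ion, so zero-noise
  guarantees degrade gracefully at low noise.
* Mixtures are intensity-scaled unions of two bisphospho isomer spectra.
  Because the co-fragmentation hazard only matters for spectra the
  acquisition actually triggered, the mixture CID includes a −178
  interference channel scaled by the degree of mixing (0.5 of base at 1:1,
  vanishing for a degenerate 1:0 mixture, which reproduces the pure
  component pair bit for bit).
* The random backbone samplers place Ser/Thr sites explicitly on otherwise
  phosphosite-free fillers, end peptides tryptically (K/R), and — for the
  mixture sampler — reject the rare backbone whose single-phosphate
  fragments are *all* within 0.025 Da of some pyrophospho-hypothesis ion.
  Such chance isobars can propagate through a whole ion series, and no
  fragment-mass protocol can resolve them at 0.02 Da tolerance (see
  Limitations); they are excluded as ill-posed benchmark cases by a purely
  theoretical-mass criterion.

What the generator does *not* emulate: chromatography and co-elution
dynamics, isotope envelopes, charge-state distributions, intensity models
beyond rank structure, and real chimeric backgrounds. A clean benchmark
therefore demonstrates the correctness of the decision logic, not the
sensitivity of the method on real lysates — in real data, coverage gaps
and co-eluting background are exactly what the INSUFFICIENT_COVERAGE and
STEP1_FAIL outcomes absorb.

The label-blind benchmark (50 pyrophospho / 50 bisphospho / 50 mixture
pairs, zero noise, full coverage, ~1 s on one CPU) yields sensitivity 1.0
on pyrophosphopeptides, zero CONFIRMED among bisphosphopeptides (which
never fire the trigger) and among mixtures, with every mixture failing
specifically with BISPHOSPHO_EVIDENCE.

## Site-property analyses

`pyrosite.siteprops` covers the downstream cohort characterization:

* **Local pI profile.** For each residue, the isoelectric point of the
  ±10-residue window (width configurable) is found by bisecting the
  Henderson–Hasselbalch net-charge equation over the ionizable side chains
  (D, E, C, Y acids; H, K, R bases; Lehninger pKa set, documented in
  `PKA_SIDE_CHAINS`) to |Q| < 1e−4. Interior windows have no free termini,
  so terminal groups are excluded; windows without ionizable side chains
  report a flagged neutral sentinel of 7.0; windows whose charge never
  crosses zero inside pH 0–14 (pure acid / pure base) report the clamped
  boundary. Phosphate charges are deliberately not included: the profile
  describes the sequence, not the modification state.
* **CK2-consensus partition.** A site matches the acidophilic casein
  kinase 2 consensus iff position +3 holds Glu/Asp/Ser/Thr; a site within
  three residues of the C terminus cannot fire the rule and falls to the
  remainder (where, in the published cohorts, a proline-directed consensus
  emerges).
* **Disorder-stretch rule.** A site counts as disordered iff it lies in a
  run of ≥ 20 consecutive residues with disorder score ≥ 0.5 (the score
  track is an input, e.g. an IUPred-style per-residue TSV; the site's own
  score must qualify). The cohort statistic is the fraction of flagged
  sites.
* **Tally and PFM.** Ser/Thr counts and a position frequency matrix over
  the ±7 windows (padding excluded from column sums) — the count matrix
  underlying a sequence logo.

Window half-widths (pI 10, motif 7) are conventional motif-analysis sizes;
neither is dictated by the protocol and both are flags.

## Numerical choices

* All tolerances are in Da unless marked ppm; matching ties between
  equidistant peaks go to the higher-intensity peak.
* Candidate ranking is deterministic: fewer modifications first, then the
  lexicographic form key.
* MGF m/z values are written with 6 decimals (< 1 ppm at m/z 1000), which
  preserves 0.02 Da matching across a write/read cycle; a fixed simulator
  seed gives byte-identical files.
* Intensity ranks use "equal intensities share the best rank".

## Known limitations

* **Isobaric blind spot.** If every single-phosphate fragment of a
  bisphospho explanation happens to fall within the fragment tolerance of
  some 0/2-phosphate ion of the pyrophospho hypothesis, step 3 is blind by
  construction (the conservative ambiguity rule) and a co-fragmentation
  mixture can slip through to CONFIRMED. This is a property of the peptide,
  not of the implementation; narrowing the fragment tolerance shrinks the
  exposure.
* Site localization is per-candidate: forms with several putative
  pyrophospho sites are validated one site at a time.
* No database-search scoring, decoy FDR, quantification or retention-time
  modeling; candidate generation is exhaustive enumeration under the search
  caps, not a scored search.
* The mzML reader covers the common subset (MS2, selected ion + charge,
  CID/ETD activation terms, 32/64-bit plain or zlib arrays); MGF is the
  primary format.
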