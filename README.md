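# pyrosite

Detection and validation of **protein pyrophosphorylation** (ppSer/ppThr)
sites from neutral-loss-triggered CID/EThcD tandem mass spectra.

Pyrophosphorylation puts a diphosphate group on one Ser/Thr side chain. Its
tryptic peptides are *exactly* isobaric with bisphosphopeptides — the same
backbone carrying two monophosphates on two residues — so the precursor mass
proves nothing and the peptide must be assumed bisphosphorylated unless
pyrophosphorylation can be positively asserted. `pyrosite` implements the
spectral logic that makes that assertion, for proteomics researchers who
want to screen peak lists for the modification or to study the behaviour of
the assignment protocol itself:

1. **Trigger.** CID of a pyrophosphopeptide releases pyrophosphoric acid,
   a neutral loss of **H4P2O7 = 177.9432 Da** from the precursor (−178 m/z
   channel); mono- and bisphosphopeptides can only produce the −98 (H3PO4)
   and −196 (H6P2O8) channels. A −178 loss at ≥ 15% relative intensity on a
   2+–4+ precursor triggers an EThcD scan of the same precursor.
2. **Rank filter.** The −178 peak must be among the three most intense CID
   signals; weaker losses indicate bisphosphopeptide co-fragmentation.
3. **Counter-evidence.** In the EThcD spectrum, any fragment explainable
   only with exactly **one** phosphate group proves a bisphosphorylated
   contributor and discards the spectrum. This step rejects the nasty case
   where two co-fragmented bisphospho isomers with overlapping site pairs
   jointly supply every ion needed to fake a pyrophospho site.
4. **Site-bridging couplet.** Confirmation requires sequential ions
   c(k−1)/z(L−k) with zero phosphates and c(k)/z(L−k+1) with two, placing
   both phosphates on residue k.

The package also ships a ground-truth spectrum simulator (pyrophospho-,
mono-, bisphosphopeptides and co-fragmentation mixtures, paired CID/EThcD,
seeded and byte-reproducible), in-silico tryptic candidate generation, and
the sequence-property analyses used on validated site cohorts (sliding
local pI, CK2-consensus partition, disorder-stretch rule, Ser/Thr tally and
position frequency matrix). See `docs/methods.md` for the model, defaults
and limitations.

## Worked example

Simulate paired CID/EThcD spectra of the five synthetic pyrophosphopeptide
standards, then validate them against a protein database containing the
ppS-3 standard (`LDSEEDSAWPTNEK`, pyrophospho-Ser3) in a tryptic context:

```sh
pyrosite simulate --class STANDARDS --seed 2 --out standards.mgf
printf '>NOLC1_FRAG synthetic context\nMAGKLDSEEDSAWPTNEKAAAR\n' > db.fa
pyrosite run --spectra standards.mgf --fasta db.fa --out verdicts.tsv
```

which prints

```
wrote 10 spectra (5 pairs) -> standards.mgf
3 candidate assessments, 1 CONFIRMED -> verdicts.tsv
```

and `verdicts.tsv` contains one row per candidate site hypothesis:

```
scan_id      peptide                          site_in_peptide  site_in_protein  verdict              nl_rank  couplets
ppS-3|EThcD  LDSEEDSAWPTNEK[pyrophospho@11]   11               15               BISPHOSPHO_EVIDENCE  1
ppS-3|EThcD  LDSEEDSAWPTNEK[pyrophospho@3]    3                7                CONFIRMED            1        N:c2/c3;C:z11/z12
```

Every peptide form within 10 ppm of the precursor is assessed. The wrong
site hypotheses (pyrophospho at Ser7 or Thr11) are rejected because the
spectrum contains fragments that would then carry exactly one phosphate
(e.g. `b5` for the Thr11 hypothesis), while the true Ser3 site is CONFIRMED:
the −178 loss ranks first in the CID scan (`nl_rank 1`) and the site is
bridged on both termini — the `c2/c3` couplet (c2 unphosphorylated, c3
carrying both phosphates) and its C-terminal mirror `z11/z12`.

The same machinery is available as a library:

```python
from pyrosite import classify, make_standard_fixtures, simulate_pair

pep = make_standard_fixtures()["ppS-3"]
cid, ethcd, label = simulate_pair(pep, rng=2)
verdict = classify(cid, ethcd, pep)
print(verdict.verdict, [c.describe() for c in verdict.couplets])
# CONFIRMED ['N:c2/c3', 'N:c2/c3', 'C:z11/z12', 'C:z11/z12']
```

(couplets are reported per charge state).

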