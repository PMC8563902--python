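# trnam1a

Quantitative detection of **tRNA m¹A58 stoichiometry** from
reverse-transcription misincorporation signatures, with the downstream
ribosome-profiling and codon-content analysis that links hypermethylated
tRNAs to translationally upregulated transcripts.

## Who this is for

N1-methyladenosine at tRNA position 58 (the T-loop) blocks Watson–Crick
pairing, so a thermostable RT (e.g. TGIRT) reads through the site but
misincorporates a base.  In an immunoprecipitation-free small-RNA library
the *fraction of non-reference bases* at position 58 therefore estimates
the methylated fraction of molecules — the stoichiometry — provided false
signals (SNPs, other modifications, sequencing error) are removed by
contrasting against a parallel **demethylase (AlkB) treated** library in
which the genuine m¹A signal collapses.  This package implements that
estimator and everything around it for researchers studying tRNA
modification dynamics and their translational consequences:

* a read-level simulator of the whole assay (10-nt random barcodes, 3′
  adapter `AGATCGGAAGAGCGTCGTG`, PE150 read-2 layout, PCR duplication,
  sequencing error, configurable demethylation efficiency) with exact
  truth tables;
* preprocessing (Q20 quality + adapter trimming, barcode extraction),
  a self-contained glocal affine-gap aligner for the mature-tRNA
  reference set, UMI deduplication keyed on (position, barcode), and
  per-position pileups;
* the stoichiometry model and demethylation-contrast site calling, plus
  cross-condition differential methylation;
* ribosome-footprint QC (25–33 nt length filter, 12-nt P-site offset,
  3-nt periodicity), RPKM, translation efficiency TE = RPKM_ribo /
  RPKM_rna, and fold-change-4 TE classification;
* codon frequency profiles, rank percentiles, and a label-permutation
  test for enrichment of the codons decoded by hypermethylated tRNAs in
  TE-up gene sets; dual-luciferase normalisation arithmetic.

## The model in brief

For tRNA *t* with coverage *n* at its position-58 adenosine, the
misincorporation rate is *m̂ = (n − n_A)/n*.  With untreated and
demethylated arms, a site is called m¹A58 when both arms pass a coverage
gate and Δ = m̂_untr − m̂_dem ≥ δ_min (default 0.05); the stoichiometry
estimate is m̂_untr (optionally Δ with background subtraction), with Wald
standard error √(m̂(1−m̂)/n).  Differential methylation between
conditions flags tRNAs whose stoichiometry gain exceeds an elevation
threshold in both-called sites.

## Worked example

```python
from trnam1a import (M1AStoichiometryModel, default_truth,
                     make_trna_reference)
from trnam1a.simulate import simulate_trna_alignments

refs = make_trna_reference(4, seed=7)
truth = default_truth(refs, seed=7)        # stoichiometries 0, 0.2, 0.5, 0.9
alu, _ = simulate_trna_alignments(refs, truth, 4000, False, "A", seed=11)
ald, _ = simulate_trna_alignments(refs, truth, 4000, True, "A", seed=12)
print(M1AStoichiometryModel.from_alignments(alu, ald, refs).fit().summary())
```

```
m1A58 stoichiometry (misincorporation contrast)
========================================================================
references: 4   called: 3   min_coverage=50  delta_min=0.05
------------------------------------------------------------------------
tRNA                   pos  mism_untr  mism_dem  stoich      se    band  called
------------------------------------------------------------------------
tRNA-Asp-GTC-1          66     0.0031    0.0010  0.0031  0.0018     low   False
tRNA-Ala-AGC-1          66     0.2011    0.0039  0.2011  0.0124     low    True
tRNA-Glu-CTC-1          60     0.5247    0.0029  0.5247  0.0162  medium    True
tRNA-Ser-GCT-1          66     0.9096    0.0000  0.9096  0.0090    high    True
------------------------------------------------------------------------
```

Each row is one tRNA: the untreated misincorporation rate at position 58
(`mism_untr`) recovers the planted stoichiometry to within binomial
error; the demethylated arm (`mism_dem`) collapses to the sequencing
error floor, which is what licenses the call.  `pos` is 1-based.

The full pipeline (simulate → trim → align → dedup → call → TE → codon
enrichment) runs from the shell:

```bash
trnam1a run-all --seed 1 --out run/
```

and writes `calls_A.tsv`, `calls_B.tsv`, `diff.tsv`, `te.tsv`,
`enrichment.tsv`, `qc.json` and a manifest; reruns with the same seed are
byte-identical.

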