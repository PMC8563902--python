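# Methods

## The misincorporation model

m¹A58 blocks Watson–Crick pairing, and a thermostable group II intron RT
reads through the site with a base misincorporation rather than stopping.
The package models each sequenced molecule of tRNA *t* as methylated with
probability θ_t (the stoichiometry).  A methylated molecule yields a
non-A base at the position-58 adenosine (drawn from a configurable
spectrum, uniform over C/G/T by default); every base additionally suffers
independent sequencing error at rate ε.  The observed mismatch count at
position 58 is therefore Binomial(n, θ_t + (1−θ_t)·ε·(…)) to first
order, and the raw mismatch rate m̂ = (n − n_A)/n estimates θ_t with
standard error √(m̂(1−m̂)/n) and an additive bias bounded by ε.

The demethylase-treated arm erases the methyl mark with efficiency η
(default 1.0): its molecules are methylated with probability θ_t(1−η),
so at η = 1 its mismatch rate is pure error floor.  A site is **called**
when both arms reach `min_coverage` (default 50) and
Δ = m̂_untr − m̂_dem ≥ `delta_min` (default 0.05).  Both thresholds are
declared defaults, exposed in `CallConfig` and recorded in output
headers.  The stoichiometry reported is the raw untreated rate; an
opt-in `background_subtract` mode reports Δ instead — both conventions
are defensible readings of a contrast-based estimator, so both are
implemented with the raw rate as default.

Stoichiometry bands: low < 0.3 ≤ medium < 0.9 ≤ high.  Differential
methylation between conditions A and B flags a tRNA as elevated when it
is called in both conditions and θ̂_B − θ̂_A ≥ `elevation_min` (default
0.05); the band annotated on the differential row comes from the
lower-stoichiometry condition.  Deletions at the inspected site are
excluded from both numerator and denominator by default (read-through
chemistry produces mismatches, not gaps); a flag counts them as
mismatches.

## Library processing

Reads follow the assayed library layout: the analysed read is
`10-nt random barcode + cDNA insert + 3′ adapter AGATCGGAAGAGCGTCGTG`,
150 nt total.  Preprocessing quality-trims the 3′ end at Q20 with the
BWA running-sum rule, then removes the adapter at the earliest suffix
overlap of ≥ 5 nt with ≤ 10% mismatches (Trim-Galore-like defaults; the
exact trimmer options behind the assay are not published, so these are
declared stand-ins).  The barcode is split off as the UMI.  Both arms
must be processed with identical settings; the config hash recorded in
outputs makes silent divergence detectable.

PCR deduplication keeps one representative per
(reference, mapping position, UMI) key — *both* the identical position
and the identical 10-nt barcode are required — choosing the first record
in a stable sort by read id, so deduplication is deterministic and
idempotent.  Barcode collisions are possible and intentionally not
corrected (two distinct molecules sharing position and barcode collapse
to one); at 4¹⁰ barcode space and ≤ 10⁴ molecules per tRNA the induced
coverage loss is < 0.5%.

## Alignment

Reads are aligned to the mature-tRNA set with a self-contained glocal
aligner: the read aligns end-to-end (up to 2 nt of free soft clip per
end, absorbing residual adapter/ligation bases) while the reference is
entered and left for free.  Scoring is +1/−1 with affine gaps (open −3,
extend −1); alignments scoring below 0.8 × read length are discarded.
The recurrence is vectorised per read row; because a gap never pays two
openings when `gap_open ≤ gap_extend`, the within-row dependency of
read-gaps reduces to a prefix running maximum.  Reads tying across
references are dropped by default (`best-unique`): stoichiometry should
not mix reads of ambiguous origin.  `random-tiebreak` (seeded) and
`drop` are available, and byte-identical reference sequences are
collapsed into a jointly named entry before alignment, since mismatch
attribution between indistinguishable isodecoders is undefined.  An
external aligner can be substituted through the plain-SAM import path.

Score ties can admit several co-optimal paths; the aligner picks one
deterministically (diagonal first), and correctness is asserted as score
equality against a brute-force oracle plus independent rescoring of the
emitted path.

## Ribosome profiling and TE

Footprints of 25–33 nt are qualified; simulated lengths concentrate on
28–32 nt.  Each footprint's 5′ end sits 12 nt upstream of an in-frame
P-site codon.  The simulator places a configurable fraction (default
10%) of footprints at the start codon — the initiation pile-up — because
with strictly uniform codon occupancy every offset congruent to 12 mod 3
ties and the offset search is undefined; real Ribo-seq libraries show
exactly this initiation peak.  Optional positional jitter is symmetric
with binomial weights (peaked at 0), so the offset mode is preserved.
The offset estimator scans 0–18 nt for the shift maximising the
aggregate 5′-end count at `cds_start − offset`; periodicity is the
frame-0 fraction of P-site assignments.

RPKM is computed over the CDS; `total_mapped` is the number of reads
assigned to CDS regions of the analysed transcript set per library (the
denominator convention is not published; this choice makes the Ribo and
RNA denominators commensurable and is recorded in output metadata).
TE = RPKM_ribo / RPKM_rna, undefined (flagged, excluded) when the RNA
RPKM is zero — no pseudocount by default, matching the literal ratio
definition; a pseudocount flag exists for exploration.  Transcripts with
a ≥ 4-fold TE change between conditions are classed up/down.

Note that RPKM-ratio TE is compositional: planting a TE gain on a
fraction *f* of genes deflates every estimated fold change by the scale
1 + (fold−1)·f.  The synthetic truth therefore uses a 16-fold gain on
10% of genes so the estimated fold change (≈ 6.4) clears the 4-fold
threshold while unchanged genes (≈ 0.4-fold) stay inside it.

## Codon analysis

Codon profiles count internal sense codons (start and stop excluded by
default; including the start is a flag because rank-percentile claims
are sensitive to it).  "Top X%" uses strict-greater ranking with ties
ranking equally.  The tRNA→codon link uses the narrow Watson–Crick
mapping (anticodon reverse complement) by default, with standard wobble
expansion available; synonymous-codon control experiments argue for the
narrow default.  Enrichment of target codons in TE-up genes is a
label-permutation test on the mean summed target-codon frequency with
the add-one p-value rule — distribution-free and matched to the
between-set comparison it formalises.  Dual-luciferase normalisation is
(F/R)_test / (F/R)_control.

## Synthetic data: what it does and does not emulate

The generators reproduce the assay's information structure — barcodes,
adapters, read-2 layout, misincorporation, demethylation efficiency,
sequencing error, Poisson PCR duplication (1 + Poisson(mean) copies per
molecule), codon-biased CDS classes, footprint geometry — with exact,
seed-reproducible truth sidecars.  They do **not** model AlkB reaction
chemistry, ligation sequence biases, tRNA secondary-structure-dependent
RT behaviour, position-dependent error profiles, or other modifications
(m¹G9, m³C32); RT fall-off at m¹A is off by default
(`truncation_rate = 0`) since the estimator is read-through-based.
Passing tests therefore demonstrate correctness of the *estimators and
bookkeeping* under the declared generative model, not robustness to
every artefact of real libraries.  tRNA abundance defaults to uniform
and equal across conditions (expression is treated as constant; only
methylation moves).

## Numerical and design choices

* Coordinates are 0-based half-open internally; report tables print
  1-based positions.
* Zero coverage yields NaN rates (never 0.0) and `min_cov_ok = False`;
  such sites are recorded, not dropped.
* 'N' read bases count as neither match nor mismatch anywhere.
* All randomness flows through `numpy.random.default_rng` seeds; the
  modification draw precedes all other draws per tRNA so that raising
  the demethylation efficiency only shrinks the surviving methyl set
  (monotonicity under a fixed seed).
* Gzipped outputs are written with a zeroed mtime so identical runs are
  byte-identical.
* Problem sizes in the test-suite property checks (coverage 2000 at
  error 0.002 over 100 replicates; coverage 4000 for differential
  recovery, where 3 SE < half the elevation threshold; 250-gene
  transcriptomes for permutation calibration) are chosen so the stated
  statistical bounds have comfortable margins at desk scale.

## Known limitations

* The aligner is O(nm) per read/reference pair and intended for small
  curated reference sets (tens of tRNAs), not genomes.
* Stoichiometry is a per-site marginal; no joint haplotype/isodecoder
  deconvolution is attempted, and reads mapping ambiguously across
  isodecoders are discarded by default rather than fractionally
  assigned.
* The permutation test assumes exchangeability of gene labels under the
  null; gene-length or GC covariates are not modelled.
* Reproducing transcriptome-wide human codon percentiles requires a
  user-supplied CDS catalogue; the bundled transcriptomes are synthetic.
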