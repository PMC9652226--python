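# Methods

## The measurement model

The assay quantifies each reporter insert's steady-state mRNA level as the
log2 ratio of its summed mRNA barcode counts to its summed genomic-DNA
barcode counts, median-normalized across the library. Barcodes are the unit
of replication: an insert is integrated in many independent cell lineages,
each tagged by a distinct 24-nt barcode, and the genomic counts normalize
away lineage-to-lineage copy-number and representation differences. The
estimator is deliberately plain — summed counts, one ratio, one median
shift — because that is what the count filters are designed around.

An insert's measurement is reported only when it passes all of: at least 200
reads summed across the mRNA and gDNA samples, at least 6 barcodes with any
counts, and a nonzero gDNA sum. Failing inserts are reported `missing` with
an NaN level; no pseudocounts are added anywhere. The median used for
normalization is computed over passing inserts only, per library, which makes
the normalization idempotent.

Uncertainty is a bootstrap over barcodes: each resample draws an insert's
barcodes with replacement, carrying each barcode's (mRNA, gDNA) count pair
jointly, and recomputes the summed log2 ratio. The SEM is the standard
deviation (ddof=1) over replicates; replicates whose resampled gDNA or mRNA
sum is zero are dropped and counted. Default replicate number is 100 for
libraries over 1000 inserts and 1000 otherwise. With a single barcode the
bootstrap is degenerate and the SEM is exactly 0.

## Library design

* Dicodon pool: all 4096 ordered codon pairs, each as a tandem 8× repeat
  (48 nt, 16 residues), enumerated in lexicographic order. 375 inserts
  contain a stop codon; the 3721 stop-free inserts partition into 400
  ordered dipeptide classes, of which 190 are unordered heterodipeptide
  classes once reversed repeats are excluded.
* Frameshift partners: reading the infinite (c₁c₂) repeat at a +s nucleotide
  offset yields the same periodic peptide as reading, in frame 0, the left
  rotation of the hexamer by s, re-split into two codons. A +3 shift swaps
  the codons, so its peptide is the reversed dipeptide repeat.
* Variant series: repeat-length series (1–8 repeats, padded 3′ to 48 nt with
  a Ser-Gly linker encoded AGC GGT — a fixed, composition-neutral choice, as
  Ser-Gly dipeptides are non-destabilizing in the assay), periodicity series
  (block size b = b tandem dipeptides followed by b reversed copies, tiled
  to 16 residues; all members share the pure repeat's composition), and
  combination peptides (4× repeats of explicit 4-residue units such as SVKF).
  Designed peptides are reverse-translated with the most frequent human codon
  per residue; the codons actually used in synthesized pools are generally
  unknowable from a design spec, so frameshift-control identities of variant
  pools are not re-derived.
* Barcodes: (VNN)×8 with V ∈ {A, C, G}. Since every stop codon starts with
  T, the design structurally excludes in-frame stops; the space holds 48⁸
  sequences and sampling is uniform with global rejection of duplicates.

## Amino-acid scales

The packaged table (`data/aa_scales.tsv`) carries the Zimmerman isoelectric
point (pH units) and bulkiness (side-chain volume/length, Å²) scales and the
Chou–Fasman α-helix/β-strand propensities (dimensionless). The table is
guarded by a test against a second, independently transcribed copy. Bulky
residues are those with bulkiness strictly above 18 Å² (I, L, F, W, Y, V);
the proteome scan uses the subset {L, V, I, Y, F}. Secondary-structure
classification of a peptide takes the mean per-residue probability from an
external predictor's output and calls helix or strand only when the mean is
strictly above 0.5; all thresholds in the package are strict inequalities.

## The synthetic-data generator

The generator emulates every input the pipeline consumes, with ground-truth
sidecar tables, so each stage can be tested against what it should recover.

True insert levels follow the physicochemical linear model on the encoded
dipeptide's mean pI, mean bulkiness, their product, and mean β-strand
propensity, with defaults β = (0.31, 0.20, −0.03, −0.52) on the log2 scale,
plus a −2.0 log2 penalty for stop-containing inserts (premature termination
feeding nonsense-mediated decay) and Gaussian insert-level noise with
noise_sd = 0.5 log2 units. The coefficients serve as simulation truth for
recovery testing; the noise and stop-penalty magnitudes are generator
choices, not measured values. For stop-containing dipeptides the features
are computed over the standard residues only.

Sequencing is modelled as: a truncated-geometric number of barcodes per
insert (median 15, minimum 1, with a half-step-corrected rate so 15 is the
strict population median); Poisson (or fixed) reads per linkage barcode;
Dirichlet-multinomial barcode abundances around equal genomic representation
(dispersion 0.2 by default; the Dirichlet concentration is 1/dispersion);
mRNA abundance equal to the genomic proportion times 2^level, sampled
multinomially, so the log-ratio estimator is the generative inverse; uniform
per-base substitution errors (0.001/base) that never silently reproduce the
original base; constant quality strings. Sorted low-fluorescence samples
weight each barcode by its insert's premature-termination probability;
transcription-shutoff timecourses decay each insert as 0.5^(t/half-life)
against a constant-abundance spike-in barcode set, sampled at 0, 0.5, 1, 2,
4, 6 h. Luminescence traces are max(0, rate·(t − transit)) plus Gaussian
noise on a 10-s grid over 25 min.

What the generator does **not** emulate: PCR jackpotting and duplicate
reads, indels, position- or quality-dependent error profiles, barcode
bottlenecking during cloning, cell-line differences, UMI structure, or
secondary-structure prediction itself (the strand feature of the generative
model is the Chou–Fasman propensity, not a neural-network profile). Passing
recovery tests therefore demonstrates the correctness of the estimators
under overdispersed multinomial sampling with substitution noise — not
robustness to every artefact of real libraries.

## Linkage and filtering

Read insert regions are matched to the library by exact lookup with a
vectorised Hamming fallback: the unique insert within ≤2 substitutions wins;
ties and everything farther are unassigned. This replaces aligner-based
mapping with an explicit, deterministic contract appropriate to fixed-length
synthesized regions (no indels; the distance cap and metric are
configurable). The dicodon library's minimum pairwise distance is 8, so a
≤2-mismatch read can never tie between two pool inserts.

Tallied (barcode, insert) pairs then pass three order-independent filters:
drop barcodes seen fewer than 4 times (the low end of the assay's 4–10
range, exposed as a flag); drop barcodes linked to two or more distinct
inserts; and among same-insert barcodes within Hamming distance 2, keep the
higher-count member, processing in descending count with lexicographic
tie-break (the smaller sequence wins equal counts) so results are invariant
to read order. Every barcode's disposition is logged and round-trips through
the gzip TSV export.

Sample counting is exact-match with an optional one-mismatch rescue: a read
one substitution from exactly one kept barcode is rescued; a read within one
mismatch of two kept barcodes stays unmatched.

## Statistical analyses

* Positional effects: mean level of each codon at each repeat position,
  averaged over all partners at the other position; amino-acid effects pool
  synonymous codons, with stop as a 21st class.
* Physicochemical model: OLS with intercept (statsmodels); coefficients are
  reported with two-sided p-values and adjusted R², and the retained set is
  filtered at p < 0.05 with no multiple-testing correction. Rank-deficient
  designs are rejected naming the terms.
* Frame correlations: the frame-0 axis aggregates stop-free heterodipeptide
  classes in canonical orientation only (first residue alphabetically before
  the second — i.e. excluding reversed repeats), and the partner axis
  carries the frameshift partners' own measured levels. This matters for the
  +3 shift, whose partner is the physically distinct reversed-repeat insert:
  aggregating both orientations onto both axes would force r(+3) = 1
  identically and void the comparison. Pairs whose own or partner peptide
  contains a stop are dropped; shifts with fewer than 3 classes report NaN.
* Propensity correlations: two-sided Spearman rank correlation; exact
  permutation p-value by full enumeration for n ≤ 10, t-approximation above.
* Group comparisons: pairwise two-sided Mann–Whitney U, exact null when the
  combined sample is ≤ 20 and tie-free, tie-corrected normal approximation
  otherwise.

## Proteome scan

Score of a window = D + O, with D the number of adjacent positions whose
unordered residue pair crosses {K, R} × {L, V, I, Y, F} and O the overlap
bonus. Homopairs (KK, RR, KR) and bulky–bulky pairs score 0. The default
bonus counts each adjacent overlapping pair of destabilizing dipeptides, so
a run of L consecutive dipeptides contributes L + (L − 1); the alternative
reading — a flat +1 per overlapping cluster, L + 1 — is implemented behind
`overlap_mode="per_cluster"`. Per protein the scan reports the
maximum-scoring 16-residue window, leftmost on ties; windows with
non-standard residues are not scored, proteins shorter than the window are
skipped and counted, and terminal stops are stripped. Windows scoring > 9
are classified destabilizing, < 3 control. The reordering mutant performs a
stable three-way partition of the window's codons — K/R codons first, then
the rest, then L/V/I/Y/F codons — preserving order within blocks, which
keeps the codon multiset (hence amino-acid composition) intact and is
idempotent.

## Transit-time estimation

In a continuous in vitro translation assay, luminescence rises linearly once
the first ribosomes traverse the transcript; the transit time is the
X-intercept (−intercept/slope) of a least-squares line over a user-chosen
window of the linear regime, reported as mean ± SEM over replicate traces.
Fits with non-positive slope are rejected, as are windows outside the trace
span or containing fewer than 3 points. The SEM of very few replicates can
be much smaller than the common sampling error of the extrapolated
intercept, so recovery checks in the test suite use an absolute tolerance
derived from the intercept's sampling variance rather than a multiple of the
replicate SEM. An automatic window mode (sliding 300-s window maximizing R²)
exists for exploration and is explicitly not the reported procedure.

## Problem sizes and determinism

The end-to-end checks run the full 4096-insert pool at 2×10⁶ reads per count
sample (about half a minute on one CPU); the error-free linkage-recovery
check uses a 512-insert subset with fixed read counts; scoring oracles use
10,000 random 16-mers and 1,000 random proteins; null calibrations use
100-seed banks. All simulators take an explicit `numpy` Generator and are
byte-reproducible under a fixed seed; the pipeline writes a JSON run log
with the seed, stage record counts, and (in simulation) the truth-recovery
Spearman ρ.

## Known limitations

* The physicochemical coefficients recovered from simulated data validate
  the estimator, not the biology; reproducing the assay's measured
  coefficients requires the original sequencing data.
* The insert matcher assumes fixed-length, indel-free variable regions;
  libraries with indels need the configurable edit-distance extension.
* The strand feature conflates Chou–Fasman propensity with predicted
  structure probability; consumers with per-residue predictor output should
  ingest it via `StructureProfile` instead.
* Collision filtering is greedy (highest count first); a globally optimal
  clustering of near-duplicate barcodes is not attempted.
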