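# stallseq

Analysis toolkit for massively parallel reporter assays (MPRAs) that measure
how short nascent-peptide motifs alter mRNA stability in human cells, and for
finding such motifs across a proteome.

## The assay and who this is for

In the assay this package models, every ordered codon pair (4096 dicodons) is
tiled as a tandem 8× repeat — a 48-nt insert encoding a 16-residue dipeptide
repeat — between two fluorescent reporter cassettes, tagged with multiple
random 24-nt barcodes ((VNN)×8, so barcodes never carry an in-frame stop), and
integrated as a pool into cells. Sequencing barcodes in mRNA and in genomic
DNA gives, per insert, a steady-state mRNA level:

    level(insert) = log2( Σ mRNA barcode counts / Σ gDNA barcode counts ) − library median

Dipeptide repeats combining positively charged residues (K, R) with bulky
ones (side-chain volume/length > 18 Å²: I, L, F, W, Y, V) destabilize the
mRNA that encodes them, an effect captured by a linear model on the encoded
dipeptide's mean isoelectric point (pI), mean Zimmerman bulkiness, their
interaction, and mean Chou–Fasman β-strand propensity:

    level ≈ β₀ + β₁·pI̅ + β₂·bulk̅ + β₃·pI̅·bulk̅ + β₄·strand̅

The package is aimed at people building or re-analysing such reporter pools:
it designs the libraries, simulates every sequencing readout under a stated
generative model (so the whole pipeline is testable without raw data), builds
the barcode→insert map with the count/collision/duplicate filters, quantifies
levels with bootstrap SEMs, fits the physicochemical models, scans proteomes
with a destabilizing-dipeptide score, and estimates ribosome transit times
from in vitro translation luminescence traces.

## Worked example

Simulate the full 4096-insert pool at default depths (2×10⁶ reads per
sample), run linkage → counting → quantification → analyses, and compare the
estimated levels with the simulation truth:

```python
from stallseq.workflow import PipelineConfig, run_pipeline

res = run_pipeline(PipelineConfig(seed=1, outdir="run1"))
print("spearman", res["log"]["recovery_spearman"])
print(res["frame_correlations"])
```

prints (about 30 s on one CPU):

```
spearman 0.982761845331215
   shift         r  n_classes
0      1  0.021797        182
1      2 -0.163237        182
2      3  0.363622        186
```

The Spearman ρ = 0.98 between true and estimated levels says the barcode
pipeline recovers the simulated insert effects almost perfectly at these
depths. The frame correlations compare each heterodipeptide repeat's level
with the insert whose peptide matches its +1/+2/+3-nt frameshifted reading:
only the codon-matched +3 frame (the reversed repeat, a near-identical
peptide) correlates — the signature of a translation-level, peptide-driven
effect rather than a nucleotide-level one.

Scanning a coding sequence for destabilizing motifs and designing the
composition-preserving disruption mutant:

```bash
$ stallseq scan --fasta cds.fa --cds --mutants-out mut.tsv
$ cat motifs.tsv
gene_id  window_start  window_seq        score  class
g1       31            VKVKVKVKVKVKVKVK  29     destabilizing
$ cut -f1,4,5 mut.tsv
gene_id  wt_peptide        mut_peptide
g1       VKVKVKVKVKVKVKVK  KKKKKKKKVVVVVVVV
```

Each adjacent K/R–L/V/I/Y/F pair scores 1 and each overlapping pair of such
dipeptides adds 1, so the perfect (VK)₈ window scores 15 + 14 = 29; moving
all charged codons 5′ and all bulky codons 3′ leaves at most the single
block-junction dipeptide scoring.

Other entry points: `stallseq design | simulate | link | count | quantify |
model | transit | run-all` (see `--help`), or the library modules directly
(`reporter_library`, `simulate`, `linkage`, `quantify`, `analysis_models`,
`proteome_scan`, `kinetics`).

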