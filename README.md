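# mitostall

Mitoribosome stalling and mt-RNA 3'-end extension analysis for the human
mitochondrial transcriptome.

Human mtDNA encodes 13 OxPhos subunits, 22 tRNAs and 2 rRNAs.  When the
3' ends of mitochondrial non-coding RNAs are corrupted — e.g. by spurious
oligoadenylation of mt-tRNAs past their CCA end, which blocks
aminoacylation — translation stalls at the codons those tRNAs decode.
`mitostall` provides, as a library plus a thin CLI, the two computational
read-outs of this biology:

- **MitoRibo-Seq** (mitochondrial ribosome profiling): map 31–35 nt
  ribosome-protected fragments to the mt-mRNAs, infer the ribosomal
  A-site (read nt 16–18 for frame-1 5' ends, 17–19 for frame-3), and
  compute a per-codon-species **occupancy**

  *occ(c) = mean over occurrences of c of [density at the occurrence /
  mean density of its CDS]*,

  which is 1.0 under uniform translation and rises at codons where
  ribosomes dwell awaiting a scarce aminoacyl-tRNA.

- **MPAT-Seq** (mitochondrial poly(A)-tail sequencing): map anchor-ligated
  3'-end reads to an N-padded gene reference so non-templated ends align
  penalty-free, classify every molecule's 3' end relative to the tRNA
  discriminator base (DB = 0, CCA at +1..+3), and report per-gene end
  profiles, **percent extended beyond CCA** = 100 · extended / (mature +
  extended), extension composition, templated 16S ends, and the
  mt-tRNA-Tyr repair states.

Synthetic read generators (codon-stalling footprints; per-genotype 3'-end
extension models; cRT-PCR junction clones) emit machine-readable ground
truth, so every statistic can be validated by parameter recovery.  The
bundled reference annotation is a synthetic human-mtDNA-like emulation
(correct gene complement, layout, overlaps and codon-usage statistics;
simulated sequence — see `docs/methods.md`); a real NC_012920-style
GenBank/GFF3 annotation can be used instead anywhere.

The package is aimed at people building or sanity-checking mitochondrial
ribosome-profiling / 3'-end-sequencing pipelines, and at teaching the
corresponding analysis contracts with fully controlled inputs.

## Worked example

Simulate ~10^5 footprints with a 5× A-site dwell on the lysine codons
(the signature of a depleted aminoacylated mt-tRNA-Lys pool) and recover
the stall (`examples/stalling_recovery.py`):

```text
simulated 99962 footprints over 3635 codons
read fates: {'length': 20057, 'frame': 7770, 'near_stop': 795,
             'near_start': 1099, 'multimapped': 209, 'overlap_region': 214}
codon  occupancy  expected  n_reads
AAG        4.651     4.520     2325
AAA        4.491     4.526     5732
TAT        0.981     0.913     1259
GCG        0.979     0.912      465
```

AAA and AAG stand ~4.5× above the unit baseline — within sampling error
of the analytic expectation printed beside them — while every other codon
sits near 1.0.  The read-fate line is the QC accounting: every input read
is either rejected for a named reason or counted.

The 3'-end side (`examples/mpat_three_prime_ends.py`) compares a
PDE12-proficient control (WT) with the deadenylase knock-out (KO):

```text
WT: 16S modal 3' extension 4 nt (86% of molecules extended)
KO: 16S modal 3' extension 10 nt (89% of molecules extended)

tRNA    WT %ext  KO %ext
TK          8.7     87.8
TS2        14.4     55.5
TH          9.0     55.3
TW         14.2     37.7

KO vs WT over all 22 mt-tRNAs: t = -9.31, p = 9.16e-12 (Student t-test)
```

TK (mt-tRNA-Lys) shifts from ~9% to ~88% of CCA-complete molecules
carrying oligo(A) extensions (6–9 nt, essentially all A), and control 16S
ends show the characteristic 4–5 nt extensions.

Other examples: `examples/codon_usage.py` (Lys 2.5% / Ser(AGY) 1.4% of
the 3,791 coding triplets; 11 Lys codons in ND4, none in ND4L) and
`examples/crtpcr_tails.py` (poly(A) tails read from circularisation
RT-PCR junction clones; the 50 bp MPAT amplicon rule).

## Command line

```bash
mitostall codon-usage  --genome mt.fa --features mt.gff3 --out out/
mitostall simulate-ribo --genome mt.fa --features mt.gff3 --stall AAA=5 --stall AAG=5 --out sim/
mitostall ribo  --genome mt.fa --features mt.gff3 --reads sim/footprints.fastq --out ribo/
mitostall simulate-mpat --genome mt.fa --features mt.gff3 --genotype KO --out sim/
mitostall mpat  --genome mt.fa --features mt.gff3 --reads sim/mpat.fastq --out mpat/
mitostall crtpcr --genome mt.fa --features mt.gff3 --gene ND1 --clones clones.fasta --out crt/
```

All outputs are plain TSV/JSON; each run serialises its configuration and
a read-fate QC report into the output directory.

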