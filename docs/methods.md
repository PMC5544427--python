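# Methods

## Scope

`mitostall` implements two read-level analyses of human mitochondrial gene
expression and the simulators needed to validate them end to end:

1. **Mitoribosome profiling** — placement of ribosome-protected fragments
   (mtRPFs) on the 13 mtDNA-encoded mRNAs, A-site inference, and a
   per-codon-species occupancy statistic that quantifies ribosome stalling.
2. **MPAT-Seq** — classification of mt-tRNA and mt-rRNA 3' ends from
   anchor-ligated 3'-end sequencing reads mapped to an N-padded reference:
   discriminator-base-relative end profiles, the percent of CCA-complete
   molecules extended beyond the CCA, extension composition, detection of
   templated (alternative-processing) 16S ends, and the special
   mt-tRNA-Tyr 3'-end states.  The small calculus of the radioactive MPAT
   amplicon and circularisation RT-PCR junction parsing are included.

## Ribosome profiling model

A translating mitoribosome protects a ~31–35 nt mRNA fragment.  Reads are
mapped to the mature mRNA transcript sequences (not the genome) with a
best-match, maximum-two-mismatch contract.  For footprints whose 5' end
falls on the first position of a codon, the A-site codon is taken to be
read nucleotides 16–18; for 5' ends on the third codon position,
nucleotides 17–19.  These offsets are fixed parameters of the package
(`ASiteParams`), exposed for recalibration; they assume the offset
calibration performed against Lys-codon pause peaks in a
mt-tRNA-Lys-deleted line.  Only reads of length 31–35 nt in frame 1 or 3
are used for occupancy; frame-2 reads are rejected rather than shifted.

**Filters.** Reads with 5' ends within 15 nt of the start codon or 45 nt
of the stop codon are rejected (`near_start`/`near_stop`), multi-mapped
reads are rejected, and codons in CDS–CDS overlap regions (ATP8/ATP6,
ND4L/ND4) are excluded via a deterministic codon mask derived from the
annotation.  The mask and the read-level margins are mutually consistent:
a codon is masked when any 5' end generating it (3c−15 for frame 1,
3c−16 for frame 3) would fall inside a margin, so no unmasked codon is
partially observable.  A zero margin masks nothing — the mask encodes
margin-caused exclusions only, and the structurally unreachable first
five codons of each ORF are in practice always covered by the non-zero
default margins.

**Occupancy statistic.** Within each CDS, the per-codon A-site count
vector is scaled by its mean over the unmasked codons of that CDS, so a
uniformly translated gene has scaled density 1 everywhere.  The occupancy
of a codon species is the mean scaled density over all its unmasked
occurrences pooled across the examined CDSs ("summed … and downweighted
by the number of occurrences" read as division).  Two consequences define
the statistic's calibration: a stall-free library gives occupancy 1.0 for
every species (unit-mean null), and the statistic is invariant to
per-gene sequencing depth.  The denominator of the per-CDS scaling is the
number of unmasked codon positions, not nucleotides: densities are
defined per A-site codon and masked codons carry no valid counts.  A CDS
with no accepted footprints is excluded from pooling with a warning.

**Profiles.** Per-gene profiles are histograms of 5'-end positions
shifted by a fixed +17 nt (approximate A-site), smoothed with a 3-nt
running mean.  All mapped footprint lengths contribute to profiles; the
strict 31–35 nt/frame filter applies only to the occupancy statistic.
At vector edges the smoothing window shrinks to the available cells,
preserving vector length.

## Read mapping

Both mappers are exact, not heuristic: the combined target set is under
20 kb, so candidate placements are generated by pigeonhole seeding (with
≤ m mismatches, any m+1 disjoint read segments contain one exact segment)
and every candidate is verified directly.  Output is identical to an
exhaustive Hamming scan — the test suite asserts this against a
brute-force oracle — while handling ~10^4 reads/s.  Ties on mismatch
count break deterministically (lowest target index, forward strand first,
leftmost coordinate) and the winner is flagged multi-mapped.  Multi-mapped
reads are retained for per-gene 3'-end profiles but excluded from codon
occupancy, which needs unambiguous CDS assignment.

Alignments are ungapped.  With the discouraged-gap convention adopted
(gap open 7, extend 5, mismatch 6), a single 1-nt gap already costs more
than the two mismatches the acceptance bound allows, so a gapped
alignment can never beat the best ungapped one within that bound; the
gap parameters are retained in `MappingParams` for reporting.

**Padded 3'-end mapping.** Every tRNA/rRNA gene sequence is extended 3'
with 30 uncalled `N` positions that match any read base at zero penalty,
so reads carrying non-templated CCA/oligo(A) ends map in full.  Reads
must anchor ≥ 15 templated nt in the gene body (configurable; the anchor
minimum is a package choice, as anchor-trimming specifics are protocol
dependent); mismatches are counted on templated positions only.  Reads
whose extensions run past the pad are aligned to the pad end and flagged
(right-censored, length reported as a lower bound).

**Adapter trimming** removes the longest read suffix matching a prefix of
the adapter (3 nt exact seed, one tolerated mismatch per started 10 nt),
discarding reads at or below 20 nt.

## MPAT-Seq 3'-end classification

Read structure: 3' region of the gene + any non-templated nucleotides +
the reverse-complemented ligation anchor.  After anchor trimming and
padded mapping, the 3' end is classified positionally relative to the
discriminator base (DB = 0): `pre_DB`, `at_DB`, `within_CCA` (+1/+2),
`mature_CCA` (+3), `extended` (> +3, extension = bases past +3).  CCA is
positional, never a sequence search, so a templated 3' end that happens
to read "CCA" cannot masquerade as the non-templated addition.

`percent_extended_beyond_cca` = 100 × extended / (mature + extended);
pre-CCA intermediates are excluded from the denominator and reported
separately — the quantity is the fraction of CCA-complete molecules
carrying extensions.  It is computed per read (no UMI structure exists in
the protocol), and is invariant under read duplication.

**rRNAs** have no DB/CCA; the DB-analog is the annotated last nucleotide
and any overhang is an extension, except that 16S overhangs whose first
≥ 4 nt equal the 5' terminus of the immediately distal mt-tRNA-Leu(UUR)
are classified as templated (alternative processing, not adenylation) and
only the remainder counts as extension.  A match to a poly(A) downstream
prefix is `ambiguous` (indistinguishable from adenylation).  The 12S
3'-terminus convention is the annotation's last nucleotide (configurable;
its native ends are heterogeneous).

**mt-tRNA-Tyr** shares its discriminator-base adenosine with the 5' end
of mt-tRNA-Cys; processing predominantly yields Tyr(−1), repaired by DB
addition before CCA synthesis.  The state machine maps end position and
non-templated tail to {−1, −1A, −1ACCA, −1Aₙ, beyond-CCA-adenylated};
ends matching none of the canonical patterns (partial CCA, mixed tails)
fall into an explicit `other` state so the machine is total over every
end/extension combination reachable within the pad.

**Group comparison** uses the two-sample Student t-test with pooled
variance (Welch by flag).  Degenerate (zero-variance, equal-mean) input
returns t = 0, p = 1 and is flagged.

**Amplicon calculus**: the nested MPAT PCR product is 50 bp for an
exactly processed, unmodified 3' end; each non-templated nucleotide adds
1 bp.  **cRT-PCR parsing** finds the maximal clone prefix matching a
gene suffix (3' side) and the maximal remaining suffix matching the gene
prefix (5' side), requiring ≥ 12 templated nt each; the middle is the
tail.  When a poly(A) tail abuts a gene 5' end that begins with A the
split is intrinsically ambiguous; the convention maximises the 3' side
first.

## Synthetic data

The generators are first-class, tested code whose defaults are the
experimental conditions the analyses assume.

**Footprints** (`StallModel`): the A-site codon is sampled first with
probability proportional to its stall factor, then length and frame, and
the 5' end is back-computed — the generative model is the exact inverse
of the assignment rule, which is what makes parameter recovery a
meaningful acceptance surface.  Defaults: 80% of length mass uniform on
31–35 nt and 20% on 25–30 nt (so the length filter is exercised), frames
1/2/3 at 0.45/0.10/0.45, mismatch rate 0, coverage in mean footprints
per codon.  Sampling is restricted to codons where every frame's read
fits inside the transcript; the restriction lies strictly inside the
margin-masked zone, so unmasked codons are sampled without boundary bias
and the analytic expected occupancy (`expected_occupancy`) is exact.

**MPAT reads** (`ExtensionModel`): per-gene 3'-state distributions over
pre-CCA / mature / extended(k), extension composition P(A) = 0.95 with
the remainder spread over C/G/U, one anchor per read (the Spacer C3
modification is modelled only as "no concatemers"), constant `I` quality
strings (neither analysis uses qualities).  Genotype presets encode the
characteristic phenotypes: control 16S extensions of 4–5 nt and ~50%
of 16S ends carrying 4–5 templated nt of the downstream tRNA; the
deadenylase-knock-out (KO) preset shifting mt-tRNA-Lys to 6–9 nt all-A
extensions on most molecules and lengthening 16S extensions; poly(A)
polymerase overexpression raising extended fractions genome-wide, most
strongly on the KO background (where the mt-tRNA-Lys pre-CCA pool is
also shrunk, reflecting near-complete adenylation).  Per-tRNA baseline
fractions beyond those anchors are free parameters — per-tRNA extension
levels are typically observed only as gel profiles — chosen once as a
deterministic spread over 0.05–0.15 and documented here; they are not
fitted quantities.

**cRT-PCR clones**: gene 3' flank + normal(50, 8) poly(A) tail
(rounded, clipped at 0; mature mt-mRNA tails average 45–55 nt) + gene 5'
flank, with 20 nt flanks.

**Reference annotation.**  `synthetic_human_mito_annotation()` builds a
deterministic, clearly synthetic stand-in for the human mtDNA annotation:
the real gene complement (13 CDS, 22 tRNA, 2 rRNA), gene order, strands
and approximate lengths; the ATP8/ATP6 (46 nt) and ND4L/ND4 (7 nt) CDS
overlaps with both reading frames valid across the junctions; seven ORFs
with polyadenylation-completed stop codons; the 16S–tRNA-Leu(UUR)
adjacency; the Tyr/Cys shared discriminator base on the light strand; and
a codon composition constructed to the published codon-usage statistics
of the human mitochondrial ORFs (exactly 11 Lys codons in ND4, none in
ND4L, Lys = 2.5% and Ser(AGY) = 1.4% of the 3,791 coding triplets).  The
nucleotide sequence itself is simulated — analyses of sequence-level
biology beyond these constraints (e.g. real codon context, tRNA
structure) do not transfer.  `load_annotation` accepts a real
NC_012920-style GenBank or GFF3+FASTA annotation wherever the synthetic
one is used.

**What passing tests do and do not show.**  The simulators produce
error-free or low-error reads with exact read structure, no ligation or
PCR bias, no RT stops at modified nucleotides, and no rRNA contamination.
Closure of the pipelines on simulated data therefore demonstrates the
correctness of the computational contracts (mapping, assignment,
normalisation, classification, recovery of generative parameters), not
robustness to the library-preparation artefacts of real data — in
particular the known MPAT caveat that reverse transcription through
modified bases over-represents unmodified molecules.

## Numerical and degenerate-input conventions

- Internal coordinates 0-based half-open; user-facing coordinates
  1-based inclusive.
- Genetic code fixed to vertebrate mitochondrial (table 2); codon species
  are keyed by triplet, with amino-acid families (Lys, Ser(AGY)/(UCN),
  Leu(UUR)/(CUN), …) derived on top.  Codon frequencies are percentages
  of complete coding triplets over the 13 ORFs, stop codons included and
  polyadenylation-completed partial codons excluded.
- Aligner tie-break: (mismatches, target index, strand, leftmost).
- Smoothing at vector edges: window shrinks to available cells.
- Empty inputs: empty MPAT FASTQ yields empty outputs with QC flags; a
  gene profile with no DB-position reads keeps raw counts and flags the
  normalised profile undefined; an empty percent-extended denominator is
  an error (or `None` in non-strict mode).
- Every pipeline accounts for each input read exactly once (trimmed
  short / unmapped / rejected-by-reason / counted), asserted at run time.
- All randomness flows from a single integer seed per generator/run.

## Problem sizes used in the tests

The validation suite exercises the full transcriptome: null calibration
at coverage 100 per codon (~3.6 × 10^5 footprints), stall recovery at
~10^5 footprints, and MPAT closure at 10^4 reads per gene across three
genotype presets (~7 × 10^5 reads), each completing in tens of seconds.

## Known limitations

- No gapped alignment (see above); indel-bearing reads are unmapped.
- No quality-aware processing, spliced alignment, or genome-scale
  indexing; targets beyond ~10^5 nt would need a real aligner.
- A-site offsets are fixed parameters; the package does not re-derive
  them from pause peaks.
- Extensions longer than the 30 nt pad are right-censored.
- Occupancy requires unique mapping, so paralogous CDS regions beyond
  the two annotated overlaps would silently lose reads to the
  multi-mapped class (visible in QC).
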