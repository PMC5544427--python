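"""Codon usage of the mitochondrial ORFs under translation table 2.

Builds the package's human-mtDNA-like reference annotation (13 CDS,
22 tRNA, 2 rRNA), pools codons over the 13 ORFs and prints the family
frequencies that matter for stalling: lysine (AAA/AAG, decoded by
mt-tRNA-Lys) and Ser(AGY) (AGU/AGC, decoded by mt-tRNA-Ser(AGY)) — the
two mt-tRNAs most affected by spurious 3' adenylation.
"""

from mitostall import (
    codon_frequency_table,
    count_codon_occurrences,
    synthetic_human_mito_annotation,
)

ann = synthetic_human_mito_annotation()
table = codon_frequency_table(ann)

print(f"{table.total} coding triplets pooled over {len(ann.cds_names)} ORFs")
for family in ("Lys", "Ser(AGY)", "Leu(UUR)", "Trp"):
    print(f"  {family:<9} {table.group_count(family):>4} codons "
          f"({table.group_frequency(family):.1f}%)")

# the bicistronic ND4L/ND4 transcript: ND4L has no Lys codons at all,
# so only ND4 translation collapses when mt-tRNA-Lys is unavailable
for orf in ("ND4L", "ND4"):
    n = count_codon_occurrences(ann, orf, ["AAA", "AAG"])
    print(f"{orf}: {n} Lys codons")
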