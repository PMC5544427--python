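"""Ribosome-profiling round trip: simulate Lys-codon stalling, recover it.

Simulates ~100k mitoribosome footprints with a 5x A-site dwell on AAA/AAG
(the signature of a depleted aminoacylated mt-tRNA-Lys pool), runs the
full analysis — best-match mapping to the mRNA transcripts, 31-35 nt /
frame filtering, A-site assignment (read nt 16-18 or 17-19), per-CDS
scaling, per-species pooling — and compares the recovered occupancy with
the generative truth.  Occupancy 1.0 means no stalling; the Lys codons
should stand far above everything else.
"""

from mitostall import (
    RunConfig,
    StallModel,
    simulate_footprints,
    run_ribo_pipeline,
    synthetic_human_mito_annotation,
)

ann = synthetic_human_mito_annotation()
model = StallModel(stall_factors={"AAA": 5.0, "AAG": 5.0},
                   coverage=27.5, seed=11)
reads, truths, summary = simulate_footprints(ann, model)
print(f"simulated {len(reads)} footprints over {summary['n_sites']} codons")

result = run_ribo_pipeline(RunConfig(), annotation=ann, reads=reads)
occ = result.occupancy
print("read fates:", result.qc["read_fates"]["rejected"])

print(f"{'codon':<6}{'occupancy':>10}{'expected':>10}{'n_reads':>9}")
for codon in occ.top_codons(4):
    print(f"{codon:<6}{occ.occupancy[codon]:>10.3f}"
          f"{summary['expected_occupancy'][codon]:>10.3f}"
          f"{occ.n_reads[codon]:>9}")
print("(values near 1.0 = no stalling; AAA/AAG recover the simulated 5x dwell)")
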