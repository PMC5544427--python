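"""MPAT-Seq 3'-end profiling across genotypes.

Simulates anchor-ligated 3'-end reads for all 22 mt-tRNAs and both
mt-rRNAs under two genotype presets — a PDE12-proficient control (WT) and
the deadenylase knock-out (KO) — maps them to the N-padded reference and
classifies every molecule's 3' end relative to the tRNA discriminator
base (DB = 0, CCA at +1..+3).  Prints the percent of CCA-complete
molecules extended beyond the CCA for the most affected tRNAs, the 16S
rRNA extension mode, and the group comparison across all 22 tRNAs.
"""

from mitostall import (
    RunConfig,
    compare_groups,
    run_mpat_pipeline,
    simulate_mpat_reads,
    synthetic_human_mito_annotation,
)

ann = synthetic_human_mito_annotation()
trnas = [f.name for f in ann.features_of_kind("tRNA")]

pct = {}
for genotype in ("WT", "KO"):
    reads, _, _ = simulate_mpat_reads(ann, genotype=genotype, seed=17)
    res = run_mpat_pipeline(RunConfig(genotype_label=genotype),
                            annotation=ann, reads=reads)
    pct[genotype] = {r.gene: r.percent_extended
                     for r in res.summary.itertuples()}
    r2 = res.profiles["RNR2"]
    print(f"{genotype}: 16S modal 3' extension {r2.modal_extension} nt "
          f"({r2.percent_extended_beyond_cca:.0f}% of molecules extended)")

print(f"\n{'tRNA':<6}{'WT %ext':>9}{'KO %ext':>9}")
for gene in ("TK", "TS2", "TH", "TW"):
    print(f"{gene:<6}{pct['WT'][gene]:>9.1f}{pct['KO'][gene]:>9.1f}")

test = compare_groups([pct["WT"][g] for g in trnas],
                      [pct["KO"][g] for g in trnas])
print(f"\nKO vs WT over all 22 mt-tRNAs: t = {test['t']:.2f}, "
      f"p = {test['p']:.2e} (Student t-test)")
print("(TK = mt-tRNA-Lys: the KO shifts most of its molecules to 6-9 nt "
      "oligo(A) tails beyond the CCA)")
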