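import pytest

from mitostall import (
    build_overlap_exclusion_mask,
    synthetic_human_mito_annotation,
    toy_annotation,
)


@pytest.fixture(scope="session")
def human_ann():
    """The package's human-mtDNA-like reference emulation (synthetic)."""
    return synthetic_human_mito_annotation()


@pytest.fixture(scope="session")
def human_mask(human_ann):
    return build_overlap_exclusion_mask(human_ann)


@pytest.fixture()
def mini_ann():
    """Small fixture genome: 3 CDS, 4 tRNA, 1 rRNA (8 features)."""
    return toy_annotation(
        cds={
            "GENE1": "ATG" + "GCT" * 40 + "TAA",
            "GENE2": "ATG" + "AAA" * 5 + "CTT" * 35 + "TAA",
            "GENE3": "ATG" + "CAC" * 38 + "TA",  # polyA-completed stop
        },
        trna={
            "T1": "GCTAAACCTGTAGCTGGATTTACCGGCACTGAAGGGCTTAAGCTCTTACTTCTAGGTGGA",
            "T2": "GGGCCCATAGCTCAGTGGTAGAGCGCCTGCTTTGCACGCAGGAGGTCTGCGGTTCGATCC",
            "T3": "GTTTCCGTAGTGTAGTGGTTATCACGTTCGCCTCACACGCGAAAGGTCCCCGGTTCGAAA",
            "T4": "ACTTTTAAAGGATAACAGCTATCCATTGGTCTTAGGCCCCAAAAATTTTGGTGCAACTCC",
        },
        rrna={"R1": "GCCTTCCCCCGTAAATGATAT" * 10},
    )
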