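"""Annotation loading, codon statistics, exclusion masks, padded reference."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mitostall import (
    AnnotationError,
    Feature,
    MitoAnnotation,
    build_overlap_exclusion_mask,
    build_padded_reference,
    codon_frequency_table,
    count_codon_occurrences,
    extract_orf_codons,
    load_annotation,
    reverse_complement,
    toy_annotation,
    write_fasta,
    write_gff3,
)

# ---------------------------------------------------------------------------
# loading


def test_gff3_round_trip_preserves_features(mini_ann, tmp_path):
    fa, gff = tmp_path / "g.fa", tmp_path / "g.gff3"
    write_fasta(mini_ann, fa)
    write_gff3(mini_ann, gff)
    ann = load_annotation(fa, gff)
    assert len(ann.features) == 8
    assert ann.genome_sequence == mini_ann.genome_sequence
    for f in mini_ann.features:
        g = ann[f.name]
        assert (g.kind, g.start, g.end, g.strand) == (
            f.kind, f.start, f.end, f.strand
        )
        assert g.completion_by_polyadenylation == f.completion_by_polyadenylation


def test_human_like_reference_gene_complement(human_ann):
    assert len(human_ann.cds_names) == 13
    assert len(human_ann.features_of_kind("tRNA")) == 22
    assert len(human_ann.features_of_kind("rRNA")) == 2


def test_feature_beyond_genome_without_wrap_flag_rejected():
    with pytest.raises(AnnotationError, match="wrap"):
        MitoAnnotation(
            genome_sequence="ACGT" * 30,
            features=[Feature("X", "tRNA", start=100, end=130, strand="+")],
        )


def test_wrapping_feature_unwraps_across_origin():
    genome = "ATGAAATAA" + "C" * 91
    ann = MitoAnnotation(
        genome_sequence=genome,
        features=[Feature("W", "rRNA", start=95, end=106, strand="+", wraps=True)],
    )
    assert ann.transcript("W") == "CCCCCC" + "ATGAAA"


# ---------------------------------------------------------------------------
# codon extraction and counting


def test_extract_orf_codons_simple_frame_walk():
    ann = toy_annotation(cds={"X": "ATGAAATAA"})
    codons, partial = extract_orf_codons(ann, "X")
    assert codons == ["ATG", "AAA", "TAA"]
    assert partial is None


def test_partial_stop_codon_flagged_and_excluded():
    # length = 1 mod 3: the trailing templated T of a polyA-completed stop
    ann = toy_annotation(cds={"X": "ATGAAACCCT"})
    codons, partial = extract_orf_codons(ann, "X")
    assert codons == ["ATG", "AAA", "CCC"]
    assert partial == "T"
    assert count_codon_occurrences(ann, "X", ["AAA"]) == 1


def test_reverse_strand_codons_are_reverse_complemented():
    fwd = "ATGAAAGGCTAA"
    genome = "C" * 10 + reverse_complement(fwd) + "C" * 10
    ann = MitoAnnotation(
        genome_sequence=genome,
        features=[Feature("R", "CDS", start=11, end=10 + len(fwd), strand="-")],
    )
    codons, _ = extract_orf_codons(ann, "R")
    assert codons == ["ATG", "AAA", "GGC", "TAA"]
    # composing the extraction with itself is the identity on the sequence
    assert reverse_complement(reverse_complement(fwd)) == fwd


def test_count_codon_occurrences_contracts(mini_ann):
    assert count_codon_occurrences(mini_ann, "GENE2", ["AAA", "AAG"]) == 5
    assert count_codon_occurrences(mini_ann, "GENE1", ["AAA"]) == 0
    with pytest.raises(AnnotationError):
        count_codon_occurrences(mini_ann, "GENE1", ["AAXA"])
    with pytest.raises(KeyError):
        count_codon_occurrences(mini_ann, "NOPE", ["AAA"])


@settings(derandomize=True, max_examples=30)
@given(st.lists(st.sampled_from(["GCT", "AAA", "AAG", "CAT", "TGG"]),
                min_size=2, max_size=40))
def test_codon_count_additivity(body):
    """Count over a codon set equals the sum of per-codon counts, checked
    against a brute-force scan of the frame walk."""
    seq = "ATG" + "".join(body) + "TAA"
    ann = toy_annotation(cds={"X": seq})
    group = ["AAA", "AAG"]
    total = count_codon_occurrences(ann, "X", group)
    assert total == sum(count_codon_occurrences(ann, "X", [c]) for c in group)
    brute = sum(
        1 for i in range(0, len(seq) - 2, 3) if seq[i : i + 3] in group
    )
    assert total == brute


# ---------------------------------------------------------------------------
# codon usage


def test_codon_frequencies_normalise_to_100(human_ann):
    table = codon_frequency_table(human_ann)
    assert np.isclose(sum(table.frequencies.values()), 100.0)
    assert table.total == sum(table.counts.values())


def test_codon_frequencies_invariant_under_genome_rotation(human_ann):
    shift = 400  # within the non-coding region at the origin
    g = human_ann.genome_sequence
    rotated = MitoAnnotation(
        genome_sequence=g[shift:] + g[:shift],
        features=[
            Feature(
                f.name, f.kind, f.start - shift, f.end - shift, f.strand,
                f.db_offset, f.completion_by_polyadenylation,
            )
            for f in human_ann.features
        ],
    )
    t1 = codon_frequency_table(human_ann)
    t2 = codon_frequency_table(rotated)
    assert t1.counts == t2.counts


def test_empty_annotation_has_no_codon_table():
    ann = toy_annotation(trna={"T": "ACGTACGTACGTACGTACGT"})
    with pytest.raises(AnnotationError, match="no CDS"):
        codon_frequency_table(ann)


# ---------------------------------------------------------------------------
# exclusion mask


def _brute_force_mask(ann, start_margin, stop_margin):
    """Interval-arithmetic oracle for the exclusion mask."""
    out = {}
    cds = ann.features_of_kind("CDS")
    for f in cds:
        n = f.length // 3
        mask = np.zeros(n, dtype=bool)
        for c in range(n):
            ends = [3 * c - 15, 3 * c - 16]
            if start_margin > 0 and min(ends) < start_margin:
                mask[c] = True
            if stop_margin > 0 and max(ends) >= f.length - stop_margin:
                mask[c] = True
            if f.strand == "+":
                lo, hi = f.start0 + 3 * c, f.start0 + 3 * c + 3
            else:
                hi = f.end0 - 3 * c
                lo = hi - 3
            for g in cds:
                if g.name != f.name and lo < g.end0 and g.start0 < hi:
                    mask[c] = True
        out[f.name] = mask
    return out


def test_zero_margins_and_no_overlap_give_empty_mask():
    ann = toy_annotation(cds={"X": "ATG" + "GCT" * 30 + "TAA"})
    mask = build_overlap_exclusion_mask(ann, 0, 0)
    assert not mask.masks["X"].any()


def test_overlapping_cds_masked_on_both_sides():
    # two CDS overlapping by 12 nt on the genome
    a = "ATG" + "GCA" * 20 + "TCCCTATTATAA"  # last 12 nt start GENE_B
    b = "TCCCTATTATAA" + "GCC" * 20 + "TGA"
    genome = "G" * 10 + a + b[12:] + "G" * 10
    ann = MitoAnnotation(
        genome_sequence=genome,
        features=[
            Feature("A", "CDS", 11, 10 + len(a), "+"),
            Feature("B", "CDS", 10 + len(a) - 11, 10 + len(a) - 12 + len(b), "+"),
        ],
    )
    mask = build_overlap_exclusion_mask(ann, 0, 0)
    n_a, n_b = len(a) // 3, len(b) // 3
    assert list(np.flatnonzero(mask.masks["A"])) == [n_a - 4, n_a - 3, n_a - 2, n_a - 1]
    assert list(np.flatnonzero(mask.masks["B"])) == [0, 1, 2, 3]
    assert mask.reasons["A"][n_a - 1] == "overlap_region"


def test_nd4l_nd4_masked_region_matches_annotated_overlap(human_ann, human_mask):
    nd4l, nd4 = human_ann["ND4L"], human_ann["ND4"]
    overlap_nt = nd4l.end - nd4.start + 1
    assert overlap_nt == 7
    over_idx = [
        i
        for i, why in human_mask.reasons["ND4"].items()
        if why == "overlap_region"
    ]
    # ND4 codons genomically inside ND4L: indices 0..ceil(7/3)-1
    assert over_idx == [0, 1, 2]
    over_idx_l = [
        i
        for i, why in human_mask.reasons["ND4L"].items()
        if why == "overlap_region"
    ]
    assert over_idx_l == [96, 97, 98]


def test_mask_matches_interval_oracle_on_random_annotations():
    rng = np.random.default_rng(5)
    for _ in range(25):
        n1 = int(rng.integers(40, 90))
        n2 = int(rng.integers(40, 90))
        ann = toy_annotation(
            cds={
                "A": "ATG" + "GCT" * n1 + "TAA",
                "B": "ATG" + "CAT" * n2 + "TAA",
            },
            spacer=int(rng.integers(5, 40)),
        )
        sm, tm = int(rng.integers(0, 20)), int(rng.integers(0, 50))
        mask = build_overlap_exclusion_mask(ann, sm, tm)
        brute = _brute_force_mask(ann, sm, tm)
        for name in ("A", "B"):
            assert np.array_equal(mask.masks[name], brute[name]), (name, sm, tm)


def test_margins_exceeding_cds_mask_everything_with_warning():
    ann = toy_annotation(cds={"X": "ATG" + "GCT" * 10 + "TAA"})
    with pytest.warns(UserWarning, match="whole CDS"):
        mask = build_overlap_exclusion_mask(ann, 30, 30)
    assert mask.masks["X"].all()


# ---------------------------------------------------------------------------
# padded reference


def test_padded_reference_geometry(human_ann):
    seq69 = "G" * 69
    ann = toy_annotation(trna={"T69": seq69})
    padded = build_padded_reference(ann, 30)
    assert len(padded["T69"]) == 99
    assert padded["T69"].endswith("N" * 30)
    with pytest.raises(AnnotationError):
        build_padded_reference(ann, 0)
    # constructor property over the full reference gene set
    ref = build_padded_reference(human_ann, 30)
    assert len(ref) == 24  # 22 tRNA + 2 rRNA; no CDS
    for name, seq in ref.items():
        assert seq.endswith("N" * 30)
        assert "N" not in seq[:-30]
        assert seq[:-30] == human_ann.transcript(name)


def test_genbank_annotation_loads(mini_ann, tmp_path):
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio.SeqFeature import SeqFeature, SimpleLocation
    from Bio import SeqIO

    rec = SeqRecord(
        Seq(mini_ann.genome_sequence), id="MTSYN1", name="MTSYN1",
        description="synthetic test genome",
        annotations={"molecule_type": "DNA", "topology": "circular"},
    )
    for f in mini_ann.features:
        rec.features.append(
            SeqFeature(
                SimpleLocation(f.start0, f.end0, 1 if f.strand == "+" else -1),
                type=f.kind,
                qualifiers={"gene": [f.name]},
            )
        )
    gb = tmp_path / "mt.gb"
    SeqIO.write(rec, gb, "genbank")
    ann = load_annotation(gb, gb)
    assert len(ann.features) == 8
    assert ann.genome_sequence == mini_ann.genome_sequence
    g3 = ann["GENE3"]
    assert g3.completion_by_polyadenylation  # inferred from length % 3
    assert ann.transcript("GENE1") == mini_ann.transcript("GENE1")
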