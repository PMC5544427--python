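"""3'-end classification, profiles, percent-extended, Tyr states, cRT-PCR."""

import itertools
import math

import numpy as np
import pytest

from mitostall import (
    EndState,
    MappingParams,
    ThreePrimeCall,
    TyrState,
    amplicon_length,
    build_padded_reference,
    classify_three_prime_end,
    classify_tyr_state,
    compare_groups,
    detect_templated_overlap,
    end_profile_relative_to_db,
    extension_composition,
    gene_end_model,
    map_to_padded_reference,
    parse_crtpcr_junction,
    percent_extended_beyond_cca,
    simulate_crtpcr_clones,
)
from mitostall.mpat import CrtPcrParseError


@pytest.fixture(scope="module")
def ref(human_ann):
    return build_padded_reference(human_ann, 30)


def _call(human_ann, ref, gene, tail, body_nt=25, trim_db=0):
    """Map a constructed read (gene 3' body + non-templated tail) and
    classify its 3' end."""
    t = human_ann.transcript(gene)
    body = t[: len(t) - trim_db][-body_nt:]
    aln = map_to_padded_reference("r", body + tail, ref)
    assert aln is not None and aln.target == gene
    return classify_three_prime_end(aln, gene_end_model(human_ann, gene))


class TestClassify:
    def test_mature_cca_end(self, human_ann, ref):
        c = _call(human_ann, ref, "TK", "CCA")
        assert c.state is EndState.MATURE_CCA
        assert c.end_position_relative_to_db == 3
        assert c.extension_length == 0

    def test_six_nt_adenylate_extension(self, human_ann, ref):
        c = _call(human_ann, ref, "TK", "CCAAAAAAA")
        assert c.state is EndState.EXTENDED
        assert c.extension_length == 6
        assert c.extension_sequence == "AAAAAA"

    def test_end_exactly_at_discriminator_base(self, human_ann, ref):
        c = _call(human_ann, ref, "TK", "")
        assert c.state is EndState.AT_DB
        assert c.end_position_relative_to_db == 0

    def test_end_within_cca(self, human_ann, ref):
        c = _call(human_ann, ref, "TK", "CC")
        assert c.state is EndState.WITHIN_CCA

    def test_end_before_db(self, human_ann, ref):
        c = _call(human_ann, ref, "TK", "", trim_db=2)
        assert c.state is EndState.PRE_DB
        assert c.end_position_relative_to_db == -2

    def test_16s_four_nt_extension(self, human_ann, ref):
        c = _call(human_ann, ref, "RNR2", "AAAA")
        assert c.kind == "rRNA"
        assert c.state is EndState.EXTENDED
        assert c.extension_length == 4
        assert c.templated == "no"

    def test_16s_templated_overlap_detected(self, human_ann, ref):
        # downstream tRNA-Leu(UUR) starts GTTAAG
        c = _call(human_ann, ref, "RNR2", "GTTAA")
        assert c.templated == "yes"
        assert c.state is EndState.AT_DB  # alternative processing, no extension
        assert c.extension_length == 0

    def test_16s_templated_prefix_plus_adenylation(self, human_ann, ref):
        c = _call(human_ann, ref, "RNR2", "GTTAAAAAA")
        assert c.templated == "yes"
        assert c.state is EndState.EXTENDED
        assert c.extension_sequence == "AAAA"


class TestEndProfile:
    def _calls(self, human_ann, ref, spec):
        out = []
        for tail, n in spec:
            out.extend(_call(human_ann, ref, "TK", tail) for _ in range(n))
        return out

    def test_counts_normalised_to_db(self, human_ann, ref):
        calls = self._calls(human_ann, ref, [("", 4), ("CCA", 8), ("CCAAA", 2)])
        prof = end_profile_relative_to_db(calls)
        assert prof.counts == {0: 4, 3: 8, 5: 2}
        assert prof.normalized[0] == 1.0
        assert prof.normalized[3] == 2.0
        assert prof.db_count == 4

    def test_no_db_reads_flags_normalisation_undefined(self, human_ann, ref):
        calls = self._calls(human_ann, ref, [("CCA", 5)])
        prof = end_profile_relative_to_db(calls)
        assert prof.normalized is None
        assert prof.counts == {3: 5}

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            end_profile_relative_to_db([])

    def test_modal_extension(self, human_ann, ref):
        calls = self._calls(
            human_ann, ref, [("CCA" + "A" * 7, 6), ("CCA" + "A" * 3, 2)]
        )
        assert end_profile_relative_to_db(calls).modal_extension == 7


class TestPercentExtended:
    def test_no_extension_is_zero_percent(self, human_ann, ref):
        calls = [_call(human_ann, ref, "TK", "CCA") for _ in range(100)]
        assert percent_extended_beyond_cca(calls) == 0.0

    def test_seventy_thirty_split(self, human_ann, ref):
        calls = [_call(human_ann, ref, "TK", "CCA") for _ in range(70)]
        calls += [_call(human_ann, ref, "TK", "CCAAAA") for _ in range(30)]
        assert percent_extended_beyond_cca(calls) == pytest.approx(30.0)

    def test_pre_cca_molecules_not_in_denominator(self, human_ann, ref):
        calls = [_call(human_ann, ref, "TK", "CCA"),
                 _call(human_ann, ref, "TK", "CCAA")]
        calls += [_call(human_ann, ref, "TK", "") for _ in range(50)]
        assert percent_extended_beyond_cca(calls) == pytest.approx(50.0)

    def test_invariant_under_read_duplication(self, human_ann, ref):
        base = [_call(human_ann, ref, "TK", "CCA") for _ in range(3)]
        base += [_call(human_ann, ref, "TK", "CCAAA") for _ in range(2)]
        assert percent_extended_beyond_cca(base) == pytest.approx(
            percent_extended_beyond_cca(base * 7)
        )

    def test_empty_denominator_raises_or_flags(self, human_ann, ref):
        calls = [_call(human_ann, ref, "TK", "")]
        with pytest.raises(ValueError):
            percent_extended_beyond_cca(calls)
        assert percent_extended_beyond_cca(calls, strict=False) is None


class TestComposition:
    def test_all_a_extensions(self, human_ann, ref):
        calls = [_call(human_ann, ref, "TK", "CCAAAAA") for _ in range(5)]
        df = extension_composition(calls)
        assert np.allclose(df["A"], 1.0)
        assert df.attrs["overall_A_fraction"] == 1.0
        assert list(df.index) == [1, 2, 3, 4]

    def test_mixed_final_position(self, human_ann, ref):
        calls = [_call(human_ann, ref, "TK", "CCAAAAA") for _ in range(4)]
        calls += [_call(human_ann, ref, "TK", "CCAAAAC") for _ in range(4)]
        df = extension_composition(calls)
        assert df.loc[4, "A"] == pytest.approx(0.5)
        assert df.loc[4, "C"] == pytest.approx(0.5)
        assert df.loc[1, "A"] == 1.0


class TestTemplatedOverlap:
    def test_non_a_four_mer_match_is_templated(self):
        assert detect_templated_overlap("GTTA", "GTTAAG") == "yes"

    def test_poly_a_extension_not_templated_when_downstream_differs(self):
        assert detect_templated_overlap("AAAAA", "GTTAAG") == "no"

    def test_match_to_poly_a_downstream_is_ambiguous(self):
        assert detect_templated_overlap("AAAA", "AAAAGC") == "ambiguous"

    def test_short_match_is_not_templated(self):
        assert detect_templated_overlap("GTT", "GTTAAG") == "no"

    def test_missing_downstream_is_an_error(self):
        with pytest.raises(ValueError):
            detect_templated_overlap("GTTA", "")


@pytest.fixture(scope="module")
def tyr(human_ann):
    return gene_end_model(human_ann, "TY")


class TestTyrStateMachine:
    def _tyr_call(self, human_ann, ref, tail):
        # the processed Tyr molecule ends one base short of the DB
        return _call(human_ann, ref, "TY", tail, trim_db=1)

    def test_processed_end_is_minus1(self, human_ann, ref, tyr):
        c = self._tyr_call(human_ann, ref, "")
        assert c.end_position_relative_to_db == -1
        assert classify_tyr_state(c, tyr) is TyrState.MINUS1

    def test_repaired_db_only(self, human_ann, ref, tyr):
        c = self._tyr_call(human_ann, ref, "A")
        assert classify_tyr_state(c, tyr) is TyrState.MINUS1_A

    def test_mature_minus1_acca(self, human_ann, ref, tyr):
        c = self._tyr_call(human_ann, ref, "ACCA")
        assert classify_tyr_state(c, tyr) is TyrState.MINUS1_ACCA

    def test_adenylated_beyond_cca(self, human_ann, ref, tyr):
        c = self._tyr_call(human_ann, ref, "ACCAAAA")
        assert classify_tyr_state(c, tyr) is TyrState.BEYOND_CCA

    def test_oligo_a_without_cca(self, human_ann, ref, tyr):
        c = self._tyr_call(human_ann, ref, "AAAA")
        assert classify_tyr_state(c, tyr) is TyrState.MINUS1_AN

    def test_non_tyr_call_rejected(self, human_ann, ref, tyr):
        c = _call(human_ann, ref, "TK", "CCA")
        with pytest.raises(ValueError):
            classify_tyr_state(c, tyr)

    def test_exhaustive_enumeration_is_total_and_deterministic(self, tyr):
        """Every end/extension combination reachable within the pad maps to
        exactly one state, stably."""
        combos = [(-2, ""), (-1, ""), (0, "")]
        for k in range(1, 5):
            for tail in itertools.product("ACGT", repeat=k):
                combos.append((k, "".join(tail)))
        for k in range(5, 31):  # canonical long tails up to the pad
            combos.append((k, "A" * k))
            combos.append((k, "CCA" + "A" * (k - 3)))
        seen = {}
        for rel, tail in combos:
            call = ThreePrimeCall(
                read_id="r", gene="TY", kind="tRNA",
                end_position_relative_to_db=rel,
                state=EndState.EXTENDED if rel > 3 else EndState.AT_DB,
                extension_length=max(0, rel - 3),
                extension_sequence=tail[3:] if rel > 3 else "",
                post_db_sequence=tail,
            )
            s1 = classify_tyr_state(call, tyr)
            s2 = classify_tyr_state(call, tyr)
            assert isinstance(s1, TyrState)
            assert s1 is s2
            seen[(rel, tail)] = s1
        # the five canonical patterns are all reachable
        assert set(seen.values()) >= {
            TyrState.MINUS1, TyrState.MINUS1_A, TyrState.MINUS1_ACCA,
            TyrState.MINUS1_AN, TyrState.BEYOND_CCA, TyrState.OTHER,
        }


class TestAmplicon:
    def test_unmodified_end_gives_50_bp(self):
        assert amplicon_length(0) == 50

    def test_each_extension_nt_adds_one_bp(self):
        assert amplicon_length(6) == 56

    def test_negative_extension_rejected(self):
        with pytest.raises(ValueError):
            amplicon_length(-1)


class TestCrtPcr:
    def test_constructed_clone_parses_exactly(self, human_ann):
        t = human_ann.transcript("ND1")
        clone = t[-20:] + "A" * 50 + t[:20]
        k3, k5, tail_len, tail = parse_crtpcr_junction(clone, t)
        assert (k3, k5, tail_len) == (20, 20, 50)
        assert tail == "A" * 50

    def test_zero_tail_junction(self, human_ann):
        t = human_ann.transcript("ND1")
        k3, k5, tail_len, tail = parse_crtpcr_junction(t[-20:] + t[:20], t)
        assert tail_len == 0 and tail == ""

    def test_random_sequence_fails_to_parse(self, human_ann):
        with pytest.raises(CrtPcrParseError):
            parse_crtpcr_junction("ACGT" * 20, human_ann.transcript("ND1"))

    def test_simulated_clone_set_round_trips(self, human_ann):
        clones, truths = simulate_crtpcr_clones(
            human_ann, "COII", n=200, tail_mean=50, tail_sd=8, seed=2
        )
        t = human_ann.transcript("COII")
        for (cid, seq), tr in zip(clones, truths):
            _, _, tail_len, _ = parse_crtpcr_junction(seq, t)
            assert tail_len == tr["tail_length"]


class TestCompareGroups:
    def test_identical_groups(self):
        res = compare_groups([5.0, 5.0, 5.0], [5.0, 5.0, 5.0])
        assert res["t"] == 0.0 and res["p"] == 1.0
        assert res["degenerate_variance"]

    def test_matches_closed_form_pooled_t(self):
        # A={1,2,3}, B={4,5,6}: pooled variance 1, se = sqrt(2/3),
        # t = -3/sqrt(2/3) = -3.6742, df = 4, p = 0.021312
        res = compare_groups([1, 2, 3], [4, 5, 6])
        assert res["t"] == pytest.approx(-3.674234614, rel=1e-6)
        assert res["p"] == pytest.approx(0.0213, abs=2e-4)
        assert res["summary"]["A"]["median"] == 2.0

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            compare_groups([1.0], [2.0, 3.0])
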