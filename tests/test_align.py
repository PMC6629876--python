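import numpy as np
import pytest
from Bio import Align
from hypothesis import given, settings, strategies as st

from cdgmine.align import (
    AlignmentParams,
    global_align,
    local_align,
    map_reference_positions,
)

from oracles import bruteforce_global_score, bruteforce_local_score

short_seq = st.text(alphabet="ARND", min_size=1, max_size=6)


def test_identical_triplet_scores_sum_of_diagonal():
    # BLOSUM62 diagonal: A=4, R=5, N=6
    res = global_align("ARN", "ARN")
    assert res.score == 15.0
    assert res.identity_percent == 100.0


def test_self_alignment_identity_map():
    seq = "MKVLDARNDCE"
    res = global_align(seq, seq)
    assert res.identity_percent == 100.0
    assert res.column_map == {i: i for i in range(1, len(seq) + 1)}


@given(short_seq, short_seq)
def test_global_score_equals_bruteforce_enumeration(q, s):
    assert global_align(q, s).score == pytest.approx(bruteforce_global_score(q, s))


@settings(max_examples=30)
@given(short_seq, short_seq)
def test_local_score_equals_bruteforce_enumeration(q, s):
    assert local_align(q, s).score == pytest.approx(bruteforce_local_score(q, s))


@given(st.text(alphabet="ARNDCQEGH", min_size=1, max_size=12),
       st.text(alphabet="ARNDCQEGH", min_size=1, max_size=12))
def test_global_score_symmetry(a, b):
    assert global_align(a, b).score == global_align(b, a).score


@given(st.text(alphabet="ARNDCQEGH", min_size=1, max_size=10),
       st.text(alphabet="ARNDCQEGH", min_size=1, max_size=10),
       st.text(alphabet="ARNDCQEGH", min_size=1, max_size=4))
def test_appending_identical_suffix_never_decreases_global_score(a, b, suffix):
    assert global_align(a + suffix, b + suffix).score >= global_align(a, b).score


def test_local_alignment_extracts_embedded_match():
    res = local_align("ARND", "XXARNDXX")
    assert res.query_aligned == "ARND" and res.subject_aligned == "ARND"
    assert res.identity_percent == 100.0
    assert res.subject_start == 3


def test_local_all_negative_pairs_empty_alignment():
    # BLOSUM62 W/P = -4: no positive-scoring cell exists.
    res = local_align("WWW", "PPP")
    assert res.score == 0.0
    assert res.query_aligned == "" and res.column_map == {}


def test_empty_sequence_is_an_error():
    with pytest.raises(ValueError):
        global_align("", "ARN")
    with pytest.raises(ValueError):
        local_align("ARN", "")


def test_global_degapped_strings_equal_inputs():
    rng = np.random.default_rng(3)
    aa = list("ACDEFGHIKLMNPQRSTVWY")
    for _ in range(10):
        q = "".join(rng.choice(aa, size=rng.integers(5, 40)))
        s = "".join(rng.choice(aa, size=rng.integers(5, 40)))
        res = global_align(q, s)
        assert res.query_aligned.replace("-", "") == q
        assert res.subject_aligned.replace("-", "") == s


def test_scores_match_biopython_pairwise_aligner():
    """Independent cross-check against Biopython's exact aligner under the
    same gap convention (first gap residue pays the opening penalty)."""
    mat = Align.substitution_matrices.load("BLOSUM62")
    checks = []
    for mode in ("global", "local"):
        a = Align.PairwiseAligner()
        a.substitution_matrix = mat
        a.open_gap_score = -10
        a.extend_gap_score = -1
        a.mode = mode
        checks.append(a)
    rng = np.random.default_rng(11)
    aa = list("ACDEFGHIKLMNPQRSTVWY")
    for _ in range(15):
        q = "".join(rng.choice(aa, size=rng.integers(10, 70)))
        s = "".join(rng.choice(aa, size=rng.integers(10, 70)))
        assert global_align(q, s).score == pytest.approx(checks[0].score(q, s))
        assert local_align(q, s).score == pytest.approx(checks[1].score(q, s))


def test_map_positions_self_alignment():
    seq = "MKVLDARND"
    res = global_align(seq, seq)
    mapped = map_reference_positions(res, [3, 5])
    assert mapped == {3: (3, "V"), 5: (5, "D")}


def test_map_positions_deletion_yields_gap():
    subject = "MKVLDARNDCEQGH"
    query = subject[:4] + subject[8:]  # residues 5-8 deleted
    res = global_align(query, subject)
    mapped = map_reference_positions(res, [6])
    assert mapped[6] == (None, None)


def test_map_positions_substitution_maps_in_place():
    subject = "MKVLDARNDCEQGH"
    query = subject[:6] + "W" + subject[7:]  # position 7 mutated, no indels
    res = global_align(query, subject)
    mapped = map_reference_positions(res, [7, 9])
    assert mapped[7] == (7, "W")
    assert mapped[9] == (9, subject[8])


def test_map_positions_out_of_range_errors():
    res = global_align("ARN", "ARN")
    with pytest.raises(ValueError):
        map_reference_positions(res, [4])


def test_gap_penalties_must_be_nonnegative():
    with pytest.raises(ValueError):
        AlignmentParams(gap_open=-1)
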