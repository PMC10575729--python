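"""m1/m2 scoring semantics, site calling, context extraction and the
PFM/IUPAC consensus, with brute-force oracles and range properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from m6amseq import (
    LibraryRole,
    Peak,
    SiteCall,
    call_sites,
    consensus_motif,
    extract_context,
    score_position,
)
from conftest import make_tracks

R = LibraryRole


def test_unmodified_position_scores_zero():
    assert score_position(0, 100, 100.0, 100.0) == (0.0, 0.0, 0.0)


def test_complete_fto_depletion():
    m1, m2, score = score_position(30, 100, 0.0, 100.0)
    assert (m1, m2, score) == (0.3, 1.0, 0.3)


def test_zero_depth_yields_zero_not_error():
    assert score_position(0, 0, 0.0, 0.0) == (0.0, 0.0, 0.0)


def test_negative_m2_clamped_to_zero():
    m1, m2, score = score_position(10, 100, 150.0, 100.0)
    assert m2 == 0.0 and score == 0.0


def test_start_exceeding_depth_raises():
    with pytest.raises(ValueError):
        score_position(10, 5, 0.0, 5.0)


@pytest.mark.parametrize("combiner,expected", [
    ("product", 0.5 * 0.8), ("min", 0.5), ("mean", 0.65),
])
def test_combiner_rules(combiner, expected):
    _, _, score = score_position(50, 100, 20.0, 100.0, combiner=combiner)
    assert score == pytest.approx(expected)


@settings(deadline=None, max_examples=100)
@given(
    depth=st.integers(min_value=0, max_value=1000),
    start_frac=st.floats(min_value=0, max_value=1),
    dminus=st.floats(min_value=0, max_value=1e4),
    dplus=st.floats(min_value=0, max_value=1e4),
)
def test_scores_always_in_unit_interval_and_monotone(depth, start_frac, dminus, dplus):
    start = int(depth * start_frac)
    m1, m2, score = score_position(start, depth, dplus, dminus)
    assert 0.0 <= m1 <= 1.0 and 0.0 <= m2 <= 1.0 and 0.0 <= score <= 1.0
    # product combiner is monotone in each component
    if depth > 0 and start < depth:
        m1b, _, score_b = score_position(depth, depth, dplus, dminus)
        assert m1b >= m1 and score_b >= score


def _site_tracks(seq_len=60, lib=1_000_000):
    """FTO- IP pileup at position 5: depth 100, 80 starts; FTO+ depth 20."""
    dm = np.full(seq_len, 100)
    sm = np.zeros(seq_len, dtype=int)
    sm[5] = 80
    dp = np.full(seq_len, 100)
    dp[5] = 20
    return make_tracks(
        length=seq_len,
        depth={R.M6A_IP_FTO_MINUS: dm, R.M6A_IP_FTO_PLUS: dp, R.INPUT: dm},
        start_count={R.M6A_IP_FTO_MINUS: sm},
        library_size=lib,
    )


def test_call_sites_scores_every_qualifying_adenosine():
    tracks = _site_tracks()
    seq = "C" * 60
    seq = seq[:5] + "A" + seq[6:10] + "A" + seq[11:]  # A at 5 and 10
    peaks = [Peak("tx", 0, 30, 5, 3.0, 0.5, True)]
    sites = call_sites(peaks, tracks, {"tx": seq}, min_score=0.0)
    assert [s.position for s in sites] == [5, 10]
    by_pos = {s.position: s for s in sites}
    assert by_pos[5].m1 == pytest.approx(0.8)
    assert by_pos[5].m2 == pytest.approx(0.8)
    assert by_pos[5].score == pytest.approx(0.64)
    assert by_pos[10].score == 0.0
    # threshold removes the background adenosine
    sites = call_sites(peaks, tracks, {"tx": seq}, min_score=0.1)
    assert [s.position for s in sites] == [5]


def test_peak_without_adenosine_yields_no_sites():
    tracks = _site_tracks()
    peaks = [Peak("tx", 0, 30, 5, 3.0, 0.5, True)]
    assert call_sites(peaks, tracks, {"tx": "C" * 60}) == []


def test_min_site_depth_gates_low_coverage_positions():
    tracks = _site_tracks()
    seq = "C" * 5 + "A" + "C" * 54
    peaks = [Peak("tx", 0, 30, 5, 3.0, 0.5, True)]
    assert call_sites(peaks, tracks, {"tx": seq}, min_site_depth=101) == []


def test_scoring_is_local_to_the_peak():
    """Altering tracks outside a peak does not change calls inside it."""
    tracks = _site_tracks()
    seq = "C" * 5 + "A" + "C" * 54
    peaks = [Peak("tx", 0, 30, 5, 3.0, 0.5, True)]
    before = call_sites(peaks, tracks, {"tx": seq}, min_score=0.0)
    tracks["tx"].depth[R.M6A_IP_FTO_MINUS][40:] = 9999
    tracks["tx"].depth[R.M6A_IP_FTO_PLUS][40:] = 1
    after = call_sites(peaks, tracks, {"tx": seq}, min_score=0.0)
    assert before == after


def test_uracil_sequences_accepted():
    tracks = _site_tracks()
    seq = ("C" * 5 + "A" + "C" * 54).replace("C", "U")
    peaks = [Peak("tx", 0, 30, 5, 3.0, 0.5, True)]
    sites = call_sites(peaks, tracks, {"tx": seq}, min_score=0.0)
    assert [s.position for s in sites] == [5]


def test_sequence_shorter_than_model_raises():
    tracks = _site_tracks()
    peaks = [Peak("tx", 0, 30, 5, 3.0, 0.5, True)]
    with pytest.raises(ValueError):
        call_sites(peaks, tracks, {"tx": "ACGT"})
    with pytest.raises(KeyError):
        call_sites(peaks, tracks, {"other": "A" * 60})


def test_context_extraction_and_edge_padding():
    seq = "ACGT" * 20
    ctx = extract_context(seq, 30)
    assert len(ctx) == 30
    assert ctx[14] == seq[30]
    assert ctx == seq[16:46]
    edge = extract_context(seq, 0)
    assert edge.startswith("N" * 14)
    assert edge[14] == seq[0]
    tail = extract_context(seq, 79)
    assert tail.endswith("N" * 15)


def _mk_site(context):
    return SiteCall("t", 0, 14, "A", 1.0, 1.0, 1.0, context)


def test_identical_contexts_give_unit_pfm_and_that_consensus():
    ctx = "ACGTACGTACGTACGTACGTACGTACGTAC"
    motif = consensus_motif([_mk_site(ctx)] * 7)
    assert motif.n_sites == 7
    assert motif.consensus == ctx
    assert np.allclose(motif.pfm.sum(axis=0), 1.0)
    assert set(np.unique(motif.pfm)) == {0.0, 1.0}


def test_empty_site_list_gives_sentinel():
    motif = consensus_motif([])
    assert motif.n_sites == 0 and motif.consensus == ""
    assert not motif.pfm.any()


def test_n_only_columns_get_uniform_frequencies():
    ctx = "N" * 14 + "A" + "C" * 15
    motif = consensus_motif([_mk_site(ctx)])
    assert np.allclose(motif.pfm[:, 0], 0.25)
    assert motif.consensus[0] == "N"
    assert motif.consensus[14] == "A"
    assert np.allclose(motif.pfm.sum(axis=0), 1.0)


def test_uniform_random_contexts_approach_uniform_pfm():
    rng = np.random.default_rng(0)
    bases = np.array(list("ACGT"))
    sites = [
        _mk_site("".join(rng.choice(bases, size=30))) for _ in range(10_000)
    ]
    motif = consensus_motif(sites)
    assert np.allclose(motif.pfm, 0.25, atol=0.02)


def test_mismatched_context_width_raises():
    with pytest.raises(ValueError):
        consensus_motif([_mk_site("ACGT")])
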