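"""End-to-end orchestration: simulate -> tracks -> peaks -> sites ->
motif -> TE -> integrate, with a deterministic run-directory layout.

Layout of a completed run directory::

    config.yaml          fully resolved configuration
    MANIFEST             stage completion states
    transcripts.tsv, transcripts.fa, truth.tsv
    alignments_rep<k>.tsv.gz
    tracks/              bedGraph per replicate and library
    peaks.bed            filtered peaks (replicate 1); peaks_rep<k>.bed all
    sites.tsv            site calls  (replicate 1); sites_rep<k>.tsv all
    motif.pfm            PFM + IUPAC consensus over replicate-1 sites
    te.tsv               TE per condition and TR classification
    report/              integration tables, text summary, gene lists

Identical config + seed => byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np

from . import integrate as integ
from . import io as mio
from . import peaks as pk
from . import sites as st
from . import tracks as trk
from . import translation as tl
from .config import RunConfig
from .models import LibraryRole, ModType, TEClass
from .simulate import generate_transcriptome, simulate_libraries, simulate_te_counts, write_truth

__all__ = ["run_pipeline", "call_peaks_full"]

logger = logging.getLogger(__name__)

_STAGES = ["simulate", "tracks", "peaks", "sites", "motif", "te", "integrate"]


def call_peaks_full(tracks, transcripts, p) -> list:
    """The full peak filter chain: enrichment -> FTO sensitivity -> cap
    proximity, with parameters from a :class:`~m6amseq.config.PeakParams`."""
    peaks = pk.call_enriched_windows(
        tracks, window=p.window, step=p.step, min_fold=p.min_fold,
        min_ip_depth=p.min_ip_depth, pseudocount=p.pseudocount,
    )
    peaks = pk.filter_fto_sensitive(peaks, tracks, min_depletion=p.min_depletion)
    peaks = pk.filter_cap_proximal(
        peaks, tracks, transcripts, max_tss_distance=p.max_tss_distance,
        m7g_min_fold=p.m7g_min_fold, pseudocount=p.pseudocount,
    )
    return peaks


def _write_manifest(outdir: Path, states: dict[str, str]) -> None:
    with open(outdir / "MANIFEST", "w") as fh:
        for stage in _STAGES:
            fh.write(f"{stage}\t{states.get(stage, 'pending')}\n")


def run_pipeline(config: RunConfig, outdir) -> Path:
    """Run every stage; on stage failure, partial outputs are retained and
    the MANIFEST marks where the run stopped (the exception propagates)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.validate()
    config.to_yaml(outdir / "config.yaml")
    states: dict[str, str] = {}
    _write_manifest(outdir, states)

    current = "simulate"
    try:
        # --- simulate ---------------------------------------------------
        transcripts, truth = generate_transcriptome(config.sim)
        mio.write_transcript_models(transcripts, outdir / "transcripts.tsv")
        mio.write_fasta(transcripts, outdir / "transcripts.fa")
        write_truth(truth, outdir / "truth.tsv")
        replicates = []
        for r in range(config.n_replicates):
            params = dataclasses.replace(config.sim, seed=config.seed + 7919 * r)
            aln = simulate_libraries(transcripts, truth, params)
            mio.write_alignments(aln, outdir / f"alignments_rep{r + 1}.tsv.gz")
            replicates.append(aln)
            logger.info("simulate: replicate %d, %d records/library",
                        r + 1, config.sim.depth_per_library)
        states[current] = "done"
        _write_manifest(outdir, states)

        # --- tracks -----------------------------------------------------
        current = "tracks"
        (outdir / "tracks").mkdir(exist_ok=True)
        rep_tracks = []
        for r, aln in enumerate(replicates):
            tr = trk.compute_tracks(aln, transcripts)
            rep_tracks.append(tr)
            for role in aln:
                trk.export_bedgraph(
                    tr, role, outdir / "tracks" / f"rep{r + 1}_{role.value}.bedgraph"
                )
        states[current] = "done"
        _write_manifest(outdir, states)

        # --- peaks ------------------------------------------------------
        current = "peaks"
        rep_peaks = []
        for r, tr in enumerate(rep_tracks):
            peaks = call_peaks_full(tr, transcripts, config.peaks)
            rep_peaks.append(peaks)
            pk.export_peaks_bed(peaks, outdir / f"peaks_rep{r + 1}.bed")
            logger.info("peaks: replicate %d, %d peaks", r + 1, len(peaks))
        pk.export_peaks_bed(rep_peaks[0], outdir / "peaks.bed")
        states[current] = "done"
        _write_manifest(outdir, states)

        # --- sites ------------------------------------------------------
        current = "sites"
        seqs = {t.transcript_id: t.sequence for t in transcripts}
        gene_by_tid = {t.transcript_id: t.gene_id for t in transcripts}
        rep_sites = []
        for r, (peaks, tr) in enumerate(zip(rep_peaks, rep_tracks)):
            sites = st.call_sites(
                peaks, tr, seqs, gene_by_tid,
                min_score=config.sites.min_score,
                min_site_depth=config.sites.min_site_depth,
                combiner=config.sites.combiner,
            )
            rep_sites.append(sites)
            st.write_sites(sites, outdir / f"sites_rep{r + 1}.tsv")
            logger.info("sites: replicate %d, %d calls", r + 1, len(sites))
        st.write_sites(rep_sites[0], outdir / "sites.tsv")
        states[current] = "done"
        _write_manifest(outdir, states)

        # --- motif ------------------------------------------------------
        current = "motif"
        motif = st.consensus_motif(rep_sites[0])
        st.write_pfm(motif, outdir / "motif.pfm")
        st.contexts_to_fasta(rep_sites[0], outdir / "site_contexts.fa")
        states[current] = "done"
        _write_manifest(outdir, states)

        # --- te ---------------------------------------------------------
        current = "te"
        gene_ids = [t.gene_id for t in transcripts]
        modified = sorted(
            {gene_by_tid[t.transcript_id] for t in truth
             if t.mod_type is ModType.CAP_M6AM}
        )
        rng = np.random.default_rng([config.seed, 3])
        log2_tr = np.zeros(len(gene_ids))
        gidx = {g: i for i, g in enumerate(gene_ids)}
        n_aff = int(round(config.te_sim.frac_modified_affected * len(modified)))
        affected = list(rng.choice(modified, size=n_aff, replace=False)) if n_aff else []
        for g in affected:
            log2_tr[gidx[g]] = config.te_sim.effect_log2
        unmod = [g for g in gene_ids if g not in set(modified)]
        bg = rng.choice(
            unmod,
            size=min(len(unmod),
                     config.te_sim.n_background_up + config.te_sim.n_background_down),
            replace=False,
        )
        for j, g in enumerate(bg):
            log2_tr[gidx[g]] = (
                config.te_sim.effect_log2
                if j < config.te_sim.n_background_up
                else -config.te_sim.effect_log2
            )
        counts = simulate_te_counts(
            gene_ids, log2_tr, depth=config.te_sim.depth, seed=config.seed
        )
        te_ctrl = tl.compute_te(counts["fp_ctrl"], counts["rna_ctrl"],
                                config.te.pseudocount, condition="ctrl")
        te_cond = tl.compute_te(counts["fp_cond"], counts["rna_cond"],
                                config.te.pseudocount, condition="ko")
        trs = tl.translation_ratio(te_cond, te_ctrl, config.te.log2_threshold)
        tl.tr_table(trs).to_csv(outdir / "te.tsv", sep="\t", index=False)
        states[current] = "done"
        _write_manifest(outdir, states)

        # --- integrate --------------------------------------------------
        current = "integrate"
        report_dir = outdir / "report"
        report_dir.mkdir(exist_ok=True)
        per_sample = {f"rep{r + 1}": s for r, s in enumerate(rep_sites)}
        shared = integ.shared_modified_genes(per_sample)
        te_up = {t.gene_id for t in trs if t.te_class is TEClass.UP}
        report = integ.overlap_with_te(
            shared, te_up, {k: integ.genes_of(v) for k, v in per_sample.items()}
        )
        integ.report_table(report).to_csv(
            report_dir / "integration.tsv", sep="\t", index=False
        )
        (report_dir / "summary.txt").write_text(integ.report_text(report))
        for name, gs in (
            ("shared_modified_genes", report.shared_genes),
            ("te_upregulated_genes", report.te_changed),
            ("overlap_genes", report.overlap_genes),
        ):
            (report_dir / f"{name}.txt").write_text(
                "".join(f"{g}\n" for g in sorted(gs))
            )
        states[current] = "done"
        _write_manifest(outdir, states)
    except Exception:
        states[current] = "failed"
        _write_manifest(outdir, states)
        raise
    return outdir
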