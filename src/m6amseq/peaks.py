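"""Enrichment peak calling and m6Am-candidate filtering.

A candidate peak is an interval that is (i) enriched in the FTO- m6A-IP
library over input, (ii) depleted in the FTO+ arm relative to the FTO-
arm (demethylation-sensitive), and (iii) cap-proximal (summit near the
TSS and, when an m7G-IP library is present, m7G-enriched). Enrichment and
depletion statistics are computed on cpm-normalized depth with a
symmetric pseudocount so that library-size differences cannot masquerade
as signal.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .models import LibraryRole, Peak, PositionTracks, TranscriptModel
from .tracks import cpm

__all__ = [
    "call_enriched_windows",
    "filter_fto_sensitive",
    "filter_cap_proximal",
    "merge_intervals",
    "export_peaks_bed",
    "read_peaks_bed",
]

logger = logging.getLogger(__name__)


def _window_means(x: np.ndarray, starts: np.ndarray, width: int) -> np.ndarray:
    cs = np.concatenate([[0.0], np.cumsum(x, dtype=float)])
    return (cs[starts + width] - cs[starts]) / width


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or book-ended half-open intervals (idempotent)."""
    if not intervals:
        return []
    ivs = sorted(intervals)
    merged = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _interval_stats(
    tr: PositionTracks, start: int, end: int, pseudocount: float
) -> tuple[int, float]:
    """Summit (max FTO- cpm depth, smallest coordinate on ties) and
    IP/input cpm fold enrichment over [start, end)."""
    ip = cpm(tr.depth[LibraryRole.M6A_IP_FTO_MINUS], tr.library_size[LibraryRole.M6A_IP_FTO_MINUS])
    inp = cpm(tr.depth[LibraryRole.INPUT], tr.library_size[LibraryRole.INPUT])
    seg = ip[start:end]
    summit = start + int(np.argmax(seg))
    fold = (seg.mean() + pseudocount) / (inp[start:end].mean() + pseudocount)
    return summit, float(fold)


def call_enriched_windows(
    tracks: dict[str, PositionTracks],
    window: int = 25,
    step: int = 5,
    min_fold: float = 2.0,
    min_ip_depth: float = 5.0,
    pseudocount: float = 0.5,
) -> list[Peak]:
    """Sliding-window scan for IP-over-input enrichment.

    Windows with cpm fold ``(mean IP + pc)/(mean input + pc) >= min_fold``
    and mean raw IP depth ``>= min_ip_depth`` are kept; overlapping or
    adjacent kept windows are merged, and summit/enrichment are recomputed
    on the merged interval. Output is sorted by (transcript_id, start).
    """
    if window < 1 or step < 1:
        raise ValueError("window and step must be >= 1")
    peaks: list[Peak] = []
    for tid in sorted(tracks):
        tr = tracks[tid]
        for req in (LibraryRole.INPUT, LibraryRole.M6A_IP_FTO_MINUS):
            if req not in tr.depth:
                raise ValueError(f"peak calling requires {req.value} tracks")
        n = tr.length
        if n < window:
            continue
        ip_raw = tr.depth[LibraryRole.M6A_IP_FTO_MINUS]
        ip = cpm(ip_raw, tr.library_size[LibraryRole.M6A_IP_FTO_MINUS])
        inp = cpm(tr.depth[LibraryRole.INPUT], tr.library_size[LibraryRole.INPUT])

        starts = np.arange(0, n - window + 1, step)
        if starts[-1] != n - window:  # cover the 3' tail
            starts = np.append(starts, n - window)
        fold = (_window_means(ip, starts, window) + pseudocount) / (
            _window_means(inp, starts, window) + pseudocount
        )
        raw_mean = _window_means(ip_raw.astype(float), starts, window)
        keep = (fold >= min_fold) & (raw_mean >= min_ip_depth)
        merged = merge_intervals(
            [(int(s), int(s) + window) for s in starts[keep]]
        )
        for s, e in merged:
            summit, enr = _interval_stats(tr, s, e, pseudocount)
            peaks.append(Peak(tid, s, e, summit, enr))
    return peaks


def filter_fto_sensitive(
    peaks: list[Peak],
    tracks: dict[str, PositionTracks],
    min_depletion: float = 0.3,
) -> list[Peak]:
    """Keep peaks whose coverage drops after FTO treatment.

    ``fto_depletion = 1 - mean(FTO+ cpm)/mean(FTO- cpm)`` within the peak,
    clamped to [0, 1] (sampling noise can push FTO+ above FTO-); it is
    populated on every input peak, and peaks with depletion >=
    ``min_depletion`` are returned.
    """
    kept = []
    for p in peaks:
        tr = tracks[p.transcript_id]
        for req in (LibraryRole.M6A_IP_FTO_MINUS, LibraryRole.M6A_IP_FTO_PLUS):
            if req not in tr.depth:
                raise ValueError(f"FTO filtering requires {req.value} tracks")
        dm = cpm(
            tr.depth[LibraryRole.M6A_IP_FTO_MINUS],
            tr.library_size[LibraryRole.M6A_IP_FTO_MINUS],
        )[p.start : p.end].mean()
        dp = cpm(
            tr.depth[LibraryRole.M6A_IP_FTO_PLUS],
            tr.library_size[LibraryRole.M6A_IP_FTO_PLUS],
        )[p.start : p.end].mean()
        p.fto_depletion = float(np.clip(1.0 - dp / dm, 0.0, 1.0)) if dm > 0 else 0.0
        if p.fto_depletion >= min_depletion:
            kept.append(p)
    return kept


def filter_cap_proximal(
    peaks: list[Peak],
    tracks: dict[str, PositionTracks],
    transcripts: list[TranscriptModel],
    max_tss_distance: int = 100,
    m7g_min_fold: float = 2.0,
    pseudocount: float = 0.5,
) -> list[Peak]:
    """Keep peaks whose summit lies near the transcript 5' end.

    When an m7G-IP track is available the peak must additionally show
    m7G-IP enrichment over input (capped-fragment evidence); without it
    the distance test alone applies (logged).
    """
    have_m7g = any(LibraryRole.M7G_IP in tr.depth for tr in tracks.values())
    if not have_m7g:
        logger.warning("no m7G-IP track: cap-proximal filter uses TSS distance only")
    kept = []
    for p in peaks:
        tr = tracks[p.transcript_id]
        ok = p.summit <= max_tss_distance
        if ok and have_m7g and LibraryRole.M7G_IP in tr.depth:
            m7g = cpm(tr.depth[LibraryRole.M7G_IP], tr.library_size[LibraryRole.M7G_IP])
            inp = cpm(tr.depth[LibraryRole.INPUT], tr.library_size[LibraryRole.INPUT])
            fold = (m7g[p.start : p.end].mean() + pseudocount) / (
                inp[p.start : p.end].mean() + pseudocount
            )
            ok = fold >= m7g_min_fold
        p.cap_proximal = bool(ok)
        if ok:
            kept.append(p)
    return kept


# ---------------------------------------------------------------------------
# BED6+ export (name=peak id, score=round(100*fto_depletion), extra
# columns: summit, enrichment, cap_proximal, fto_depletion at full
# precision so the round trip is lossless)
# ---------------------------------------------------------------------------

def export_peaks_bed(peaks: list[Peak], path) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            score = 0 if np.isnan(p.fto_depletion) else round(100 * p.fto_depletion)
            fh.write(
                f"{p.transcript_id}\t{p.start}\t{p.end}\tpeak{i:05d}\t"
                f"{score}\t+\t{p.summit}\t{p.enrichment!r}\t"
                f"{int(p.cap_proximal)}\t{p.fto_depletion!r}\n"
            )


def read_peaks_bed(path) -> list[Peak]:
    names = ["tid", "start", "end", "name", "score", "strand", "summit",
             "enrichment", "cap_proximal", "fto_depletion"]
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, names=names, dtype={"tid": str},
            float_precision="round_trip",
        )
    except pd.errors.EmptyDataError:
        return []
    out = []
    for r in df.itertuples(index=False):
        pk = Peak(
            str(r.tid), int(r.start), int(r.end), int(r.summit),
            float(r.enrichment), float(r.fto_depletion), bool(r.cap_proximal),
        )
        out.append(pk)
    return out
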