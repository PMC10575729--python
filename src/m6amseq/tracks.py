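"""Per-transcript depth and read-start count tracks.

``depth[p]`` counts fragments with ``start <= p < end``; ``start_count[p]``
counts fragments whose 5' end is exactly ``p``. Tracks are integer-valued;
normalization (counts per million records of the library) is explicit and
lazy via :func:`normalize_depth`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .models import AlignmentSet, LibraryRole, PositionTracks, TranscriptModel

__all__ = [
    "compute_tracks",
    "normalize_depth",
    "cpm",
    "export_bedgraph",
    "import_bedgraph",
]


def compute_tracks(
    alignments: dict[LibraryRole, AlignmentSet],
    transcripts: list[TranscriptModel],
) -> dict[str, PositionTracks]:
    """Build depth/start tracks for every transcript and library.

    Transcripts with zero records get all-zero vectors. A record outside
    its transcript's bounds raises a coordinate error naming the record.
    """
    index = {t.transcript_id: i for i, t in enumerate(transcripts)}
    lengths = np.array([t.length for t in transcripts], dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    total = int(offsets[-1])

    out = {
        t.transcript_id: PositionTracks(t.transcript_id, t.length)
        for t in transcripts
    }

    for role, aln in alignments.items():
        tix = np.array([index.get(tid, -1) for tid in aln.transcript_ids], dtype=np.int64)
        if len(tix) and tix.min() < 0:
            bad = aln.transcript_ids[tix < 0][0]
            raise KeyError(f"alignment references unknown transcript {bad!r}")
        if len(tix):
            over = aln.ends > lengths[tix]
            if over.any():
                j = int(np.flatnonzero(over)[0])
                raise ValueError(
                    f"record ({aln.transcript_ids[j]}, {aln.starts[j]}, "
                    f"{aln.ends[j]}) exceeds transcript length "
                    f"{lengths[tix[j]]}"
                )
        gstart = offsets[tix] + aln.starts
        gend = offsets[tix] + aln.ends
        diff = np.zeros(total + 1, dtype=np.int64)
        np.add.at(diff, gstart, 1)
        np.add.at(diff, gend, -1)
        depth_flat = np.cumsum(diff)[:-1]
        start_flat = np.zeros(total, dtype=np.int64)
        np.add.at(start_flat, gstart, 1)

        size = len(aln)
        for i, t in enumerate(transcripts):
            tr = out[t.transcript_id]
            sl = slice(offsets[i], offsets[i + 1])
            tr.depth[role] = depth_flat[sl].copy()
            tr.start_count[role] = start_flat[sl].copy()
            tr.library_size[role] = size
    return out


def cpm(depth: np.ndarray, library_size: int) -> np.ndarray:
    """Counts-per-million scaling of a depth vector."""
    if library_size <= 0:
        raise ValueError("cpm normalization requires library_size > 0")
    return depth * (1e6 / library_size)


def normalize_depth(
    tracks: dict[str, PositionTracks], mode: str = "cpm"
) -> dict[str, dict[LibraryRole, np.ndarray]]:
    """Return real-valued depth vectors per transcript and library.

    mode "cpm": depth x 1e6 / library record count; mode "none": float cast.
    """
    if mode not in ("cpm", "none"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    out: dict[str, dict[LibraryRole, np.ndarray]] = {}
    for tid, tr in tracks.items():
        out[tid] = {}
        for role, depth in tr.depth.items():
            if mode == "cpm":
                out[tid][role] = cpm(depth, tr.library_size[role])
            else:
                out[tid][role] = depth.astype(float)
    return out


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------

def _runs(values: np.ndarray):
    """Yield (start, end, value) runs of equal value."""
    if len(values) == 0:
        return
    change = np.flatnonzero(np.diff(values)) + 1
    bounds = np.concatenate([[0], change, [len(values)]])
    for s, e in zip(bounds[:-1], bounds[1:]):
        yield int(s), int(e), values[s]


def export_bedgraph(
    tracks: dict[str, PositionTracks],
    library_role: LibraryRole,
    path,
    which: str = "depth",
    keep_zero: bool = False,
) -> None:
    """Write one library's track as 4-column bedGraph (transcript as chrom).

    Adjacent equal-value runs are merged; zero runs are omitted unless
    ``keep_zero`` is set.
    """
    vec_of = {"depth": lambda t: t.depth, "start_count": lambda t: t.start_count}
    if which not in vec_of:
        raise ValueError(f"unknown track kind {which!r}")
    with open(path, "w") as fh:
        for tid in sorted(tracks):
            tr = tracks[tid]
            vecs = vec_of[which](tr)
            if library_role not in vecs:
                continue
            for s, e, v in _runs(vecs[library_role]):
                if v == 0 and not keep_zero:
                    continue
                fh.write(f"{tid}\t{s}\t{e}\t{v}\n")


def import_bedgraph(path, length_by_tid: dict[str, int]) -> dict[str, np.ndarray]:
    """Read a bedGraph back into dense per-transcript vectors (zeros where
    no interval is given)."""
    out = {tid: np.zeros(n, dtype=np.int64) for tid, n in length_by_tid.items()}
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, names=["tid", "start", "end", "value"],
            dtype={"tid": str},
        )
    except pd.errors.EmptyDataError:
        return out
    for r in df.itertuples(index=False):
        if r.tid not in out:
            raise KeyError(f"bedGraph references unknown transcript {r.tid!r}")
        out[r.tid][r.start : r.end] = r.value
    return out
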