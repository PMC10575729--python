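"""Readers/writers for the pipeline's plain-text interchange formats.

Alignment TSV dialect: columns ``library_role, transcript_id, start, end``
(0-based half-open), gzip-transparent. Transcript models: TSV with columns
``transcript_id, gene_id, length, utr5_end, cds_end``. Sequences: FASTA
with record IDs matching transcript_id. An optional BAM reader (pysam) is
provided for externally aligned data.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import AlignmentSet, LibraryRole, TranscriptModel

__all__ = [
    "write_alignments",
    "read_alignments",
    "read_alignments_bam",
    "write_transcript_models",
    "read_transcript_models",
    "write_fasta",
    "read_fasta",
]

_ALN_COLS = ["library_role", "transcript_id", "start", "end"]


def write_alignments(alignments: dict[LibraryRole, AlignmentSet], path) -> None:
    frames = []
    for role in LibraryRole:
        if role not in alignments:
            continue
        a = alignments[role]
        frames.append(
            pd.DataFrame(
                {
                    "library_role": role.value,
                    "transcript_id": a.transcript_ids,
                    "start": a.starts,
                    "end": a.ends,
                }
            )
        )
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=_ALN_COLS)
    )
    df.to_csv(path, sep="\t", index=False)  # pandas infers gzip from suffix


def read_alignments(path) -> dict[LibraryRole, AlignmentSet]:
    df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str})
    missing = set(_ALN_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"alignment TSV missing columns: {sorted(missing)}")
    out: dict[LibraryRole, AlignmentSet] = {}
    for role_name, grp in df.groupby("library_role", sort=False):
        role = LibraryRole(role_name)
        out[role] = AlignmentSet(
            role,
            grp["transcript_id"].to_numpy(dtype=object),
            grp["start"].to_numpy(dtype=np.int64),
            grp["end"].to_numpy(dtype=np.int64),
        )
    return out


def read_alignments_bam(path, library_role: LibraryRole) -> AlignmentSet:
    """Read one library from a transcriptome-aligned BAM/SAM.

    Reference names map to transcript_id; unmapped, secondary and
    supplementary records are skipped.
    """
    import pysam

    tids, starts, ends = [], [], []
    with pysam.AlignmentFile(str(path), check_sq=False) as bam:
        for rec in bam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            tids.append(rec.reference_name)
            starts.append(rec.reference_start)
            ends.append(rec.reference_end)
    return AlignmentSet(
        library_role,
        np.array(tids, dtype=object),
        np.array(starts, dtype=np.int64),
        np.array(ends, dtype=np.int64),
    )


def write_transcript_models(transcripts: list[TranscriptModel], path) -> None:
    pd.DataFrame(
        [
            {
                "transcript_id": t.transcript_id,
                "gene_id": t.gene_id,
                "length": t.length,
                "utr5_end": t.utr5_end,
                "cds_end": t.cds_end,
            }
            for t in transcripts
        ],
        columns=["transcript_id", "gene_id", "length", "utr5_end", "cds_end"],
    ).to_csv(path, sep="\t", index=False)


def read_transcript_models(path, sequences: dict[str, str] | None = None) -> list[TranscriptModel]:
    """Read transcript models; sequences (e.g. from :func:`read_fasta`)
    are attached when given, else placeholder N-runs of the right length."""
    df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str, "gene_id": str})
    out = []
    for r in df.itertuples(index=False):
        seq = (
            sequences[r.transcript_id]
            if sequences is not None
            else "N" * int(r.length)
        )
        out.append(
            TranscriptModel(
                str(r.transcript_id),
                str(r.gene_id),
                int(r.length),
                int(r.utr5_end),
                int(r.cds_end),
                seq,
            )
        )
    return out


def write_fasta(transcripts: list[TranscriptModel], path) -> None:
    records = [
        SeqRecord(Seq(t.sequence), id=t.transcript_id, description="")
        for t in transcripts
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
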