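"""Core domain types shared across the pipeline.

Coordinate conventions used everywhere in this package:

* all positions are 0-based, intervals are half-open ``[start, end)``;
* position 0 of a transcript is its first transcribed (cap-adjacent)
  nucleotide;
* reads/fragments are transcript-sense, so a fragment's "start" is its
  5'-most transcript position.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LibraryRole",
    "ModType",
    "TranscriptModel",
    "TruthAnnotation",
    "AlignmentSet",
    "PositionTracks",
    "Peak",
    "SiteCall",
    "MotifSummary",
    "TEResult",
    "TRResult",
    "GeneSetReport",
    "TEClass",
]


class LibraryRole(str, enum.Enum):
    """The four sequencing libraries the assay compares.

    ``INPUT`` is fragmented RNA without enrichment; ``M7G_IP`` enriches
    cap-carrying (5'-terminal) fragments; the two ``M6A_IP`` arms enrich
    methylated fragments with (``FTO_PLUS``) or without (``FTO_MINUS``)
    prior in-vitro FTO demethylation, which erases m6Am far more
    efficiently than internal m6A.
    """

    INPUT = "INPUT"
    M7G_IP = "M7G_IP"
    M6A_IP_FTO_MINUS = "M6A_IP_FTO_MINUS"
    M6A_IP_FTO_PLUS = "M6A_IP_FTO_PLUS"


class ModType(str, enum.Enum):
    CAP_M6AM = "CAP_M6AM"
    INTERNAL_M6A = "INTERNAL_M6A"


class TEClass(str, enum.Enum):
    UP = "UP"
    DOWN = "DOWN"
    UNCHANGED = "UNCHANGED"


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript in a TSS-anchored coordinate frame.

    ``utr5_end`` and ``cds_end`` are 0-based exclusive boundaries, so the
    5'UTR is ``[0, utr5_end)``, the CDS ``[utr5_end, cds_end)`` and the
    3'UTR ``[cds_end, length)``.
    """

    transcript_id: str
    gene_id: str
    length: int
    utr5_end: int
    cds_end: int
    sequence: str

    def __post_init__(self) -> None:
        if not (0 < self.utr5_end < self.cds_end < self.length):
            raise ValueError(
                f"{self.transcript_id}: require 0 < utr5_end < cds_end < length, "
                f"got utr5_end={self.utr5_end}, cds_end={self.cds_end}, "
                f"length={self.length}"
            )
        if len(self.sequence) != self.length:
            raise ValueError(
                f"{self.transcript_id}: sequence length {len(self.sequence)} "
                f"!= declared length {self.length}"
            )


@dataclass(frozen=True)
class TruthAnnotation:
    """A planted modification site; ground truth for recovery tests."""

    transcript_id: str
    position: int
    mod_type: ModType
    stoichiometry: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.stoichiometry <= 1.0:
            raise ValueError(f"stoichiometry {self.stoichiometry} outside [0, 1]")
        if self.position < 0:
            raise ValueError(f"negative position {self.position}")


@dataclass
class AlignmentSet:
    """Alignment records for one library, in transcript coordinates.

    Records are stored column-wise (numpy arrays) for speed; iteration
    yields ``(transcript_id, start, end)`` tuples.
    """

    library_role: LibraryRole
    transcript_ids: np.ndarray  # dtype object/str
    starts: np.ndarray  # int
    ends: np.ndarray  # int

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        self.transcript_ids = np.asarray(self.transcript_ids, dtype=object)
        if not (len(self.transcript_ids) == len(self.starts) == len(self.ends)):
            raise ValueError("column lengths differ")
        if len(self.starts) and (
            np.any(self.starts < 0) or np.any(self.ends <= self.starts)
        ):
            raise ValueError("require 0 <= start < end for every record")

    def __len__(self) -> int:
        return len(self.starts)

    def __iter__(self):
        for tid, s, e in zip(self.transcript_ids, self.starts, self.ends):
            yield str(tid), int(s), int(e)


@dataclass
class PositionTracks:
    """Per-transcript, per-library depth and read-start count vectors.

    ``depth[role][p]`` is the number of fragments covering position ``p``;
    ``start_count[role][p]`` the number whose 5' end is exactly ``p``.
    ``library_size[role]`` is the total record count of that library over
    ALL transcripts (the cpm denominator).
    """

    transcript_id: str
    length: int
    depth: dict[LibraryRole, np.ndarray] = field(default_factory=dict)
    start_count: dict[LibraryRole, np.ndarray] = field(default_factory=dict)
    library_size: dict[LibraryRole, int] = field(default_factory=dict)


@dataclass
class Peak:
    """An IP-enriched interval with its FTO-sensitivity statistic.

    ``enrichment`` is the cpm-fold of FTO- IP depth over input depth within
    the peak (pseudocounted); ``fto_depletion`` is
    ``1 - mean(FTO+ cpm)/mean(FTO- cpm)`` clamped to [0, 1].
    """

    transcript_id: str
    start: int
    end: int
    summit: int
    enrichment: float
    fto_depletion: float = float("nan")
    cap_proximal: bool = False

    def __post_init__(self) -> None:
        if not (self.start <= self.summit < self.end):
            raise ValueError(
                f"summit {self.summit} outside peak "
                f"[{self.start}, {self.end}) on {self.transcript_id}"
            )


@dataclass
class SiteCall:
    """A single-adenosine m6Am call.

    ``m1`` is the start-read fraction in the FTO- IP library (cap
    signature), ``m2`` the relative FTO+ depth loss (demethylation
    sensitivity), ``score`` their combination. ``context`` is the 30-nt
    site-centered sense sequence, N-padded at transcript edges.
    """

    transcript_id: str
    gene_id: str
    position: int
    base: str
    m1: float
    m2: float
    score: float
    context: str


@dataclass
class MotifSummary:
    """Position frequency matrix and IUPAC consensus over site contexts."""

    pfm: np.ndarray  # 4 x W, rows A,C,G,T
    consensus: str
    n_sites: int


@dataclass
class TEResult:
    """Translation efficiency of one gene in one condition."""

    gene_id: str
    footprint_cds_count: int
    rna_count: int
    te: float
    condition: str


@dataclass
class TRResult:
    """Between-condition translation ratio and its classification."""

    gene_id: str
    tr: float
    log2_tr: float
    te_class: TEClass


@dataclass
class GeneSetReport:
    """Cross-sample / cross-assay gene-set integration summary."""

    per_sample: dict[str, set[str]]
    shared_genes: set[str]
    te_changed: set[str]
    overlap_genes: set[str]
    fraction_percent: float  # |overlap|/|shared| x 100, 1 decimal; nan if undefined
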