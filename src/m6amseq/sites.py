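"""Per-nucleotide m6Am scoring, single-base site calls and motif consensus.

For every adenosine inside a candidate peak two fractions are computed
from the tracks:

* ``m1 = (FTO- start reads) / (FTO- depth)`` — the fraction of FTO- IP
  fragments covering the position that *start* on it. Because no fragment
  of a capped molecule can extend 5' of the cap, a cap-adjacent m6Am pulls
  m1 toward 1 while internal positions stay near the fragmentation
  background.
* ``m2 = (FTO- depth - FTO+ depth) / (FTO- depth)`` — the relative
  coverage loss after in-vitro FTO demethylation, on cpm-normalized
  depths (cross-library comparison), clamped to [0, 1].

The combined score defaults to ``m1 * m2``: high only where a position is
both a dominant fragment start (cap signature) and FTO-sensitive. The
combination rule is a package choice (``product``; ``min`` and ``mean``
are selectable) — see docs/methods.md.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .models import LibraryRole, MotifSummary, Peak, PositionTracks, SiteCall
from .tracks import cpm

__all__ = [
    "score_position",
    "call_sites",
    "extract_context",
    "consensus_motif",
    "write_sites",
    "read_sites",
    "write_pfm",
    "contexts_to_fasta",
]

CONTEXT_WIDTH = 30
# even width: 14 nt of 5' flank, the site, then 15 nt of 3' flank
_SITE_OFFSET = CONTEXT_WIDTH // 2 - 1

_COMBINERS = {
    "product": lambda m1, m2: m1 * m2,
    "min": min,
    "mean": lambda m1, m2: 0.5 * (m1 + m2),
}

_IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G",
    frozenset("T"): "T", frozenset("AC"): "M", frozenset("AG"): "R",
    frozenset("AT"): "W", frozenset("CG"): "S", frozenset("CT"): "Y",
    frozenset("GT"): "K", frozenset("ACG"): "V", frozenset("ACT"): "H",
    frozenset("AGT"): "D", frozenset("CGT"): "B", frozenset("ACGT"): "N",
    frozenset(): "N",
}


def score_position(
    start_fto_minus: int,
    depth_fto_minus: int,
    depth_fto_plus_norm: float,
    depth_fto_minus_norm: float,
    combiner: str = "product",
) -> tuple[float, float, float]:
    """Compute (m1, m2, score) for one position.

    ``start_fto_minus``/``depth_fto_minus`` are raw FTO- IP counts (the
    ratio is scale-free); the normalized depths are cpm values for the
    FTO+ and FTO- arms. Zero denominators yield 0, not an error.
    """
    if start_fto_minus < 0 or depth_fto_minus < start_fto_minus:
        raise ValueError(
            f"inconsistent counts: start={start_fto_minus}, depth={depth_fto_minus}"
        )
    if depth_fto_plus_norm < 0 or depth_fto_minus_norm < 0:
        raise ValueError("normalized depths must be >= 0")
    m1 = start_fto_minus / depth_fto_minus if depth_fto_minus > 0 else 0.0
    if depth_fto_minus_norm > 0:
        m2 = (depth_fto_minus_norm - depth_fto_plus_norm) / depth_fto_minus_norm
        m2 = float(np.clip(m2, 0.0, 1.0))
    else:
        m2 = 0.0
    return m1, m2, float(_COMBINERS[combiner](m1, m2))


def extract_context(sequence: str, position: int, width: int = CONTEXT_WIDTH) -> str:
    """Site-centered sense-strand context, N-padded at transcript edges."""
    off = width // 2 - 1
    lo = position - off
    hi = lo + width
    left = "N" * max(0, -lo)
    right = "N" * max(0, hi - len(sequence))
    return left + sequence[max(lo, 0) : min(hi, len(sequence))] + right


def call_sites(
    peaks: list[Peak],
    tracks: dict[str, PositionTracks],
    sequences: dict[str, str],
    gene_by_tid: dict[str, str] | None = None,
    min_score: float = 0.1,
    min_site_depth: int = 10,
    combiner: str = "product",
) -> list[SiteCall]:
    """Score every adenosine within every peak; emit those passing cutoffs.

    Positions require base 'A' (T/U alphabet agnostic) and FTO- IP raw
    depth >= ``min_site_depth``. Output sorted by (transcript, position).
    """
    calls: list[SiteCall] = []
    for p in peaks:
        tr = tracks[p.transcript_id]
        if p.transcript_id not in sequences:
            raise KeyError(f"no sequence for transcript {p.transcript_id}")
        seq = sequences[p.transcript_id].upper().replace("U", "T")
        if len(seq) < tr.length:
            raise ValueError(
                f"sequence for {p.transcript_id} shorter than transcript model"
            )
        dm_raw = tr.depth[LibraryRole.M6A_IP_FTO_MINUS]
        sm_raw = tr.start_count[LibraryRole.M6A_IP_FTO_MINUS]
        dm = cpm(dm_raw, tr.library_size[LibraryRole.M6A_IP_FTO_MINUS])
        dp = cpm(
            tr.depth[LibraryRole.M6A_IP_FTO_PLUS],
            tr.library_size[LibraryRole.M6A_IP_FTO_PLUS],
        )
        for pos in range(p.start, p.end):
            if seq[pos] != "A" or dm_raw[pos] < min_site_depth:
                continue
            m1, m2, score = score_position(
                int(sm_raw[pos]), int(dm_raw[pos]), float(dp[pos]), float(dm[pos]),
                combiner=combiner,
            )
            if score >= min_score:
                gid = gene_by_tid.get(p.transcript_id, "") if gene_by_tid else ""
                calls.append(
                    SiteCall(
                        p.transcript_id, gid, pos, "A", m1, m2, score,
                        extract_context(seq, pos),
                    )
                )
    calls.sort(key=lambda c: (c.transcript_id, c.position))
    return calls


# ---------------------------------------------------------------------------
# motif consensus (PFM replacement for de novo discovery)
# ---------------------------------------------------------------------------

def consensus_motif(sites: list[SiteCall], width: int = CONTEXT_WIDTH) -> MotifSummary:
    """Position frequency matrix and IUPAC consensus of site contexts.

    Each column's frequencies are computed over non-N characters only; the
    consensus letter covers the bases with column frequency >= 0.25. An
    empty site list yields the empty-summary sentinel (n_sites=0, empty
    consensus, zero matrix).
    """
    if not sites:
        return MotifSummary(np.zeros((4, width)), "", 0)
    contexts = [s.context for s in sites]
    if any(len(c) != width for c in contexts):
        raise ValueError(f"all contexts must have width {width}")
    mat = np.frombuffer(
        "".join(contexts).encode("ascii"), dtype="S1"
    ).reshape(len(contexts), width)
    counts = np.stack(
        [(mat == base.encode()).sum(axis=0) for base in "ACGT"]
    ).astype(float)
    denom = counts.sum(axis=0)
    pfm = np.divide(counts, denom, out=np.full_like(counts, 0.25), where=denom > 0)
    letters = []
    for col in range(width):
        bases = frozenset(b for i, b in enumerate("ACGT") if pfm[i, col] >= 0.25)
        letters.append(_IUPAC[bases])
    return MotifSummary(pfm, "".join(letters), len(sites))


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------

_SITE_COLS = ["transcript_id", "gene_id", "position", "base", "m1", "m2",
              "score", "context"]


def write_sites(sites: list[SiteCall], path) -> None:
    pd.DataFrame(
        [
            {
                "transcript_id": s.transcript_id, "gene_id": s.gene_id,
                "position": s.position, "base": s.base,
                "m1": repr(s.m1), "m2": repr(s.m2), "score": repr(s.score),
                "context": s.context,
            }
            for s in sites
        ],
        columns=_SITE_COLS,
    ).to_csv(path, sep="\t", index=False)


def read_sites(path) -> list[SiteCall]:
    df = pd.read_csv(
        path, sep="\t", dtype={"transcript_id": str, "gene_id": str},
        float_precision="round_trip",
    )
    return [
        SiteCall(
            str(r.transcript_id),
            "" if pd.isna(r.gene_id) else str(r.gene_id),
            int(r.position), str(r.base),
            float(r.m1), float(r.m2), float(r.score), str(r.context),
        )
        for r in df.itertuples(index=False)
    ]


def write_pfm(motif: MotifSummary, path) -> None:
    """4-row tab-separated matrix (rows A,C,G,T) under a consensus header."""
    with open(path, "w") as fh:
        fh.write(f"#consensus\t{motif.consensus}\tn_sites\t{motif.n_sites}\n")
        for i, base in enumerate("ACGT"):
            row = "\t".join(f"{v:.6f}" for v in motif.pfm[i])
            fh.write(f"{base}\t{row}\n")


def contexts_to_fasta(sites: list[SiteCall], path) -> None:
    """Site contexts as FASTA, usable as input to external motif tools."""
    with open(path, "w") as fh:
        for s in sites:
            fh.write(f">{s.transcript_id}_{s.position}\n{s.context}\n")
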