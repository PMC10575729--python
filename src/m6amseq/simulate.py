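"""Truth-annotated transcriptome and four-library read simulator.

Emulates the statistical structure the assay relies on:

* every molecule of a transcript begins at that transcript's cap position,
  so the only fragments covering a cap-adjacent site are the ones that
  start exactly on it (the origin of the m1 start-read signature);
* anti-m6A IP over-samples fragments overlapping a methylated position,
  where methylation of an individual molecule at a planted site is
  Bernoulli(stoichiometry);
* in the FTO-treated arm each m6Am (resp. internal m6A) mark is erased
  with probability ``fto_efficiency_m6am`` (resp. ``fto_efficiency_m6a``)
  *before* IP selection — the selectivity gap between the two is what
  makes the FTO+ / FTO- contrast informative;
* anti-m7G IP over-samples cap-carrying (5'-terminal) fragments.

All randomness flows from explicitly seeded :class:`numpy.random.Generator`
streams derived from ``SimParams.seed``; for a fixed seed every output is
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .models import (
    AlignmentSet,
    LibraryRole,
    ModType,
    TranscriptModel,
    TruthAnnotation,
)

__all__ = [
    "SimParams",
    "generate_transcriptome",
    "simulate_libraries",
    "simulate_te_counts",
    "write_truth",
    "read_truth",
]

_BASES = np.array(["A", "C", "G", "T"])


@dataclass
class SimParams:
    """Tunables of the synthetic four-library experiment.

    ``ip_enrichment`` is the fold by which methylated-overlap (or, for the
    m7G arm, cap-terminal) fragments are over-sampled relative to
    background. ``cap_window`` > 0 allows cap m6Am sites at positions
    1..cap_window (TSS heterogeneity); the default plants them at
    position 0 only.
    """

    n_transcripts: int = 200
    depth_per_library: int = 200_000
    fragment_length_mean: float = 30.0
    fragment_length_sd: float = 5.0
    fragment_length_min: int = 20
    ip_enrichment: float = 5.0
    fto_efficiency_m6am: float = 0.9
    fto_efficiency_m6a: float = 0.05
    frac_cap_m6am: float = 0.25
    frac_internal_m6a: float = 0.25
    stoichiometry: float = 0.8
    cap_window: int = 0
    min_length: int = 500
    max_length: int = 1500
    seed: int = 0

    def validate(self) -> None:
        if self.n_transcripts <= 0:
            raise ValueError("n_transcripts must be positive")
        for name in (
            "fto_efficiency_m6am",
            "fto_efficiency_m6a",
            "frac_cap_m6am",
            "frac_internal_m6a",
            "stoichiometry",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.ip_enrichment < 1.0:
            raise ValueError("ip_enrichment must be >= 1")
        if self.fto_efficiency_m6am < self.fto_efficiency_m6a:
            raise ValueError(
                "fto_efficiency_m6am must be >= fto_efficiency_m6a "
                "(the FTO selectivity the assay depends on)"
            )
        if self.depth_per_library <= 0:
            raise ValueError("depth_per_library must be positive")
        if not 20 <= self.min_length < self.max_length:
            raise ValueError("require 20 <= min_length < max_length")

    @classmethod
    def from_dict(cls, d: dict) -> "SimParams":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown SimParams keys: {sorted(unknown)}")
        p = cls(**d)
        p.validate()
        return p

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# transcriptome generation
# ---------------------------------------------------------------------------

def generate_transcriptome(
    params: SimParams,
) -> tuple[list[TranscriptModel], list[TruthAnnotation]]:
    """Generate random transcript models with planted modification sites.

    Exactly ``floor(frac_cap_m6am * n_transcripts)`` transcripts carry a
    cap m6Am truth site and ``floor(frac_internal_m6a * n_transcripts)``
    carry one internal m6A (the two subsets are drawn independently and
    may overlap). Cap sites are written into the sequence as an ``A`` with
    a ``C`` immediately 5' when the site position is > 0, so the "CA"
    motif is recoverable; internal sites are embedded in a GGACT
    (DRACH-like) context inside the CDS.
    """
    params.validate()
    rng = np.random.default_rng([params.seed, 0])

    n = params.n_transcripts
    lengths = rng.integers(params.min_length, params.max_length + 1, size=n)
    transcripts: list[TranscriptModel] = []
    truth: list[TruthAnnotation] = []

    n_cap = int(np.floor(params.frac_cap_m6am * n))
    n_int = int(np.floor(params.frac_internal_m6a * n))
    cap_idx = set(rng.choice(n, size=n_cap, replace=False)) if n_cap else set()
    int_idx = set(rng.choice(n, size=n_int, replace=False)) if n_int else set()

    for i in range(n):
        length = int(lengths[i])
        utr5_end = int(rng.integers(80, 201))
        cds_end = int(rng.integers(utr5_end + 150, length - 50))
        seq = rng.choice(_BASES, size=length)
        tid = f"tx{i:04d}"
        gid = f"gene{i:04d}"

        if i in cap_idx:
            if params.cap_window > 0:
                pos = int(rng.integers(1, params.cap_window + 1))
                seq[pos] = "A"
                seq[pos - 1] = "C"
            else:
                pos = 0
                seq[0] = "A"
            truth.append(
                TruthAnnotation(tid, pos, ModType.CAP_M6AM, params.stoichiometry)
            )
        if i in int_idx:
            # DRACH-like context, safely downstream of the cap-proximal window
            lo = max(params.cap_window + 30, utr5_end)
            pos = int(rng.integers(lo, cds_end))
            seq[pos - 2 : pos + 3] = list("GGACT")
            truth.append(
                TruthAnnotation(tid, pos, ModType.INTERNAL_M6A, params.stoichiometry)
            )

        transcripts.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gid,
                length=length,
                utr5_end=utr5_end,
                cds_end=cds_end,
                sequence="".join(seq),
            )
        )

    truth.sort(key=lambda t: (t.transcript_id, t.position))
    return transcripts, truth


# ---------------------------------------------------------------------------
# library simulation
# ---------------------------------------------------------------------------

def _truth_arrays(
    transcripts: list[TranscriptModel], truth: list[TruthAnnotation]
) -> dict[str, np.ndarray]:
    """Per-transcript site/stoichiometry lookup arrays (-1 = no site)."""
    index = {t.transcript_id: i for i, t in enumerate(transcripts)}
    n = len(transcripts)
    arr = {
        "length": np.array([t.length for t in transcripts], dtype=np.int64),
        "cap_pos": np.full(n, 0, dtype=np.int64),  # molecule 5' end (TSS)
        "cap_site": np.full(n, -1, dtype=np.int64),
        "cap_stoich": np.zeros(n),
        "int_site": np.full(n, -1, dtype=np.int64),
        "int_stoich": np.zeros(n),
    }
    for t in truth:
        if t.transcript_id not in index:
            raise KeyError(f"truth annotation on unknown transcript {t.transcript_id}")
        i = index[t.transcript_id]
        if t.position >= arr["length"][i]:
            raise ValueError(
                f"truth position {t.position} beyond length of {t.transcript_id}"
            )
        if t.mod_type is ModType.CAP_M6AM:
            arr["cap_site"][i] = t.position
            arr["cap_stoich"][i] = t.stoichiometry
            arr["cap_pos"][i] = t.position  # molecules begin at the cap base
        else:
            arr["int_site"][i] = t.position
            arr["int_stoich"][i] = t.stoichiometry
    return arr


def _draw_candidates(
    rng: np.random.Generator, arr: dict[str, np.ndarray], size: int, params: SimParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw fragments: transcript uniform, length truncated-normal.

    A molecule of available length ``L`` fragmented into ~``L/flen`` pieces
    yields exactly one 5'-terminal (cap-carrying) fragment, so a sampled
    fragment is terminal with probability ``flen/L`` and starts at the cap;
    otherwise its start is uniform over the interior. The terminal share is
    what produces the read-start pileup at the cap that m1 measures.
    """
    n = len(arr["length"])
    tix = rng.integers(0, n, size=size)
    a = (params.fragment_length_min - params.fragment_length_mean) / params.fragment_length_sd
    flen = stats.truncnorm.rvs(
        a,
        np.inf,
        loc=params.fragment_length_mean,
        scale=params.fragment_length_sd,
        size=size,
        random_state=rng,
    )
    flen = np.rint(flen).astype(np.int64)
    cap = arr["cap_pos"][tix]
    avail = arr["length"][tix] - cap
    flen = np.minimum(flen, avail)
    n_interior = avail - flen  # interior start positions: cap+1 .. cap+n_interior
    terminal = rng.random(size) * avail < flen
    interior_start = cap + 1 + (rng.random(size) * n_interior).astype(np.int64)
    start = np.where(terminal | (n_interior == 0), cap, interior_start)
    return tix, start, start + flen


def _accept_mask(
    rng: np.random.Generator,
    role: LibraryRole,
    tix: np.ndarray,
    start: np.ndarray,
    end: np.ndarray,
    arr: dict[str, np.ndarray],
    params: SimParams,
) -> np.ndarray:
    """Rejection-sampling acceptance: weight ``ip_enrichment`` for the
    fragments the arm's antibody pulls down, 1 otherwise."""
    if role is LibraryRole.INPUT:
        return np.ones(len(tix), dtype=bool)

    if role is LibraryRole.M7G_IP:
        reactive = start == arr["cap_pos"][tix]
    else:
        # molecule-level methylation state at each planted site
        cap_site = arr["cap_site"][tix]
        meth_cap = (cap_site >= 0) & (rng.random(len(tix)) < arr["cap_stoich"][tix])
        int_site = arr["int_site"][tix]
        meth_int = (int_site >= 0) & (rng.random(len(tix)) < arr["int_stoich"][tix])
        if role is LibraryRole.M6A_IP_FTO_PLUS:
            # FTO demethylation happens before IP selection
            meth_cap &= rng.random(len(tix)) >= params.fto_efficiency_m6am
            meth_int &= rng.random(len(tix)) >= params.fto_efficiency_m6a
        reactive = (meth_cap & (start <= cap_site) & (cap_site < end)) | (
            meth_int & (start <= int_site) & (int_site < end)
        )

    p_accept = np.where(reactive, 1.0, 1.0 / params.ip_enrichment)
    return rng.random(len(tix)) < p_accept


def simulate_libraries(
    transcripts: list[TranscriptModel],
    truth: list[TruthAnnotation],
    params: SimParams,
) -> dict[LibraryRole, AlignmentSet]:
    """Simulate the four libraries as alignment records.

    Each library receives exactly ``depth_per_library`` fragments, drawn
    from its own seeded stream so libraries are independent yet jointly
    reproducible for a fixed ``params.seed``.
    """
    params.validate()
    arr = _truth_arrays(transcripts, truth)
    tids = np.array([t.transcript_id for t in transcripts], dtype=object)

    out: dict[LibraryRole, AlignmentSet] = {}
    for k, role in enumerate(LibraryRole):
        rng = np.random.default_rng([params.seed, 1, k])
        need = params.depth_per_library
        cols: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
        got = 0
        while got < need:
            batch = int((need - got) * params.ip_enrichment * 1.2) + 1024
            tix, start, end = _draw_candidates(rng, arr, batch, params)
            keep = _accept_mask(rng, role, tix, start, end, arr, params)
            cols.append((tix[keep], start[keep], end[keep]))
            got += int(keep.sum())
        tix = np.concatenate([c[0] for c in cols])[:need]
        start = np.concatenate([c[1] for c in cols])[:need]
        end = np.concatenate([c[2] for c in cols])[:need]
        out[role] = AlignmentSet(role, tids[tix], start, end)
    return out


# ---------------------------------------------------------------------------
# synthetic Ribo-Seq / RNA-Seq gene counts
# ---------------------------------------------------------------------------

def simulate_te_counts(
    gene_ids: list[str],
    log2_tr: np.ndarray,
    depth: int = 1_000_000,
    seed: int = 0,
    balance_composition: bool = True,
) -> dict[str, pd.DataFrame]:
    """Synthetic gene-count tables with a known per-gene translation ratio.

    RNA abundance per gene is log-normal and shared between conditions;
    footprint expectation is abundance x baseline TE, multiplied by
    ``2**log2_tr`` in the "condition" sample. All four tables are Poisson
    samples scaled to ``depth`` total expected counts.

    cpm normalization recovers the planted ratios only when the
    expression-weighted effects cancel (otherwise every gene's measured
    log2 TR is offset by the library-composition shift
    ``log2(sum(e)/sum(e * 2**t))``). With ``balance_composition`` the
    abundance of down-shifted genes is rescaled so that the shift is
    exactly zero in expectation; when effects are all in one direction no
    balance is possible and the shift remains, as it would in real data.

    Returns a dict with keys ``fp_ctrl``, ``fp_cond``, ``rna_ctrl``,
    ``rna_cond``; each DataFrame has columns (gene_id, count).
    """
    rng = np.random.default_rng([seed, 2])
    g = len(gene_ids)
    log2_tr = np.asarray(log2_tr, dtype=float)
    if log2_tr.shape != (g,):
        raise ValueError("log2_tr must have one entry per gene")
    abundance = rng.lognormal(mean=0.0, sigma=0.7, size=g)
    base_te = rng.lognormal(mean=0.0, sigma=0.3, size=g)

    if balance_composition:
        e = abundance * base_te
        up = log2_tr > 0
        down = log2_tr < 0
        gain = float(np.sum(e[up] * (2.0 ** log2_tr[up] - 1.0)))
        loss = float(np.sum(e[down] * (1.0 - 2.0 ** log2_tr[down])))
        if gain > 0 and loss > 0:
            abundance[down] *= gain / loss

    def _poisson_table(expect: np.ndarray) -> pd.DataFrame:
        lam = expect / expect.sum() * depth
        return pd.DataFrame({"gene_id": gene_ids, "count": rng.poisson(lam)})

    return {
        "rna_ctrl": _poisson_table(abundance),
        "rna_cond": _poisson_table(abundance),
        "fp_ctrl": _poisson_table(abundance * base_te),
        "fp_cond": _poisson_table(abundance * base_te * 2.0**log2_tr),
    }


# ---------------------------------------------------------------------------
# truth table I/O
# ---------------------------------------------------------------------------

def write_truth(truth: list[TruthAnnotation], path) -> None:
    """Write the truth table as TSV (positions 0-based)."""
    df = pd.DataFrame(
        [
            {
                "transcript_id": t.transcript_id,
                "position": t.position,
                "mod_type": t.mod_type.value,
                "stoichiometry": t.stoichiometry,
            }
            for t in truth
        ],
        columns=["transcript_id", "position", "mod_type", "stoichiometry"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_truth(path) -> list[TruthAnnotation]:
    df = pd.read_csv(path, sep="\t")
    return [
        TruthAnnotation(
            str(r.transcript_id),
            int(r.position),
            ModType(r.mod_type),
            float(r.stoichiometry),
        )
        for r in df.itertuples(index=False)
    ]
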