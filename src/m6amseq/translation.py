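"""Translation efficiency (TE) and translation ratio (TR) from gene counts.

TE is ribosome-footprint abundance over the CDS divided by mRNA
abundance, both cpm-normalized with a symmetric pseudocount, so TE is
invariant under library-wide rescaling of either count table. TR is the
between-condition TE ratio; a gene is classified DOWN when
``log2(TR) <= -1`` (a halving — the conventional reading of a "1-fold
decrease") and UP symmetrically when ``log2(TR) >= +1``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .models import TEClass, TEResult, TRResult

__all__ = ["compute_te", "translation_ratio", "te_table", "tr_table"]

logger = logging.getLogger(__name__)


def _as_count_series(table: pd.DataFrame, what: str) -> pd.Series:
    if not {"gene_id", "count"} <= set(table.columns):
        raise ValueError(f"{what} table needs columns (gene_id, count)")
    s = table.set_index("gene_id")["count"].astype(float)
    if (s < 0).any():
        raise ValueError(f"{what} table contains negative counts")
    total = s.sum()
    if total <= 0:
        raise ValueError(f"{what} library has zero total counts")
    return s


def compute_te(
    footprint_counts: pd.DataFrame,
    rna_counts: pd.DataFrame,
    pseudocount: float = 0.5,
    condition: str = "",
) -> list[TEResult]:
    """TE per gene: ``(footprint cpm + pc) / (RNA cpm + pc)``.

    Genes missing from either table are dropped (count logged).
    """
    fp = _as_count_series(footprint_counts, "footprint")
    rna = _as_count_series(rna_counts, "RNA")
    common = fp.index.intersection(rna.index).sort_values()
    dropped = len(fp.index.union(rna.index)) - len(common)
    if dropped:
        logger.info("compute_te: dropped %d genes missing from one table", dropped)
    fp_cpm = fp[common] * 1e6 / fp.sum()
    rna_cpm = rna[common] * 1e6 / rna.sum()
    te = (fp_cpm + pseudocount) / (rna_cpm + pseudocount)
    return [
        TEResult(g, int(fp[g]), int(rna[g]), float(te[g]), condition)
        for g in common
    ]


def translation_ratio(
    te_cond: list[TEResult],
    te_ctrl: list[TEResult],
    log2_threshold: float = 1.0,
) -> list[TRResult]:
    """TR per gene (condition TE over control TE) with classification.

    Genes with control TE of 0 are excluded (count logged). Classification
    is symmetric on the log2 scale with inclusive boundaries.
    """
    cond = {r.gene_id: r.te for r in te_cond}
    ctrl = {r.gene_id: r.te for r in te_ctrl}
    common = sorted(set(cond) & set(ctrl))
    excluded = sum(1 for g in common if ctrl[g] == 0)
    if excluded:
        logger.info("translation_ratio: excluded %d genes with zero control TE", excluded)
    out = []
    for g in common:
        if ctrl[g] == 0:
            continue
        tr = cond[g] / ctrl[g]
        log2_tr = float(np.log2(tr)) if tr > 0 else float("-inf")
        if log2_tr <= -log2_threshold:
            cls = TEClass.DOWN
        elif log2_tr >= log2_threshold:
            cls = TEClass.UP
        else:
            cls = TEClass.UNCHANGED
        out.append(TRResult(g, float(tr), log2_tr, cls))
    return out


def te_table(results: list[TEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "footprint_cds_count": r.footprint_cds_count,
                "rna_count": r.rna_count,
                "te": r.te,
                "condition": r.condition,
            }
            for r in results
        ],
        columns=["gene_id", "footprint_cds_count", "rna_count", "te", "condition"],
    )


def tr_table(results: list[TRResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "tr": r.tr,
                "log2_tr": r.log2_tr,
                "te_class": r.te_class.value,
            }
            for r in results
        ],
        columns=["gene_id", "tr", "log2_tr", "te_class"],
    )
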