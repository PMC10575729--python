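"""Replicate-level and cross-assay gene-set integration.

Gene identity is the join key throughout: a gene counts once per sample
regardless of how many sites it carries. An optional site-level
intersection with positional tolerance is provided for replicate
concordance checks.
"""

from __future__ import annotations

import math

import pandas as pd

from .models import GeneSetReport, SiteCall

__all__ = [
    "genes_of",
    "shared_modified_genes",
    "shared_sites",
    "overlap_with_te",
    "venn_counts",
    "report_text",
    "report_table",
]


def genes_of(sites: list[SiteCall]) -> set[str]:
    """The set of gene IDs carrying at least one site (transcript_id used
    as a fallback key when a site has no gene annotation)."""
    return {s.gene_id or s.transcript_id for s in sites}


def shared_modified_genes(per_sample_sites: dict[str, list[SiteCall]]) -> set[str]:
    """Genes modified in every sample (intersection of per-sample sets)."""
    if not per_sample_sites:
        raise ValueError("need at least one sample")
    sets = [genes_of(s) for s in per_sample_sites.values()]
    return set.intersection(*sets)


def shared_sites(
    per_sample_sites: dict[str, list[SiteCall]], tolerance: int = 2
) -> set[tuple[str, int]]:
    """Site-level replicate intersection with +-``tolerance`` nt slack.

    A site from the first sample is kept when every other sample has a
    site on the same transcript within ``tolerance`` nt. Off by default in
    the pipeline; gene-level integration is the primary route.
    """
    if not per_sample_sites:
        raise ValueError("need at least one sample")
    samples = list(per_sample_sites.values())
    keep = set()
    for s in samples[0]:
        ok = all(
            any(
                o.transcript_id == s.transcript_id
                and abs(o.position - s.position) <= tolerance
                for o in other
            )
            for other in samples[1:]
        )
        if ok:
            keep.add((s.transcript_id, s.position))
    return keep


def overlap_with_te(
    shared: set[str],
    te_changed: set[str],
    per_sample: dict[str, set[str]] | None = None,
) -> GeneSetReport:
    """Overlap of shared modified genes with translationally changed genes.

    The fraction is reported as a percentage rounded to 1 decimal place;
    with an empty shared set it is NaN (undefined sentinel).
    """
    overlap = shared & te_changed
    fraction = (
        round(100.0 * len(overlap) / len(shared), 1) if shared else float("nan")
    )
    return GeneSetReport(
        per_sample=per_sample or {},
        shared_genes=set(shared),
        te_changed=set(te_changed),
        overlap_genes=overlap,
        fraction_percent=fraction,
    )


def venn_counts(a: set, b: set) -> tuple[int, int, int]:
    """Two-set Venn partition: (only in a, only in b, in both)."""
    both = a & b
    return len(a - b), len(b - a), len(both)


def report_table(report: GeneSetReport) -> pd.DataFrame:
    rows = [
        {"quantity": f"genes_in_{name}", "value": len(gs)}
        for name, gs in sorted(report.per_sample.items())
    ]
    rows += [
        {"quantity": "shared_modified_genes", "value": len(report.shared_genes)},
        {"quantity": "te_changed_genes", "value": len(report.te_changed)},
        {"quantity": "overlap_genes", "value": len(report.overlap_genes)},
        {"quantity": "overlap_percent", "value": report.fraction_percent},
    ]
    return pd.DataFrame(rows, columns=["quantity", "value"])


def report_text(report: GeneSetReport) -> str:
    only_m, only_te, both = venn_counts(report.shared_genes, report.te_changed)
    frac = (
        "undefined"
        if isinstance(report.fraction_percent, float)
        and math.isnan(report.fraction_percent)
        else f"{report.fraction_percent}%"
    )
    lines = ["m6Am / translation integration summary", ""]
    for name, gs in sorted(report.per_sample.items()):
        lines.append(f"  modified genes in {name}: {len(gs)}")
    lines += [
        f"  shared modified genes: {len(report.shared_genes)}",
        f"  translationally changed genes: {len(report.te_changed)}",
        f"  venn (modified-only / TE-only / both): {only_m} / {only_te} / {both}",
        f"  overlap: {len(report.overlap_genes)} of "
        f"{len(report.shared_genes)} shared modified genes ({frac})",
    ]
    return "\n".join(lines) + "\n"
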