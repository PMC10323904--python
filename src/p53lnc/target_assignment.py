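"""Regulatory-mechanism classification of recurrently regulated genes.

A gene is a *direct* p53 target when a recurrent p53-binding site lies
within 2.5 kb of one of its TSSs; *enhancer-mediated* when a high-confidence
(double-elite) linked enhancer overlaps a recurrent p53 site while no site
lies within 2.5 kb of any of the gene's TSSs. DREAM- and RB-bound genes use
the tighter 1 kb TSS window. Direct/enhancer flags are evaluated on the
recurrently up-regulated set, DREAM/RB flags on the down-regulated set,
mirroring the activating vs repressive arms of the p53 network.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .annotation_io import GeneCatalog, extract_tss_windows
from .binding_recurrence import RecurrentSiteSet

logger = logging.getLogger(__name__)

#: TSS window half-widths (bases)
P53_TSS_HALF_WIDTH = 2500
POCKET_TSS_HALF_WIDTH = 1000

ENHANCER_COLUMNS = ["chrom", "start", "end", "gene_id", "elite"]


class _SiteIndex:
    """Per-chromosome sorted disjoint intervals with O(log n) overlap tests."""

    def __init__(self, sites: pd.DataFrame):
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, sub in sites.groupby("chrom", sort=False):
            sub = sub.sort_values("start")
            self._by_chrom[chrom] = (
                sub["start"].to_numpy(),
                sub["end"].to_numpy(),
            )

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """Does any site overlap [start, end) by >= 1 base?"""
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return False
        starts, ends = entry
        # sites are disjoint and sorted: the only candidate is the last site
        # starting before `end`
        i = int(np.searchsorted(starts, end, side="left")) - 1
        return i >= 0 and ends[i] > start


def assign_tss_proximal(
    catalog: GeneCatalog,
    sites: RecurrentSiteSet,
    half_width: int,
) -> set[str]:
    """Genes with a recurrent site within ``half_width`` of any TSS.

    Overlap means >= 1 shared base between the site interval and the TSS
    window ``[tss - w, tss + w + 1)``. An empty site set yields an empty
    result.
    """
    if sites.sites.empty:
        return set()
    index = _SiteIndex(sites.sites)
    windows = extract_tss_windows(catalog, half_width)
    hit = set()
    for gene in catalog:
        for ws, we in windows[gene.gene_id]:
            if index.overlaps(gene.chrom, ws, we):
                hit.add(gene.gene_id)
                break
    return hit


def read_enhancer_links(path: str | Path) -> pd.DataFrame:
    """Enhancer:gene association TSV (chrom, start, end, gene_id, elite)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(ENHANCER_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    df["elite"] = df["elite"].astype(bool)
    return df


def assign_enhancer_mediated(
    catalog: GeneCatalog,
    sites: RecurrentSiteSet,
    links: pd.DataFrame,
    tss_half_width: int = P53_TSS_HALF_WIDTH,
) -> set[str]:
    """Genes regulated through a p53-bound enhancer rather than the promoter.

    A gene qualifies when (a) one of its elite-linked enhancers overlaps a
    recurrent p53 site and (b) no recurrent site lies within
    ``tss_half_width`` of any of the gene's TSSs — TSS-proximal binding
    takes precedence. Links pointing at unknown genes are skipped with a
    warning.
    """
    elite = links[links["elite"]]
    index = _SiteIndex(sites.sites) if not sites.sites.empty else None
    bound_genes: set[str] = set()
    for row in elite.itertuples(index=False):
        if row.gene_id not in catalog:
            logger.warning(
                "enhancer link references unknown gene %r; skipped", row.gene_id
            )
            continue
        if index is not None and index.overlaps(row.chrom, row.start, row.end):
            bound_genes.add(row.gene_id)
    direct = assign_tss_proximal(catalog, sites, tss_half_width)
    return bound_genes - direct


def build_target_annotation(
    up_set: Iterable[str],
    down_set: Iterable[str],
    p53_sites: RecurrentSiteSet,
    dream: RecurrentSiteSet,
    rb: RecurrentSiteSet,
    catalog: GeneCatalog,
    links: pd.DataFrame | None = None,
    p53_half_width: int = P53_TSS_HALF_WIDTH,
    pocket_half_width: int = POCKET_TSS_HALF_WIDTH,
    all_genes_mode: bool = False,
) -> pd.DataFrame:
    """Mechanism flags for every recurrently regulated gene.

    direct_p53 / enhancer_p53 are evaluated on the up-regulated set and
    dream / rb on the down-regulated set (unless ``all_genes_mode``, which
    evaluates every flag on the union for exploratory use). enhancer_p53
    implies not direct_p53 by construction.
    """
    up_set, down_set = set(up_set), set(down_set)
    universe = up_set | down_set
    sub = GeneCatalog(
        {g: catalog[g] for g in universe if g in catalog},
        annotation_tag=catalog.annotation_tag,
    )
    direct = assign_tss_proximal(sub, p53_sites, p53_half_width)
    if links is not None:
        enhancer = assign_enhancer_mediated(sub, p53_sites, links, p53_half_width)
    else:
        enhancer = set()
    dream_hits = assign_tss_proximal(sub, dream, pocket_half_width)
    rb_hits = assign_tss_proximal(sub, rb, pocket_half_width)

    rows = []
    for gene_id in sorted(universe):
        if gene_id not in catalog:
            continue
        in_up = gene_id in up_set or all_genes_mode
        in_down = gene_id in down_set or all_genes_mode
        rows.append(
            {
                "gene_id": gene_id,
                "regulation": "up" if gene_id in up_set else "down",
                "direct_p53": in_up and gene_id in direct,
                "enhancer_p53": in_up and gene_id in enhancer,
                "dream": in_down and gene_id in dream_hits,
                "rb": in_down and gene_id in rb_hits,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["gene_id", "regulation", "direct_p53", "enhancer_p53", "dream", "rb"],
    )
    return out.set_index("gene_id")


def dream_rb_joined(annotation: pd.DataFrame) -> set[str]:
    """The joined DREAM/RB-bound set (union of the two flags)."""
    mask = annotation["dream"] | annotation["rb"]
    return set(annotation.index[mask])
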