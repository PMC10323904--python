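"""Nested lncRNA / host-gene detection and co-regulation testing.

A lncRNA is *nested* when its full gene span lies inside a protein-coding
gene on the same strand and chromosome (overlap fraction of the lncRNA
equals 1). Co-regulation is the Spearman correlation of the two genes'
log2 fold-change vectors across the datasets in which both were testable; a
pair is called significantly positively co-regulated when rho > 0 with a
two-sided p below alpha.
"""

from __future__ import annotations

from itertools import permutations
from math import factorial

import numpy as np
import pandas as pd
from scipy import stats

from .annotation_io import LNCRNA, PROTEIN_CODING, GeneCatalog

#: below this sample size the permutation null is enumerated exactly
EXACT_PERMUTATION_BELOW = 10
DEFAULT_ALPHA = 0.05
MIN_SHARED_DATASETS = 3


def find_nested(
    catalog: GeneCatalog,
    lnc_biotype: str = LNCRNA,
    host_biotype: str = PROTEIN_CODING,
) -> pd.DataFrame:
    """All (lncRNA, host) containments, strand-aware, fraction 1.

    Containment is evaluated on gene spans; a lncRNA lying inside several
    hosts yields one pair per host. Returns columns lnc_id, host_id.
    """
    lncs = [g for g in catalog if g.biotype == lnc_biotype]
    hosts = [g for g in catalog if g.biotype == host_biotype]
    by_loc: dict[tuple[str, str], list] = {}
    for h in hosts:
        by_loc.setdefault((h.chrom, h.strand), []).append(h)
    rows = []
    for lnc in lncs:
        for h in by_loc.get((lnc.chrom, lnc.strand), []):
            if h.start <= lnc.start and lnc.end <= h.end:
                rows.append((lnc.gene_id, h.gene_id))
    return pd.DataFrame(sorted(rows), columns=["lnc_id", "host_id"])


def spearman_with_p(
    x: np.ndarray, y: np.ndarray, exact_below: int = EXACT_PERMUTATION_BELOW
) -> tuple[float, float]:
    """Spearman rho with a two-sided p-value.

    Ties receive average ranks. For n below ``exact_below`` the p-value is
    an exact permutation tail, P(|rho_perm| >= |rho_obs|) over all n!
    pairings; otherwise the large-sample t approximation is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y) or n < 2:
        raise ValueError("need two equal-length vectors of size >= 2")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        return float("nan"), float("nan")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n < exact_below:
        perms = np.array(list(permutations(ry)))
        cx = rx - rx.mean()
        cp = perms - perms.mean(axis=1, keepdims=True)
        denom = np.sqrt((cx**2).sum()) * np.sqrt((cp**2).sum(axis=1))
        rhos = (cp @ cx) / denom
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
        assert len(perms) == factorial(n)
    else:
        p = float(stats.spearmanr(x, y).pvalue)
    return rho, p


def host_coregulation(
    pairs: pd.DataFrame,
    de: pd.DataFrame,
    min_shared: int = MIN_SHARED_DATASETS,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Attach co-regulation statistics to nested pairs.

    For each pair the log2fc vectors are restricted to datasets where both
    genes were testable. Pairs with fewer than ``min_shared`` shared
    datasets are flagged untestable and carry no statistic.

    Returns the input columns plus n_shared, rho, p_value, testable and
    positive_coregulated (rho > 0 and p < alpha).
    """
    wide = de.pivot(index="dataset_id", columns="gene_id", values="log2fc")
    rows = []
    for lnc_id, host_id in pairs[["lnc_id", "host_id"]].itertuples(index=False):
        if lnc_id in wide.columns and host_id in wide.columns:
            sub = wide[[lnc_id, host_id]].dropna()
        else:
            sub = pd.DataFrame()
        n_shared = len(sub)
        if n_shared < min_shared:
            rows.append((lnc_id, host_id, n_shared, np.nan, np.nan, False, False))
            continue
        rho, p = spearman_with_p(sub[lnc_id].to_numpy(), sub[host_id].to_numpy())
        positive = bool(rho > 0 and p < alpha)
        rows.append((lnc_id, host_id, n_shared, rho, p, True, positive))
    return pd.DataFrame(
        rows,
        columns=[
            "lnc_id",
            "host_id",
            "n_shared",
            "rho",
            "p_value",
            "testable",
            "positive_coregulated",
        ],
    )


def overlap_fraction(
    lnc_span: tuple[int, int], host_span: tuple[int, int]
) -> float:
    """Fraction of the lncRNA span covered by the host span (oracle helper)."""
    s = max(lnc_span[0], host_span[0])
    e = min(lnc_span[1], host_span[1])
    return max(0, e - s) / (lnc_span[1] - lnc_span[0])
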