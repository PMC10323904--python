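"""Multi-dataset ChIP-seq peak integration into recurrent binding sites.

Per-factor peak sets are joined into a genome partition in which every
segment carries the exact set of datasets covering it (the semantics of
``bedtools multiinter``). A binding site is *recurrent* when every base is
supported by at least k of the n datasets; the published factor thresholds
are 5/28 (p53), 4/9 (E2F4), 2/4 (p130/p107) and 3/6 (RB). Recurrent DREAM
sites are the interval intersection of recurrent E2F4 and p130/p107 sites.

All intervals are 0-based half-open; BED files are consumed as-is.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

BED_COLUMNS = ["chrom", "start", "end"]

#: published per-factor recurrence thresholds (k of n datasets)
FACTOR_THRESHOLDS: dict[str, tuple[int, int]] = {
    "p53": (5, 28),
    "E2F4": (4, 9),
    "p130/p107": (2, 4),
    "RB": (3, 6),
}


@dataclass(frozen=True)
class RecurrentSiteSet:
    """Merged recurrent sites for one factor.

    ``sites`` holds disjoint, sorted (chrom, start, end) rows; every base is
    supported by >= k of the n contributing datasets (or, for the DREAM
    label, lies in both parent recurrent sets).
    """

    factor: str
    k: int
    n: int
    sites: pd.DataFrame

    def __len__(self) -> int:
        return len(self.sites)

    def covered_bases(self) -> int:
        return int((self.sites["end"] - self.sites["start"]).sum())


def read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :3]
    df.columns = BED_COLUMNS
    return df.astype({"start": int, "end": int})


def write_bed(df: pd.DataFrame, path: str | Path, extra: Sequence[str] = ()) -> None:
    df[BED_COLUMNS + list(extra)].to_csv(path, sep="\t", header=False, index=False)


def normalize_chrom(df: pd.DataFrame, style: str = "keep") -> pd.DataFrame:
    """Reconcile 'chr1' vs '1' chromosome-name dialects.

    style: 'keep' (no change), 'chr' (ensure prefix), 'plain' (strip prefix).
    """
    if style == "keep":
        return df
    out = df.copy()
    has = out["chrom"].astype(str).str.startswith("chr")
    if style == "chr":
        out.loc[~has, "chrom"] = "chr" + out.loc[~has, "chrom"].astype(str)
    elif style == "plain":
        out.loc[has, "chrom"] = out.loc[has, "chrom"].str[3:]
    else:
        raise ValueError(f"unknown chromosome style {style!r}")
    return out


def merge_intervals(df: pd.DataFrame, gap: int = 0) -> pd.DataFrame:
    """Collapse overlapping (or <= gap separated) intervals per chromosome."""
    if df.empty:
        return df[BED_COLUMNS].copy()
    rows = []
    for chrom, sub in df.sort_values(["chrom", "start", "end"]).groupby(
        "chrom", sort=True
    ):
        cur_s = cur_e = None
        for s, e in zip(sub["start"], sub["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s - cur_e <= gap:
                cur_e = max(cur_e, e)
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        rows.append((chrom, cur_s, cur_e))
    return pd.DataFrame(rows, columns=BED_COLUMNS)


def multi_intersect(peak_sets: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Partition the union of all peak sets into constant-support segments.

    Each dataset's peaks are first merged internally, so support counts
    datasets, not peaks. The output segments exactly tile the union of all
    inputs; within a segment the covering dataset set is constant and
    adjacent segments differ in it.

    Returns columns chrom, start, end, support, dataset_ids (sorted tuple).
    """
    events: dict[str, list[tuple[int, int, str]]] = {}
    for ds, df in peak_sets.items():
        bad = df["start"] >= df["end"]
        if bad.any():
            row = df[bad].iloc[0]
            raise ValueError(
                f"dataset {ds!r}: interval with start >= end at "
                f"{row['chrom']}:{row['start']}-{row['end']}"
            )
        for chrom, s, e in merge_intervals(df).itertuples(index=False):
            events.setdefault(chrom, []).append((s, +1, ds))
            events[chrom].append((e, -1, ds))

    rows = []
    for chrom in sorted(events):
        evs = sorted(events[chrom], key=lambda t: t[0])
        active: set[str] = set()
        i, m = 0, len(evs)
        while i < m:
            pos = evs[i][0]
            if active:
                rows.append((chrom, prev, pos, tuple(sorted(active))))
            while i < m and evs[i][0] == pos:
                _, delta, ds = evs[i]
                if delta > 0:
                    active.add(ds)
                else:
                    active.discard(ds)
                i += 1
            prev = pos
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "dataset_ids"])
    out.insert(3, "support", out["dataset_ids"].map(len))
    # merging within a dataset guarantees support changes at every boundary,
    # except where two boundaries coincide across datasets with no net change
    merged = []
    for chrom, sub in out.groupby("chrom", sort=False):
        prev_row = None
        for row in sub.itertuples(index=False):
            if (
                prev_row is not None
                and prev_row[2] == row[1]
                and prev_row[4] == row[4]
            ):
                prev_row = (chrom, prev_row[1], row[2], row[3], row[4])
            else:
                if prev_row is not None:
                    merged.append(prev_row)
                prev_row = tuple(row)
        if prev_row is not None:
            merged.append(prev_row)
    return pd.DataFrame(
        merged, columns=["chrom", "start", "end", "support", "dataset_ids"]
    )


def recurrent_sites(
    partition: pd.DataFrame,
    k: int,
    merge_gap: int = 0,
    factor: str = "",
    n: int | None = None,
) -> RecurrentSiteSet:
    """Keep partition segments supported by >= k datasets and merge them.

    ``merge_gap`` is the largest separation (bases) bridged when merging
    kept segments; the default 0 merges book-ended segments only.
    """
    if n is None:
        n = len({ds for ids in partition["dataset_ids"] for ds in ids})
    if not 1 <= k <= max(n, 1):
        raise ValueError(f"recurrence threshold k={k} outside 1..{n}")
    kept = partition[partition["support"] >= k]
    sites = merge_intervals(kept[BED_COLUMNS], gap=merge_gap)
    return RecurrentSiteSet(factor=factor, k=k, n=n, sites=sites)


def recurrent_sites_from_peaks(
    peak_sets: Mapping[str, pd.DataFrame],
    k: int,
    factor: str = "",
    merge_gap: int = 0,
) -> RecurrentSiteSet:
    """Convenience: multi_intersect + recurrent_sites in one call."""
    part = multi_intersect(peak_sets)
    return recurrent_sites(
        part, k=k, merge_gap=merge_gap, factor=factor, n=len(peak_sets)
    )


def load_precompiled_sites(
    path: str | Path, factor: str, k: int, n: int
) -> RecurrentSiteSet:
    """Load an already-integrated recurrent-site BED (e.g. the published
    7705-site p53 collection, k=5 of n=28)."""
    sites = merge_intervals(read_bed(path))
    return RecurrentSiteSet(factor=factor, k=k, n=n, sites=sites)


def dream_sites(
    e2f4: RecurrentSiteSet, p130p107: RecurrentSiteSet
) -> RecurrentSiteSet:
    """Recurrent DREAM sites: interval intersection of E2F4 and p130/p107.

    Only overlapping portions are retained; the base set of the result is
    exactly the intersection of the parents' base sets.
    """
    rows = []
    a = e2f4.sites
    b = p130p107.sites
    for chrom in sorted(set(a["chrom"]) & set(b["chrom"])):
        sa = a[a["chrom"] == chrom].sort_values("start")
        sb = b[b["chrom"] == chrom].sort_values("start")
        ia = ib = 0
        va = list(zip(sa["start"], sa["end"]))
        vb = list(zip(sb["start"], sb["end"]))
        while ia < len(va) and ib < len(vb):
            s = max(va[ia][0], vb[ib][0])
            e = min(va[ia][1], vb[ib][1])
            if s < e:
                rows.append((chrom, s, e))
            if va[ia][1] <= vb[ib][1]:
                ia += 1
            else:
                ib += 1
    sites = pd.DataFrame(rows, columns=BED_COLUMNS)
    return RecurrentSiteSet(factor="DREAM", k=0, n=0, sites=sites)


def coverage_mask(sites: pd.DataFrame, chrom: str, length: int) -> np.ndarray:
    """Boolean per-base coverage on one chromosome (test/oracle helper)."""
    mask = np.zeros(length, dtype=bool)
    for _, s, e in sites[sites["chrom"] == chrom][BED_COLUMNS].itertuples(
        index=False
    ):
        mask[max(0, s) : min(length, e)] = True
    return mask
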