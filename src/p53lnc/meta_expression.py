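"""Recurrence scoring across differential-expression compendia.

The expression score of a gene is the number of datasets that call it
significantly up-regulated after p53 activation minus the number that call
it significantly down-regulated. A gene enters the score table only when it
was testable (a log2 fold-change and FDR were assigned) in at least
``min_expressed`` datasets; by default three. The median log2 fold-change is
taken over all testable entries regardless of significance, which captures
recurrent low-abundance responders that rarely clear per-dataset
significance.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

DE_COLUMNS = ["dataset_id", "gene_id", "log2fc", "fdr"]

#: significance threshold applied per dataset
DEFAULT_SIG_FDR = 0.05
#: minimum number of datasets in which a gene must be testable
DEFAULT_MIN_EXPRESSED = 3
#: conservative recurrence thresholds on the score
DEFAULT_UP_THRESHOLD = 10
DEFAULT_DOWN_THRESHOLD = -10


def read_de_tables(
    paths: Mapping[str, str | Path] | None = None,
    long_path: str | Path | None = None,
) -> pd.DataFrame:
    """Load a DE compendium into long format.

    Either one TSV per dataset (``paths`` maps dataset_id -> file with
    columns gene_id, log2fc, fdr) or a single long-format TSV with a
    dataset_id column. Absent (gene, dataset) rows mean the gene was not
    testable in that dataset.
    """
    if (paths is None) == (long_path is None):
        raise ValueError("provide exactly one of paths / long_path")
    if long_path is not None:
        df = pd.read_csv(long_path, sep="\t")
        missing = set(DE_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"{long_path}: missing columns {sorted(missing)}")
        return df[DE_COLUMNS + [c for c in df.columns if c not in DE_COLUMNS]]
    frames = []
    for dataset_id, p in paths.items():
        t = pd.read_csv(p, sep="\t")
        t.insert(0, "dataset_id", dataset_id)
        frames.append(t)
    return pd.concat(frames, ignore_index=True)


def _validate(de: pd.DataFrame) -> pd.DataFrame:
    dup = de.duplicated(subset=["gene_id", "dataset_id"])
    if dup.any():
        example = de.loc[dup, ["gene_id", "dataset_id"]].iloc[0]
        raise ValueError(
            "duplicate DE entry for gene "
            f"{example.gene_id!r} in dataset {example.dataset_id!r}"
        )
    if not np.isfinite(de["log2fc"]).all():
        bad = de.loc[~np.isfinite(de["log2fc"]), "gene_id"].iloc[0]
        raise ValueError(f"non-finite log2fc for present entry of gene {bad!r}")
    return de


def compute_scores(
    de: pd.DataFrame,
    sig_fdr: float = DEFAULT_SIG_FDR,
    min_expressed: int = DEFAULT_MIN_EXPRESSED,
) -> pd.DataFrame:
    """Per-gene recurrence summary over a long-format DE compendium.

    Parameters
    ----------
    de
        Long-format table (dataset_id, gene_id, log2fc, fdr); only testable
        entries are present. An optional ``call`` column with values
        up/down/ns overrides the fdr/log2fc significance rule, allowing
        published per-dataset calls to be reused verbatim.
    sig_fdr
        Per-dataset significance: ``fdr < sig_fdr``.
    min_expressed
        Genes testable in fewer datasets are dropped from the output
        entirely (not reported with score 0).

    Returns
    -------
    DataFrame indexed by gene_id with columns n_expressed, n_up, n_down,
    score, median_log2fc. Direction requires a non-zero log2fc: a
    significant entry with log2fc == 0 counts neither up nor down.
    """
    if de.empty:
        raise ValueError("empty DE compendium")
    if not 0 < sig_fdr < 1:
        raise ValueError("sig_fdr must be in (0, 1)")
    if min_expressed < 1:
        raise ValueError("min_expressed must be >= 1")
    de = _validate(de)

    if "call" in de.columns:
        up = de["call"].eq("up")
        down = de["call"].eq("down")
    else:
        sig = de["fdr"] < sig_fdr
        up = sig & (de["log2fc"] > 0)
        down = sig & (de["log2fc"] < 0)

    grouped = pd.DataFrame(
        {
            "gene_id": de["gene_id"],
            "up": up,
            "down": down,
            "log2fc": de["log2fc"],
        }
    ).groupby("gene_id", sort=True)
    out = grouped.agg(
        n_expressed=("log2fc", "size"),
        n_up=("up", "sum"),
        n_down=("down", "sum"),
        median_log2fc=("log2fc", "median"),
    )
    out["score"] = out["n_up"] - out["n_down"]
    out = out[out["n_expressed"] >= min_expressed]
    return out[["n_expressed", "n_up", "n_down", "score", "median_log2fc"]]


def classify_recurrent(
    scores: pd.DataFrame,
    up_threshold: int = DEFAULT_UP_THRESHOLD,
    down_threshold: int = DEFAULT_DOWN_THRESHOLD,
) -> tuple[set[str], set[str]]:
    """Split the score table into recurrently up- and down-regulated genes.

    Thresholds are inclusive: score >= up_threshold / score <= down_threshold.
    """
    if not up_threshold > 0 > down_threshold:
        raise ValueError("need up_threshold > 0 > down_threshold")
    up = set(scores.index[scores["score"] >= up_threshold])
    down = set(scores.index[scores["score"] <= down_threshold])
    return up, down


def median_log2fc_profile(
    gene_id: str, de: pd.DataFrame
) -> tuple[float, pd.Series]:
    """Median log2 fold-change of one gene plus its per-dataset vector.

    The median ignores significance; an even number of values yields the
    midpoint of the two central ones.
    """
    sub = de[de["gene_id"] == gene_id]
    if sub.empty:
        raise ValueError(f"no expression data for gene {gene_id!r}")
    vec = sub.set_index("dataset_id")["log2fc"]
    return float(vec.median()), vec


def restrict_to_genes(de: pd.DataFrame, gene_ids: Iterable[str]) -> pd.DataFrame:
    """Subset a long-format compendium to a gene universe (e.g. lncRNAs)."""
    return de[de["gene_id"].isin(set(gene_ids))].reset_index(drop=True)


def write_score_table(
    scores: pd.DataFrame, path: str | Path, names: Mapping[str, str] | None = None
) -> None:
    """Write the score table TSV; optionally adds a display-name column."""
    out = scores.reset_index()
    if names is not None:
        out.insert(1, "name", out["gene_id"].map(dict(names)).fillna(out["gene_id"]))
    out.to_csv(path, sep="\t", index=False)
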