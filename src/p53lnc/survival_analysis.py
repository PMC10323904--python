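"""Gene-set survival stratification.

Each patient receives a single-sample enrichment score for a lncRNA gene
set (rank-weighted running sum over the sample's expression ranking), the
cohort is split into score tertiles (low / medium / high), and the tertile
groups are related to overall survival with a Cox proportional-hazards
model adjusted for age and sex. Analyses can be repeated within p53
wild-type and mutant sub-cohorts, and gene-set overlaps are tested with
Fisher's exact test.

The enrichment statistic for a sample with N genes ranked descending by
expression (average ranks on ties, rank weight N for the top gene) is

    ES = sum_i [ P_in(i) - P_out(i) ]
    P_in(i)  = sum_{set genes at position <= i} w^alpha / sum_{set} w^alpha
    P_out(i) = #(non-set genes at position <= i) / #(non-set genes)

with alpha = 0.75 by default. Raw scores are rescaled by the cohort's
score range before grouping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy import stats

DEFAULT_SSGSEA_ALPHA = 0.75
GROUP_LABELS = ("low", "medium", "high")

COHORT_COLUMNS = ["sample_id", "time_days", "event", "age", "sex", "p53_status"]


def ssgsea_score(
    expr: pd.DataFrame,
    gene_set: Iterable[str],
    alpha: float = DEFAULT_SSGSEA_ALPHA,
) -> pd.Series:
    """Raw single-sample enrichment score per sample (column) of ``expr``.

    ``expr`` is a genes × samples matrix; scores depend only on each
    sample's within-sample expression ranking, so any strictly increasing
    per-sample transform leaves them unchanged.
    """
    gene_set = set(gene_set)
    in_set = expr.index.isin(gene_set)
    n_in = int(in_set.sum())
    if n_in == 0:
        raise ValueError("gene set does not intersect the expression matrix")
    if n_in == len(expr.index):
        raise ValueError("gene set covers every gene; outside fraction undefined")
    scores = {}
    n = len(expr.index)
    n_out = n - n_in
    for sample in expr.columns:
        values = expr[sample].to_numpy(dtype=float)
        ranks = stats.rankdata(values)  # ascending, average ties
        # descending order; ties broken by gene label for determinism
        order = np.lexsort((expr.index.to_numpy(), -ranks))
        weights = np.where(in_set[order], ranks[order] ** alpha, 0.0)
        p_in = np.cumsum(weights) / weights.sum()
        p_out = np.cumsum(~in_set[order]) / n_out
        scores[sample] = float(np.sum(p_in - p_out))
    return pd.Series(scores, name="raw_es")


def normalize_scores(raw: pd.Series) -> pd.Series:
    """Rescale raw scores by the cohort's score range (max - min)."""
    if len(raw) < 2:
        warnings.warn("single sample: normalization is a pass-through", stacklevel=2)
        return raw.copy()
    span = raw.max() - raw.min()
    if span == 0:
        warnings.warn("constant enrichment scores; normalized to zero", stacklevel=2)
        return pd.Series(0.0, index=raw.index, name=raw.name)
    return raw / span


def tertile_groups(scores: pd.Series) -> pd.Series:
    """Assign low / medium / high by score tertile.

    Samples are sorted by (score, sample id) so ties resolve
    deterministically. When n is not divisible by 3, the extra sample goes
    to the low group first, then the high group — sizes differ by at most
    one, |low| >= |medium| and |low| >= |high|.
    """
    n = len(scores)
    if n < 3:
        raise ValueError("need at least 3 samples for tertiles")
    order = scores.sort_index().sort_values(kind="stable").index
    base, rem = divmod(n, 3)
    sizes = [base + (1 if rem >= 1 else 0), base, base + (1 if rem == 2 else 0)]
    labels = np.repeat(GROUP_LABELS, sizes)
    return pd.Series(labels, index=order, name="group").reindex(scores.index)


@dataclass
class CoxResult:
    """Hazard ratios (vs the low group) with CIs, and the group LR test."""

    summary: pd.DataFrame  # rows: group_medium, group_high, age, sex_male
    lr_statistic: float
    lr_p: float
    n: int
    n_events: int


def _cox_frame(cohort: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    df = cohort.set_index("sample_id") if "sample_id" in cohort.columns else cohort
    out = pd.DataFrame(
        {
            "time": df["time_days"].astype(float),
            "event": df["event"].astype(int),
            "age": df["age"].astype(float),
            "sex_male": (df["sex"] == "male").astype(int),
        }
    )
    g = groups.reindex(out.index)
    out["group_medium"] = (g == "medium").astype(int)
    out["group_high"] = (g == "high").astype(int)
    return out


def cox_fit(cohort: pd.DataFrame, groups: pd.Series) -> CoxResult:
    """Cox PH fit of survival on score group, adjusted for age and sex.

    Efron handling for tied event times; the likelihood-ratio p compares
    the full model against the same model without the two group
    indicators. Raises when fewer than two groups carry an event.
    """
    df = _cox_frame(cohort, groups)
    if df["event"].sum() == 0:
        raise ValueError("no events in the cohort; Cox model undefined")
    g = groups.reindex(df.index)
    events_per_group = df.groupby(g.values)["event"].sum()
    with_events = (events_per_group > 0).sum()
    if len(events_per_group) < 2 or with_events < 2:
        empty = events_per_group[events_per_group == 0].index.tolist()
        raise ValueError(
            f"need >= 2 groups with events; event-free strata: {empty or 'n/a'}"
        )
    full = CoxPHFitter()
    full.fit(df, duration_col="time", event_col="event")
    reduced = CoxPHFitter()
    reduced.fit(
        df.drop(columns=["group_medium", "group_high"]),
        duration_col="time",
        event_col="event",
    )
    lr = 2 * (full.log_likelihood_ - reduced.log_likelihood_)
    lr_p = float(stats.chi2.sf(lr, df=2))
    summary = full.summary[["exp(coef)", "exp(coef) lower 95%", "exp(coef) upper 95%", "p"]]
    summary = summary.rename(
        columns={
            "exp(coef)": "hr",
            "exp(coef) lower 95%": "hr_ci_low",
            "exp(coef) upper 95%": "hr_ci_high",
        }
    )
    return CoxResult(
        summary=summary,
        lr_statistic=float(lr),
        lr_p=lr_p,
        n=len(df),
        n_events=int(df["event"].sum()),
    )


def km_estimate(
    cohort: pd.DataFrame,
    groups: pd.Series,
    plot_horizon: float = 5000.0,
) -> dict[str, pd.DataFrame]:
    """Kaplan–Meier curves per score group.

    Returns one step-function table (time, survival) per group. The
    product-limit estimate itself is unaffected by ``plot_horizon``; a
    truncated copy for display is exposed by :func:`truncate_km`.
    """
    df = _cox_frame(cohort, groups)
    g = groups.reindex(df.index)
    curves: dict[str, pd.DataFrame] = {}
    for label in GROUP_LABELS:
        mask = (g == label).to_numpy()
        if not mask.any():
            warnings.warn(f"empty group {label!r} omitted from KM", stacklevel=2)
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(df.loc[mask, "time"], df.loc[mask, "event"], label=label)
        sf = kmf.survival_function_
        curves[label] = pd.DataFrame(
            {"time": sf.index.to_numpy(dtype=float), "survival": sf[label].to_numpy()}
        )
    return curves


def truncate_km(curves: Mapping[str, pd.DataFrame], horizon: float) -> dict[str, pd.DataFrame]:
    return {k: v[v["time"] <= horizon].reset_index(drop=True) for k, v in curves.items()}


def plot_km(curves: Mapping[str, pd.DataFrame], path: str | Path, horizon: float = 5000.0) -> None:
    """Optional Kaplan–Meier plot (display truncated at ``horizon`` days)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for label, curve in truncate_km(curves, horizon).items():
        ax.step(curve["time"], curve["survival"], where="post", label=label)
    ax.set_xlabel("days")
    ax.set_ylabel("overall survival")
    ax.set_ylim(0, 1.02)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def split_by_p53(cohort: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(wild-type, mutant) sub-cohorts; unknown-status samples are dropped."""
    wt = cohort[cohort["p53_status"] == "wild_type"].reset_index(drop=True)
    mut = cohort[cohort["p53_status"] == "mutant"].reset_index(drop=True)
    return wt, mut


def overlap_fisher(
    set_a: Iterable[str], set_b: Iterable[str], background: Iterable[str]
) -> tuple[float, float]:
    """Fisher's exact test of the overlap of two gene sets over a background.

    Returns (odds ratio, two-sided p) from the 2×2 membership table.
    """
    background = set(background)
    if not background:
        raise ValueError("empty background")
    a = set(set_a) & background
    b = set(set_b) & background
    if set(set_a) - background or set(set_b) - background:
        raise ValueError("gene sets must be subsets of the background")
    both = len(a & b)
    only_a = len(a) - both
    only_b = len(b) - both
    neither = len(background) - both - only_a - only_b
    odds, p = stats.fisher_exact(
        [[both, only_a], [only_b, neither]], alternative="two-sided"
    )
    return float(odds), float(p)


def read_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if (df["time_days"] <= 0).any():
        raise ValueError(f"{path}: non-positive survival time")
    if not df["event"].isin([0, 1]).all():
        raise ValueError(f"{path}: event must be 0/1")
    return df


def read_gene_set(path: str | Path, set_name: str | None = None) -> list[str]:
    """One gene id per line, or a GMT file (pick ``set_name``)."""
    lines = [ln.rstrip("\n") for ln in open(path) if ln.strip()]
    if lines and "\t" in lines[0]:
        sets = {}
        for ln in lines:
            parts = ln.split("\t")
            sets[parts[0]] = [g for g in parts[2:] if g]
        if set_name is None:
            if len(sets) != 1:
                raise ValueError("GMT holds several sets; pass set_name")
            return next(iter(sets.values()))
        return sets[set_name]
    return lines
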