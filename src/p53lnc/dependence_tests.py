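"""Perturbation-dependence analyses on TPM-level expression.

Treated-vs-control contrasts use a two-sided unpaired Student's t-test
(pooled variance) on log2(TPM + 1) values. Three classifications share this
machinery:

* p21 dependence — a gene is repressed by p53 through p21 when it is
  significantly repressed in parental cells but repression fails in the
  p21-null line (not significant, or the log2 repression magnitude drops
  below half the parental one).
* pocket-protein predominance — across a depletion series (parental,
  RB-depleted, p130/p107-depleted, triple-depleted), repression lost only
  under RB depletion marks RB predominance, the mirror case marks DREAM
  (p130/p107) predominance, loss only in the triple marks cooperation.
* mediator dependence (e.g. siRFX7 vs siControl) reuses the p21 rule with
  the knockdown standing in for the knockout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_ALPHA = 0.05
#: knockout repression below this fraction of the parental magnitude counts
#: as a failure of repression even when nominally significant
FAILURE_FRACTION = 0.5
#: a gene is "detected" when its mean TPM in the parental control arm
#: reaches this floor
DETECTION_TPM = 1.0

POCKET_GENOTYPES = ("parental", "rb_depleted", "p130p107_depleted", "triple_depleted")


class TTestResult(NamedTuple):
    t: float
    df: int
    p: float
    degenerate: bool = False


def ttest_two_sided(a, b) -> TTestResult:
    """Pooled-variance two-sided unpaired Student's t-test.

    Degenerate inputs: zero pooled variance with equal means gives
    t = 0, p = 1; zero variance with unequal means gives p = 0 flagged
    degenerate.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 replicates per group")
    na, nb = len(a), len(b)
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    diff = a.mean() - b.mean()
    if sp2 == 0:
        if diff == 0:
            return TTestResult(0.0, df, 1.0, False)
        return TTestResult(float(np.sign(diff)) * np.inf, df, 0.0, True)
    t = diff / np.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * stats.t.sf(abs(t), df)
    return TTestResult(float(t), df, float(p), False)


@dataclass(frozen=True)
class TpmExperiment:
    """Replicate TPM values of one gene under a control/treated contrast."""

    gene_id: str
    control: np.ndarray
    treated: np.ndarray

    def __post_init__(self) -> None:
        for arm in (self.control, self.treated):
            if np.any(np.asarray(arm) < 0):
                raise ValueError(f"{self.gene_id}: negative TPM")


@dataclass
class DependenceCall:
    gene_id: str
    call: str
    reason: str = ""
    contrasts: dict = field(default_factory=dict)


def _log2_tpm(x: np.ndarray, log_scale: bool) -> np.ndarray:
    return np.log2(np.asarray(x, dtype=float) + 1.0) if log_scale else np.asarray(x, float)


def repression_contrast(
    exp: TpmExperiment, alpha: float = DEFAULT_ALPHA, log_scale: bool = True
) -> dict:
    """Treated-vs-control contrast with log2 effect, t, p and repression call."""
    a = _log2_tpm(exp.treated, log_scale)
    b = _log2_tpm(exp.control, log_scale)
    res = ttest_two_sided(a, b)
    delta = float(a.mean() - b.mean())
    return {
        "delta_log2": delta,
        "t": res.t,
        "p": res.p,
        "df": res.df,
        "repressed": bool(delta < 0 and res.p < alpha),
        "induced": bool(delta > 0 and res.p < alpha),
    }


def classify_p21_dependence(
    parental: TpmExperiment | None,
    knockout: TpmExperiment | None,
    alpha: float = DEFAULT_ALPHA,
    failure_fraction: float = FAILURE_FRACTION,
    log_scale: bool = True,
) -> DependenceCall:
    """p21 dependence of p53-mediated repression.

    p21_dependent iff (i) the parental line shows significant repression
    and (ii) repression fails in the knockout: not significant at alpha, or
    a log2 repression magnitude below ``failure_fraction`` of the parental
    one. A missing arm renders the gene untestable.
    """
    gene_id = (parental or knockout).gene_id if (parental or knockout) else "?"
    if parental is None or knockout is None:
        return DependenceCall(gene_id, "untestable", "missing experiment arm")
    par = repression_contrast(parental, alpha, log_scale)
    ko = repression_contrast(knockout, alpha, log_scale)
    contrasts = {"parental": par, "knockout": ko}
    if not par["repressed"]:
        return DependenceCall(
            gene_id, "not_p21_dependent", "no significant parental repression", contrasts
        )
    failure = (not ko["repressed"]) or (
        abs(ko["delta_log2"]) < failure_fraction * abs(par["delta_log2"])
    )
    if failure:
        return DependenceCall(gene_id, "p21_dependent", "repression fails in knockout", contrasts)
    return DependenceCall(
        gene_id, "not_p21_dependent", "repression retained in knockout", contrasts
    )


def classify_pocket_dependence(
    experiments: Mapping[str, TpmExperiment | None],
    alpha: float = DEFAULT_ALPHA,
    detection_tpm: float = DETECTION_TPM,
    log_scale: bool = True,
) -> DependenceCall:
    """Predominance of RB vs p130/p107 (DREAM) in mediating repression.

    ``experiments`` maps the four genotypes of :data:`POCKET_GENOTYPES` to
    contrasts. The parental line must be detected (mean control TPM >=
    ``detection_tpm``) and significantly repressed; otherwise the call is
    ``not_detected``. With repression states per genotype:

    * RB_predominant — lost in RB-depleted, retained in p130/p107-depleted
    * DREAM_predominant — the mirror case
    * cooperative — retained in both single depletions
    * unresolved — anything else

    Every non-unresolved call additionally requires loss of repression in
    the triple depletion.
    """
    gene_id = next(
        (e.gene_id for e in experiments.values() if e is not None), "?"
    )
    missing = [g for g in POCKET_GENOTYPES if experiments.get(g) is None]
    if "parental" in missing:
        return DependenceCall(gene_id, "not_detected", "missing parental arm")
    parental = experiments["parental"]
    if float(np.mean(parental.control)) < detection_tpm:
        return DependenceCall(gene_id, "not_detected", "below detection floor")
    par = repression_contrast(parental, alpha, log_scale)
    if not par["repressed"]:
        return DependenceCall(
            gene_id, "not_detected", "no parental repression", {"parental": par}
        )
    if missing:
        return DependenceCall(
            gene_id, "unresolved", f"missing genotype arms: {','.join(missing)}",
            {"parental": par},
        )
    contrasts = {"parental": par}
    state = {}
    for genotype in POCKET_GENOTYPES[1:]:
        c = repression_contrast(experiments[genotype], alpha, log_scale)
        contrasts[genotype] = c
        state[genotype] = c["repressed"]
    triple_lost = not state["triple_depleted"]
    rb_lost = not state["rb_depleted"]
    dream_lost = not state["p130p107_depleted"]
    if triple_lost and rb_lost and not dream_lost:
        call, reason = "RB_predominant", "repression lost only under RB depletion"
    elif triple_lost and dream_lost and not rb_lost:
        call, reason = "DREAM_predominant", "repression lost only under p130/p107 depletion"
    elif triple_lost and not rb_lost and not dream_lost:
        call, reason = "cooperative", "repression lost only in the triple depletion"
    else:
        call, reason = "unresolved", "repression pattern matches no rule"
    return DependenceCall(gene_id, call, reason, contrasts)


# -- matrix-level drivers -----------------------------------------------------

SAMPLE_SHEET_COLUMNS = ["sample", "genotype", "treatment"]


def _arm_values(
    tpm: pd.DataFrame, samples: pd.DataFrame, gene_id: str, genotype: str, treatment: str
) -> np.ndarray | None:
    sel = samples[(samples["genotype"] == genotype) & (samples["treatment"] == treatment)]
    cols = [s for s in sel["sample"] if s in tpm.columns]
    if len(cols) < 2 or gene_id not in tpm.index:
        return None
    return tpm.loc[gene_id, cols].to_numpy(dtype=float)


def experiment_from_matrix(
    tpm: pd.DataFrame, samples: pd.DataFrame, gene_id: str, genotype: str
) -> TpmExperiment | None:
    """Assemble one gene × genotype contrast from a TPM matrix + sample sheet.

    The sample sheet needs columns sample, genotype, treatment with
    treatment in {control, treated}; returns None when either arm has
    fewer than two replicates.
    """
    control = _arm_values(tpm, samples, gene_id, genotype, "control")
    treated = _arm_values(tpm, samples, gene_id, genotype, "treated")
    if control is None or treated is None:
        return None
    return TpmExperiment(gene_id, control=control, treated=treated)


def p21_dependence_table(
    tpm: pd.DataFrame,
    samples: pd.DataFrame,
    gene_ids,
    parental_genotype: str = "parental",
    knockout_genotype: str = "p21ko",
    alpha: float = DEFAULT_ALPHA,
    failure_fraction: float = FAILURE_FRACTION,
) -> pd.DataFrame:
    """Apply :func:`classify_p21_dependence` over a gene list."""
    rows = []
    for g in gene_ids:
        call = classify_p21_dependence(
            experiment_from_matrix(tpm, samples, g, parental_genotype),
            experiment_from_matrix(tpm, samples, g, knockout_genotype),
            alpha=alpha,
            failure_fraction=failure_fraction,
        )
        par = call.contrasts.get("parental", {})
        ko = call.contrasts.get("knockout", {})
        rows.append(
            (
                g,
                call.call,
                call.reason,
                par.get("delta_log2", np.nan),
                par.get("p", np.nan),
                ko.get("delta_log2", np.nan),
                ko.get("p", np.nan),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "call",
            "reason",
            "parental_delta_log2",
            "parental_p",
            "knockout_delta_log2",
            "knockout_p",
        ],
    ).set_index("gene_id")


def pocket_dependence_table(
    tpm: pd.DataFrame,
    samples: pd.DataFrame,
    gene_ids,
    alpha: float = DEFAULT_ALPHA,
    detection_tpm: float = DETECTION_TPM,
) -> pd.DataFrame:
    """Apply :func:`classify_pocket_dependence` over a gene list."""
    rows = []
    for g in gene_ids:
        exps = {
            genotype: experiment_from_matrix(tpm, samples, g, genotype)
            for genotype in POCKET_GENOTYPES
        }
        call = classify_pocket_dependence(
            exps, alpha=alpha, detection_tpm=detection_tpm
        )
        rows.append((g, call.call, call.reason))
    return pd.DataFrame(rows, columns=["gene_id", "call", "reason"]).set_index(
        "gene_id"
    )
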