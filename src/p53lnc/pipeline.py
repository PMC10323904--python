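"""End-to-end orchestration: one config, one report bundle.

Stages run in method order — recurrence scoring, binding-site recurrence,
mechanism assignment, nested co-regulation, then the optional perturbation
and survival analyses — and a JSON manifest records the configuration and
the count funnel at every stage (annotated → expressed → recurrently
regulated → mechanism-classified).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import (
    annotation_io,
    binding_recurrence,
    dependence_tests,
    meta_expression,
    nested_coregulation,
    survival_analysis,
    target_assignment,
)
from .binding_recurrence import FACTOR_THRESHOLDS, RecurrentSiteSet

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or incomplete pipeline configuration."""


class StageError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All inputs and thresholds of one landscape run."""

    outdir: str = "landscape_out"
    seed: int = 0
    # inputs
    annotation: str | None = None
    de: str | None = None
    peaks: dict[str, str] = field(default_factory=dict)  # factor -> BED dir
    p53_sites_bed: str | None = None  # precompiled recurrent p53 sites
    enhancer_links: str | None = None
    tpm_p21: str | None = None
    samples_p21: str | None = None
    tpm_pocket: str | None = None
    samples_pocket: str | None = None
    cohort: str | None = None
    cohort_tpm: str | None = None
    gene_set: str | None = None
    # thresholds
    sig_fdr: float = meta_expression.DEFAULT_SIG_FDR
    min_expressed: int = meta_expression.DEFAULT_MIN_EXPRESSED
    up_threshold: int = meta_expression.DEFAULT_UP_THRESHOLD
    down_threshold: int = meta_expression.DEFAULT_DOWN_THRESHOLD
    recurrence_k: dict[str, int] = field(
        default_factory=lambda: {f: k for f, (k, _) in FACTOR_THRESHOLDS.items()}
    )
    p53_tss_half_width: int = target_assignment.P53_TSS_HALF_WIDTH
    pocket_tss_half_width: int = target_assignment.POCKET_TSS_HALF_WIDTH
    alpha: float = 0.05
    ssgsea_alpha: float = survival_analysis.DEFAULT_SSGSEA_ALPHA
    km_horizon: float = 5000.0

    def validate(self) -> None:
        if not 0 < self.sig_fdr < 1:
            raise ConfigError("sig_fdr must be in (0, 1)")
        if self.min_expressed < 1:
            raise ConfigError("min_expressed must be >= 1")
        if not self.up_threshold > 0 > self.down_threshold:
            raise ConfigError("need up_threshold > 0 > down_threshold")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")
        for f, k in self.recurrence_k.items():
            if k < 1:
                raise ConfigError(f"recurrence threshold for {f!r} must be >= 1")
        for name in ("p53_tss_half_width", "pocket_tss_half_width"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text()) or {}
        except (OSError, yaml.YAMLError) as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _require(config: PipelineConfig, *names: str) -> None:
    missing = [n for n in names if not getattr(config, n)]
    if missing:
        raise ConfigError(f"config lacks required inputs: {missing}")


def _outdir(config: PipelineConfig) -> Path:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    return out


# -- stages -------------------------------------------------------------------


def stage_score(config: PipelineConfig) -> dict:
    """Expression-score stage; returns tables and the count funnel."""
    _require(config, "annotation", "de")
    catalog = annotation_io.read_gene_annotation(config.annotation)
    de = meta_expression.read_de_tables(long_path=config.de)
    scores = meta_expression.compute_scores(
        de, sig_fdr=config.sig_fdr, min_expressed=config.min_expressed
    )
    lnc_ids = {g.gene_id for g in catalog if g.biotype == annotation_io.LNCRNA}
    lnc_scores = scores[scores.index.isin(lnc_ids)]
    up, down = meta_expression.classify_recurrent(
        lnc_scores, config.up_threshold, config.down_threshold
    )
    out = _outdir(config)
    names = {g.gene_id: g.name for g in catalog}
    meta_expression.write_score_table(scores, out / "scores.tsv", names=names)
    counts = {
        "genes_annotated": len(catalog),
        "lnc_annotated": len(lnc_ids),
        "genes_scored": int(len(scores)),
        "lnc_scored": int(len(lnc_scores)),
        "lnc_up_recurrent": len(up),
        "lnc_down_recurrent": len(down),
    }
    return {
        "catalog": catalog,
        "de": de,
        "scores": scores,
        "up": up,
        "down": down,
        "counts": counts,
    }


def _read_peak_dir(path: str) -> dict[str, pd.DataFrame]:
    beds = sorted(Path(path).glob("*.bed"))
    if not beds:
        raise FileNotFoundError(f"no BED files under {path}")
    return {p.stem: binding_recurrence.read_bed(p) for p in beds}


def stage_recurrence(config: PipelineConfig) -> dict[str, RecurrentSiteSet]:
    """Recurrent sites per factor plus the derived DREAM set."""
    sites: dict[str, RecurrentSiteSet] = {}
    if config.p53_sites_bed:
        k, n = FACTOR_THRESHOLDS["p53"]
        sites["p53"] = binding_recurrence.load_precompiled_sites(
            config.p53_sites_bed, "p53", k=k, n=n
        )
    for factor, peak_dir in config.peaks.items():
        if factor == "p53" and "p53" in sites:
            continue
        peak_sets = _read_peak_dir(peak_dir)
        k = config.recurrence_k.get(factor, FACTOR_THRESHOLDS.get(factor, (1,))[0])
        sites[factor] = binding_recurrence.recurrent_sites_from_peaks(
            peak_sets, k=k, factor=factor
        )
    if "E2F4" in sites and "p130/p107" in sites:
        sites["DREAM"] = binding_recurrence.dream_sites(
            sites["E2F4"], sites["p130/p107"]
        )
    out = _outdir(config)
    for factor, ss in sites.items():
        tag = factor.replace("/", "_")
        binding_recurrence.write_bed(ss.sites, out / f"recurrent_{tag}.bed")
    return sites


def stage_assign(
    config: PipelineConfig,
    score_result: dict,
    sites: dict[str, RecurrentSiteSet],
) -> pd.DataFrame:
    needed = {"p53", "DREAM", "RB"} - set(sites)
    if needed:
        raise ConfigError(f"mechanism assignment needs recurrent sites for {sorted(needed)}")
    links = (
        target_assignment.read_enhancer_links(config.enhancer_links)
        if config.enhancer_links
        else None
    )
    annotation = target_assignment.build_target_annotation(
        up_set=score_result["up"],
        down_set=score_result["down"],
        p53_sites=sites["p53"],
        dream=sites["DREAM"],
        rb=sites["RB"],
        catalog=score_result["catalog"],
        links=links,
        p53_half_width=config.p53_tss_half_width,
        pocket_half_width=config.pocket_tss_half_width,
    )
    annotation.reset_index().to_csv(
        _outdir(config) / "target_annotation.tsv", sep="\t", index=False
    )
    return annotation


def stage_nested(config: PipelineConfig, score_result: dict) -> pd.DataFrame:
    pairs = nested_coregulation.find_nested(score_result["catalog"])
    regulated = score_result["up"] | score_result["down"]
    pairs = pairs[pairs["lnc_id"].isin(regulated)].reset_index(drop=True)
    stats = nested_coregulation.host_coregulation(
        pairs, score_result["de"], alpha=config.alpha
    )
    stats.to_csv(_outdir(config) / "nested_pairs.tsv", sep="\t", index=False)
    return stats


def stage_dependence(
    config: PipelineConfig, annotation: pd.DataFrame
) -> dict[str, pd.DataFrame]:
    out: dict[str, pd.DataFrame] = {}
    joint = sorted(target_assignment.dream_rb_joined(annotation))
    if config.tpm_p21 and config.samples_p21:
        tpm = pd.read_csv(config.tpm_p21, sep="\t", index_col="gene_id")
        samples = pd.read_csv(config.samples_p21, sep="\t")
        genes = [g for g in joint if g in tpm.index]
        p21 = dependence_tests.p21_dependence_table(
            tpm, samples, genes, alpha=config.alpha
        )
        p21.reset_index().to_csv(
            _outdir(config) / "p21_dependence.tsv", sep="\t", index=False
        )
        out["p21"] = p21
    if config.tpm_pocket and config.samples_pocket:
        tpm = pd.read_csv(config.tpm_pocket, sep="\t", index_col="gene_id")
        samples = pd.read_csv(config.samples_pocket, sep="\t")
        candidates = (
            list(out["p21"].index[out["p21"]["call"] == "p21_dependent"])
            if "p21" in out
            else joint
        )
        genes = [g for g in candidates if g in tpm.index]
        pocket = dependence_tests.pocket_dependence_table(
            tpm, samples, genes, alpha=config.alpha
        )
        pocket.reset_index().to_csv(
            _outdir(config) / "pocket_dependence.tsv", sep="\t", index=False
        )
        out["pocket"] = pocket
    return out


def stage_survival(config: PipelineConfig) -> dict:
    _require(config, "cohort", "cohort_tpm", "gene_set")
    cohort = survival_analysis.read_cohort(config.cohort)
    tpm = pd.read_csv(config.cohort_tpm, sep="\t", index_col="gene_id")
    gene_set = survival_analysis.read_gene_set(config.gene_set)
    out = _outdir(config)

    def _analyze(sub: pd.DataFrame, tag: str) -> dict:
        expr = tpm[sub["sample_id"]]
        raw = survival_analysis.ssgsea_score(expr, gene_set, alpha=config.ssgsea_alpha)
        norm = survival_analysis.normalize_scores(raw)
        groups = survival_analysis.tertile_groups(norm)
        cox = survival_analysis.cox_fit(sub, groups)
        curves = survival_analysis.km_estimate(sub, groups)
        pd.DataFrame({"raw_es": raw, "normalized_es": norm, "group": groups}).rename_axis(
            "sample_id"
        ).reset_index().to_csv(out / f"scores_{tag}.tsv", sep="\t", index=False)
        cox.summary.reset_index(names="covariate").to_csv(
            out / f"cox_{tag}.tsv", sep="\t", index=False
        )
        km_rows = pd.concat(
            [c.assign(group=g) for g, c in curves.items()], ignore_index=True
        )
        km_rows.to_csv(out / f"km_{tag}.tsv", sep="\t", index=False)
        return {"groups": groups, "cox": cox, "curves": curves}

    result = {"all": _analyze(cohort, "all")}
    wt, mut = survival_analysis.split_by_p53(cohort)
    for tag, sub in (("wt", wt), ("mutant", mut)):
        if len(sub) >= 3 and sub["event"].sum() > 0:
            try:
                result[tag] = _analyze(sub, tag)
            except ValueError as exc:
                logger.warning("survival sub-analysis %s skipped: %s", tag, exc)
        else:
            logger.warning("survival sub-analysis %s skipped: too few samples/events", tag)
    return result


def run_landscape(config: PipelineConfig) -> dict:
    """Run every configured stage and write the manifest.

    Mandatory stages: score → recurrence → assignment → nesting.
    Perturbation and survival stages run when their inputs are configured.
    A stage failure aborts with :class:`StageError`; outputs of completed
    stages are left in place.
    """
    config.validate()
    manifest: dict = {"config": config.to_dict(), "counts": {}}
    results: dict = {}

    def _run(name, fn, *args):
        try:
            return fn(config, *args)
        except ConfigError:
            raise
        except Exception as exc:
            raise StageError(name, exc) from exc

    score_result = _run("score", stage_score)
    results["score"] = score_result
    manifest["counts"].update(score_result["counts"])

    sites = _run("recurrence", stage_recurrence)
    results["sites"] = sites
    for factor, ss in sites.items():
        manifest["counts"][f"recurrent_sites_{factor.replace('/', '_')}"] = len(ss)

    annotation = _run("assignment", stage_assign, score_result, sites)
    results["annotation"] = annotation
    manifest["counts"]["lnc_direct_p53"] = int(annotation["direct_p53"].sum())
    manifest["counts"]["lnc_enhancer_p53"] = int(annotation["enhancer_p53"].sum())
    manifest["counts"]["lnc_dream"] = int(annotation["dream"].sum())
    manifest["counts"]["lnc_rb"] = int(annotation["rb"].sum())
    manifest["counts"]["lnc_dream_rb_joined"] = len(
        target_assignment.dream_rb_joined(annotation)
    )

    nested = _run("nesting", stage_nested, score_result)
    results["nested"] = nested
    manifest["counts"]["nested_pairs"] = int(len(nested))
    manifest["counts"]["nested_positive_coregulated"] = int(
        nested["positive_coregulated"].sum()
    )

    if config.tpm_p21 or config.tpm_pocket:
        dep = _run("dependence", stage_dependence, annotation)
        results["dependence"] = dep
        if "p21" in dep:
            manifest["counts"]["p21_dependent"] = int(
                (dep["p21"]["call"] == "p21_dependent").sum()
            )
        if "pocket" in dep:
            manifest["counts"]["pocket_calls"] = (
                dep["pocket"]["call"].value_counts().to_dict()
            )

    if config.cohort:
        surv = _run("survival", stage_survival)
        results["survival"] = surv
        cox = surv["all"]["cox"]
        manifest["counts"]["cohort_n"] = cox.n
        manifest["counts"]["cohort_events"] = cox.n_events
        manifest["survival"] = {
            "hr_high_vs_low": float(cox.summary.loc["group_high", "hr"]),
            "hr_medium_vs_low": float(cox.summary.loc["group_medium", "hr"]),
            "lr_p": cox.lr_p,
        }

    out = _outdir(config)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    results["manifest"] = manifest
    return results
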