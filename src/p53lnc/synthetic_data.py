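"""Synthetic inputs with planted ground truth for the whole pipeline.

Every generator is a pure function of its parameters and a seed, and every
plant is emitted in a truth table, so precision and recall of each
downstream classification can be computed without reaching into generator
internals. The default scales mirror the real study conditions: 44
differential-expression datasets, 28/9/4/6 ChIP-seq peak sets for
p53/E2F4/p130-p107/RB with recurrence thresholds 5/4/2/3, score cutoffs
±10, and three replicates per perturbation arm.

Genome layout: genes are placed on one synthetic chromosome in fixed-size
slots with wide intergenic gaps, so that planted binding sites sit near the
TSSs they are meant for and decoy sites stay clear of every TSS window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation_io import LNCRNA, PROTEIN_CODING, GeneCatalog, GeneModel
from .dependence_tests import POCKET_GENOTYPES

CHROM = "chr1"
SLOT = 60_000
CODING_LEN = 15_000
LNC_LEN = 2_000
SITE_HALF = 150
ENHANCER_OFFSET = 25_000  # upstream of the target gene's slot
ENHANCER_LEN = 1_000
DECOY_OFFSET = 12_000  # upstream, outside every TSS window

#: study-condition scales
N_DE_DATASETS = 44
N_PEAK_SETS = {"p53": 28, "E2F4": 9, "p130/p107": 4, "RB": 6}
RECURRENCE_K = {"p53": 5, "E2F4": 4, "p130/p107": 2, "RB": 3}


@dataclass
class LandscapePlant:
    """Ground truth of one synthetic landscape."""

    up_lnc: list[str] = field(default_factory=list)
    down_lnc: list[str] = field(default_factory=list)
    direct: list[str] = field(default_factory=list)
    enhancer: list[str] = field(default_factory=list)
    dream: list[str] = field(default_factory=list)
    rb: list[str] = field(default_factory=list)
    nested_pairs: list[tuple[str, str, str]] = field(default_factory=list)
    p21_dependent: list[str] = field(default_factory=list)
    pocket_calls: dict[str, str] = field(default_factory=dict)
    cohort_groups: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        up, down = set(self.up_lnc), set(self.down_lnc)
        assert not up & down
        assert set(self.direct) <= up
        assert set(self.enhancer) <= up
        assert not set(self.direct) & set(self.enhancer)
        assert set(self.dream) <= down and set(self.rb) <= down

    def truth_frames(self) -> dict[str, pd.DataFrame]:
        def _set(name, ids):
            return pd.DataFrame({"gene_id": sorted(ids), "truth": name})

        frames = {
            "regulation": pd.concat(
                [_set("up", self.up_lnc), _set("down", self.down_lnc)],
                ignore_index=True,
            ),
            "mechanism": pd.concat(
                [
                    _set("direct", self.direct),
                    _set("enhancer", self.enhancer),
                    _set("dream", self.dream),
                    _set("rb", self.rb),
                ],
                ignore_index=True,
            ),
            "nested": pd.DataFrame(
                self.nested_pairs, columns=["lnc_id", "host_id", "direction"]
            ),
            "p21": pd.DataFrame(
                {"gene_id": sorted(self.p21_dependent), "truth": "p21_dependent"}
            ),
            "pocket": pd.DataFrame(
                sorted(self.pocket_calls.items()), columns=["gene_id", "truth"]
            ),
            "cohort_groups": pd.DataFrame(
                sorted(self.cohort_groups.items()), columns=["sample_id", "group"]
            ),
        }
        return frames


# -- annotation ---------------------------------------------------------------


@dataclass
class AnnotationSim:
    catalog: GeneCatalog
    nested_truth: pd.DataFrame  # lnc_id, host_id
    coding_ids: list[str]
    lnc_ids: list[str]
    decoy_lnc_ids: list[str]  # antisense / partial-overlap placements


def _gtf_attrs(gene: GeneModel, transcript_id: str | None = None) -> str:
    parts = [
        f'gene_id "{gene.gene_id}"',
        f'gene_name "{gene.name}"',
        f'gene_biotype "{gene.biotype}"',
    ]
    if transcript_id:
        parts.insert(1, f'transcript_id "{transcript_id}"')
    return "; ".join(parts) + ";"


def write_gtf(catalog: GeneCatalog, path: str | Path) -> None:
    """Emit the catalog as GTF (1-based closed), one transcript per TSS."""
    lines = []
    for g in catalog:
        lines.append(
            "\t".join(
                [
                    g.chrom,
                    "sim",
                    "gene",
                    str(g.start + 1),
                    str(g.end),
                    ".",
                    g.strand,
                    ".",
                    _gtf_attrs(g),
                ]
            )
        )
        for i, tss in enumerate(g.tss_list, start=1):
            if g.strand == "+":
                ts, te = tss, g.end
            else:
                ts, te = g.start, tss + 1
            lines.append(
                "\t".join(
                    [
                        g.chrom,
                        "sim",
                        "transcript",
                        str(ts + 1),
                        str(te),
                        ".",
                        g.strand,
                        ".",
                        _gtf_attrs(g, f"{g.gene_id}.t{i}"),
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def simulate_annotation(
    n_coding: int,
    n_lnc: int,
    n_nested: int,
    genome_len: int | None = None,
    seed: int = 0,
    with_decoys: bool = True,
) -> AnnotationSim:
    """Place genes on one chromosome with planted nesting.

    The first ``n_nested`` lncRNAs are nested strictly inside distinct
    protein-coding hosts on the same strand; when ``with_decoys`` two
    additional lncRNAs form deliberate non-pairs (an antisense-nested and
    a partial-overlap placement). Remaining lncRNAs get their own slots.
    """
    if n_nested > n_lnc:
        raise ValueError("n_nested cannot exceed n_lnc")
    n_decoys = 2 if with_decoys and n_lnc - n_nested >= 2 and n_coding >= n_nested + 2 else 0
    n_free = n_lnc - n_nested - n_decoys
    needed = (n_coding + n_free + 1) * SLOT + 10_000
    if genome_len is None:
        genome_len = needed
    if genome_len < needed:
        raise ValueError(
            f"genome of {genome_len} bases cannot hold {n_coding} coding and "
            f"{n_free} free lncRNA slots without unintended containment "
            f"(need >= {needed})"
        )
    rng = np.random.default_rng(seed)
    genes: dict[str, GeneModel] = {}

    coding_ids, lnc_ids, decoy_ids = [], [], []
    nested_rows = []
    slot_i = 0
    for i in range(n_coding):
        gid = f"GC{i:04d}"
        start = 10_000 + slot_i * SLOT
        strand = rng.choice(["+", "-"])
        end = start + CODING_LEN
        # two transcripts, the second starting 500 b inside, to exercise
        # multi-TSS genes
        tss = (start, start + 500) if strand == "+" else (end - 501, end - 1)
        genes[gid] = GeneModel(gid, gid, PROTEIN_CODING, CHROM, strand, start, end, tss)
        coding_ids.append(gid)
        slot_i += 1

    for i in range(n_nested):
        gid = f"GL{i:04d}"
        host = genes[coding_ids[i]]
        start = host.start + 5_000
        end = start + LNC_LEN
        tss = (start,) if host.strand == "+" else (end - 1,)
        genes[gid] = GeneModel(gid, gid, LNCRNA, CHROM, host.strand, start, end, tss)
        lnc_ids.append(gid)
        nested_rows.append((gid, host.gene_id))

    next_lnc = n_nested
    if n_decoys:
        # antisense inside a host: same span relation, opposite strand
        host = genes[coding_ids[n_nested]]
        gid = f"GL{next_lnc:04d}"
        strand = "-" if host.strand == "+" else "+"
        start = host.start + 5_000
        end = start + LNC_LEN
        tss = (start,) if strand == "+" else (end - 1,)
        genes[gid] = GeneModel(gid, gid, LNCRNA, CHROM, strand, start, end, tss)
        lnc_ids.append(gid)
        decoy_ids.append(gid)
        next_lnc += 1
        # partial overlap: straddles a coding gene's end (fraction 0.5)
        host = genes[coding_ids[n_nested + 1]]
        gid = f"GL{next_lnc:04d}"
        start = host.end - LNC_LEN // 2
        end = start + LNC_LEN
        tss = (start,) if host.strand == "+" else (end - 1,)
        genes[gid] = GeneModel(gid, gid, LNCRNA, CHROM, host.strand, start, end, tss)
        lnc_ids.append(gid)
        decoy_ids.append(gid)
        next_lnc += 1

    for i in range(n_free):
        gid = f"GL{next_lnc + i:04d}"
        start = 10_000 + slot_i * SLOT
        strand = rng.choice(["+", "-"])
        end = start + LNC_LEN
        tss = (start,) if strand == "+" else (end - 1,)
        genes[gid] = GeneModel(gid, gid, LNCRNA, CHROM, strand, start, end, tss)
        lnc_ids.append(gid)
        slot_i += 1

    return AnnotationSim(
        catalog=GeneCatalog(genes, annotation_tag=f"sim(seed={seed})"),
        nested_truth=pd.DataFrame(nested_rows, columns=["lnc_id", "host_id"]),
        coding_ids=coding_ids,
        lnc_ids=lnc_ids,
        decoy_lnc_ids=decoy_ids,
    )


# -- DE compendium ------------------------------------------------------------


def simulate_de_compendium(
    up_genes: Sequence[str],
    down_genes: Sequence[str],
    null_genes: Sequence[str],
    coupled_pairs: Sequence[tuple[str, str]] = (),
    n_datasets: int = N_DE_DATASETS,
    response_prob: float = 0.55,
    effect_mu: float = 1.5,
    noise_sd: float = 0.4,
    missing_prob: float = 0.2,
    coupling_sd: float = 0.1,
    sig_fdr: float = 0.05,
    min_expressed: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Long-format DE compendium with planted recurrent regulation.

    Planted up genes respond (significant, log2fc ~ N(+effect_mu,
    noise_sd)) in ~``response_prob`` of the datasets where they are
    present; down genes mirror this; null genes sit at N(0, noise_sd) with
    a uniform FDR. Presence is dropped independently with
    ``missing_prob``. ``coupled_pairs`` (follower, driver) makes the
    follower track the driver's fold-change and significance up to
    N(0, coupling_sd), with shared presence — the nested lncRNA/host
    pattern. With ``noise_sd = 0`` generation is noiseless: null genes sit
    exactly at zero and every present planted entry responds.
    """
    if n_datasets < min_expressed:
        raise ValueError("n_datasets below the min_expressed filter")
    for p in (response_prob, missing_prob):
        if not 0 <= p <= 1:
            raise ValueError("probabilities must be in [0, 1]")
    rng = np.random.default_rng(seed)
    noiseless = noise_sd == 0
    followers = {f: d for f, d in coupled_pairs}
    classes = {g: +1 for g in up_genes}
    classes.update({g: -1 for g in down_genes})
    classes.update({g: 0 for g in null_genes})
    datasets = [f"DS{j:02d}" for j in range(n_datasets)]

    rows: list[tuple] = []
    driver_rows: dict[tuple[str, str], tuple[float, float] | None] = {}

    def _emit(gene: str, cls: int) -> None:
        for ds in datasets:
            present = rng.random() >= missing_prob
            if not present:
                driver_rows[(gene, ds)] = None
                continue
            if cls == 0:
                fc = 0.0 if noiseless else rng.normal(0.0, noise_sd)
                fdr = rng.uniform(0.0, 1.0)
            else:
                responds = noiseless or (rng.random() < response_prob)
                if responds:
                    fc = cls * effect_mu + (0.0 if noiseless else rng.normal(0.0, noise_sd))
                    fdr = rng.uniform(0.0, sig_fdr)
                else:
                    fc = rng.normal(0.0, noise_sd)
                    fdr = rng.uniform(sig_fdr, 1.0)
            driver_rows[(gene, ds)] = (fc, fdr)
            rows.append((ds, gene, fc, fdr))

    for gene, cls in classes.items():
        if gene in followers:
            continue
        _emit(gene, cls)
    for follower, driver in followers.items():
        if driver not in classes:
            raise ValueError(f"coupled driver {driver!r} has no planted class")
        for ds in datasets:
            drv = driver_rows.get((driver, ds))
            if drv is None:
                continue
            fc = drv[0] + (0.0 if noiseless else rng.normal(0.0, coupling_sd))
            rows.append((ds, follower, fc, drv[1]))

    return pd.DataFrame(rows, columns=["dataset_id", "gene_id", "log2fc", "fdr"])


# -- peak compendium ----------------------------------------------------------


def simulate_peak_compendium(
    truth_sites: pd.DataFrame,
    n_datasets: int,
    detect_prob: float = 0.85,
    jitter_sd: float = 10.0,
    decoy_sites: pd.DataFrame | None = None,
    decoy_detect_prob: float = 0.05,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Per-dataset BED peak sets from planted truth sites.

    Each truth site appears in each dataset with ``detect_prob``, its
    endpoints jittered by rounded N(0, jitter_sd) (capped so intervals stay
    valid); decoy sites appear with ``decoy_detect_prob``.
    """
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    rng = np.random.default_rng(seed)
    out: dict[str, pd.DataFrame] = {}
    frames = [(truth_sites, detect_prob)]
    if decoy_sites is not None and len(decoy_sites):
        frames.append((decoy_sites, decoy_detect_prob))
    for j in range(n_datasets):
        rows = []
        for sites, prob in frames:
            for chrom, s, e in sites[["chrom", "start", "end"]].itertuples(index=False):
                if rng.random() >= prob:
                    continue
                cap = (e - s) // 2 - 1
                if jitter_sd > 0 and cap > 0:
                    js = int(np.clip(round(rng.normal(0, jitter_sd)), -cap, cap))
                    je = int(np.clip(round(rng.normal(0, jitter_sd)), -cap, cap))
                else:
                    js = je = 0
                rows.append((chrom, s + js, e + je))
        out[f"peaks{j:02d}"] = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return out


# -- TPM perturbation experiments --------------------------------------------


def simulate_tpm_experiment(
    gene_classes: Mapping[str, str],
    design: str,
    n_replicates: int = 3,
    base_log2_tpm: float = 5.0,
    base_sd: float = 1.0,
    effect_log2: float = 2.0,
    noise_sd: float = 0.2,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """TPM matrix + sample sheet with planted repression/induction effects.

    design='p21': genotypes parental / p21ko; gene classes
    p21_dependent (repressed in parental only), independent_repressed
    (repressed in both), induced (induced in both), null.

    design='pocket': the four-genotype depletion series; classes
    RB_predominant, DREAM_predominant, cooperative, not_detected
    (baseline forced below the detection floor), null. Repression is lost
    in the genotype(s) the class names and always in the triple depletion.
    """
    if n_replicates < 2:
        raise ValueError("need >= 2 replicates per arm")
    if design == "p21":
        genotypes = ("parental", "p21ko")
        repressed_in = {
            "p21_dependent": {"parental"},
            "independent_repressed": {"parental", "p21ko"},
            "null": set(),
        }
        induced_in = {"induced": {"parental", "p21ko"}}
    elif design == "pocket":
        genotypes = POCKET_GENOTYPES
        repressed_in = {
            "RB_predominant": {"parental", "p130p107_depleted"},
            "DREAM_predominant": {"parental", "rb_depleted"},
            "cooperative": {"parental", "rb_depleted", "p130p107_depleted"},
            "not_detected": {"parental"},
            "null": set(),
        }
        induced_in = {}
    else:
        raise ValueError(f"unknown design {design!r}")

    rng = np.random.default_rng(seed)
    samples = []
    for gt in genotypes:
        for arm in ("control", "treated"):
            for r in range(n_replicates):
                samples.append((f"{gt}_{arm}_{r}", gt, arm))
    sheet = pd.DataFrame(samples, columns=["sample", "genotype", "treatment"])

    mat = {}
    for gene, cls in gene_classes.items():
        if cls not in repressed_in and cls not in induced_in:
            raise ValueError(f"unknown class {cls!r} for design {design!r}")
        base = rng.normal(base_log2_tpm, base_sd)
        if cls == "not_detected":
            base = -2.0  # ~0.25 TPM, under the detection floor
        vals = []
        for _, gt, arm in samples:
            delta = 0.0
            if arm == "treated":
                if gt in repressed_in.get(cls, ()):  # noqa: SIM118
                    delta = -effect_log2
                elif gt in induced_in.get(cls, ()):
                    delta = +effect_log2
            log2_tpm = base + delta + rng.normal(0, noise_sd)
            vals.append(max(0.0, 2.0**log2_tpm - 1.0))
        mat[gene] = vals
    tpm = pd.DataFrame.from_dict(mat, orient="index", columns=sheet["sample"])
    tpm.index.name = "gene_id"
    return tpm, sheet


# -- survival cohort ----------------------------------------------------------


def simulate_cohort(
    n: int = 600,
    group_fractions: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
    hr_medium: float = 1.0,
    hr_high: float = 2.0,
    baseline_hazard: float = 1 / 2000.0,
    censor_fraction: float = 0.3,
    age_mean: float = 62.0,
    age_sd: float = 11.0,
    male_fraction: float = 0.5,
    p53_mutant_fraction: float = 0.4,
    gene_set_size: int = 40,
    n_background_genes: int = 160,
    group_shift: float = 1.0,
    expr_sd: float = 1.0,
    wt_only_effect: bool = False,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str], pd.Series]:
    """Survival cohort with planted group hazards and a matching TPM matrix.

    Event times are exponential with hazard baseline × HR(group); an
    independent exponential censoring process is tuned to censor about
    ``censor_fraction`` of the baseline group. Expression of the target
    gene set is shifted by ``group_shift`` (in units of the per-sample
    noise SD) per group step, so enrichment scoring plus tertile grouping
    approximately reconstructs the planted groups. With
    ``wt_only_effect`` the hazard contrast applies only to p53 wild-type
    patients.

    Returns (cohort table, TPM matrix, target gene set, planted groups).
    """
    if abs(sum(group_fractions) - 1) > 1e-9:
        raise ValueError("group fractions must sum to 1")
    rng = np.random.default_rng(seed)
    sizes = [int(round(f * n)) for f in group_fractions]
    sizes[2] = n - sizes[0] - sizes[1]
    group_idx = np.repeat([0, 1, 2], sizes)
    rng.shuffle(group_idx)
    hrs = np.array([1.0, hr_medium, hr_high])[group_idx]
    mutant = rng.random(n) < p53_mutant_fraction
    if wt_only_effect:
        hrs = np.where(mutant, 1.0, hrs)
    event_t = rng.exponential(1.0 / (baseline_hazard * hrs))
    censor_rate = baseline_hazard * censor_fraction / (1 - censor_fraction)
    censor_t = rng.exponential(1.0 / censor_rate, size=n)
    time = np.minimum(event_t, censor_t)
    event = (event_t <= censor_t).astype(int)

    sample_ids = [f"S{i:04d}" for i in range(n)]
    cohort = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "time_days": np.maximum(time, 1.0).round(1),
            "event": event,
            "age": rng.normal(age_mean, age_sd, n).round(1),
            "sex": np.where(rng.random(n) < male_fraction, "male", "female"),
            "p53_status": np.where(mutant, "mutant", "wild_type"),
        }
    )

    set_genes = [f"SET{i:03d}" for i in range(gene_set_size)]
    bg_genes = [f"BG{i:03d}" for i in range(n_background_genes)]
    base = rng.normal(5.0, 2.0, gene_set_size + n_background_genes)
    log2e = base[:, None] + rng.normal(0.0, expr_sd, (len(base), n))
    shift = group_shift * expr_sd * group_idx
    log2e[: gene_set_size] += shift[None, :]
    tpm = pd.DataFrame(
        np.maximum(0.0, 2.0**log2e - 1.0), index=set_genes + bg_genes, columns=sample_ids
    )
    tpm.index.name = "gene_id"
    groups = pd.Series(
        np.array(["low", "medium", "high"])[group_idx], index=sample_ids, name="group"
    )
    return cohort, tpm, set_genes, groups


# -- the full landscape -------------------------------------------------------


@dataclass
class LandscapeSim:
    """Everything the pipeline consumes, plus the plant."""

    plant: LandscapePlant
    annotation: AnnotationSim
    de: pd.DataFrame
    peak_sets: dict[str, dict[str, pd.DataFrame]]  # factor -> dataset -> BED
    enhancer_links: pd.DataFrame
    p21_tpm: pd.DataFrame
    p21_samples: pd.DataFrame
    pocket_tpm: pd.DataFrame
    pocket_samples: pd.DataFrame
    cohort: pd.DataFrame
    cohort_tpm: pd.DataFrame
    cohort_gene_set: list[str]


def simulate_landscape(
    seed: int = 0,
    n_coding: int = 60,
    n_lnc: int = 110,
    n_up: int = 30,
    n_down: int = 14,
    n_direct: int = 10,
    n_enhancer: int = 4,
    n_dream_only: int = 4,
    n_rb_only: int = 2,
    n_dream_rb_both: int = 3,
    n_nested_up: int = 6,
    n_nested_down: int = 4,
    n_decoy_sites: int = 30,
    noiseless: bool = False,
    cohort_n: int = 600,
    de_kwargs: dict | None = None,
    peak_kwargs: dict | None = None,
) -> LandscapeSim:
    """Generate one coherent synthetic landscape with planted truth.

    Planted subsets are consistent by construction: direct and enhancer
    targets are disjoint subsets of the up-regulated lncRNAs, DREAM/RB
    targets are subsets of the down-regulated ones, nested lncRNAs share
    their host's response, and the p21/pocket perturbation plants live in
    the DREAM/RB joint set. ``noiseless`` switches every stochastic layer
    off (full response, no missingness, perfect peak detection) for exact
    planted-recovery checks.
    """
    rng = np.random.default_rng(seed)
    n_nested = n_nested_up + n_nested_down
    ann = simulate_annotation(
        n_coding=n_coding, n_lnc=n_lnc, n_nested=n_nested, seed=seed + 1
    )
    catalog = ann.catalog

    nested_lnc = list(ann.nested_truth["lnc_id"])
    free_lnc = [
        g for g in ann.lnc_ids if g not in set(nested_lnc) | set(ann.decoy_lnc_ids)
    ]
    need_free = n_up - n_nested_up + n_down - n_nested_down
    if len(free_lnc) < need_free:
        raise ValueError("not enough free lncRNAs for the requested plant sizes")

    up_free = free_lnc[: n_up - n_nested_up]
    down_free = free_lnc[n_up - n_nested_up : need_free]
    up_lnc = up_free + nested_lnc[:n_nested_up]
    down_lnc = down_free + nested_lnc[n_nested_up:]

    # mechanism subsets live on free (non-nested) lncRNAs so that nested
    # genes remain pure host-mechanism cases
    direct = up_free[:n_direct]
    enhancer = up_free[n_direct : n_direct + n_enhancer]
    dream_only = down_free[:n_dream_only]
    rb_only = down_free[n_dream_only : n_dream_only + n_rb_only]
    both = down_free[
        n_dream_only + n_rb_only : n_dream_only + n_rb_only + n_dream_rb_both
    ]
    dream = dream_only + both
    rb = rb_only + both

    nested_pairs = [
        (l, h, "up" if l in set(up_lnc) else "down")
        for l, h in ann.nested_truth.itertuples(index=False)
    ]

    # --- binding truth -------------------------------------------------------
    def _tss_site(gene_id: str, half: int = SITE_HALF) -> tuple[str, int, int]:
        g = catalog[gene_id]
        t = g.tss_list[0]
        return (g.chrom, max(0, t - half), t + half)

    p53_truth = [_tss_site(g) for g in direct]
    enhancer_rows = []
    for g in enhancer:
        gene = catalog[g]
        es = max(0, gene.start - ENHANCER_OFFSET)
        enhancer_rows.append((gene.chrom, es, es + ENHANCER_LEN, g, True))
        p53_truth.append((gene.chrom, es + 300, es + 700))
    # a non-elite link and an unbound elite enhancer as negative controls
    if enhancer:
        gene = catalog[enhancer[0]]
        enhancer_rows.append(
            (gene.chrom, gene.start - ENHANCER_OFFSET - 5_000,
             gene.start - ENHANCER_OFFSET - 4_000, enhancer[0], False)
        )
    if up_free[n_direct + n_enhancer :]:
        g = up_free[n_direct + n_enhancer]
        gene = catalog[g]
        enhancer_rows.append(
            (gene.chrom, max(0, gene.start - ENHANCER_OFFSET),
             max(0, gene.start - ENHANCER_OFFSET) + ENHANCER_LEN, g, True)
        )
    enhancer_links = pd.DataFrame(
        enhancer_rows, columns=["chrom", "start", "end", "gene_id", "elite"]
    )

    e2f4_truth = [_tss_site(g) for g in dream]
    p130_truth = [_tss_site(g) for g in dream]
    rb_truth = [_tss_site(g) for g in rb]

    decoys = []
    decoy_pool = [g for g in ann.coding_ids[n_nested + 2 :]][:n_decoy_sites]
    for g in decoy_pool:
        gene = catalog[g]
        s = max(0, gene.start - DECOY_OFFSET)
        decoys.append((gene.chrom, s, s + 2 * SITE_HALF))
    decoy_df = pd.DataFrame(decoys, columns=["chrom", "start", "end"])

    pk = dict(detect_prob=1.0, jitter_sd=0.0, decoy_detect_prob=0.0) if noiseless else {}
    pk.update(peak_kwargs or {})
    peak_sets = {}
    for fi, (factor, n_sets) in enumerate(N_PEAK_SETS.items()):
        truth = {"p53": p53_truth, "E2F4": e2f4_truth, "p130/p107": p130_truth, "RB": rb_truth}[factor]
        peak_sets[factor] = simulate_peak_compendium(
            pd.DataFrame(truth, columns=["chrom", "start", "end"]),
            n_datasets=n_sets,
            decoy_sites=decoy_df,
            seed=seed + 10 + fi,
            **pk,
        )

    # --- DE compendium -------------------------------------------------------
    hosts_up = [h for _, h, d in nested_pairs if d == "up"]
    hosts_down = [h for _, h, d in nested_pairs if d == "down"]
    null_genes = [
        g
        for g in list(catalog.genes)
        if g not in set(up_lnc) | set(down_lnc) | set(hosts_up) | set(hosts_down)
    ]
    dk = dict(noise_sd=0.0, missing_prob=0.0, response_prob=1.0) if noiseless else {}
    dk.update(de_kwargs or {})
    de = simulate_de_compendium(
        up_genes=list(up_lnc) + hosts_up,
        down_genes=list(down_lnc) + hosts_down,
        null_genes=null_genes,
        coupled_pairs=[(l, h) for l, h, _ in nested_pairs],
        seed=seed + 2,
        **dk,
    )

    # --- perturbation experiments -------------------------------------------
    joint = list(dict.fromkeys(dream + rb))
    p21_dependent = joint[: max(1, 2 * len(joint) // 3)]
    p21_classes = {g: "p21_dependent" for g in p21_dependent}
    p21_classes.update({g: "independent_repressed" for g in joint[len(p21_dependent):]})
    p21_classes["GC_MDM2_LIKE"] = "induced"
    p21_tpm, p21_samples = simulate_tpm_experiment(
        p21_classes, design="p21", seed=seed + 3,
        noise_sd=0.0 if noiseless else 0.2,
    )

    pocket_labels = ["RB_predominant", "DREAM_predominant", "cooperative", "not_detected"]
    pocket_calls = {
        g: pocket_labels[i % len(pocket_labels)] for i, g in enumerate(p21_dependent)
    }
    pocket_tpm, pocket_samples = simulate_tpm_experiment(
        pocket_calls, design="pocket", seed=seed + 4,
        noise_sd=0.0 if noiseless else 0.2,
    )

    # --- cohort --------------------------------------------------------------
    cohort, cohort_tpm, cohort_set, cohort_groups = simulate_cohort(
        n=cohort_n, seed=seed + 5
    )

    plant = LandscapePlant(
        up_lnc=sorted(up_lnc),
        down_lnc=sorted(down_lnc),
        direct=sorted(direct),
        enhancer=sorted(enhancer),
        dream=sorted(dream),
        rb=sorted(rb),
        nested_pairs=nested_pairs,
        p21_dependent=sorted(p21_dependent),
        pocket_calls=pocket_calls,
        cohort_groups=dict(cohort_groups),
    )
    plant.validate()
    return LandscapeSim(
        plant=plant,
        annotation=ann,
        de=de,
        peak_sets=peak_sets,
        enhancer_links=enhancer_links,
        p21_tpm=p21_tpm,
        p21_samples=p21_samples,
        pocket_tpm=pocket_tpm,
        pocket_samples=pocket_samples,
        cohort=cohort,
        cohort_tpm=cohort_tpm,
        cohort_gene_set=cohort_set,
    )


def write_landscape(sim: LandscapeSim, outdir: str | Path) -> dict[str, str]:
    """Write every input file the pipeline reads, plus truth tables.

    Returns a manifest of logical name -> path.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    gtf = out / "annotation.gtf"
    write_gtf(sim.annotation.catalog, gtf)
    paths["annotation"] = str(gtf)

    de_path = out / "de_compendium.tsv"
    sim.de.to_csv(de_path, sep="\t", index=False)
    paths["de"] = str(de_path)

    for factor, sets in sim.peak_sets.items():
        tag = factor.replace("/", "_")
        d = out / f"peaks_{tag}"
        d.mkdir(exist_ok=True)
        for ds, df in sets.items():
            df.to_csv(d / f"{ds}.bed", sep="\t", header=False, index=False)
        paths[f"peaks_{tag}"] = str(d)

    links = out / "enhancer_links.tsv"
    sim.enhancer_links.to_csv(links, sep="\t", index=False)
    paths["enhancer_links"] = str(links)

    for name, tpm, sheet in (
        ("p21", sim.p21_tpm, sim.p21_samples),
        ("pocket", sim.pocket_tpm, sim.pocket_samples),
    ):
        tp = out / f"tpm_{name}.tsv"
        sp = out / f"samples_{name}.tsv"
        tpm.to_csv(tp, sep="\t")
        sheet.to_csv(sp, sep="\t", index=False)
        paths[f"tpm_{name}"] = str(tp)
        paths[f"samples_{name}"] = str(sp)

    cp = out / "cohort.tsv"
    sim.cohort.to_csv(cp, sep="\t", index=False)
    paths["cohort"] = str(cp)
    ctp = out / "cohort_tpm.tsv"
    sim.cohort_tpm.to_csv(ctp, sep="\t")
    paths["cohort_tpm"] = str(ctp)
    gsp = out / "gene_set.txt"
    gsp.write_text("\n".join(sim.cohort_gene_set) + "\n")
    paths["gene_set"] = str(gsp)

    for name, frame in sim.plant.truth_frames().items():
        p = out / f"truth_{name}.tsv"
        frame.to_csv(p, sep="\t", index=False)
        paths[f"truth_{name}"] = str(p)
    return paths
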