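import numpy as np
import pandas as pd
import pytest

from p53lnc.annotation_io import GeneCatalog, GeneModel


def make_gene(
    gene_id,
    start,
    end,
    strand="+",
    biotype="lncRNA",
    chrom="chr1",
    tss=None,
):
    if tss is None:
        tss = (start,) if strand == "+" else (end - 1,)
    return GeneModel(gene_id, gene_id, biotype, chrom, strand, start, end, tuple(tss))


def make_catalog(*genes):
    return GeneCatalog({g.gene_id: g for g in genes}, annotation_tag="test")


@pytest.fixture
def rng():
    return np.random.default_rng(20230309)


@pytest.fixture(scope="session")
def noiseless_landscape():
    from p53lnc.synthetic_data import simulate_landscape

    return simulate_landscape(seed=11, noiseless=True, cohort_n=150)


@pytest.fixture(scope="session")
def noisy_landscape():
    from p53lnc.synthetic_data import simulate_landscape

    return simulate_landscape(seed=13, cohort_n=300)


def random_peak_sets(rng, n_datasets, genome_len=2000, max_peaks=8):
    """Random per-dataset interval collections on one small chromosome."""
    sets = {}
    for d in range(n_datasets):
        rows = []
        for _ in range(rng.integers(0, max_peaks + 1)):
            s = int(rng.integers(0, genome_len - 2))
            e = int(rng.integers(s + 1, min(genome_len, s + 1 + rng.integers(1, 200))))
            rows.append(("chr1", s, e))
        sets[f"d{d}"] = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return sets


def per_base_support(peak_sets, genome_len=2000):
    """Brute-force per-base dataset-coverage counts (the oracle)."""
    cov = np.zeros(genome_len, dtype=int)
    for df in peak_sets.values():
        mask = np.zeros(genome_len, dtype=bool)
        for _, s, e in df.itertuples(index=False):
            mask[max(0, s) : min(genome_len, e)] = True
        cov += mask
    return cov
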