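import numpy as np
import pandas as pd
import pytest

from p53lnc.binding_recurrence import RecurrentSiteSet
from p53lnc.target_assignment import (
    assign_enhancer_mediated,
    assign_tss_proximal,
    build_target_annotation,
    dream_rb_joined,
)

from .conftest import make_catalog, make_gene


def rss(*ivals, factor="p53"):
    df = pd.DataFrame([("chr1", s, e) for s, e in ivals], columns=["chrom", "start", "end"])
    return RecurrentSiteSet(factor, 1, 1, df)


def links(*rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id", "elite"])


GENE_A = make_gene("A", 4000, 9000, tss=(5000,))


class TestTssProximal:
    @pytest.mark.parametrize(
        "site,expected",
        [
            ((4990, 5010), True),   # on the TSS
            ((7400, 7600), True),   # clips the window end (7501)
            ((7600, 7800), False),  # just beyond the inclusive 2.5 kb window
            ((2400, 2501), True),   # one base inside the left edge
            ((2400, 2500), False),
        ],
    )
    def test_window_overlap_arithmetic(self, site, expected):
        cat = make_catalog(GENE_A)
        hit = assign_tss_proximal(cat, rss(site), half_width=2500)
        assert ("A" in hit) is expected

    def test_empty_site_set_yields_empty_result(self):
        empty = RecurrentSiteSet("p53", 1, 1, pd.DataFrame(columns=["chrom", "start", "end"]))
        assert assign_tss_proximal(make_catalog(GENE_A), empty, 2500) == set()

    def test_any_tss_of_a_multi_tss_gene_counts(self):
        g = make_gene("M", 1000, 50000, tss=(1000, 40000))
        hit = assign_tss_proximal(make_catalog(g), rss((41000, 41100)), 2500)
        assert hit == {"M"}


class TestEnhancerMediated:
    def test_bound_distal_enhancer_without_tss_site_is_included(self):
        cat = make_catalog(make_gene("E", 60000, 62000, tss=(60000,)))
        sites = rss((10200, 10400))  # inside the enhancer, 50 kb upstream
        lk = links(("chr1", 10000, 11000, "E", True))
        assert assign_enhancer_mediated(cat, sites, lk) == {"E"}

    def test_tss_proximal_binding_takes_precedence(self):
        cat = make_catalog(make_gene("E", 60000, 62000, tss=(60000,)))
        sites = rss((10200, 10400), (59900, 60100))
        lk = links(("chr1", 10000, 11000, "E", True))
        assert assign_enhancer_mediated(cat, sites, lk) == set()

    def test_non_elite_links_and_unbound_enhancers_excluded(self):
        cat = make_catalog(
            make_gene("X", 60000, 62000, tss=(60000,)),
            make_gene("Y", 160000, 162000, tss=(160000,)),
        )
        sites = rss((10200, 10400))
        lk = links(
            ("chr1", 10000, 11000, "X", False),   # bound but not elite
            ("chr1", 110000, 111000, "Y", True),  # elite but unbound
        )
        assert assign_enhancer_mediated(cat, sites, lk) == set()

    def test_matches_all_pairs_overlap_oracle(self, rng):
        genes = [make_gene(f"G{i}", 100000 + 10000 * i, 100000 + 10000 * i + 2000) for i in range(8)]
        cat = make_catalog(*genes)
        site_rows = sorted(
            (int(s), int(s) + 300) for s in rng.choice(np.arange(0, 90000, 500), 10, replace=False)
        )
        sites = rss(*site_rows)
        lk_rows = []
        for i, g in enumerate(genes):
            es = int(rng.integers(0, 90000))
            lk_rows.append(("chr1", es, es + 800, g.gene_id, bool(rng.random() < 0.8)))
        lk = links(*lk_rows)
        result = assign_enhancer_mediated(cat, sites, lk)
        oracle = set()
        for chrom, es, ee, gid, elite in lk_rows:
            if not elite:
                continue
            if any(es < e and s < ee for s, e in site_rows):
                oracle.add(gid)
        # no gene here has TSS-proximal sites (sites all below 90 kb + 300)
        assert result == oracle

    def test_unknown_gene_link_is_skipped_with_warning(self, caplog):
        cat = make_catalog(GENE_A)
        lk = links(("chr1", 0, 100, "nope", True))
        with caplog.at_level("WARNING"):
            out = assign_enhancer_mediated(cat, rss((0, 100)), lk)
        assert out == set()
        assert "nope" in caplog.text


class TestBuildTargetAnnotation:
    def _landscape(self):
        genes = [
            make_gene("U_direct", 100000, 102000, tss=(100000,)),
            make_gene("U_enh", 200000, 202000, tss=(200000,)),
            make_gene("U_plain", 300000, 302000, tss=(300000,)),
            make_gene("D_both", 400000, 402000, tss=(400000,)),
            make_gene("D_rb", 500000, 502000, tss=(500000,)),
            make_gene("D_plain", 600000, 602000, tss=(600000,)),
            make_gene("Unscored", 700000, 702000, tss=(700000,)),
        ]
        cat = make_catalog(*genes)
        p53 = rss((99900, 100100), (170200, 170400))
        dream = rss((400100, 400200), factor="DREAM")
        # RB at 900 b from D_rb's TSS (in the 1 kb window) and a second
        # site 1.5 kb from D_plain's TSS (outside it)
        rb = rss((400000, 400050), (500900, 501000), (601500, 601600), factor="RB")
        lk = links(("chr1", 170000, 171000, "U_enh", True))
        return cat, p53, dream, rb, lk

    def test_planted_flags_recovered_exactly(self):
        cat, p53, dream, rb, lk = self._landscape()
        ann = build_target_annotation(
            up_set={"U_direct", "U_enh", "U_plain"},
            down_set={"D_both", "D_rb", "D_plain"},
            p53_sites=p53, dream=dream, rb=rb, catalog=cat, links=lk,
        )
        assert "Unscored" not in ann.index
        assert ann.loc["U_direct", ["direct_p53", "enhancer_p53"]].tolist() == [True, False]
        assert ann.loc["U_enh", ["direct_p53", "enhancer_p53"]].tolist() == [False, True]
        assert not ann.loc["U_plain", ["direct_p53", "enhancer_p53", "dream", "rb"]].any()
        assert ann.loc["D_both", ["dream", "rb"]].tolist() == [True, True]
        assert ann.loc["D_rb", ["dream", "rb"]].tolist() == [False, True]
        assert not ann.loc["D_plain", ["dream", "rb"]].any()
        # direct/enhancer never asserted on down-genes and vice versa
        assert not ann.loc[["D_both", "D_rb", "D_plain"], ["direct_p53", "enhancer_p53"]].any().any()
        assert not ann.loc[["U_direct", "U_enh", "U_plain"], ["dream", "rb"]].any().any()

    def test_direct_and_enhancer_are_disjoint_within_up_set(self):
        cat, p53, dream, rb, lk = self._landscape()
        up = {"U_direct", "U_enh", "U_plain"}
        ann = build_target_annotation(up, set(), p53, dream, rb, cat, lk)
        both = ann["direct_p53"] & ann["enhancer_p53"]
        assert not both.any()
        assert (ann["direct_p53"] | ann["enhancer_p53"]).sum() <= len(up)

    def test_joined_dream_rb_set_follows_inclusion_exclusion(self):
        cat, p53, dream, rb, lk = self._landscape()
        ann = build_target_annotation(set(), {"D_both", "D_rb", "D_plain"}, p53, dream, rb, cat, lk)
        n_dream, n_rb = int(ann["dream"].sum()), int(ann["rb"].sum())
        n_both = int((ann["dream"] & ann["rb"]).sum())
        assert len(dream_rb_joined(ann)) == n_dream + n_rb - n_both

    def test_invariant_to_site_order_and_book_ended_split(self):
        cat, p53, dream, rb, lk = self._landscape()
        up, down = {"U_direct", "U_enh", "U_plain"}, {"D_both", "D_rb", "D_plain"}
        base = build_target_annotation(up, down, p53, dream, rb, cat, lk)
        shuffled = rss(*[(s, e) for _, s, e in p53.sites.iloc[::-1].itertuples(index=False)])
        split_rows = []
        for _, s, e in p53.sites.itertuples(index=False):
            mid = (s + e) // 2
            split_rows += [(s, mid), (mid, e)]
        split = rss(*split_rows)
        for variant in (shuffled, split):
            ann = build_target_annotation(up, down, variant, dream, rb, cat, lk)
            pd.testing.assert_frame_equal(ann, base)
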