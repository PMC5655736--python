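import numpy as np
import pandas as pd
import pytest

from epivasc.dmr_detection import (
    DmrRecord,
    MethWindow,
    associate_genes,
    build_windows,
    classify_dmrs,
    cluster_dmrs,
    dmr_level_matrix,
    hypermethylated_genes,
    merge_windows,
    score_windows,
    window_fisher,
)
from epivasc.io_formats import GeneModel
from epivasc.methylation_core import MethylationCallSet, STATUS_METHYLATED

from conftest import binom_tail_oracle, fisher_two_sided_oracle, make_methcounts


def _callset(rows, sample_id="s"):
    sites = make_methcounts(rows)
    sites["p_value"] = np.nan
    sites["q_value"] = np.nan
    sites["status"] = np.where(
        sites["total"] < 4,
        "uncallable",
        np.where(sites["meth"] * 2 >= sites["total"], STATUS_METHYLATED, "unmethylated"),
    )
    return MethylationCallSet(sample_id, sites, 0.002)


def _window(ma, ua, mb, ub, n_cyt=20, tested=True):
    return MethWindow("chr1", 0, 100, ma, ua, mb, ub, n_cyt, tested)


class TestBuildWindows:
    def test_window_starts_fully_inside_chromosome(self):
        a = _callset([("chr1", 10, "+", "CG", 0, 5)])
        b = _callset([("chr1", 10, "+", "CG", 0, 5)])
        windows = build_windows(a, b, {"chr1": 250})
        assert [w.start for w in windows] == [0, 50, 100, 150]

    def test_fourteen_cytosines_untested(self):
        rows = [("chr1", p, "+", "CHH", 1, 5) for p in range(0, 28, 2)]  # 14 sites
        a, b = _callset(rows, "a"), _callset(rows, "b")
        windows = build_windows(a, b, {"chr1": 100})
        assert windows[0].n_cytosines == 14
        assert windows[0].tested is False

    def test_low_coverage_in_one_sample_excludes_site(self):
        rows_a = [("chr1", p, "+", "CHH", 1, 5) for p in range(0, 30, 2)]
        rows_b = [("chr1", p, "+", "CHH", 1, 5 if p else 3) for p in range(0, 30, 2)]
        a, b = _callset(rows_a, "a"), _callset(rows_b, "b")
        windows = build_windows(a, b, {"chr1": 100})
        assert windows[0].n_cytosines == 14  # site at pos 0 dropped (3x in B)

    def test_counts_are_read_level_sums(self):
        rows_a = [("chr1", p, "+", "CHH", 2, 10) for p in range(15)]
        rows_b = [("chr1", p, "+", "CHH", 8, 10) for p in range(15)]
        a, b = _callset(rows_a, "a"), _callset(rows_b, "b")
        w = build_windows(a, b, {"chr1": 100})[0]
        assert (w.meth_a, w.unmeth_a) == (30, 120)
        assert (w.meth_b, w.unmeth_b) == (120, 30)


class TestWindowFisher:
    def test_matches_enumeration_oracle(self):
        p = window_fisher(_window(60, 40, 10, 90))
        assert p == pytest.approx(fisher_two_sided_oracle(60, 40, 10, 90), abs=1e-10)

    def test_identical_tables_give_p_one(self):
        assert window_fisher(_window(25, 25, 25, 25)) == pytest.approx(1.0)

    def test_extreme_table_closed_form(self):
        from math import comb

        p = window_fisher(_window(15, 0, 0, 15))
        assert p == pytest.approx(2 / comb(30, 15), rel=1e-10)

    def test_random_tables_against_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            ma, ua, mb, ub = rng.integers(0, 50, size=4)
            if (ma + ua) == 0 or (mb + ub) == 0:
                continue
            p = window_fisher(_window(ma, ua, mb, ub))
            assert p == pytest.approx(
                fisher_two_sided_oracle(int(ma), int(ua), int(mb), int(ub)),
                abs=1e-10,
            )

    def test_untested_window_rejected(self):
        with pytest.raises(ValueError):
            window_fisher(_window(1, 1, 1, 1, tested=False))


class TestMergeWindows:
    def _w(self, start, p, chrom="chr1"):
        return MethWindow(chrom, start, start + 100, 1, 1, 1, 1, 20, True, p)

    def test_overlapping_significant_windows_concatenate(self):
        regions = merge_windows([self._w(100, 1e-5), self._w(150, 1e-4)])
        assert regions == [("chr1", 100, 250, 1e-5)]

    def test_disjoint_windows_stay_separate(self):
        regions = merge_windows([self._w(100, 1e-5), self._w(300, 1e-5)])
        assert len(regions) == 2

    def test_alpha_boundary_is_strict(self):
        regions = merge_windows([self._w(100, 0.001)])
        assert regions == []
        assert len(merge_windows([self._w(100, 0.000999)])) == 1

    def test_output_disjoint_and_sorted(self):
        rng = np.random.default_rng(6)
        windows = [
            self._w(int(s), float(p))
            for s, p in zip(
                rng.choice(np.arange(0, 5_000, 50), 40, replace=False),
                rng.uniform(0, 0.002, 40),
            )
        ]
        regions = merge_windows(windows)
        for (c1, s1, e1, _), (c2, s2, e2, _) in zip(regions, regions[1:]):
            assert (c1, s1) < (c2, s2)
            assert e1 <= s2


class TestClassifyDmrs:
    def _pair(self, frac_a, frac_b, n_sites=20, cov=10):
        ka, kb = int(round(frac_a * cov)), int(round(frac_b * cov))
        rows_a = [("chr1", p, "+", "CHH", ka, cov) for p in range(n_sites)]
        rows_b = [("chr1", p, "+", "CHH", kb, cov) for p in range(n_sites)]
        return _callset(rows_a, "a"), _callset(rows_b, "b")

    def test_clear_dmr_called_with_direction(self):
        a, b = self._pair(0.75, 0.20)
        dmrs = classify_dmrs([("chr1", 0, 100, 1e-6)], a, b)
        assert len(dmrs) == 1
        assert dmrs[0].direction == "a"
        assert dmrs[0].level_a == pytest.approx(0.8, abs=0.1)

    def test_intermediate_levels_rejected(self):
        a, b = self._pair(0.50, 0.10)
        assert classify_dmrs([("chr1", 0, 100, 1e-6)], a, b) == []

    def test_exact_thresholds_rejected(self):
        a, b = self._pair(0.70, 0.30)
        assert classify_dmrs([("chr1", 0, 100, 1e-6)], a, b) == []


class TestAssociateGenes:
    def _gene(self, start=5_000, end=8_000, strand="+"):
        return GeneModel("g1", "chr1", strand, start, end)

    def _dmr(self, start, end):
        return DmrRecord("chr1", start, end, 0.8, 0.1, "a", 1e-6, name="d")

    def test_five_prime_flank_association(self):
        dmrs = associate_genes([self._dmr(4_100, 4_200)], [self._gene()])
        assert dmrs[0].associated_genes == [("g1", "5_prime")]

    def test_beyond_flank_not_associated(self):
        dmrs = associate_genes([self._dmr(3_900, 3_990)], [self._gene()])
        assert dmrs[0].associated_genes == []

    def test_overlap_relation(self):
        dmrs = associate_genes([self._dmr(6_000, 6_100)], [self._gene()])
        assert dmrs[0].associated_genes == [("g1", "overlap")]

    def test_strand_aware_flank_labels(self):
        dmrs = associate_genes(
            [self._dmr(8_500, 8_600)], [self._gene(strand="-")]
        )
        assert dmrs[0].associated_genes == [("g1", "5_prime")]


class TestHypermethylatedGenes:
    def _calls(self, gene_fracs, n_per_gene=25, n_bg=400, bg_frac=0.1, cov=10):
        rng = np.random.default_rng(12)
        rows = []
        pos = 0
        for frac in gene_fracs:
            for _ in range(n_per_gene):
                meth = cov if rng.random() < frac else 0
                rows.append(("chr1", pos, "+", "CG", meth, cov))
                pos += 40
            pos += 4_000
        for _ in range(n_bg):
            meth = cov if rng.random() < bg_frac else 0
            rows.append(("chr1", pos, "+", "CG", meth, cov))
            pos += 40
        return _callset(rows, "s")

    def _genes(self, n, n_per_gene=25):
        genes = []
        pos = 0
        for i in range(n):
            span = n_per_gene * 40
            genes.append(GeneModel(f"g{i}", "chr1", "+", pos, pos + span))
            pos += span + 4_000
        return genes

    def test_saturated_gene_significant(self):
        calls = self._calls([1.0, 0.1, 0.1])
        out = hypermethylated_genes(calls, self._genes(3), "CG").set_index("gene_id")
        assert bool(out.loc["g0", "significant"])
        assert out.loc["g0", "p_value"] < 1e-10

    def test_background_rate_gene_not_significant(self):
        calls = self._calls([0.1, 0.1, 0.1])
        out = hypermethylated_genes(calls, self._genes(3), "CG")
        assert not out["significant"].any()

    def test_few_cytosines_excluded(self):
        calls = self._calls([1.0])
        genes = self._genes(1)
        genes[0] = GeneModel("g0", "chr1", "+", 0, 19 * 40)  # only 19 sites
        out = hypermethylated_genes(calls, genes, "CG")
        assert "g0" not in set(out["gene_id"])

    def test_one_tailed_binomial_matches_oracle(self):
        calls = self._calls([1.0, 0.1])
        out = hypermethylated_genes(calls, self._genes(2), "CG").set_index("gene_id")
        row = out.loc["g0"]
        assert row["p_value"] == pytest.approx(
            binom_tail_oracle(int(row["K"]), int(row["N"]), float(row["p_bg"])),
            rel=1e-9,
        )


class TestClusterDmrs:
    def _levels(self, n_per_type=20, seed=0):
        rng = np.random.default_rng(seed)
        rows = {}
        for i in range(n_per_type):
            rows[f"hiA_{i}"] = {
                "a": 0.9 + rng.normal(0, 0.02),
                "b": 0.1 + rng.normal(0, 0.02),
            }
        for i in range(n_per_type):
            rows[f"hiB_{i}"] = {
                "a": 0.1 + rng.normal(0, 0.02),
                "b": 0.9 + rng.normal(0, 0.02),
            }
        return pd.DataFrame(rows).T

    def test_archetypes_recovered(self):
        levels = self._levels()
        labels, sil = cluster_dmrs(levels, k=2, seed=1)
        a_labels = labels[labels.index.str.startswith("hiA")]
        b_labels = labels[labels.index.str.startswith("hiB")]
        agreement = max(
            (a_labels == 0).mean() * (b_labels == 1).mean(),
            (a_labels == 1).mean() * (b_labels == 0).mean(),
        )
        assert agreement >= 0.95
        assert sil > 0.5

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            cluster_dmrs(self._levels(2), k=10)

    def test_degenerate_identical_vectors_signalled(self):
        levels = pd.DataFrame(
            {"d1": {"a": 0.5, "b": 0.5}, "d2": {"a": 0.5, "b": 0.5}}
        ).T
        with pytest.warns(UserWarning, match="degenerate"):
            labels, sil = cluster_dmrs(levels, k=2, seed=0)
        assert np.isnan(sil)


class TestSelfComparison:
    def test_self_vs_self_yields_no_dmrs(self, small_methylome):
        from epivasc.methylation_core import call_methylation, merge_replicates
        from epivasc.synthetic_data import split_spikein

        _, tables = small_methylome
        pooled = merge_replicates(
            [split_spikein(tables[("vascular", r)])[0] for r in (1, 2)]
        )
        calls = call_methylation(pooled, 0.002, "v")
        calls2 = MethylationCallSet("v2", calls.sites.copy(), calls.error_rate)
        windows = score_windows(build_windows(calls, calls2, {"chr1": 100_000}))
        tested = [w for w in windows if w.tested]
        assert len(tested) > 100
        assert all(w.p_value == pytest.approx(1.0) for w in tested)
        assert merge_windows(windows) == []
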