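import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epivasc.methylation_core import (
    STATUS_METHYLATED,
    STATUS_UNCALLABLE,
    MethylationCallSet,
    binomial_tail,
    build_state_matrix,
    call_methylation,
    estimate_error_rate,
    merge_replicates,
    methylation_pca,
    replicate_correlation,
    weighted_level,
)

from conftest import binom_tail_oracle, make_methcounts


def _calls_from_status(sample_id, statuses, start=0):
    """Fabricate a call set with given statuses at consecutive positions."""
    rows, status = [], []
    for i, s in enumerate(statuses):
        rows.append(("chr1", start + i, "+", "CG", 4 if s else 0, 4))
        status.append(STATUS_METHYLATED if s else "unmethylated")
    sites = make_methcounts(rows)
    sites["p_value"] = 0.5
    sites["q_value"] = 0.5
    sites["status"] = status
    return MethylationCallSet(sample_id, sites, 0.002)


class TestMergeReplicates:
    def test_additive_pooling(self):
        reps = [
            make_methcounts([("chr1", 100, "+", "CG", 1, 2)]),
            make_methcounts([("chr1", 100, "+", "CG", 2, 3)]),
            make_methcounts([("chr1", 100, "+", "CG", 0, 1)]),
        ]
        pooled = merge_replicates(reps)
        assert pooled.loc[0, "meth"] == 3 and pooled.loc[0, "total"] == 6

    def test_site_in_single_replicate_kept(self):
        reps = [
            make_methcounts([("chr1", 100, "+", "CG", 1, 2)]),
            make_methcounts([("chr1", 200, "-", "CHH", 0, 5)]),
        ]
        pooled = merge_replicates(reps)
        assert len(pooled) == 2
        assert pooled.set_index("pos").loc[200, "total"] == 5

    def test_conflicting_contexts_rejected(self):
        reps = [
            make_methcounts([("chr1", 100, "+", "CG", 1, 2)]),
            make_methcounts([("chr1", 100, "+", "CHG", 1, 2)]),
        ]
        with pytest.raises(ValueError, match="context"):
            merge_replicates(reps)


class TestErrorRate:
    def test_pooled_fraction(self):
        spike = make_methcounts(
            [("spikein", i, "+", "CHH", 2, 1000) for i in range(10)]
        )
        assert estimate_error_rate(spike) == pytest.approx(0.002)

    def test_zero_meth_floored(self):
        spike = make_methcounts([("spikein", 0, "+", "CG", 0, 10_000)])
        assert estimate_error_rate(spike) == pytest.approx(1e-4)

    def test_out_of_range_warns(self):
        spike = make_methcounts([("spikein", 0, "+", "CG", 100, 1000)])
        with pytest.warns(UserWarning, match="outside"):
            assert estimate_error_rate(spike) == pytest.approx(0.1)

    def test_empty_spikein_rejected(self):
        with pytest.raises(ValueError):
            estimate_error_rate(make_methcounts([]))


class TestBinomialTail:
    @pytest.mark.parametrize(
        "k,n,p,expected",
        [
            (0, 4, 0.01, 1.0),
            (4, 4, 0.01, 1e-8),
            (3, 10, 0.003, 3.189335889030405e-06),  # frozen from the pmf-sum oracle
        ],
    )
    def test_examples(self, k, n, p, expected):
        assert binomial_tail(k, n, p) == pytest.approx(expected, rel=1e-9)

    @given(
        n=st.integers(1, 50),
        kfrac=st.floats(0, 1),
        p=st.floats(1e-4, 0.5),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_bruteforce_oracle(self, n, kfrac, p):
        k = int(round(kfrac * n))
        assert abs(binomial_tail(k, n, p) - binom_tail_oracle(k, n, p)) < 1e-12

    def test_monotone_nonincreasing_in_k(self):
        vals = [binomial_tail(k, 30, 0.01) for k in range(31)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            binomial_tail(5, 4, 0.01)
        with pytest.raises(ValueError):
            binomial_tail(1, 4, 0.0)


class TestCallMethylation:
    def test_all_zero_counts_give_no_calls(self):
        pooled = make_methcounts(
            [("chr1", i, "+", "CG", 0, 8) for i in range(100)]
        )
        calls = call_methylation(pooled, 0.002)
        assert (calls.sites["status"] != STATUS_METHYLATED).all()

    def test_single_signal_site_among_nulls(self):
        rng = np.random.default_rng(0)
        rows = [("chr1", i, "+", "CG", int(k), 10)
                for i, k in enumerate(rng.binomial(10, 0.002, size=1000))]
        rows.append(("chr1", 5000, "+", "CG", 30, 30))
        calls = call_methylation(make_methcounts(rows), 0.002)
        hit = calls.sites[calls.sites["pos"] == 5000]
        assert (hit["status"] == STATUS_METHYLATED).all()

    def test_low_coverage_uncallable(self):
        pooled = make_methcounts(
            [("chr1", 0, "+", "CG", 3, 3), ("chr1", 1, "+", "CG", 4, 4)]
        )
        calls = call_methylation(pooled, 0.002)
        by_pos = calls.sites.set_index("pos")
        assert by_pos.loc[0, "status"] == STATUS_UNCALLABLE
        assert by_pos.loc[1, "status"] == STATUS_METHYLATED

    def test_bh_matches_textbook_definition(self):
        from conftest import bh_reject_oracle

        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(3)
        for _ in range(50):
            m = int(rng.integers(5, 200))
            # mixture of null and signal p-values, as the caller produces
            pv = np.concatenate(
                [rng.uniform(size=m), rng.uniform(size=m // 2) * 1e-4]
            )
            reject, _, _, _ = multipletests(pv, alpha=0.01, method="fdr_bh")
            assert np.array_equal(reject, bh_reject_oracle(pv, 0.01))


class TestWeightedLevel:
    def test_read_weighted_not_site_weighted(self):
        sites = make_methcounts(
            [("chr1", 0, "+", "CG", 5, 10), ("chr1", 1, "+", "CG", 0, 10)]
        )
        assert weighted_level(sites) == pytest.approx(0.25)

    def test_fully_methylated(self):
        sites = make_methcounts([("chr1", i, "+", "CG", 6, 6) for i in range(4)])
        assert weighted_level(sites) == 1.0

    def test_equals_coverage_weighted_mean_of_fractions(self):
        rng = np.random.default_rng(9)
        total = rng.integers(1, 40, size=500)
        meth = rng.integers(0, total + 1)
        sites = make_methcounts(
            [("chr1", i, "+", "CHH", int(k), int(n))
             for i, (k, n) in enumerate(zip(meth, total))]
        )
        frac = meth / total
        expected = np.average(frac, weights=total)
        assert weighted_level(sites) == pytest.approx(expected, abs=1e-12)

    def test_empty_selection_signalled(self):
        sites = make_methcounts([("chr1", 0, "+", "CG", 1, 2)])
        with pytest.raises(ValueError):
            weighted_level(sites, chrom="chr2")


class TestReplicateCorrelation:
    def test_identical_replicates(self):
        a = _calls_from_status("a", [1, 0, 1, 0, 1])
        b = _calls_from_status("b", [1, 0, 1, 0, 1])
        assert replicate_correlation(a, b) == pytest.approx(1.0)

    def test_complementary_statuses(self):
        a = _calls_from_status("a", [1, 0, 1, 0])
        b = _calls_from_status("b", [0, 1, 0, 1])
        assert replicate_correlation(a, b) == pytest.approx(-1.0)

    def test_independent_nulls_near_zero(self):
        rng = np.random.default_rng(11)
        a = _calls_from_status("a", rng.integers(0, 2, size=10_000))
        b = _calls_from_status("b", rng.integers(0, 2, size=10_000))
        assert abs(replicate_correlation(a, b)) < 0.05

    def test_constant_vector_signalled(self):
        a = _calls_from_status("a", [1, 1, 1])
        b = _calls_from_status("b", [1, 0, 1])
        with pytest.warns(UserWarning):
            assert np.isnan(replicate_correlation(a, b))


class TestMethylationPca:
    def _state(self, rows):
        return pd.DataFrame(
            rows,
            index=[f"s{i}" for i in range(len(rows))],
        )

    def test_planted_groups_separate_on_pc1(self):
        rng = np.random.default_rng(21)
        base = rng.integers(0, 2, size=2_000)
        flip = rng.random(2_000) < 0.2
        group_b = np.where(flip, 1 - base, base)
        rows = []
        for _ in range(3):
            noise = rng.random(2_000) < 0.01
            rows.append(np.where(noise, 1 - base, base))
        for _ in range(3):
            noise = rng.random(2_000) < 0.01
            rows.append(np.where(noise, 1 - group_b, group_b))
        coords, var_exp = methylation_pca(self._state(rows))
        pc1 = coords["PC1"].to_numpy()
        within = max(
            np.ptp(pc1[:3]),
            np.ptp(pc1[3:]),
        )
        between = abs(pc1[:3].mean() - pc1[3:].mean())
        assert between > within
        assert var_exp[0] > 0.5

    def test_all_identical_samples_collapse_to_zero(self):
        rows = [np.array([1, 0, 1, 0])] * 4
        coords, var_exp = methylation_pca(self._state(rows))
        assert np.allclose(coords.to_numpy(), 0.0)
        assert np.allclose(var_exp, 0.0)

    def test_duplicate_sample_coincides(self):
        rng = np.random.default_rng(5)
        rows = [rng.integers(0, 2, 200) for _ in range(3)]
        rows.append(rows[0].copy())
        coords, _ = methylation_pca(self._state(rows))
        assert np.allclose(coords.iloc[0], coords.iloc[3])

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(8)
        rows = [rng.integers(0, 2, 100) for _ in range(5)]
        a, _ = methylation_pca(self._state(rows))
        b, _ = methylation_pca(self._state(rows))
        pd.testing.assert_frame_equal(a, b)


class TestStateMatrix:
    def test_site_universe_is_intersection_of_callable(self):
        a = _calls_from_status("a", [1, 0, 1])
        b = _calls_from_status("b", [0, 1], start=1)  # covers positions 1,2 only
        mat = build_state_matrix({"a": a, "b": b})
        assert mat.shape == (2, 2)
        assert set(mat.columns.get_level_values(1)) == {1, 2}
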