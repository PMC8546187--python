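"""Window arithmetic, the circular-shift null, and the enrichment driver."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirgwas.enrichment import (
    assign_snps,
    bh_fdr,
    build_background_index,
    build_windows,
    circular_shift,
    compute_tsum,
    empirical_pvalue,
    exclude_region,
    permutation_tsums,
    run_enrichment,
)
from mirgwas.intervals import FeatureSet, GenomicInterval


def feature(chrom, start, end, fid):
    return GenomicInterval(chrom=chrom, start=start, end=end, feature_id=fid)


class TestBuildWindows:
    def test_symmetric_flank_arithmetic(self):
        fs = FeatureSet([feature("chr1", 100_000, 100_080, "mir-x")])
        win = build_windows(fs, 50_000)
        assert win.iloc[0].tolist() == ["chr1", 50_000, 150_080]

    def test_clipped_at_position_one(self):
        fs = FeatureSet([feature("chr1", 10_000, 10_080, "mir-x")])
        win = build_windows(fs, 50_000)
        assert win.iloc[0]["start"] == 1

    def test_overlapping_windows_merge_and_shrink_total_cover(self):
        fs = FeatureSet(
            [feature("chr1", 100_000, 100_100, "a"), feature("chr1", 130_000, 130_100, "b")]
        )
        separate = build_windows(fs, 1_000)
        merged = build_windows(fs, 50_000)
        assert len(separate) == 2 and len(merged) == 1
        cover = lambda w: int((w["end"] - w["start"] + 1).sum())
        # union oracle: two extended intervals overlap, so the merged cover is
        # smaller than the sum of the two extended lengths
        ext_len = 2 * (101 + 2 * 50_000)
        assert cover(merged) < ext_len
        assert cover(merged) == 130_100 + 50_000 - (100_000 - 50_000) + 1


class TestExcludeRegion:
    region = GenomicInterval(chrom="chr1", start=2_000_000, end=2_010_000, feature_id="major_gene")

    def make(self, chrom, pos):
        return pd.DataFrame({"snp_id": ["s"], "chrom": [chrom], "pos": [pos], "beta": [0.1]})

    def test_upstream_within_margin_removed(self):
        snps = self.make("chr1", 2_000_000 - 900_000)
        assert exclude_region(snps, self.region, 1_000_000).empty

    def test_downstream_past_margin_kept(self):
        snps = self.make("chr1", 2_010_000 + 1_100_000)
        assert len(exclude_region(snps, self.region, 1_000_000)) == 1

    def test_other_chromosome_untouched(self):
        snps = self.make("chr2", 2_000_000)
        assert len(exclude_region(snps, self.region, 1_000_000)) == 1


class TestAssignSnps:
    def test_inclusive_boundaries_and_brute_force_scan(self, toy_snps):
        bg = build_windows(FeatureSet([feature("chr1", 1, 100_000, "all")]), 0)
        index = build_background_index(toy_snps, bg)
        win = pd.DataFrame(
            {"chrom": ["chr1"] * 3, "start": [2000, 5000, 9000], "end": [2000, 5999, 9001]}
        )
        ranks = assign_snps(index, win)
        # brute force membership over all SNPs
        expected = [
            i + 1
            for i, pos in enumerate(index.snps["pos"])
            if any(s <= pos <= e for s, e in zip(win["start"], win["end"]))
        ]
        assert list(ranks) == expected == [2, 5, 9]

    def test_one_base_past_end_excluded(self, toy_snps):
        bg = build_windows(FeatureSet([feature("chr1", 1, 100_000, "all")]), 0)
        index = build_background_index(toy_snps, bg)
        assert list(assign_snps(index, pd.DataFrame({"chrom": ["chr1"], "start": [1], "end": [1999]}))) == [1]

    def test_candidate_outside_background_rejected(self, toy_snps):
        bg = build_windows(FeatureSet([feature("chr1", 1, 5_500, "half")]), 0)
        index = build_background_index(toy_snps, bg)
        win = pd.DataFrame({"chrom": ["chr1"], "start": [1], "end": [100_000]})
        with pytest.raises(ValueError, match="outside the background"):
            assign_snps(index, win, all_snps=toy_snps)


class TestTsumAndShift:
    def test_tsum_examples(self):
        assert compute_tsum(np.array([0.1, -0.2, 0.3]), np.array([1, 2, 3])) == pytest.approx(0.14)
        assert compute_tsum(np.zeros(5), np.arange(1, 6)) == 0.0
        assert compute_tsum(np.array([1.0, 2.0, 3.0]), np.array([1, 3])) == pytest.approx(10.0)

    def test_tsum_empty_candidate_is_an_explicit_error(self):
        with pytest.raises(ValueError, match="no testable SNPs"):
            compute_tsum(np.ones(3), np.array([], dtype=int))

    def test_shift_wraps_past_m(self):
        assert list(circular_shift(np.array([1, 3]), M=5, R=4)) == [5, 2]

    def test_shift_by_m_is_identity(self):
        n = np.array([2, 4, 7])
        assert list(circular_shift(n, M=9, R=9)) == list(n)

    def test_shift_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="1..5"):
            circular_shift(np.array([1]), M=5, R=6)

    @settings(deadline=None, derandomize=True)
    @given(data=st.data(), M=st.integers(2, 60))
    def test_shift_is_a_permutation(self, data, M):
        n = data.draw(
            st.sets(st.integers(1, M), min_size=1, max_size=M).map(sorted).map(np.array)
        )
        R = data.draw(st.integers(1, M))
        shifted = circular_shift(n, M, R)
        assert len(set(shifted)) == len(n)
        assert shifted.min() >= 1 and shifted.max() <= M


class TestEmpiricalPvalue:
    def test_no_exceedance(self):
        n_over, p = empirical_pvalue(5.0, np.zeros(10_000))
        assert (n_over, p) == (0, 1 / 10_001)

    def test_all_exceed(self):
        n_over, p = empirical_pvalue(0.0, np.ones(100))
        assert (n_over, p) == (100, 1.0)

    def test_ties_not_counted_under_strict_rule(self):
        n_over, p = empirical_pvalue(1.0, np.ones(99))
        assert (n_over, p) == (0, 0.01)
        n_over_geq, _ = empirical_pvalue(1.0, np.ones(99), tie="geq")
        assert n_over_geq == 99


def brute_force_n_over(beta, candidate_ranks):
    """Independent oracle: enumerate every shift with plain Python loops.

    Uses math.fsum (correctly rounded) for both the observed and the
    shifted statistics so exact ties — notably the identity shift R = M —
    are resolved exactly under the strict > rule.
    """
    import math

    M = len(beta)
    tsum_obs = math.fsum(beta[N - 1] ** 2 for N in candidate_ranks)
    n_over = 0
    for R in range(1, M + 1):
        shifted = [N + R if N + R <= M else N + R - M for N in candidate_ranks]
        t = math.fsum(beta[P - 1] ** 2 for P in shifted)
        if t > tsum_obs:
            n_over += 1
    return n_over


class TestPermutationNull:
    def make_index(self, M, seed=0):
        rng = np.random.default_rng(seed)
        snps = pd.DataFrame(
            {
                "snp_id": [f"s{i}" for i in range(M)],
                "chrom": "chr1",
                "pos": np.arange(1, M + 1) * 100,
                "beta": rng.standard_normal(M) * 0.1,
            }
        )
        win = pd.DataFrame({"chrom": ["chr1"], "start": [1], "end": [M * 100]})
        return build_background_index(snps, win)

    def test_every_shift_conserves_total_sum_of_squares(self):
        index = self.make_index(30)
        total = float((index.betas**2).sum())
        full = np.arange(1, 31)
        perms = permutation_tsums(index, full, nperm=1, rng=np.random.default_rng(0), exhaustive=True)
        assert np.allclose(perms, total)

    def test_exhaustive_matches_brute_force_oracle(self):
        """All-M-shifts enumeration equals an independent loop-based oracle."""
        rng = np.random.default_rng(7)
        for trial in range(20):
            M = int(rng.integers(10, 51))
            index = self.make_index(M, seed=trial)
            n = int(rng.integers(1, M))
            ranks = np.sort(rng.choice(np.arange(1, M + 1), size=n, replace=False))
            tsum_obs = compute_tsum(index.betas, ranks)
            perms = permutation_tsums(index, ranks, nperm=0, rng=rng, exhaustive=True)
            n_over, _ = empirical_pvalue(tsum_obs, perms)
            assert n_over == brute_force_n_over(index.betas, ranks)

    def test_identical_betas_give_floor_pvalue(self):
        index = self.make_index(20)
        index.betas[:] = 0.3
        ranks = np.array([3, 7, 11])
        tsum_obs = compute_tsum(index.betas, ranks)
        perms = permutation_tsums(index, ranks, nperm=500, rng=np.random.default_rng(1))
        n_over, p = empirical_pvalue(tsum_obs, perms)
        assert n_over == 0 and p == pytest.approx(1 / 501)

    def test_scaling_candidate_effects_never_raises_pvalue(self):
        """Inflating every candidate |beta| (background fixed elsewhere) is
        monotone: the p-value cannot increase."""
        index = self.make_index(40, seed=3)
        ranks = np.array([5, 6, 17, 30])
        p_prev = 1.1
        for scale in (1.0, 2.0, 5.0, 20.0):
            scaled = self.make_index(40, seed=3)
            scaled.betas[ranks - 1] *= scale
            tsum_obs = compute_tsum(scaled.betas, ranks)
            perms = permutation_tsums(scaled, ranks, nperm=0, rng=np.random.default_rng(0), exhaustive=True)
            _, p = empirical_pvalue(tsum_obs, perms)
            assert p <= p_prev + 1e-12
            p_prev = p

    def test_random_set_mode_is_calibrated_against_circular(self):
        index = self.make_index(200, seed=5)
        ranks = np.arange(50, 60)
        tsum_obs = compute_tsum(index.betas, ranks)
        rng = np.random.default_rng(2)
        p_random = empirical_pvalue(
            tsum_obs, permutation_tsums(index, ranks, 400, rng, null_mode="random_set")
        )[1]
        p_circ = empirical_pvalue(
            tsum_obs, permutation_tsums(index, ranks, 400, rng, null_mode="circular")
        )[1]
        # same data, two exchangeable nulls: p-values agree loosely
        assert abs(p_random - p_circ) < 0.25


class TestBhFdr:
    def test_single_p_is_identity(self):
        assert bh_fdr([0.03]) == pytest.approx([0.03])

    def test_step_up_hand_computation(self):
        # m=4: sorted adjustments 0.01*4/1, 0.02*4/2, 0.04*4/3, 0.05*4/4
        # -> (0.04, 0.04, 0.0533, 0.05) then step-up monotonicity from below
        assert bh_fdr([0.01, 0.02, 0.04, 0.05]) == pytest.approx([0.04, 0.04, 0.05, 0.05])

    def test_all_ones_stay_one(self):
        assert bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    def test_fdr_never_below_p_within_family(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=25)
        assert (bh_fdr(p) >= p - 1e-12).all()


class TestRunEnrichment:
    def test_seed_reproducibility_and_order_invariance(self, small_config):
        from mirgwas.simulate import simulate_annotation, simulate_gwas_summary

        prec, _ = simulate_annotation(small_config)
        snps = simulate_gwas_summary(small_config, prec, flank=10_000)
        sets = {
            "a": prec.subset([f"mir_{i}" for i in range(1, 6)]),
            "b": prec.subset([f"mir_{i}" for i in range(6, 11)]),
        }
        r1 = run_enrichment(snps, sets, prec, flank=10_000, nperm=100, seed=9)
        r2 = run_enrichment(
            snps, dict(reversed(list(sets.items()))), prec, flank=10_000, nperm=100, seed=9
        )
        merged = r1.set_index("feature_set").join(
            r2.set_index("feature_set"), lsuffix="_1", rsuffix="_2"
        )
        assert (merged["pvalue_1"] == merged["pvalue_2"]).all()

    def test_empty_background_rejected(self, toy_snps):
        empty = FeatureSet([feature("chr9", 1, 10, "far")])
        with pytest.raises(ValueError, match="no SNPs"):
            run_enrichment(toy_snps, {"x": empty}, empty, flank=0, nperm=10)

    def test_candidate_without_snps_reported_not_zero(self, toy_snps):
        bg = FeatureSet([feature("chr1", 1, 100_000, "all")])
        lonely = FeatureSet([feature("chr1", 50_000, 50_010, "desert")])
        res = run_enrichment(
            toy_snps, {"desert": lonely}, bg, flank=0, candidate_flank=0, nperm=10
        )
        row = res.iloc[0]
        assert row["m"] == 0 and np.isnan(row["tsum"]) and np.isnan(row["pvalue"])
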