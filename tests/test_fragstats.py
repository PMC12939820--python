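"""Fragment counting, fusion sites, rate regression, and Mott fits."""

import itertools

import numpy as np
import pytest

from isofrag import fragstats, synthdata
from isofrag.isocall import IsoCall
from .conftest import MB, seg_df


def p_call(sample="S1", chrom="chrA"):
    return IsoCall(sample, chrom, "p", "q", "major", 2)


def q_call(sample="S1", chrom="chrA"):
    return IsoCall(sample, chrom, "q", "p", "major", 2)


class TestCountHetFragments:
    def test_two_fragments_plus_centromere(self, simple_cents):
        segs = seg_df(
            [
                ("S1", "chrA", 0, 5 * MB, 1, 0),
                ("S1", "chrA", 5 * MB, 6 * MB, 1, 1),
                ("S1", "chrA", 6 * MB, 20 * MB, 1, 0),
                ("S1", "chrA", 20 * MB, 22 * MB, 1, 1),
                ("S1", "chrA", 22 * MB, 50 * MB, 1, 0),
                ("S1", "chrA", 50 * MB, 100 * MB, 2, 1),
            ]
        )
        fs = fragstats.count_het_fragments(p_call(), segs, simple_cents)
        assert fs.n_het_fragments == 3 and len(fs.fragments) == 2
        assert not fs.centromere_gap_corrected

    def test_bare_loh_arm_counts_one(self, simple_cents):
        segs = seg_df(
            [("S1", "chrA", 0, 50 * MB, 1, 0), ("S1", "chrA", 50 * MB, 100 * MB, 2, 1)]
        )
        fs = fragstats.count_het_fragments(p_call(), segs, simple_cents)
        assert fs.n_het_fragments == 1 and fs.fragments.empty

    def test_centromere_gap_with_equal_flanks_subtracts_one(self, simple_cents):
        # centromere 45-55 Mb entirely uncovered; both flanks at (1,0)
        segs = seg_df(
            [
                ("S1", "chrA", 0, 5 * MB, 1, 0),
                ("S1", "chrA", 5 * MB, 7 * MB, 1, 1),
                ("S1", "chrA", 7 * MB, 20 * MB, 1, 0),
                ("S1", "chrA", 20 * MB, 21 * MB, 1, 1),
                ("S1", "chrA", 21 * MB, 45 * MB, 1, 0),
                ("S1", "chrA", 55 * MB, 100 * MB, 1, 0),
            ]
        )
        fs = fragstats.count_het_fragments(p_call(), segs, simple_cents)
        assert fs.centromere_gap_corrected
        assert fs.n_het_fragments == 2

    def test_arm_containment_is_strict(self, simple_cents):
        # a het segment straddling the midpoint is not a p-arm fragment
        segs = seg_df(
            [
                ("S1", "chrA", 0, 49 * MB, 1, 0),
                ("S1", "chrA", 49 * MB, 52 * MB, 1, 1),
                ("S1", "chrA", 52 * MB, 100 * MB, 2, 1),
            ]
        )
        fs = fragstats.count_het_fragments(p_call(), segs, simple_cents)
        assert fs.fragments.empty


class TestFusionSite:
    def test_outer_boundary_of_farthest_fragment(self, simple_cents):
        c = simple_cents.midpoint("chrA")
        segs = seg_df(
            [
                ("S1", "chrA", 0, 50 * MB, 2, 1),
                ("S1", "chrA", 50 * MB, c + 10 * MB, 1, 0),
                ("S1", "chrA", c + 10 * MB, c + 20 * MB, 1, 1),
                ("S1", "chrA", c + 20 * MB, c + 40 * MB, 1, 0),
                ("S1", "chrA", c + 40 * MB, c + 55 * MB - 10, 1, 1),
                ("S1", "chrA", c + 55 * MB - 10, 100 * MB, 1, 0),
            ]
        )
        fs = fragstats.count_het_fragments(q_call(), segs, simple_cents)
        site, dist = fragstats.locate_fusion_site(q_call(), fs, simple_cents)
        assert site == c + 55 * MB - 10
        assert dist == 55 * MB - 10

    def test_monocentric_distance_zero(self, simple_cents):
        segs = seg_df(
            [("S1", "chrA", 0, 50 * MB, 2, 1), ("S1", "chrA", 50 * MB, 100 * MB, 1, 0)]
        )
        fs = fragstats.count_het_fragments(q_call(), segs, simple_cents)
        site, dist = fragstats.locate_fusion_site(q_call(), fs, simple_cents)
        assert dist == 0 and site == simple_cents.midpoint("chrA")

    def test_planted_fusion_sites_recovered(self, genome, centromeres):
        spec = synthdata.CohortSpec(n_patients=60, p_iso=0.5, p_mono=0.0, seed=5)
        segments, truth = synthdata.generate_cohort(spec)
        from isofrag import isocall

        calls = isocall.call_cohort(segments, centromeres, chromosomes=["c1", "c2", "c3"])
        fragstats.annotate_calls(calls, segments, centromeres)
        got = {(k.sample_id, k.chrom): k.fusion_site for k in calls}
        planted = truth[truth["iso"]]
        assert len(got) == len(planted)
        for _, row in planted.iterrows():
            assert got[(row["sample"], row["chrom"])] == row["fusion_site"]


class TestRegression:
    def test_exact_three_point_line(self):
        fit = fragstats.regress_fragment_count(
            [0.0, 12 * MB, 24 * MB], [1.0, 2.0, 3.0]
        )
        assert fit.slope == pytest.approx(1.0 / (12 * MB), rel=1e-12)
        assert fit.intercept == pytest.approx(1.0, abs=1e-9)
        assert fit.mb_per_fragment == pytest.approx(12.0, rel=1e-9)
        assert fit.slope_ci[0] <= fit.slope <= fit.slope_ci[1]

    def test_refuses_small_or_degenerate_designs(self):
        with pytest.raises(ValueError, match="at least 3"):
            fragstats.regress_fragment_count([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError, match="degenerate"):
            fragstats.regress_fragment_count([5.0, 5.0, 5.0], [1.0, 2.0, 3.0])

    def test_recovers_planted_rate_consistently(self):
        # consistency on growing cohorts: the slope tightens around 1/12 Mb
        errs = []
        for n_patients, seed in ((120, 3), (1200, 3)):
            spec = synthdata.CohortSpec(n_patients=n_patients, p_iso=0.4, p_mono=0.0, seed=seed)
            _, truth = synthdata.generate_cohort(spec)
            t = truth[truth["centricity"] == "dicentric"]
            fit = fragstats.regress_fragment_count(
                t["fusion_distance"].astype(float), t["n_het_fragments"].astype(float)
            )
            errs.append(abs(fit.mb_per_fragment - 12.0) / 12.0)
        assert errs[1] < 0.1
        assert errs[1] <= errs[0] + 0.02


class TestCompareFragmentation:
    def test_identical_lists(self):
        u, p, fold = fragstats.compare_fragmentation([3, 4, 5], [3, 4, 5])
        assert fold == 1.0 and p > 0.99

    def test_fold_of_constant_lists(self):
        _, _, fold = fragstats.compare_fragmentation([4, 4], [2, 2])
        assert fold == 2.0

    def test_u_and_p_match_exhaustive_enumeration_tie_free(self):
        x, y = [5.0, 6.0, 7.0], [1.0, 2.0, 4.0]
        u, p, _ = fragstats.compare_fragmentation(x, y, method="exact")
        # U = number of (xi, yj) pairs with xi > yj
        u_expected = sum(xi > yj for xi in x for yj in y)
        assert u == u_expected
        # exact two-sided p by enumerating all group assignments of the ranks
        pooled = x + y
        stats_all = []
        for comb in itertools.combinations(range(6), 3):
            gx = [pooled[i] for i in comb]
            gy = [pooled[i] for i in range(6) if i not in comb]
            stats_all.append(sum(a > b for a in gx for b in gy))
        mean_u = np.mean(stats_all)
        p_expected = np.mean([abs(s - mean_u) >= abs(u - mean_u) for s in stats_all])
        assert p == pytest.approx(p_expected, rel=1e-9)

    def test_u_statistic_with_ties_matches_enumeration(self):
        x, y = [5.0, 6.0, 7.0], [1.0, 1.0, 2.0]
        u, _, _ = fragstats.compare_fragmentation(x, y)
        assert u == sum(xi > yj for xi in x for yj in y)

    def test_empty_group_refused(self):
        with pytest.raises(ValueError):
            fragstats.compare_fragmentation([], [1.0])


class TestMott:
    def test_mean_fragment_size_closed_forms(self):
        fit = fragstats.MottFit(mu=0.5, beta=1.0, log_n0=0, rss=0, n_points=0,
                                n_fragments=0, scale=1.0)
        assert fit.mean_fragment_size == pytest.approx(1 / 0.5)
        fit = fragstats.MottFit(mu=0.5, beta=0.5, log_n0=0, rss=0, n_points=0,
                                n_fragments=0, scale=1.0)
        assert fit.mean_fragment_size == pytest.approx(2 / 0.25)

    def test_parameter_recovery_from_seeded_survival_draws(self):
        rng = np.random.default_rng(0)
        lengths_mb = synthdata.sample_mott_lengths(2000, 0.05, 0.7, rng)
        mott, expo = fragstats.fit_mott(lengths_mb * 1e6)
        assert mott.mu == pytest.approx(0.05, rel=0.10)
        assert mott.beta == pytest.approx(0.7, rel=0.10)
        assert expo.rss > mott.rss

    def test_beta_ci_covers_one_on_exponential_data(self):
        covered = 0
        for s in range(100):
            rng = np.random.default_rng(1000 + s)
            lengths_mb = synthdata.sample_mott_lengths(300, 1.0, 1.0, rng)
            mott, _ = fragstats.fit_mott(lengths_mb * 1e6)
            lo, hi = mott.beta_ci()
            covered += lo <= 1.0 <= hi
        assert covered >= 90

    def test_empirical_counts_non_increasing_and_anchor(self, rng):
        lengths = rng.exponential(2.0, size=200)
        ls, n_gt = fragstats.empirical_cumulative_counts(lengths)
        assert (np.diff(n_gt) <= 0).all()
        assert n_gt.max() < 200  # strictly-greater counts never reach n
        assert (n_gt > 0).all()

    @pytest.mark.parametrize(
        "lengths,match",
        [
            ([1.0] * 5, "at least 10"),
            ([1.0, -2.0] + [1.0] * 10, "positive"),
            ([3.0] * 20, "degenerate"),
        ],
    )
    def test_refusals(self, lengths, match):
        with pytest.raises(ValueError, match=match):
            fragstats.fit_mott(lengths)
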