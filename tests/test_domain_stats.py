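"""Interval statistics: intra-domain classification, overlaps, recall,
rank-sum contrast, compartment composition — each against a brute-force
oracle where the computation is non-trivial."""

import numpy as np
import pytest

from ramscan import (
    AnchorPair,
    DomainSet,
    GenomicInterval,
    ValidationError,
    boundary_recall,
    boundary_track_overlap,
    classify_pairs,
    compartment_composition,
    interval_intra_fraction,
    pair_set_comparison,
    rank_sum_test,
)
from ramscan.consensus import ConsensusBoundarySet
from ramscan.domain_stats import density_contrast
from ramscan.genomic_io import BoundarySet
from ramscan.ram_caller import DensityProfile


def domain_set(intervals, chrom="chrT", label="RAM"):
    return DomainSet(label, {chrom: [GenomicInterval(chrom, s, e) for s, e in intervals]})


def random_domains(rng, n=10, chrom="chrT", span=10_000_000):
    cuts = np.sort(rng.choice(span, size=2 * n, replace=False))
    return domain_set([(int(cuts[2 * i]), int(cuts[2 * i + 1])) for i in range(n)], chrom=chrom)


def pair(c1, m1, m2, chrom="chrT", half=50):
    return AnchorPair(
        GenomicInterval(chrom, m1 - half, m1 + half), GenomicInterval(chrom, m2 - half, m2 + half)
    )


class TestClassifyPairs:
    def test_both_anchors_in_one_domain(self):
        ds = domain_set([(0, 3_000_000)])
        rep = classify_pairs([pair(0, 100_000, 2_000_000)], ds)
        assert rep.labels == ["intra"] and rep.fraction_intra == 1.0

    def test_anchors_in_adjacent_domains(self):
        ds = domain_set([(0, 1_000_000), (1_500_000, 3_000_000)])
        rep = classify_pairs([pair(0, 500_000, 2_000_000)], ds)
        assert rep.labels == ["inter"]

    def test_cross_chromosome_is_inter(self):
        ds = domain_set([(0, 10_000_000)])
        p = AnchorPair(GenomicInterval("chrT", 0, 100), GenomicInterval("chrU", 0, 100))
        assert classify_pairs([p], ds).labels == ["inter"]

    def test_midpoint_in_gap_is_inter(self):
        ds = domain_set([(0, 1_000_000), (2_000_000, 3_000_000)])
        rep = classify_pairs([pair(0, 1_500_000, 2_500_000)], ds)
        assert rep.labels == ["inter"]

    def test_empty_pair_list_flagged(self):
        rep = classify_pairs([], domain_set([(0, 100)]))
        assert rep.n_total == 0 and rep.fraction_intra is None

    def test_matches_brute_force_containment_scan(self, rng):
        ds = random_domains(rng)
        ivs = ds.domains["chrT"]
        pairs = [
            pair(0, int(rng.integers(100, 9_999_000)), int(rng.integers(100, 9_999_000)))
            for _ in range(200)
        ]
        rep = classify_pairs(pairs, ds)
        for p, label in zip(pairs, rep.labels):
            m1, m2 = p.anchor1.midpoint, p.anchor2.midpoint
            expected = "inter"
            for d in ivs:
                if d.start <= m1 < d.end and d.start <= m2 < d.end:
                    expected = "intra"
            assert label == expected


class TestPairSetComparison:
    def test_fg_only(self):
        fg = domain_set([(0, 3_000_000)])
        bg = domain_set([(0, 1_000_000), (1_500_000, 3_000_000)])
        part = pair_set_comparison([pair(0, 500_000, 2_000_000)], fg, bg)
        assert part.intra_fg_only == 1 and part.n_total == 1

    def test_identical_sets_have_no_exclusives(self, rng):
        ds = random_domains(rng)
        pairs = [pair(0, int(rng.integers(0, 9_900_000)), int(rng.integers(0, 9_900_000))) for _ in range(100)]
        part = pair_set_comparison(pairs, ds, ds)
        assert part.intra_fg_only == 0 and part.intra_bg_only == 0

    def test_composes_two_classifications(self, rng):
        fg, bg = random_domains(rng), random_domains(rng)
        pairs = [pair(0, int(rng.integers(0, 9_900_000)), int(rng.integers(0, 9_900_000))) for _ in range(200)]
        part = pair_set_comparison(pairs, fg, bg)
        a = classify_pairs(pairs, fg).labels
        b = classify_pairs(pairs, bg).labels
        assert part.intra_both == sum(x == "intra" and y == "intra" for x, y in zip(a, b))
        assert part.intra_fg_only == sum(x == "intra" and y == "inter" for x, y in zip(a, b))
        assert part.intra_bg_only == sum(x == "inter" and y == "intra" for x, y in zip(a, b))
        assert part.inter_both == sum(x == "inter" and y == "inter" for x, y in zip(a, b))


class TestIntervalIntraFraction:
    def test_median_cutoff_drops_large_intervals(self):
        ds = domain_set([(0, 1), (10, 12), (20, 23), (30, 34), (40, 45)])
        ds = domain_set(
            [(0, 1_000_000), (2_000_000, 4_000_000), (5_000_000, 8_000_000),
             (9_000_000, 13_000_000), (14_000_000, 19_000_000)]
        )  # lengths 1..5 Mb -> median 3 Mb
        intervals = [GenomicInterval("chrT", 9_500_000, 13_000_000)]  # 3.5 Mb
        rep, cutoff = interval_intra_fraction(intervals, ds, size_filter="median")
        assert cutoff == 3_000_000
        assert rep.n_total == 0  # dropped by the filter

    def test_interval_equal_to_domain_is_intra(self):
        ds = domain_set([(100, 200)])
        rep, _ = interval_intra_fraction([GenomicInterval("chrT", 100, 200)], ds, size_filter=None)
        assert rep.labels == ["intra"]

    def test_empty_domain_set_is_error(self):
        with pytest.raises(ValidationError):
            interval_intra_fraction([], DomainSet("RAM", {}), size_filter=None)

    def test_matches_brute_force_containment(self, rng):
        ds = random_domains(rng)
        ivs = ds.domains["chrT"]
        intervals = []
        for _ in range(500):
            s = int(rng.integers(0, 9_000_000))
            intervals.append(GenomicInterval("chrT", s, s + int(rng.integers(1, 900_000))))
        rep, cutoff = interval_intra_fraction(intervals, ds, size_filter="median")
        kept = [iv for iv in intervals if iv.length < cutoff]
        assert rep.n_total == len(kept)
        for iv, label in zip(kept, rep.labels):
            expected = "inter"
            for d in ivs:
                if d.start <= iv.start and iv.end <= d.end:
                    expected = "intra"
            assert label == expected


class TestBoundaryTrackOverlap:
    def test_one_bp_overlap_counts(self):
        b = [GenomicInterval("chrT", 1_000_000, 2_000_000)]
        t = [GenomicInterval("chrT", 1_900_000, 3_000_000)]
        assert boundary_track_overlap(b, t) == (1.0, 1.0)

    def test_adjacent_half_open_do_not_overlap(self):
        b = [GenomicInterval("chrT", 0, 100)]
        t = [GenomicInterval("chrT", 100, 200)]
        assert boundary_track_overlap(b, t) == (0.0, 0.0)

    def test_matches_brute_force_scan(self, rng):
        def random_ivs(n):
            out = []
            for _ in range(n):
                s = int(rng.integers(0, 9_000_000))
                out.append(GenomicInterval("chrT", s, s + int(rng.integers(1, 500_000))))
            return out

        b, t = random_ivs(50), random_ivs(70)
        fb, ft = boundary_track_overlap(b, t)
        exp_fb = sum(any(x.start < y.end and y.start < x.end for y in t) for x in b) / len(b)
        exp_ft = sum(any(x.start < y.end and y.start < x.end for y in b) for x in t) / len(t)
        assert fb == pytest.approx(exp_fb) and ft == pytest.approx(exp_ft)

    def test_symmetry_under_argument_swap(self, rng):
        b = [GenomicInterval("chrT", 100, 300), GenomicInterval("chrT", 900, 1000)]
        t = [GenomicInterval("chrT", 250, 950)]
        assert boundary_track_overlap(b, t) == tuple(reversed(boundary_track_overlap(t, b)))


class TestBoundaryRecall:
    def b(self, centers, sample="s", step=250_000):
        regs = [GenomicInterval("chrT", c - 125_000, c + 125_000) for c in centers]
        return BoundarySet(sample_id=sample, step=step, regions={"chrT": regs})

    def test_identical_sets(self):
        bs = self.b([1_000_000, 5_000_000])
        rep = boundary_recall(bs, bs)
        assert rep.recall == 1.0

    def test_empty_query(self):
        rep = boundary_recall(self.b([1_000_000]), self.b([]))
        assert rep.recall == 0.0

    def test_empty_reference_is_error(self):
        with pytest.raises(ValidationError):
            boundary_recall(self.b([]), self.b([1_000_000]))

    def test_jittered_query_matches_nearest_neighbor_check(self, rng):
        ref_centers = sorted(int(c) for c in rng.choice(np.arange(1, 40) * 1_000_000, 10, replace=False))
        jitter = rng.integers(-400_000, 400_000, size=10)
        qry_centers = [c + int(j) for c, j in zip(ref_centers, jitter)]
        rep = boundary_recall(self.b(ref_centers), self.b(sorted(qry_centers)), tolerance=250_000)
        expected = sum(
            min(abs(q - c) for q in qry_centers) <= 250_000 for c in ref_centers
        )
        assert rep.n_matched == expected


class TestRankSum:
    def test_exact_small_sample(self):
        _, p = rank_sum_test([1, 2], [3, 4])
        assert p == pytest.approx(2 / 6)

    def test_identical_groups_null(self):
        _, p = rank_sum_test(np.arange(20), np.arange(20))
        assert p > 0.9

    def test_normal_approximation_matches_permutation_monte_carlo(self, rng):
        x = rng.normal(0.8, 1.0, 30)
        y = rng.normal(0.0, 1.0, 30)
        _, p = rank_sum_test(x, y)
        pooled = np.concatenate([x, y])
        ranks = np.argsort(np.argsort(pooled)) + 1.0
        obs = abs(ranks[:30].sum() - 30 * 61 / 2)
        n_mc = 100_000
        stats_mc = np.empty(n_mc)
        for i in range(n_mc):
            perm = rng.permutation(60)
            stats_mc[i] = abs(ranks[perm[:30]].sum() - 30 * 61 / 2)
        p_mc = (stats_mc >= obs - 1e-9).mean()
        se = np.sqrt(p_mc * (1 - p_mc) / n_mc) + 1e-6
        assert abs(p - p_mc) < max(2 * se, 0.005)

    def test_invariant_under_monotone_transform(self, rng):
        x = rng.normal(5, 1, 25)
        y = rng.normal(6, 1, 25)
        _, p1 = rank_sum_test(x, y)
        _, p2 = rank_sum_test(np.exp(x), np.exp(y))
        assert p1 == pytest.approx(p2, rel=1e-12)


def test_density_contrast_boundary_vs_other_bins():
    step = 250_000
    n = 40
    counts = np.full(n, 100.0)
    counts[10:13] = 5.0  # deep boundary
    prof = DensityProfile(
        chrom="chrT", step=step, flank=500_000,
        bin_centers=np.arange(n, dtype=np.int64) * step, raw_counts=counts,
    )
    cbs = ConsensusBoundarySet(
        cohort="c", step=step,
        regions={"chrT": [GenomicInterval("chrT", 10 * step - step // 2, 12 * step + step // 2)]},
        fractions={"chrT": [1.0]},
    )
    df = density_contrast({"s1": {"chrT": prof}}, cbs)
    row = df.iloc[0]
    assert row.n_boundary_bins == 3
    assert row.median_boundary < row.median_other
    assert row.p_value < 0.05


class TestCompartmentComposition:
    def test_three_quarters_a(self):
        ds = domain_set([(0, 1_000_000)])
        labels = {"chrT": np.array(["A", "A", "B", "A"], dtype=object)}
        df = compartment_composition(ds, labels, resolution=250_000)
        assert df.iloc[0].frac_A == 0.75 and df.iloc[0].frac_B == 0.25

    def test_all_a(self):
        ds = domain_set([(0, 500_000), (500_000, 1_000_000)])
        labels = {"chrT": np.array(["A"] * 4, dtype=object)}
        df = compartment_composition(ds, labels, resolution=250_000)
        assert (df.frac_A == 1.0).all()

    def test_unlabeled_bins_counted_separately(self):
        ds = domain_set([(0, 1_000_000)])
        labels = {"chrT": np.array(["A", "NA", "B", "NA"], dtype=object)}
        df = compartment_composition(ds, labels, resolution=250_000)
        assert df.iloc[0].n_unlabeled == 2 and df.iloc[0].frac_A == 0.5

    def test_no_labeled_bins_flagged(self):
        ds = domain_set([(0, 500_000)])
        labels = {"chrT": np.array(["NA", "NA"], dtype=object)}
        df = compartment_composition(ds, labels, resolution=250_000)
        assert bool(df.iloc[0].no_labeled_bins) and np.isnan(df.iloc[0].frac_A)

    def test_matches_brute_force_bin_count(self, rng):
        ds = random_domains(rng, n=6)
        n_bins = 40
        labels = {"chrT": rng.choice(np.array(["A", "B", "NA"], dtype=object), size=n_bins)}
        df = compartment_composition(ds, labels, resolution=250_000)
        for (_, row), domain in zip(df.iterrows(), ds.domains["chrT"]):
            n_a = n_b = 0
            for b in range(n_bins):
                mid = b * 250_000 + 125_000
                if domain.start <= mid < domain.end:
                    if labels["chrT"][b] == "A":
                        n_a += 1
                    elif labels["chrT"][b] == "B":
                        n_b += 1
            assert row.n_A == n_a and row.n_B == n_b


def test_intra_prob_one_gives_fraction_one():
    """Pairs drawn strictly inside modules are all intra vs the true module set."""
    from ramscan import SimConfig, simulate_layout, simulate_pairs

    cfg = SimConfig(seed=3, intra_prob=1.0, n_pairs=200,
                    chrom_lengths={"chrS1": 40_000_000})
    truth = simulate_layout(cfg)
    pairs = simulate_pairs(truth)
    rep = classify_pairs(pairs, DomainSet("truth", truth.modules))
    assert rep.fraction_intra == 1.0
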