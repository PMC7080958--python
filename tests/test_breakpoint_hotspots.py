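import numpy as np
import pandas as pd
import pytest
from _oracles import breakpoints_bruteforce, poisson_upper_tail_bruteforce

from cnascape.breakpoint_hotspots import (
    count_per_bin,
    extract_breakpoints,
    hotspot_test,
    permute_breakpoints,
    region_overlap,
)
from cnascape.genome_model import (
    GenomeBuild,
    RegionSet,
    exclusion_zones,
    make_bins,
)
from cnascape.seg_io import Cohort
from conftest import make_cohort, random_segments


class TestExtractBreakpoints:
    def test_delta_above_threshold_detected(self, tiny_build, cohort_factory):
        cohort = cohort_factory(
            [("A", "1", 0, 1_000_000, 0.0), ("A", "1", 1_000_000, 2_000_000, 0.5)],
            b=tiny_build,
        )
        bps = extract_breakpoints(cohort)
        assert len(bps) == 1
        assert bps.iloc[0]["position"] == 1_000_000
        assert bps.iloc[0]["delta"] == pytest.approx(0.5)

    def test_delta_below_threshold_ignored(self, tiny_build, cohort_factory):
        cohort = cohort_factory(
            [("A", "1", 0, 1_000_000, 0.0), ("A", "1", 1_000_000, 2_000_000, 0.3)],
            b=tiny_build,
        )
        assert len(extract_breakpoints(cohort)) == 0

    def test_exact_threshold_is_not_a_breakpoint(self, tiny_build, cohort_factory):
        cohort = cohort_factory(
            [("A", "1", 0, 1_000_000, 0.0), ("A", "1", 1_000_000, 2_000_000, 0.4)],
            b=tiny_build,
        )
        assert len(extract_breakpoints(cohort)) == 0

    def test_small_segment_removed_before_comparison(self, tiny_build, cohort_factory):
        # A(0.0), B(5 kb, 0.6), C(0.0): B filtered, A-C delta 0 -> nothing
        cohort = cohort_factory([
            ("A", "1", 0, 1_000_000, 0.0),
            ("A", "1", 1_000_000, 1_005_000, 0.6),
            ("A", "1", 1_005_000, 2_000_000, 0.0),
        ], b=tiny_build)
        assert len(extract_breakpoints(cohort)) == 0

    def test_centromeric_boundary_excluded(self, tiny_build, cohort_factory):
        # boundary at 5.0 Mb falls inside the 4.8-5.2 Mb centromere
        cohort = cohort_factory(
            [("A", "1", 0, 5_000_000, 0.0), ("A", "1", 5_000_000, 10_000_000, 0.6)],
            b=tiny_build,
        )
        assert len(extract_breakpoints(cohort)) == 0

    def test_gap_assigns_midpoint(self, tiny_build, cohort_factory):
        cohort = cohort_factory(
            [("A", "1", 0, 1_000_000, 0.0), ("A", "1", 3_000_000, 4_000_000, 0.6)],
            b=tiny_build,
        )
        bps = extract_breakpoints(cohort)
        assert bps.iloc[0]["position"] == 2_000_000

    def test_matches_bruteforce_on_random_toys(self, tiny_build):
        """Fixed filter order agrees with a literal brute-force oracle."""
        zones = [tuple(z) for z in exclusion_zones(tiny_build).intervals("1")]
        rng = np.random.default_rng(11)
        for _ in range(300):
            df = random_segments(rng, 10_000_000)
            cohort = Cohort.from_frame(df, tiny_build)
            got = extract_breakpoints(cohort)
            want = breakpoints_bruteforce(
                list(zip(df["start"], df["end"], df["log2"])), zones
            )
            assert len(got) == len(want)
            if want:
                np.testing.assert_array_equal(
                    got["position"].to_numpy(), [p for p, _ in want]
                )
                np.testing.assert_allclose(
                    got["delta"].to_numpy(), [d for _, d in want]
                )

    def test_raising_delta_threshold_monotone(self, build):
        rng = np.random.default_rng(5)
        frames = [random_segments(rng, 120_000_000, n_max=20, sample=f"S{i}")
                  for i in range(5)]
        cohort = Cohort.from_frame(pd.concat(frames), build)
        counts = [len(extract_breakpoints(cohort, delta_thr=t))
                  for t in (0.2, 0.4, 0.6, 0.8)]
        assert counts == sorted(counts, reverse=True)


class TestCountPerBin:
    def test_assignment_and_conservation(self, tiny_build):
        grid = make_bins(tiny_build, 1_000_000)
        bps = pd.DataFrame({
            "sample": "A", "chrom": "1",
            "position": [100_000, 200_000, 1_500_000], "delta": 0.5,
        })
        counts = count_per_bin(bps, grid)
        assert counts[0] == 2 and counts[1] == 1 and counts[2:].sum() == 0

    def test_empty_input_gives_zero_counts(self, tiny_build):
        grid = make_bins(tiny_build, 1_000_000)
        bps = pd.DataFrame(columns=["sample", "chrom", "position", "delta"])
        assert count_per_bin(bps, grid).sum() == 0

    def test_total_conserved_for_many_random_positions(self, build, grid):
        rng = np.random.default_rng(3)
        bps = pd.DataFrame({
            "sample": "A",
            "chrom": rng.choice(build.chroms, size=10_000),
            "delta": 0.5,
        })
        bps["position"] = [
            rng.integers(0, build.length(c)) for c in bps["chrom"]
        ]
        assert count_per_bin(bps, grid).sum() == 10_000


class TestPermutation:
    def test_two_bin_symmetry(self):
        b = GenomeBuild("b", {"1": 2_000_000}, {}, telomere_size=0)
        grid = make_bins(b, 1_000_000)
        bps = pd.DataFrame(
            {"sample": "A", "chrom": "1", "position": [10], "delta": 0.5}
        )
        null = permute_breakpoints(bps, b, grid, n_perm=4000, seed=1)
        assert null.mean[0] == pytest.approx(0.5, abs=0.03)
        assert null.mean[1] == pytest.approx(0.5, abs=0.03)

    def test_per_chromosome_totals_conserved(self, build, grid):
        rng = np.random.default_rng(9)
        bps = pd.DataFrame({
            "sample": rng.choice(["A", "B"], 50),
            "chrom": rng.choice(build.chroms, 50),
            "delta": 0.5,
        })
        bps["position"] = [rng.integers(0, build.length(c)) for c in bps["chrom"]]
        null = permute_breakpoints(bps, build, grid, n_perm=50, seed=2,
                                   return_matrix=True)
        for chrom in build.chroms:
            sl = grid.chrom_slice(chrom)
            expected = (bps["chrom"] == chrom).sum()
            per_perm = null.matrix[:, sl].sum(axis=1)
            assert (per_perm == expected).all()

    def test_null_mean_matches_uniform_expectation(self, build, grid):
        """Per-chromosome null bin means approach N_chrom / n_bins_chrom."""
        rng = np.random.default_rng(4)
        n_bp = 600
        bps = pd.DataFrame({
            "sample": "A", "chrom": "1", "delta": 0.5,
            "position": rng.integers(0, build.length("1"), n_bp),
        })
        n_perm = 1000
        null = permute_breakpoints(bps, build, grid, n_perm=n_perm, seed=8)
        sl = grid.chrom_slice("1")
        means = null.mean[sl]
        # exclusion-aware expectation: zone bins get ~0, others slightly more
        zone_free = np.array([
            not (55_000_000 <= s < 65_000_000)
            and s >= 10_000 and e <= 120_000_000 - 10_000
            for s, e in zip(grid.df["start"][sl], grid.df["end"][sl])
        ])
        expected = n_bp / zone_free.sum()
        mc_sd = np.sqrt(expected / n_perm)
        inner = means[zone_free]
        assert np.all(np.abs(inner - expected) < max(4 * mc_sd, 0.05 * expected))

    def test_empty_chromosome_without_space_rejected(self):
        b = GenomeBuild("b", {"1": 15_000}, {"1": (0, 15_000)}, telomere_size=0)
        grid = make_bins(b, 10_000)
        bps = pd.DataFrame(
            {"sample": "A", "chrom": "1", "position": [5_000], "delta": 0.5}
        )
        with pytest.raises(ValueError, match="no allowed positions"):
            permute_breakpoints(bps, b, grid, n_perm=10, seed=0)


class TestHotspotTest:
    def _null(self, mean, n_bins, n_perm=1000):
        from cnascape.breakpoint_hotspots import PermutationNull

        return PermutationNull(
            mean=np.full(n_bins, float(mean)),
            sd=np.full(n_bins, np.sqrt(mean) if mean else 0.0),
            n_perm=n_perm,
        )

    def test_no_enrichment_large_p(self, tiny_build):
        grid = make_bins(tiny_build, 1_000_000)
        observed = np.full(grid.n_bins, 5)
        res = hotspot_test(observed, self._null(5.0, grid.n_bins), grid)
        assert (res["p_raw"] > 0.4).all()
        assert not res["is_hotspot"].any()

    def test_strong_enrichment_flagged_and_matches_bruteforce_tail(self):
        b = GenomeBuild("big", {"1": 2_800_000_000}, {}, telomere_size=0)
        grid = make_bins(b, 1_000_000)
        assert grid.n_bins == 2800
        observed = np.full(grid.n_bins, 5)
        observed[7] = 60
        res = hotspot_test(observed, self._null(5.0, grid.n_bins), grid)
        assert res["is_hotspot"][7]
        assert int(res["is_hotspot"].sum()) == 1
        want = poisson_upper_tail_bruteforce(60, 5.0)
        assert res["p_raw"][7] == pytest.approx(want, rel=1e-9)
        assert res["p_bonferroni"][7] == pytest.approx(min(1, want * 2800), rel=1e-9)
        assert res["p_bonferroni"][7] < 0.01

    def test_zero_null_mean_uses_floor(self, tiny_build):
        grid = make_bins(tiny_build, 1_000_000)
        observed = np.zeros(grid.n_bins, dtype=int)
        observed[0] = 3
        res = hotspot_test(observed, self._null(0.0, grid.n_bins, n_perm=100), grid)
        want = poisson_upper_tail_bruteforce(3, 1 / 100)
        assert res["p_raw"][0] == pytest.approx(want, rel=1e-6)
        assert (res["p_raw"][1:] == 1.0).all()

    def test_empirical_method_consistent_with_matrix(self, tiny_build):
        grid = make_bins(tiny_build, 1_000_000)
        rng = np.random.default_rng(0)
        bps = pd.DataFrame({
            "sample": "A", "chrom": "1", "delta": 0.5,
            "position": rng.integers(0, 10_000_000, 40),
        })
        null = permute_breakpoints(bps, tiny_build, grid, n_perm=200, seed=3,
                                   return_matrix=True)
        observed = count_per_bin(bps, grid)
        res = hotspot_test(observed, null, grid, method="empirical")
        ge = (null.matrix >= observed[None, :]).sum(axis=0)
        np.testing.assert_allclose(res["p_raw"], (ge + 1) / 201)


class TestRegionOverlap:
    def _hotspots(self, grid, flags):
        df = grid.df.copy()
        df["is_hotspot"] = flags
        return df

    def test_whole_genome_region_gives_fraction_one(self, tiny_build):
        grid = make_bins(tiny_build, 1_000_000)
        rs = RegionSet.from_intervals("R", [("1", 0, 10_000_000)], build=tiny_build)
        hs = self._hotspots(grid, [True] * grid.n_bins)
        count, frac = region_overlap(hs, rs)
        assert (count, frac) == (grid.n_bins, 1.0)

    def test_disjoint_region_gives_zero(self, tiny_build, build):
        grid = make_bins(tiny_build, 1_000_000)
        rs = RegionSet.from_intervals("R", [("2", 0, 1_000_000)])
        hs = self._hotspots(grid, [True] * grid.n_bins)
        count, frac = region_overlap(hs, rs)
        assert (count, frac) == (0, 0.0)

    def test_no_hotspots_reports_missing_fraction(self, tiny_build):
        grid = make_bins(tiny_build, 1_000_000)
        rs = RegionSet.from_intervals("R", [("1", 0, 1_000_000)], build=tiny_build)
        hs = self._hotspots(grid, [False] * grid.n_bins)
        count, frac = region_overlap(hs, rs)
        assert count == 0 and frac is None

    def test_single_bp_intersection_counts(self, tiny_build):
        grid = make_bins(tiny_build, 1_000_000)
        # overlaps last bp of bin 0 only
        rs = RegionSet.from_intervals("R", [("1", 999_999, 1_000_000)],
                                      build=tiny_build)
        flags = [False] * grid.n_bins
        flags[0] = flags[1] = True
        count, frac = region_overlap(self._hotspots(grid, flags), rs)
        assert count == 1 and frac == pytest.approx(0.5)
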