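import numpy as np
import pandas as pd
import pytest
from _oracles import bin_states_bruteforce

from cnascape.cna_calling import (
    arm_gain_loss_correlation,
    arm_frequencies,
    burden_summary,
    call_arm_events,
    call_states,
    frequency_profile,
    sample_bin_states,
)
from cnascape.genome_model import GenomeBuild, make_bins


class TestCallStates:
    @pytest.mark.parametrize(
        "log2,expected",
        [
            (0.25, "gain"),
            (-0.21, "loss"),
            (0.20, "neutral"),  # strict threshold
            (-0.20, "neutral"),
            (0.0, "neutral"),
        ],
    )
    def test_threshold_strictness(self, cohort_factory, log2, expected):
        cohort = cohort_factory([("A", "1", 0, 1_000_000, log2)])
        assert call_states(cohort)["state"].iloc[0] == expected

    def test_inverted_thresholds_rejected(self, cohort_factory):
        cohort = cohort_factory([("A", "1", 0, 1_000_000, 0.0)])
        with pytest.raises(ValueError, match="thresholds"):
            call_states(cohort, gain_thr=-0.2, loss_thr=0.2)

    def test_state_partition(self, cohort_factory):
        rng = np.random.default_rng(0)
        rows = [("A", "1", i * 10_000, (i + 1) * 10_000, v)
                for i, v in enumerate(rng.normal(0, 0.4, size=200))]
        calls = call_states(cohort_factory(rows))
        counts = calls["state"].value_counts()
        assert counts.sum() == 200
        assert (calls.loc[calls["state"] == "gain", "log2"] > 0.2).all()
        assert (calls.loc[calls["state"] == "loss", "log2"] < -0.2).all()


class TestBurden:
    def test_event_count_and_mean_size(self, cohort_factory, build):
        cohort = cohort_factory([
            ("A", "1", 0, 2_000_000, 0.5),
            ("A", "1", 2_000_000, 6_000_000, 0.5),
            ("A", "2", 0, 100_000_000, 0.0),
        ])
        b = burden_summary(call_states(cohort), build).iloc[0]
        assert b["n_events"] == 2
        assert b["mean_event_size"] == pytest.approx(3_000_000)
        assert b["fraction_genome_altered"] == pytest.approx(6e6 / 300e6)

    def test_all_neutral_sample_missing_mean(self, cohort_factory, build):
        cohort = cohort_factory([("A", "1", 0, 120_000_000, 0.0)])
        b = burden_summary(call_states(cohort), build).iloc[0]
        assert b["n_events"] == 0
        assert np.isnan(b["mean_event_size"])
        assert b["fraction_genome_altered"] == 0.0


class TestFrequencyProfile:
    def test_fraction_of_samples_with_covering_gain(self, cohort_factory, grid):
        rows = []
        for i in range(10):
            log2 = 0.5 if i < 4 else 0.0
            rows.append((f"S{i}", "1", 0, 1_000_000, log2))
            rows.append((f"S{i}", "1", 1_000_000, 120_000_000, 0.0))
        profile = frequency_profile(call_states(cohort_factory(rows)), grid)
        assert profile["gain_freq"].iloc[0] == pytest.approx(0.4)
        assert profile["loss_freq"].iloc[0] == 0.0
        assert profile["n_samples"].iloc[0] == 10

    def test_partial_coverage_below_majority_is_neutral(self, cohort_factory, grid):
        cohort = cohort_factory([
            ("A", "1", 0, 400_000, 0.6),  # 40% of first bin
            ("A", "1", 400_000, 120_000_000, 0.0),
        ])
        profile = frequency_profile(call_states(cohort), grid)
        assert profile["gain_freq"].iloc[0] == 0.0

    def test_frequency_bounds_invariant(self, cohort_factory, grid):
        rng = np.random.default_rng(1)
        rows = []
        for s in range(8):
            bounds = np.sort(rng.choice(np.arange(1, 120_000_000), 20, replace=False))
            bounds = np.r_[0, bounds, 120_000_000]
            for a, b in zip(bounds[:-1], bounds[1:]):
                rows.append((f"S{s}", "1", a, b, rng.normal(0, 0.3)))
        profile = frequency_profile(call_states(cohort_factory(rows)), grid)
        assert ((profile["gain_freq"] >= 0) & (profile["gain_freq"] <= 1)).all()
        assert ((profile["gain_freq"] + profile["loss_freq"]) <= 1 + 1e-12).all()

    def test_bin_states_match_per_bp_oracle(self):
        """Coverage-based bin assignment agrees with a literal per-bp scan."""
        chrom_len, width = 3_000_000, 250_000
        b = GenomeBuild("t", {"1": chrom_len}, {})
        grid = make_bins(b, width)
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = rng.integers(2, 7)
            cuts = np.sort(rng.choice(np.arange(1, chrom_len), n - 1, replace=False))
            bounds = np.r_[0, cuts, chrom_len]
            log2 = rng.choice([-0.5, -0.25, 0.0, 0.25, 0.5], size=n)
            segs = list(zip(bounds[:-1], bounds[1:], log2))
            df = pd.DataFrame(
                {"sample": "A", "chrom": "1", "start": bounds[:-1],
                 "end": bounds[1:], "log2": log2}
            )
            calls = df.assign(
                state=np.where(log2 > 0.2, "gain",
                               np.where(log2 < -0.2, "loss", "neutral"))
            )
            got = sample_bin_states(calls, grid)
            want = bin_states_bruteforce(segs, chrom_len, width)
            np.testing.assert_array_equal(got, want)


class TestArmEvents:
    def test_single_segment_covering_60pct_of_q(self, cohort_factory, build):
        # q arm of chr1: 65-120 Mb (55 Mb); 60% = 33 Mb
        cohort = cohort_factory([
            ("A", "1", 65_000_000, 98_000_000, 0.5),
            ("A", "1", 98_000_000, 120_000_000, 0.0),
        ])
        ev = call_arm_events(call_states(cohort), build)
        assert len(ev) == 1
        row = ev.iloc[0]
        assert (row["arm"], row["type"]) == ("1q", "gain")
        assert row["covered_fraction"] == pytest.approx(33 / 55)

    def test_exactly_half_is_not_an_event(self, cohort_factory, build):
        cohort = cohort_factory([
            ("A", "1", 65_000_000, 92_500_000, 0.5),  # exactly 50% of q
        ])
        assert len(call_arm_events(call_states(cohort), build)) == 0

    def test_adjacent_same_state_segments_merge(self, cohort_factory, build):
        # 30% + 25% of the q arm (55 Mb): 16.5 Mb + 13.75 Mb
        cohort = cohort_factory([
            ("A", "1", 65_000_000, 81_500_000, 0.4),
            ("A", "1", 81_500_000, 95_250_000, 0.6),
        ])
        ev = call_arm_events(call_states(cohort), build)
        assert len(ev) == 1
        assert ev.iloc[0]["covered_fraction"] == pytest.approx(0.55)
        # without merging, neither segment alone qualifies
        ev2 = call_arm_events(call_states(cohort), build, merge_adjacent=False)
        assert len(ev2) == 0

    def test_neutral_gap_breaks_run(self, cohort_factory, build):
        cohort = cohort_factory([
            ("A", "1", 65_000_000, 81_500_000, 0.4),
            ("A", "1", 81_500_000, 82_000_000, 0.0),
            ("A", "1", 82_000_000, 95_250_000, 0.6),
        ])
        assert len(call_arm_events(call_states(cohort), build)) == 0

    def test_raising_gain_threshold_never_adds_events(self, cohort_factory, build):
        rng = np.random.default_rng(7)
        rows = []
        for s in range(10):
            bounds = np.sort(rng.choice(np.arange(1, 120_000_000), 10, replace=False))
            bounds = np.r_[0, bounds, 120_000_000]
            for a, b in zip(bounds[:-1], bounds[1:]):
                rows.append((f"S{s}", "1", a, b, rng.normal(0.1, 0.3)))
        cohort = cohort_factory(rows)
        counts = []
        for thr in (0.1, 0.2, 0.3, 0.4):
            ev = call_arm_events(call_states(cohort, gain_thr=thr), build)
            counts.append((ev["type"] == "gain").sum())
        assert counts == sorted(counts, reverse=True)


class TestArmCorrelation:
    def _events_from_freqs(self, build, gain, loss, n=100):
        """Construct arm events realizing given per-arm frequencies."""
        rows = []
        for arm, gf, lf in zip(build.arm_labels[:len(gain)], gain, loss):
            for i in range(int(round(gf * n))):
                rows.append((f"S{i}", arm, "gain", 0.8))
            for i in range(int(round(lf * n))):
                rows.append((f"S{i}", arm, "loss", 0.8))
        return pd.DataFrame(rows, columns=["sample", "arm", "type", "covered_fraction"])

    def test_affine_anticorrelation_is_exactly_minus_one(self, build):
        gain = (0.8, 0.6, 0.1, 0.0)
        loss = tuple(0.8 - g for g in gain)
        ev = self._events_from_freqs(build, gain, loss)
        # restrict to the 4 arms carrying events
        freqs = arm_frequencies(ev, 100, build).iloc[:4]
        r = np.corrcoef(freqs["gain_freq"], freqs["loss_freq"])[0, 1]
        assert abs(r + 1) < 1e-12
        r_all, p = arm_gain_loss_correlation(ev[ev["arm"].isin(freqs["arm"])],
                                             100, build)
        assert r_all < 0

    def test_identical_vectors_give_plus_one(self, build):
        ev = self._events_from_freqs(build, (0.5, 0.3, 0.1), (0.5, 0.3, 0.1))
        freqs = arm_frequencies(ev, 100, build).iloc[:3]
        r = np.corrcoef(freqs["gain_freq"], freqs["loss_freq"])[0, 1]
        assert r == pytest.approx(1.0)

    def test_zero_variance_reported_missing(self, build):
        ev = pd.DataFrame(columns=["sample", "arm", "type", "covered_fraction"])
        with pytest.warns(UserWarning, match="zero variance"):
            r, p = arm_gain_loss_correlation(ev, 10, build)
        assert np.isnan(r) and np.isnan(p)

    def test_too_few_arms_rejected(self):
        b = GenomeBuild("b", {"1": 10_000_000}, {"1": (4_000_000, 6_000_000)})
        ev = pd.DataFrame(columns=["sample", "arm", "type", "covered_fraction"])
        with pytest.raises(ValueError, match="3 arms"):
            arm_gain_loss_correlation(ev, 10, b)
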