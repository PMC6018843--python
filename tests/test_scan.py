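"""Variant filtering, sliding windows and candidate-region calling."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fuzzmap.errors import GridMismatchError, InvalidInputError
from fuzzmap.scan import (
    CandidateRegion,
    VariantFilterConfig,
    WindowConfig,
    WindowTrack,
    call_array_candidates,
    call_candidate_regions,
    filter_pooled_variants,
    intersect_region_sets,
    pool_frequency_from_genotypes,
    pool_frequency_from_reads,
    sliding_window_frequency,
)


def brute_force_windows(positions, freqs, chrom_length, cfg):
    """Independent oracle: test every marker against every window interval."""
    starts = list(range(0, chrom_length, cfg.step))
    rows = []
    for start in starts:
        members = [
            f
            for p, f in zip(positions, freqs)
            if start <= p - 1 < start + cfg.window_length and not math.isnan(f)
        ]
        mean = (
            sum(members) / len(members)
            if len(members) >= cfg.min_snps_per_window
            else float("nan")
        )
        rows.append((start, min(start + cfg.window_length, chrom_length), mean, len(members)))
    return rows


def make_track(chrom, values, window=1_000_000, step=500_000, chrom_length=None):
    starts = np.arange(0, step * len(values), step)
    ends = np.minimum(starts + window, chrom_length or starts[-1] + window)
    freqs = np.asarray(values, dtype=float)
    return WindowTrack(
        chromosome=chrom,
        window_length=window,
        step=step,
        data=pd.DataFrame(
            {
                "start": starts,
                "end": ends,
                "freq": freqs,
                "n_snps": np.where(np.isnan(freqs), 0, 5),
            }
        ),
    )


class TestFilter:
    def test_boundary_toy_table(self):
        """Six records spanning every threshold boundary; three survive."""
        counts = pd.DataFrame(
            {
                "marker": [f"m{i}" for i in range(6)],
                "donor_reads": [5, 3, 8, 2, 10, 7],
                "total_reads": [9, 10, 20, 10, 10, 20],
            }
        )
        # m0: coverage 9 < 10            -> out
        # m1: freq 0.30 < 0.35           -> out
        # m2: 8/20 = 0.40, cov 20        -> in
        # m3: 2 variant reads < 3        -> out
        # m4: 10/10 = 1.0                -> in
        # m5: 7/20 = 0.35 exactly        -> in (inclusive boundary)
        kept, report = filter_pooled_variants(counts, VariantFilterConfig())
        assert list(kept["marker"]) == ["m2", "m4", "m5"]
        assert report.n_input == 6 and report.n_retained == 3
        assert report.n_fail_coverage == 1

    def test_exact_boundaries_are_inclusive(self):
        counts = pd.DataFrame({"donor_reads": [3], "total_reads": [10]})
        cfg = VariantFilterConfig(min_coverage=10, min_variant_reads=3,
                                  min_variant_frequency=0.30)
        kept, _ = filter_pooled_variants(counts, cfg)
        assert len(kept) == 1

    def test_invalid_counts_rejected(self):
        with pytest.raises(InvalidInputError):
            filter_pooled_variants(
                pd.DataFrame({"donor_reads": [5], "total_reads": [4]})
            )


class TestPoolFrequency:
    def test_genotype_code_mean(self):
        assert pool_frequency_from_genotypes([1, 1, 1]) == 1.0
        assert pool_frequency_from_genotypes([1, 0.5, 0, 0.5]) == 0.5

    def test_missing_codes_excluded(self):
        assert pool_frequency_from_genotypes([1, float("nan"), 0]) == 0.5

    def test_all_missing_is_undefined(self):
        assert math.isnan(pool_frequency_from_genotypes([float("nan")] * 3))

    @pytest.mark.parametrize(
        "donor, total, expected", [(10, 20, 0.5), (20, 20, 1.0), (0, 15, 0.0)]
    )
    def test_read_frequency(self, donor, total, expected):
        assert pool_frequency_from_reads(donor, total) == expected

    def test_zero_coverage_undefined(self):
        assert math.isnan(pool_frequency_from_reads(0, 0))


class TestSlidingWindow:
    def test_constant_input_gives_constant_windows(self):
        track = sliding_window_frequency(
            positions=[250_000, 750_000, 1_250_000, 1_750_000],
            frequencies=[0.8] * 4,
            chrom_length=2_000_000,
        )
        defined = track.data.dropna(subset=["freq"])
        assert len(defined) > 0
        assert np.allclose(defined["freq"], 0.8)

    def test_single_marker_window_membership(self):
        """A marker at 1.2 Mb on a 2 Mb chromosome hits windows starting at
        500 kb and 1 Mb only (1 Mb windows, 500 kb step)."""
        track = sliding_window_frequency([1_200_000], [0.9], 2_000_000)
        data = track.data
        assert list(data["start"]) == [0, 500_000, 1_000_000, 1_500_000]
        defined = data.loc[data["n_snps"] > 0, "start"].tolist()
        assert defined == [500_000, 1_000_000]

    def test_empty_chromosome_all_undefined(self):
        track = sliding_window_frequency([], [], 2_000_000)
        assert (track.data["n_snps"] == 0).all()
        assert track.data["freq"].isna().all()

    def test_marker_beyond_chromosome_named(self):
        with pytest.raises(InvalidInputError, match="mX"):
            sliding_window_frequency(
                [3_000_000], [0.5], 2_000_000, marker_ids=["mX"]
            )

    def test_window_mean_bounded_by_member_range(self, rng):
        pos = rng.integers(1, 5_000_001, 40)
        freq = rng.random(40)
        track = sliding_window_frequency(pos, freq, 5_000_000)
        for start, f, n in zip(track.data["start"], track.data["freq"], track.data["n_snps"]):
            if n == 0:
                continue
            members = freq[(pos - 1 >= start) & (pos - 1 < start + 1_000_000)]
            assert members.min() - 1e-12 <= f <= members.max() + 1e-12

    def test_invariant_to_marker_order(self, rng):
        pos = rng.integers(1, 5_000_001, 30)
        freq = rng.random(30)
        perm = rng.permutation(30)
        a = sliding_window_frequency(pos, freq, 5_000_000)
        b = sliding_window_frequency(pos[perm], freq[perm], 5_000_000)
        pd.testing.assert_frame_equal(a.data, b.data)

    @given(
        chrom_length=st.integers(10, 400),
        window=st.integers(2, 50),
        step_frac=st.floats(0.2, 1.0),
        markers=st.lists(
            st.tuples(st.integers(1, 400), st.floats(0, 1)),
            min_size=0,
            max_size=30,
        ),
    )
    @settings(max_examples=100, derandomize=True)
    def test_agrees_with_brute_force_oracle(self, chrom_length, window, step_frac, markers):
        """Window membership and means match a per-window brute-force scan."""
        step = max(1, int(window * step_frac))
        cfg = WindowConfig(window_length=window, step=step)
        markers = [(min(p, chrom_length), f) for p, f in markers]
        pos = [p for p, _ in markers]
        # drop duplicate positions (marker maps are unique per position)
        seen, upos, ufreq = set(), [], []
        for p, f in markers:
            if p not in seen:
                seen.add(p)
                upos.append(p)
                ufreq.append(f)
        track = sliding_window_frequency(upos, ufreq, chrom_length, cfg)
        expected = brute_force_windows(upos, ufreq, chrom_length, cfg)
        assert len(track.data) == len(expected)
        for (_, row), (start, end, mean, n) in zip(track.data.iterrows(), expected):
            assert row["start"] == start and row["end"] == end
            assert row["n_snps"] == n
            if math.isnan(mean):
                assert math.isnan(row["freq"])
            else:
                assert row["freq"] == pytest.approx(mean, abs=1e-12)


class TestRegionCalling:
    def test_consecutive_qualifying_windows_merge(self):
        rec = make_track("c1", [0.98, 0.98, 0.98, 0.98], chrom_length=3_000_000)
        seg = make_track("c1", [0.49, 0.49, 0.49, 0.49], chrom_length=3_000_000)
        regions = call_candidate_regions(rec, seg)
        assert len(regions) == 1
        r = regions[0]
        assert (r.start, r.end, r.n_windows, r.evidence) == (0, 2_500_000, 4, "MBS")
        assert r.mean_freq[0] == pytest.approx(0.98)

    def test_fixation_in_segregating_pool_rejected(self):
        """Fixed donor alleles in the segregating pool (~0.95) are not ~0.5."""
        rec = make_track("c1", [0.98, 0.98, 0.98])
        seg = make_track("c1", [0.95, 0.95, 0.95])
        assert call_candidate_regions(rec, seg) == []

    def test_no_signal_no_region(self):
        rec = make_track("c1", [0.5, 0.5, 0.5])
        seg = make_track("c1", [0.5, 0.5, 0.5])
        assert call_candidate_regions(rec, seg) == []

    def test_short_runs_below_min_consecutive_dropped(self):
        rec = make_track("c1", [0.98, 0.2, 0.98, 0.98])
        seg = make_track("c1", [0.5, 0.5, 0.5, 0.5])
        regions = call_candidate_regions(rec, seg, min_consecutive=2)
        assert len(regions) == 1 and regions[0].start == 1_000_000

    def test_undefined_windows_break_runs(self):
        rec = make_track("c1", [0.98, float("nan"), 0.98])
        seg = make_track("c1", [0.5, 0.5, 0.5])
        assert call_candidate_regions(rec, seg, min_consecutive=2) == []

    def test_raising_threshold_never_enlarges_regions(self, rng):
        values_rec = rng.random(30) * 0.3 + 0.7
        values_seg = rng.random(30) * 0.6 + 0.2
        rec = make_track("c1", values_rec)
        seg = make_track("c1", values_seg)
        low = call_candidate_regions(rec, seg, high_threshold=0.8)
        high = call_candidate_regions(rec, seg, high_threshold=0.9)
        covered_low = set()
        for r in low:
            covered_low.update(range(r.start, r.end, 500_000))
        for r in high:
            for s in range(r.start, r.end, 500_000):
                assert s in covered_low

    def test_mismatched_grids_rejected(self):
        rec = make_track("c1", [0.9, 0.9])
        seg = make_track("c2", [0.5, 0.5])
        with pytest.raises(GridMismatchError):
            call_candidate_regions(rec, seg)

    @pytest.mark.parametrize(
        "reduced, normal, expect_region",
        [(0.95, 0.2, True), (0.95, 0.6, False), (0.7, 0.2, False)],
    )
    def test_array_pool_criteria(self, reduced, normal, expect_region):
        red = make_track("c1", [reduced] * 3)
        nor = make_track("c1", [normal] * 3)
        regions = call_array_candidates(red, nor)
        assert bool(regions) is expect_region
        if regions:
            assert regions[0].evidence == "array"


class TestIntersect:
    def r(self, chrom, start, end, evidence="MBS"):
        return CandidateRegion(chrom, start, end, (0.9,), 2, evidence)

    def test_overlap_yields_both(self):
        out = intersect_region_sets(
            [self.r("D12", 10_000_000, 20_000_000)],
            [self.r("D12", 15_000_000, 30_000_000, "array")],
        )
        assert len(out) == 1
        assert (out[0].start, out[0].end, out[0].evidence) == (
            15_000_000,
            20_000_000,
            "both",
        )

    def test_disjoint_sets_keep_single_source_labels(self):
        out = intersect_region_sets(
            [self.r("c1", 0, 1_000_000)], [self.r("c2", 0, 1_000_000, "array")]
        )
        assert {r.evidence for r in out} == {"MBS", "array"}

    def test_identical_sets_all_both(self):
        a = [self.r("c1", 0, 1_000_000), self.r("c2", 5_000_000, 6_000_000)]
        b = [self.r("c1", 0, 1_000_000, "array"), self.r("c2", 5_000_000, 6_000_000, "array")]
        out = intersect_region_sets(a, b)
        assert all(r.evidence == "both" for r in out)
        assert [(r.chromosome, r.start, r.end) for r in out] == [
            ("c1", 0, 1_000_000),
            ("c2", 5_000_000, 6_000_000),
        ]
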