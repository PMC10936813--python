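"""Hotspot calling: smoothing, thresholding, merging, strengths, overlap."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dsbmap.hotspots import (call_hotspots, combine_templates,
                             estimate_background, exclude_region,
                             hann_smooth, hann_window, hotspot_strengths,
                             merge_intervals, overlap_templates)
from dsbmap.maps import pool_fullmaps

from conftest import make_fullmap, uniform_fullmap


def brute_force_call(smoothed, counts, cutoff, min_len, min_reads, merge_gap):
    """Naive reference: enumerate positions, threshold, merge, filter."""
    above = [i + 1 for i, v in enumerate(smoothed) if v >= cutoff]
    runs = []
    for p in above:
        if runs and p == runs[-1][1] + 1:
            runs[-1][1] = p
        else:
            runs.append([p, p])
    merged = []
    for s, e in runs:
        if merged and s - merged[-1][1] - 1 < merge_gap:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    out = []
    for s, e in merged:
        if e - s + 1 < min_len:
            continue
        if sum(counts[s - 1:e]) < min_reads:
            continue
        out.append((s, e))
    return out


def _map_from_counts(counts, total=1_000_000, chrom="chrI"):
    pos = np.nonzero(counts)[0] + 1
    recs = [(chrom, int(p), int(counts[p - 1]), 0) for p in pos]
    return make_fullmap(recs, total, chrom_lengths={chrom: len(counts)})


class TestHannSmoothing:
    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            hann_window(200)

    def test_constant_signal_preserved_in_interior(self):
        sig = np.full(1000, 3.7)
        sm = hann_smooth(sig, 201)
        np.testing.assert_allclose(sm[200:-200], 3.7, rtol=1e-12)

    def test_impulse_peak_is_mass_over_half_window(self):
        # raw Hann-201 weights sum to (201-1)/2 = 100
        sig = np.zeros(501)
        sig[250] = 5.0
        sm = hann_smooth(sig, 201)
        assert sm[250] == pytest.approx(5.0 / 100.0)

    @given(st.integers(0, 2**32 - 1))
    def test_total_signal_conserved_on_padded_domain(self, seed):
        rng = np.random.default_rng(seed)
        sig = rng.exponential(1.0, size=400) * rng.integers(0, 2, size=400)
        sm = hann_smooth(sig, 201, full=True)
        assert sm.sum() == pytest.approx(sig.sum(), rel=1e-9)


class TestCalling:
    CUT = 0.193

    def _call(self, smoothed, counts, **kw):
        fm = _map_from_counts(counts)
        args = dict(cutoff=self.CUT, min_len=25, min_reads=25, merge_gap=200)
        args.update(kw)
        return call_hotspots({"chrI": np.asarray(smoothed, float)}, fm, **args)

    def test_single_supra_cutoff_run_called(self):
        smoothed = np.zeros(1000)
        smoothed[100:130] = 0.5            # 30 bp run
        counts = np.zeros(1000, int)
        counts[100:130] = 2                # 60 reads
        t = self._call(smoothed, counts)
        assert len(t) == 1
        assert (t.iloc[0]["start"], t.iloc[0]["end"]) == (101, 130)

    def test_runs_separated_by_150bp_merge(self):
        smoothed = np.zeros(1000)
        smoothed[100:130] = 0.5
        smoothed[280:310] = 0.5            # gap = 150 < 200
        counts = np.zeros(1000, int)
        counts[100:130] = 2
        counts[280:310] = 2
        t = self._call(smoothed, counts)
        assert len(t) == 1
        assert (t.iloc[0]["start"], t.iloc[0]["end"]) == (101, 310)

    def test_gap_of_exactly_200bp_does_not_merge(self):
        smoothed = np.zeros(1000)
        smoothed[100:130] = 0.5
        smoothed[330:360] = 0.5            # gap exactly 200
        counts = np.ones(1000, int) * 2
        t = self._call(smoothed, counts)
        assert len(t) == 2

    def test_short_run_fails_length_minimum(self):
        smoothed = np.zeros(1000)
        smoothed[100:120] = 0.5            # 20 bp < 25 bp
        counts = np.ones(1000, int) * 5
        assert len(self._call(smoothed, counts)) == 0

    def test_sparse_reads_fail_mass_minimum(self):
        smoothed = np.zeros(1000)
        smoothed[100:140] = 0.5
        counts = np.zeros(1000, int)
        counts[100:140:2] = 1              # 20 reads < 25
        assert len(self._call(smoothed, counts)) == 0

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            self._call(np.zeros(10), np.zeros(10, int), cutoff=-1.0)

    def test_equivalent_to_brute_force_on_random_profiles(self):
        # mixed peaks + noise; exact interval agreement with the naive path
        rng = np.random.default_rng(2024)
        for _ in range(100):
            n = 2000
            smoothed = rng.exponential(0.05, n)
            for _ in range(rng.integers(1, 6)):
                c = rng.integers(50, n - 50)
                w = rng.integers(5, 120)
                smoothed[max(0, c - w):c + w] += rng.uniform(0.1, 1.0)
            counts = rng.poisson(1.0, n)
            got = call_hotspots({"chrI": smoothed}, _map_from_counts(counts),
                                cutoff=self.CUT, min_len=25, min_reads=25,
                                merge_gap=200)
            expect = brute_force_call(smoothed, counts, self.CUT, 25, 25, 200)
            assert [tuple(r) for r in got[["start", "end"]].to_numpy()] == expect


class TestTemplates:
    def test_union_merges_overlaps(self):
        t = pd.DataFrame({"chrom": ["chrI", "chrI"], "start": [100, 150],
                          "end": [200, 300]})
        m = merge_intervals(t)
        assert len(m) == 1
        assert (m.iloc[0]["start"], m.iloc[0]["end"]) == (100, 300)

    def test_combine_disjoint_is_concatenation(self):
        a = pd.DataFrame({"chrom": ["chrI"], "start": [100], "end": [200]})
        b = pd.DataFrame({"chrom": ["chrI"], "start": [500], "end": [600]})
        c = combine_templates([a, b], ["x", "y"])
        assert len(c) == 2
        assert c["in_x"].tolist() == [True, False]
        assert c["in_y"].tolist() == [False, True]

    def test_combine_idempotent(self):
        t = pd.DataFrame({"chrom": ["chrI", "chrII"], "start": [10, 40],
                          "end": [20, 80]})
        once = combine_templates([t])
        twice = combine_templates([once[["chrom", "start", "end"]]])
        pd.testing.assert_frame_equal(once[["chrom", "start", "end"]],
                                      twice[["chrom", "start", "end"]])

    def test_exclude_region_counts_removals(self):
        t = pd.DataFrame({"chrom": "chrXII",
                          "start": np.arange(20) * 1000 + 1,
                          "end": np.arange(20) * 1000 + 400})
        kept, removed = exclude_region(t, ("chrXII", 2000, 4500))
        assert removed == 3 and len(kept) == 17

    def test_exclude_no_overlap_unchanged(self):
        t = pd.DataFrame({"chrom": ["chrI"], "start": [100], "end": [200]})
        kept, removed = exclude_region(t, ("chrI", 500, 900))
        assert removed == 0 and len(kept) == 1


class TestBackground:
    def test_uniform_density_recovered_exactly(self):
        fm = uniform_fullmap(length=60_000, count_per_bp=2,
                             total_reads=1_000_000)
        orfs = pd.DataFrame({"chrom": ["chrI"], "start": [1000],
                             "end": [51_000]})
        est = estimate_background(fm, orfs, min_orf_len=5500, n_orfs=1)
        assert est == pytest.approx(2.0, rel=1e-12)

    def test_zero_signal_gives_zero(self):
        fm = make_fullmap([("chrI", 100, 1, 0)], 1_000_000,
                          chrom_lengths={"chrI": 50_000})
        orfs = pd.DataFrame({"chrom": ["chrI"], "start": [10_000],
                             "end": [20_000]})
        assert estimate_background(fm, orfs) == 0.0

    def test_too_few_orfs_warns(self):
        fm = uniform_fullmap()
        orfs = pd.DataFrame({"chrom": ["chrI"], "start": [1000],
                             "end": [10_000]})
        with pytest.warns(UserWarning, match="using all"):
            estimate_background(fm, orfs, n_orfs=47)

    def test_no_qualifying_orfs_rejected(self):
        fm = uniform_fullmap()
        orfs = pd.DataFrame({"chrom": ["chrI"], "start": [100], "end": [200]})
        with pytest.raises(ValueError):
            estimate_background(fm, orfs)


class TestStrengths:
    def test_single_hotspot_takes_the_whole_million(self):
        fm = uniform_fullmap(length=1000, count_per_bp=1, total_reads=1000)
        t = pd.DataFrame({"chrom": ["chrI"], "start": [100], "end": [200]})
        out = hotspot_strengths(fm, t, background=0.0)
        assert out["NormHpM"].iloc[0] == pytest.approx(1e6)

    def test_three_to_one_split(self):
        recs = ([("chrI", p, 3, 0) for p in range(100, 110)]
                + [("chrI", p, 1, 0) for p in range(500, 510)])
        fm = make_fullmap(recs, 1_000_000, chrom_lengths={"chrI": 1000})
        t = pd.DataFrame({"chrom": ["chrI", "chrI"], "start": [100, 500],
                          "end": [109, 509]})
        out = hotspot_strengths(fm, t, background=0.0)
        assert out["NormHpM"].tolist() == pytest.approx([750_000, 250_000])

    def test_negative_corrected_floored_and_flagged(self):
        recs = ([("chrI", p, 10, 0) for p in range(100, 110)]
                + [("chrI", 500, 1, 0)])
        fm = make_fullmap(recs, 1_000_000, chrom_lengths={"chrI": 1000})
        t = pd.DataFrame({"chrom": ["chrI", "chrI"], "start": [100, 480],
                          "end": [109, 520]})
        out = hotspot_strengths(fm, t, background=0.5)
        assert out.loc[1, "corrected"] == 0.0
        assert out.loc[1, "floored"]
        assert out["NormHpM"].sum() == pytest.approx(1e6, rel=1e-12)

    def test_norm_sums_to_one_million_after_exclusion(self):
        rng = np.random.default_rng(5)
        recs = [("chrI", int(p), int(c), 0) for p, c in
                zip(rng.choice(50_000, 300, replace=False),
                    rng.integers(1, 20, 300))]
        fm = make_fullmap(recs, 1_000_000, chrom_lengths={"chrI": 50_000})
        t = pd.DataFrame({"chrom": "chrI", "start": np.arange(10) * 5000 + 1,
                          "end": np.arange(10) * 5000 + 2000})
        kept, _ = exclude_region(t, ("chrI", 1, 6000))
        out = hotspot_strengths(fm, kept, background=0.001)
        assert out["NormHpM"].sum() == pytest.approx(1e6, rel=1e-9)

    def test_empty_template_rejected(self):
        fm = uniform_fullmap()
        with pytest.raises(ValueError, match="empty"):
            hotspot_strengths(fm, pd.DataFrame(columns=["chrom", "start",
                                                        "end"]))


class TestOverlap:
    def test_identical_templates_fully_shared(self):
        t = pd.DataFrame({"chrom": ["chrI", "chrI"], "start": [10, 50],
                          "end": [20, 80]})
        s = overlap_templates(t, t)
        assert s["shared_a"] == 2 and s["a_only"] == 0 and s["b_only"] == 0

    def test_disjoint_templates_share_nothing(self):
        a = pd.DataFrame({"chrom": ["chrI"], "start": [10], "end": [20]})
        b = pd.DataFrame({"chrom": ["chrI"], "start": [100], "end": [200]})
        s = overlap_templates(a, b)
        assert s["shared_a"] == 0 and s["a_only"] == 1 and s["b_only"] == 1

    def test_constructed_seven_of_ten_overlap(self):
        a = pd.DataFrame({"chrom": "chrI",
                          "start": np.arange(10) * 1000 + 1,
                          "end": np.arange(10) * 1000 + 300})
        b_rows = [(i * 1000 + 200, i * 1000 + 500) for i in range(7)]
        b_rows += [(50_000 + i * 1000, 50_000 + i * 1000 + 300)
                   for i in range(5)]
        b = pd.DataFrame({"chrom": "chrI",
                          "start": [r[0] for r in b_rows],
                          "end": [r[1] for r in b_rows]})
        s = overlap_templates(a, b)
        assert s["shared_a"] == 7 and s["shared_b"] == 7
        assert s["a_only"] == 3 and s["b_only"] == 5


class TestPooling:
    def test_two_library_mean(self):
        a = make_fullmap([("chrI", 100, 2, 0)], 1_000_000)
        b = make_fullmap([("chrI", 100, 4, 0)], 1_000_000)
        pooled = pool_fullmaps([a, b])
        assert pooled.total_reads == 1e6
        assert pooled.df.iloc[0]["Watson"] == pytest.approx(3.0)

    def test_pooling_is_idempotent(self):
        a = make_fullmap([("chrI", 100, 2, 0), ("chrI", 300, 6, 2)], 2e6)
        b = make_fullmap([("chrI", 100, 4, 0)], 1e6)
        once = pool_fullmaps([a, b])
        twice = pool_fullmaps([once])
        pd.testing.assert_frame_equal(once.df, twice.df)

    def test_normalisation_respects_library_totals(self):
        a = make_fullmap([("chrI", 100, 2, 0)], 2_000_000)   # 1 HpM
        b = make_fullmap([("chrI", 100, 3, 0)], 1_000_000)   # 3 HpM
        pooled = pool_fullmaps([a, b])
        assert pooled.df.iloc[0]["Watson"] == pytest.approx(2.0)
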