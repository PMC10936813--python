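"""Comparative maps: correlations, ratios, loess smoothing, binning."""

import math

import numpy as np
import pandas as pd
import pytest

from dsbmap.compare import (bin_ratios_50kb, correlate_fc_with_timing,
                            hotspot_correlation, loess_smooth,
                            log2_ratio_per_hotspot, prepare_timing_track,
                            smooth_ratio)


def _table(norms, chrom="chrI", spacing=2000):
    n = len(norms)
    start = np.arange(n) * spacing + 1000
    return pd.DataFrame({"chrom": chrom, "start": start, "end": start + 200,
                         "NormHpM": np.asarray(norms, float)})


def brute_force_loess(x, y, span, eval_x):
    """Independent oracle: per-point tricube WLS via lstsq."""
    n = len(x)
    k = min(n, max(2, math.ceil(span * n)))
    out = []
    for x0 in eval_x:
        d = np.abs(x - x0)
        order = np.argsort(d, kind="stable")[:k]
        dmax = d[order].max()
        if dmax == 0:
            out.append(y[order].mean())
            continue
        w = np.clip(1 - (d[order] / dmax) ** 3, 0, None) ** 3
        if w.sum() <= 0 or np.unique(x[order][w > 0]).size < 2:
            out.append(np.average(y[order], weights=w if w.sum() > 0
                                  else np.ones_like(w)))
            continue
        A = np.c_[np.ones(k), x[order]]
        W = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(A * W[:, None], y[order] * W, rcond=None)
        out.append(coef[0] + coef[1] * x0)
    return np.array(out)


class TestCorrelation:
    def test_self_correlation_is_one(self):
        t = _table([100, 300, 600, 200])
        res = hotspot_correlation(t, t)
        assert res["r"] == pytest.approx(1.0)

    def test_permuted_large_table_near_zero(self):
        rng = np.random.default_rng(8)
        vals = rng.lognormal(0, 1, 500)
        a = _table(vals)
        b = _table(rng.permutation(vals))
        res = hotspot_correlation(a, b)
        assert abs(res["r"]) < 0.15

    def test_zero_flagged_pairs_excluded_and_counted(self):
        a = _table([100, 0, 300, 400])
        b = _table([200, 50, 600, 100])
        res = hotspot_correlation(a, b, method="spearman")
        assert res["n_excluded"] == 1 and res["n"] == 3

    def test_too_few_pairs_rejected(self):
        t = _table([1, 2])
        with pytest.raises(ValueError):
            hotspot_correlation(t, t)


class TestLog2Ratios:
    def test_identical_tables_all_zero(self):
        t = _table([100, 300, 600])
        out = log2_ratio_per_hotspot(t, t)
        np.testing.assert_allclose(out["log2fc"], 0.0)

    def test_hand_checked_three_hotspot_fixture(self):
        a = _table([400, 200, 400])
        b = _table([200, 400, 400])
        out = log2_ratio_per_hotspot(a, b)
        np.testing.assert_allclose(out["log2fc"], [1.0, -1.0, 0.0])

    def test_swap_negates(self):
        rng = np.random.default_rng(1)
        a = _table(rng.lognormal(0, 1, 50))
        b = _table(rng.lognormal(0, 1, 50))
        ab = log2_ratio_per_hotspot(a, b)["log2fc"]
        ba = log2_ratio_per_hotspot(b, a)["log2fc"]
        np.testing.assert_allclose(ab, -ba)

    def test_zero_side_flagged_no_pseudocount(self):
        a = _table([100, 0, 300])
        b = _table([100, 50, 300])
        out = log2_ratio_per_hotspot(a, b)
        assert out["excluded"].tolist() == [False, True, False]
        assert np.isnan(out.loc[1, "log2fc"])


class TestLoess:
    def test_constant_reproduced(self):
        x = np.arange(50.0)
        out = loess_smooth(x, np.full(50, 2.5), span=0.3)
        np.testing.assert_allclose(out, 2.5, rtol=1e-12)

    def test_linear_exact(self):
        x = np.arange(60.0)
        y = 0.5 * x - 3.0
        out = loess_smooth(x, y, span=0.4)
        np.testing.assert_allclose(out, y, atol=1e-9)

    def test_step_input_monotone_and_matches_oracle(self):
        rng = np.random.default_rng(3)
        x = np.sort(rng.uniform(0, 100, 200))
        y = (x > 50).astype(float)
        got = loess_smooth(x, y, span=0.25)
        expect = brute_force_loess(x, y, 0.25, x)
        np.testing.assert_allclose(got, expect, atol=1e-8)
        assert (np.diff(got) > -1e-9).all()

    def test_random_signal_matches_oracle_everywhere(self):
        rng = np.random.default_rng(9)
        x = np.sort(rng.uniform(0, 1000, 300))
        y = np.sin(x / 40) + rng.normal(0, 0.3, 300)
        got = loess_smooth(x, y, span=0.15)
        expect = brute_force_loess(x, y, 0.15, x)
        np.testing.assert_allclose(got, expect, atol=1e-8)

    def test_span_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            loess_smooth(np.arange(5.0), np.arange(5.0), span=1.5)

    def test_sparse_chromosome_passthrough_flagged(self):
        ratios = log2_ratio_per_hotspot(_table([1, 2, 3]), _table([1, 2, 3]))
        out = smooth_ratio(ratios, span=0.5, min_points=5)
        assert not out["smoothed_flag"].any()
        np.testing.assert_allclose(out["smoothed"], out["log2fc"])


class TestBinning:
    def test_small_chromosome_bin_layout(self):
        # 120 kb chromosome, centromere at 60 kb: two partial-capable bins
        # on each side of the anchor
        a = _table([100.0], spacing=1)
        binned = bin_ratios_50kb(a, a, {"chrI": 60_000}, {"chrI": 120_000})
        assert binned["bin"].tolist() == [-2, -1, 0, 1]
        assert binned.iloc[0]["start"] == 1          # clipped partial bin
        assert binned.iloc[-1]["end"] == 120_000

    def test_equal_tables_give_zero_everywhere(self):
        rng = np.random.default_rng(4)
        t = _table(rng.lognormal(0, 1, 40))
        binned = bin_ratios_50kb(t, t, {"chrI": 40_000}, {"chrI": 100_000})
        defined = binned[binned["defined"]]
        np.testing.assert_allclose(defined["log2fc"], 0.0)

    def test_four_to_one_mass_gives_two(self):
        a = _table([400, 400])
        b = _table([100, 100])
        binned = bin_ratios_50kb(a, b, {"chrI": 30_000}, {"chrI": 60_000})
        d = binned[binned["defined"]]
        assert len(d) == 1 and d.iloc[0]["log2fc"] == pytest.approx(2.0)

    def test_mass_accounting_per_chromosome(self):
        rng = np.random.default_rng(11)
        vals_a = rng.lognormal(0, 1, 200)
        vals_b = rng.lognormal(0, 1, 200)
        a, b = _table(vals_a, spacing=900), _table(vals_b, spacing=900)
        binned = bin_ratios_50kb(a, b, {"chrI": 77_000}, {"chrI": 200_000})
        assert binned["sum_a"].sum() == pytest.approx(vals_a.sum())
        assert binned["sum_b"].sum() == pytest.approx(vals_b.sum())
        assert binned["n_hotspots"].sum() == 200

    def test_centromere_outside_chromosome_rejected(self):
        a = _table([1.0])
        with pytest.raises(ValueError):
            bin_ratios_50kb(a, a, {"chrI": 500_000}, {"chrI": 100_000})


class TestTimingTrack:
    def _track(self, n=120, chrom="chrI", gradient=True):
        pos = np.arange(n) * 1000 + 500
        time = 2 + 4 * pos / pos.max() if gradient else np.full(n, 3.0)
        return pd.DataFrame({"chrom": chrom, "position": pos, "time": time,
                             "confidence": True})

    def test_constant_track_stays_constant(self):
        out = prepare_timing_track(self._track(gradient=False))
        np.testing.assert_allclose(out["time"], 3.0, rtol=1e-9)

    def test_eighty_points_means_global_span(self):
        t = self._track(n=80)
        out = prepare_timing_track(t, loess_numerator=80)
        # span = 80/80 = 1: global straight-line fit of a linear gradient
        # reproduces it exactly
        sub = t.sort_values("position")
        np.testing.assert_allclose(
            out["time"].iloc[0],
            np.mean(sub["time"].iloc[:50]), rtol=0.05)

    def test_low_confidence_points_dropped(self):
        t = self._track()
        t.loc[t.index[:60], "confidence"] = False
        out = prepare_timing_track(t)
        assert out["n_points"].sum() == 60

    def test_all_filtered_rejected(self):
        t = self._track()
        t["confidence"] = False
        with pytest.raises(ValueError):
            prepare_timing_track(t)

    def test_gradient_recovered_within_smoothing_tolerance(self):
        t = self._track(n=300)
        out = prepare_timing_track(t, loess_numerator=80)
        mids = (out["start"] + out["end"]) / 2
        expect = 2 + 4 * mids.clip(upper=300 * 1000) / (299 * 1000 + 500)
        assert np.corrcoef(out["time"], expect)[0, 1] > 0.99


class TestFcTimingCorrelation:
    def _binned(self, fc_by_bin):
        rows = []
        for k, fc in fc_by_bin.items():
            rows.append({"chrom": "chrI", "bin": k,
                         "start": 100_000 + k * 50_000,
                         "end": 100_000 + (k + 1) * 50_000 - 1,
                         "log2fc": fc, "defined": not math.isnan(fc),
                         "sum_a": 1.0, "sum_b": 1.0, "n_hotspots": 1})
        return pd.DataFrame(rows)

    def _timing(self, time_by_bin):
        rows = []
        for k, tm in time_by_bin.items():
            rows.append({"chrom": "chrI", "bin": k, "start": k * 50_000 + 1,
                         "end": (k + 1) * 50_000, "time": tm, "n_points": 5})
        return pd.DataFrame(rows)

    def test_perfect_monotone_gives_unit_magnitude(self):
        fc = {k: -float(k) for k in range(-2, 4)}
        tm = {k: float(k) + 10 for k in range(-2, 8)}
        res = correlate_fc_with_timing(self._binned(fc), self._timing(tm))
        assert res["r"] == pytest.approx(-1.0)
        assert res["p"] < 0.05

    def test_independent_random_bins_near_zero(self):
        rng = np.random.default_rng(17)
        fc = {k: float(rng.normal()) for k in range(-40, 160)}
        tm = {k: float(rng.uniform(1, 8)) for k in range(-40, 200)}
        res = correlate_fc_with_timing(self._binned(fc), self._timing(tm))
        assert abs(res["r"]) < 0.2

    def test_undefined_bins_dropped(self):
        fc = {0: 1.0, 1: float("nan"), 2: 0.5, 3: 0.2, 4: 0.1}
        tm = {k: float(k) for k in range(8)}
        res = correlate_fc_with_timing(self._binned(fc), self._timing(tm))
        assert res["n"] == 4

    def test_too_few_pairs_rejected(self):
        fc = {0: 1.0, 1: 0.5}
        tm = {0: 1.0, 1: 2.0}
        with pytest.raises(ValueError):
            correlate_fc_with_timing(self._binned(fc), self._timing(tm))
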