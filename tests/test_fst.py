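"""FST estimators, smoothing, outlier calling, region merging, and the scan."""

import numpy as np
import pandas as pd
import pytest

from driftscan.fst import (
    FstConfig,
    call_outliers,
    estimate_drift_c,
    fst_per_snp,
    merge_regions,
    pure_drift_moment_fst,
    scan,
    smooth_track,
    weir_cockerham_fst,
)

from conftest import make_geno
from oracles import naive_smooth, wc_theta_oracle


def geno_from_counts(counts1, counts2):
    """Build a two-group matrix realizing the given genotype counts."""
    rows, groups = [], []
    for counts, grp in ((counts1, "I"), (counts2, "II")):
        for dosage, k in zip((2, 1, 0), counts):
            rows += [[dosage]] * k
            groups += [grp] * k
    return make_geno(np.array(rows, dtype=np.int8), groups=groups)


def make_track(values, chroms=None, pos=None):
    m = len(values)
    return pd.DataFrame({
        "id": [f"v{j:04d}" for j in range(m)],
        "chrom": chroms if chroms is not None else ["1"] * m,
        "pos_bp": pos if pos is not None else (np.arange(m) + 1) * 1000,
        "fst_raw": np.asarray(values, dtype=float),
    })


class TestEstimators:
    def test_fixed_difference_gives_one(self):
        g = geno_from_counts((10, 0, 0), (0, 0, 10))
        for est in ("weir_cockerham", "pure_drift_moment"):
            t = fst_per_snp(g, est)
            assert t["fst_raw"].iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_identical_frequencies_nonpositive(self):
        # both groups at p = 0.5, n = 20 per group, HWE-ish counts
        g = geno_from_counts((5, 10, 5), (5, 10, 5))
        t = fst_per_snp(g, "weir_cockerham")
        assert t["fst_raw"].iloc[0] <= 0

    def test_weir_cockerham_matches_transcription_oracle(self):
        g = geno_from_counts((6, 8, 6), (2, 8, 10))
        t = fst_per_snp(g, "weir_cockerham")
        assert t["fst_raw"].iloc[0] == pytest.approx(
            wc_theta_oracle((6, 8, 6), (2, 8, 10)), abs=1e-12
        )

    def test_weir_cockerham_random_tables_match_oracle(self, rng):
        for _ in range(100):
            c1 = tuple(int(x) for x in rng.integers(0, 15, 3) + np.array([1, 1, 0]))
            c2 = tuple(int(x) for x in rng.integers(0, 15, 3) + np.array([0, 1, 1]))
            g = geno_from_counts(c1, c2)
            got = fst_per_snp(g, "weir_cockerham")["fst_raw"].iloc[0]
            assert got == pytest.approx(wc_theta_oracle(c1, c2), abs=1e-12), (c1, c2)

    def test_preconditions_produce_missing_values(self):
        # one group with a single called sample -> NaN
        d = np.array([[1], [-1], [0], [2]], dtype=np.int8)
        g = make_geno(d, groups=["I", "I", "II", "II"])
        t = fst_per_snp(g)
        assert np.isnan(t["fst_raw"].iloc[0])

    def test_single_group_rejected(self):
        g = make_geno(np.zeros((4, 2), dtype=np.int8), groups=["I"] * 4)
        with pytest.raises(ValueError, match="group"):
            fst_per_snp(g)

    def test_estimator_equivalence_large_equal_groups(self, rng):
        m, n, c = 1000, 100, 0.05
        pi = rng.uniform(0.05, 0.5, m)
        a, b = pi * (1 - c) / c, (1 - pi) * (1 - c) / c
        p1, p2 = rng.beta(a, b), rng.beta(a, b)
        d = np.vstack([
            rng.binomial(2, np.tile(p1, (n, 1))),
            rng.binomial(2, np.tile(p2, (n, 1))),
        ]).astype(np.int8)
        g = make_geno(d, groups=["I"] * n + ["II"] * n)
        wc = fst_per_snp(g, "weir_cockerham")["fst_raw"]
        dm = fst_per_snp(g, "pure_drift_moment")["fst_raw"]
        ok = wc.notna() & dm.notna()
        assert np.corrcoef(wc[ok], dm[ok])[0, 1] > 0.99

    def test_pooled_drift_estimate_recovers_c(self, rng):
        m, n, c = 2000, 50, 0.05
        pi = rng.uniform(0.05, 0.5, m)
        a, b = pi * (1 - c) / c, (1 - pi) * (1 - c) / c
        p1, p2 = rng.beta(a, b), rng.beta(a, b)
        d = np.vstack([
            rng.binomial(2, np.tile(p1, (n, 1))),
            rng.binomial(2, np.tile(p2, (n, 1))),
        ]).astype(np.int8)
        g = make_geno(d, groups=["I"] * n + ["II"] * n)
        assert estimate_drift_c(g) == pytest.approx(c, rel=0.10)


class TestSmoothing:
    def test_constant_track_unchanged(self):
        t = smooth_track(make_track([0.3] * 20), window_snps=5)
        assert np.allclose(t["fst_smooth"], 0.3)

    def test_interior_spike_spreads_as_one_over_window(self):
        vals = [0.0] * 10
        vals[5] = 1.0
        t = smooth_track(make_track(vals), window_snps=5)
        assert t["fst_smooth"].iloc[5] == pytest.approx(0.2, abs=1e-12)

    @pytest.mark.parametrize("kernel", ["uniform_mean", "triangular"])
    @pytest.mark.parametrize("window", [3, 7, 9])
    def test_matches_naive_loop_oracle(self, rng, kernel, window):
        m = 150
        vals = rng.uniform(0, 0.4, m)
        vals[rng.random(m) < 0.1] = np.nan
        chroms = ["1"] * 60 + ["2"] * 50 + ["3"] * 40
        t = smooth_track(make_track(vals, chroms=chroms), window, kernel,
                         clamp_negative=False)
        want = naive_smooth(vals, chroms, window, kernel)
        assert np.allclose(t["fst_smooth"], want, atol=1e-12, equal_nan=True)

    def test_window_larger_than_chromosome_falls_back_to_mean(self):
        vals = [0.1, 0.2, 0.3, 0.0, 0.4]
        chroms = ["1", "1", "1", "2", "2"]
        t = smooth_track(make_track(vals, chroms=chroms), window_snps=3)
        assert t["fst_smooth"].iloc[3] == pytest.approx(0.2)
        assert t["fst_smooth"].iloc[4] == pytest.approx(0.2)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            smooth_track(make_track([0.1] * 5), window_snps=4)


class TestOutlierCalling:
    def test_all_equal_flags_nothing(self):
        t = smooth_track(make_track([0.2] * 50), window_snps=1)
        out = call_outliers(t, 0.99)
        assert not out["is_outlier"].any()

    def test_top_ten_of_thousand_distinct(self, rng):
        vals = rng.permutation(np.linspace(0.001, 0.9, 1000))
        t = make_track(vals)
        t["fst_smooth"] = vals  # identity smoothing for the oracle check
        out = call_outliers(t, 0.99)
        flagged = set(out.loc[out["is_outlier"], "id"])
        want = set(t.sort_values("fst_smooth", ascending=False)["id"].head(10))
        assert flagged == want

    def test_flags_invariant_under_monotone_transform(self, rng):
        vals = rng.uniform(0, 1, 500)
        t = make_track(vals)
        t["fst_smooth"] = vals
        t2 = t.copy()
        t2["fst_smooth"] = np.exp(3 * vals) - 0.5
        f1 = call_outliers(t, 0.95)["is_outlier"]
        f2 = call_outliers(t2, 0.95)["is_outlier"]
        assert f1.equals(f2)


class TestMergeRegions:
    def _flagged_track(self, pos, chroms=None):
        t = make_track([0.5] * len(pos), chroms=chroms, pos=pos)
        t["fst_smooth"] = t["fst_raw"]
        t["is_outlier"] = True
        return t

    def test_gap_splits_regions(self):
        t = self._flagged_track([1_000_000, 1_200_000, 5_000_000])
        regions = merge_regions(t, merge_gap_bp=1_000_000)
        assert [(r.start_bp, r.end_bp, r.n_snps) for r in regions] == [
            (1_000_000, 1_200_000, 2),
            (5_000_000, 5_000_000, 1),
        ]

    def test_no_flags_empty_list(self):
        t = make_track([0.1] * 4)
        t["fst_smooth"] = t["fst_raw"]
        t["is_outlier"] = False
        assert merge_regions(t) == []

    def test_member_count_conservation_random_patterns(self, rng):
        for _ in range(20):
            m = int(rng.integers(5, 60))
            t = make_track(rng.uniform(0, 1, m),
                           chroms=list(rng.choice(["1", "2"], m)),
                           pos=np.sort(rng.integers(1, 10_000_000, m)))
            t = t.sort_values(["chrom", "pos_bp"]).reset_index(drop=True)
            t["pos_bp"] = t.groupby("chrom").cumcount() * 100_000 + 1  # ensure unique sorted
            t["fst_smooth"] = t["fst_raw"]
            t["is_outlier"] = rng.random(m) < 0.4
            regions = merge_regions(t, merge_gap_bp=int(rng.integers(1, 500_000)))
            assert sum(r.n_snps for r in regions) == int(t["is_outlier"].sum())
            for r in regions:
                assert r.start_bp <= r.end_bp
            # regions on one chromosome never overlap
            by_chrom: dict = {}
            for r in regions:
                by_chrom.setdefault(r.chrom, []).append((r.start_bp, r.end_bp))
            for spans in by_chrom.values():
                spans.sort()
                assert all(a[1] < b[0] for a, b in zip(spans, spans[1:]))


class TestScan:
    def test_planted_window_intersects_a_region(self):
        from driftscan.simulate import PlantedWindow, SimConfig, evaluate_recovery, simulate

        cfg = SimConfig(seed=5, planted_windows=[
            PlantedWindow(chrom=3, start_snp=100, n_snps=15, delta=0.4)
        ])
        g, truth, _ = simulate(cfg)
        _, regions = scan(g)
        metrics = evaluate_recovery(regions, truth)
        assert metrics.sensitivity == 1.0

    def test_null_flagged_fraction_matches_quantile(self):
        from driftscan.simulate import SimConfig, simulate

        g, _, _ = simulate(SimConfig(seed=9, n_snps=4000))
        track, _ = scan(g, FstConfig(outlier_quantile=0.95))
        frac = track["is_outlier"].mean()
        se = np.sqrt(0.05 * 0.95 / len(track))
        assert abs(frac - 0.05) < 3 * se

    def test_group_label_permutation_keeps_calibration(self, rng):
        from driftscan.simulate import PlantedWindow, SimConfig, simulate

        cfg = SimConfig(seed=21, n_snps=3000, planted_windows=[
            PlantedWindow(chrom=1, start_snp=50, n_snps=15, delta=0.5)
        ])
        g, _, _ = simulate(cfg)
        g.samples["group"] = rng.permutation(g.samples["group"].to_numpy())
        track, _ = scan(g)
        frac = track["is_outlier"].mean()
        se = np.sqrt(0.01 * 0.99 / len(track))
        assert abs(frac - 0.01) < 4 * se

    def test_peak_smoothed_fst_monotone_in_delta(self):
        from driftscan.simulate import PlantedWindow, SimConfig, simulate

        peaks = []
        for delta in (0.0, 0.15, 0.3, 0.45, 0.6):
            cfg = SimConfig(seed=33, n_snps=2000, n_chromosomes=2,
                            missing_rate=0.0, planted_windows=[
                                PlantedWindow(chrom=1, start_snp=300, n_snps=15, delta=delta)
                            ])
            g, truth, _ = simulate(cfg)  # common random numbers via fixed seed
            track, _ = scan(g)
            w = truth.windows.iloc[0]
            sel = (track["chrom"] == w["chrom"]) & \
                  (track["pos_bp"] >= w["start_bp"]) & (track["pos_bp"] <= w["end_bp"])
            peaks.append(track.loc[sel, "fst_smooth"].max())
        assert all(b >= a - 1e-9 for a, b in zip(peaks, peaks[1:]))

    def test_scan_is_deterministic(self):
        from driftscan.simulate import SimConfig, simulate

        g, _, _ = simulate(SimConfig(seed=2, n_snps=1000))
        t1, r1 = scan(g)
        t2, r2 = scan(g)
        assert t1.equals(t2)
        assert [(r.chrom, r.start_bp, r.end_bp) for r in r1] == \
               [(r.chrom, r.start_bp, r.end_bp) for r in r2]

    def test_config_validation(self):
        with pytest.raises(ValueError):
            FstConfig(smooth_window_snps=4)
        with pytest.raises(ValueError):
            FstConfig(outlier_quantile=1.0)
        with pytest.raises(ValueError):
            FstConfig(estimator="bayescan")
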