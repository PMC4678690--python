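import math

import numpy as np
import pytest

from dhssremodel.caller import (
    DhssAccessibilityModel,
    ScanGeometry,
    WindowStat,
    calibrate_cutoff,
    classify_differential,
    combined_z,
    effective_length,
    enumerate_windows,
    merge_significant,
    scan,
)
from dhssremodel.intervals import (
    GenomicInterval,
    MappabilityTrack,
    TagLibrary,
)


def make_lib(cond, positions_by_chrom):
    return TagLibrary(cond, {c: np.array(sorted(p), dtype=np.int64)
                             for c, p in positions_by_chrom.items()})


def uniform_lib(cond, chrom_len, n, seed, chrom="chr1"):
    rng = np.random.default_rng(seed)
    return make_lib(cond, {chrom: rng.integers(0, chrom_len, size=n)})


class TestScanGeometry:
    def test_defaults_follow_published_overlaps(self):
        g = ScanGeometry()
        assert g.big_window - g.big_step == 400
        assert g.small_window - g.small_step == 100

    def test_validation(self):
        with pytest.raises(ValueError):
            ScanGeometry(big_window=400, small_window=500)
        with pytest.raises(ValueError):
            ScanGeometry(small_step=0)


class TestEffectiveLength:
    def test_without_track_is_raw_length(self):
        assert effective_length(GenomicInterval("chr1", 0, 10_000), None) == 10_000

    def test_half_covered(self):
        track = MappabilityTrack({"chr1": [GenomicInterval("chr1", 0, 5000)]})
        assert effective_length(GenomicInterval("chr1", 0, 10_000), track) == 5000

    def test_random_mask_matches_per_base_oracle(self, rng):
        ivs = []
        for _ in range(40):
            s = int(rng.integers(0, 20_000))
            ivs.append(GenomicInterval("chr1", s, s + int(rng.integers(1, 500))))
        track = MappabilityTrack({"chr1": ivs})
        mask = np.zeros(25_000, dtype=bool)
        for iv in ivs:
            mask[iv.start:iv.end] = True
        for _ in range(200):
            s = int(rng.integers(0, 20_000))
            e = s + int(rng.integers(1, 3000))
            assert effective_length(GenomicInterval("chr1", s, e), track) \
                == mask[s:e].sum()


class TestEnumerateWindows:
    def test_default_tiling_20kb(self):
        pairs = enumerate_windows({"chr1": 20_000})
        bigs = sorted({b.start for _, b in pairs})
        assert bigs[:2] == [0, 9_600]
        smalls = sorted({s.start for s, _ in pairs})
        assert smalls[:3] == [0, 400, 800]

    def test_small_at_9200_pairs_with_first_big(self):
        pairs = {s.start: b for s, b in enumerate_windows({"chr1": 20_000})}
        assert pairs[9_200].start == 0 and pairs[9_200].end == 10_000
        assert pairs[9_600].start == 9_600

    def test_short_chromosome_has_no_windows(self):
        assert enumerate_windows({"tiny": 300}) == []

    def test_each_small_contained_in_unique_big(self):
        pairs = enumerate_windows({"chr1": 100_000})
        seen = set()
        for small, big in pairs:
            assert big.start <= small.start and small.end <= big.end
            assert small.start not in seen
            seen.add(small.start)

    def test_truncation_at_chromosome_end(self):
        pairs = enumerate_windows({"chr1": 10_250})
        for small, big in pairs:
            assert small.end <= 10_250 and big.end <= 10_250
            assert len(small) >= 400  # shorter truncations dropped


class TestCombinedZ:
    def test_centered_is_zero(self):
        assert combined_z(10, 10, 10, 10, 3.0, 3.0, 100, 100) == pytest.approx(0.0)

    def test_worked_example(self):
        s = math.sqrt(9.5)
        z = combined_z(30, 30, 10, 10, s, s, 1000, 1000)
        assert z == pytest.approx(40 / math.sqrt(2 * 9.5), rel=1e-6)
        assert z == pytest.approx(9.1766, abs=1e-3)

    def test_degenerate_sigma_marks_undefined(self):
        assert math.isnan(combined_z(5, 5, 5, 5, 0.0, 0.0, 100, 100))

    def test_library_ratio_scales_vpa_terms(self):
        # r = 2 doubles the weight of the VPA excess
        z1 = combined_z(0, 10, 0, 5, 1e-9, 2.0, 200, 100)
        assert z1 == pytest.approx((10 - 5) * 2 / math.sqrt((2.0 * 2) ** 2))

    def test_single_condition_limit(self):
        # empty VPA condition: reduces to the vehicle binomial z-score
        z = combined_z(17, 0, 10, 0.0, 3.0, 0.0, 500, 500)
        assert z == pytest.approx((17 - 10) / 3.0)

    def test_rejects_bad_totals(self):
        with pytest.raises(ValueError):
            combined_z(1, 1, 1, 1, 1, 1, 0, 100)


class TestScan:
    def test_planted_enrichment_attains_max_z(self):
        chrom_len = 100_000
        rng = np.random.default_rng(3)
        background = rng.integers(0, chrom_len, size=2000)
        planted = rng.integers(50_000, 50_500, size=200)  # ~20x local density
        veh = make_lib("Veh", {"chr1": np.concatenate([background, planted])})
        vpa = make_lib("VPA", {"chr1": np.concatenate(
            [rng.integers(0, chrom_len, size=2000),
             rng.integers(50_000, 50_500, size=200)])})
        stats = scan(veh, vpa, {"chr1": chrom_len}, seed=0)
        best = max(stats, key=lambda w: w.z_norm)
        assert best.interval.start <= 50_000 < best.interval.end \
            or 50_000 <= best.interval.start < 50_500

    def test_determinism_and_seed_independence_of_z_norm(self):
        veh = uniform_lib("Veh", 60_000, 3000, 1)
        vpa = uniform_lib("VPA", 60_000, 3000, 2)
        sizes = {"chr1": 60_000}
        a = scan(veh, vpa, sizes, seed=5)
        b = scan(veh, vpa, sizes, seed=5)
        c = scan(veh, vpa, sizes, seed=6)
        assert [w.z_rand for w in a] == [w.z_rand for w in b]
        assert [w.z_norm for w in a] == [w.z_norm for w in c]
        assert [w.z_rand for w in a] != [w.z_rand for w in c]

    def test_empty_big_windows_skipped(self):
        veh = make_lib("Veh", {"chr1": [100, 200, 300]})
        vpa = make_lib("VPA", {"chr1": [150, 250]})
        stats = scan(veh, vpa, {"chr1": 50_000}, seed=0)
        assert all(w.N_veh + w.N_vpa > 0 for w in stats)
        assert all(np.isfinite(w.z_norm) for w in stats)

    def test_empty_library_rejected(self):
        veh = make_lib("Veh", {"chr1": [1]})
        with pytest.raises(ValueError):
            scan(veh, TagLibrary("VPA", {}), {"chr1": 10_000})


def _ws(start, z_norm, z_rand, chrom="chr1"):
    iv = GenomicInterval(chrom, start, start + 500)
    return WindowStat(iv, 500, 10_000, 0, 0, 0, 0, z_norm, z_rand)


class TestCalibrateCutoff:
    def test_perfect_separation(self):
        stats = [_ws(i * 400, 10.0, z_rand=float(np.random.default_rng(i).uniform(-2, 2)))
                 for i in range(100)]
        c = calibrate_cutoff(stats)
        assert c is not None and c <= 2.0 + 0.1

    def test_no_qualifying_cutoff(self):
        stats = [_ws(i * 400, 1.0, 1.0) for i in range(10)]
        assert calibrate_cutoff(stats) is None

    def test_null_like_distribution_controls_estimate(self, rng):
        z = rng.normal(size=2000)
        zr = rng.normal(size=2000)
        stats = [_ws(i * 400, float(a), float(b)) for i, (a, b) in enumerate(zip(z, zr))]
        c = calibrate_cutoff(stats, target_fdr=0.05)
        if c is not None:
            est = np.sum(zr >= c) / max(1, np.sum(z >= c))
            assert est <= 0.05


class TestMergeSignificant:
    def test_overlapping_windows_merge(self):
        stats = [_ws(0, 8.0, 0.0), _ws(400, 8.0, 0.0), _ws(2000, 8.0, 0.0),
                 _ws(800, 1.0, 0.0)]
        merged = merge_significant(stats, 5.0)
        assert merged == [GenomicInterval("chr1", 0, 900),
                          GenomicInterval("chr1", 2000, 2500)]

    def test_no_significant_windows(self):
        assert merge_significant([_ws(0, 1.0, 0.0)], 5.0) == []

    def test_cluster_count_matches_connected_components(self, rng):
        stats = []
        for i in range(200):
            stats.append(_ws(i * 400, float(rng.choice([0.0, 9.0])), 0.0))
        merged = merge_significant(stats, 5.0)
        # brute-force connected components over the overlap graph
        sig = [w.interval for w in stats if w.z_norm >= 5.0]
        comps = 0
        prev_end = None
        for iv in sorted(sig, key=lambda v: v.start):
            if prev_end is None or iv.start > prev_end:
                comps += 1
                prev_end = iv.end
            else:
                prev_end = max(prev_end, iv.end)
        assert len(merged) == comps


class TestClassifyDifferential:
    def test_planted_vpa_only_region_called_induced(self):
        rng = np.random.default_rng(7)
        n = 100_000
        veh = make_lib("Veh", {"chr1": rng.integers(0, 1_000_000, size=n)})
        vpa_pos = np.concatenate([rng.integers(0, 1_000_000, size=n - 1000),
                                  rng.integers(500_000, 501_000, size=1000)])
        vpa = make_lib("VPA", {"chr1": vpa_pos})
        clusters = [GenomicInterval("chr1", 500_000, 501_000),
                    GenomicInterval("chr1", 100_000, 101_000)]
        out = classify_differential(clusters, veh, vpa)
        assert out[0].status == "vpa_induced"
        assert out[1].status == "shared"

    def test_symmetric_counts_shared(self):
        lib = make_lib("Veh", {"chr1": np.arange(0, 10_000, 10)})
        lib2 = make_lib("VPA", {"chr1": np.arange(5, 10_000, 10)})
        out = classify_differential([GenomicInterval("chr1", 0, 10_000)], lib, lib2)
        assert out[0].status == "shared"

    def test_statuses_partition_and_rates_consistent(self):
        rng = np.random.default_rng(11)
        veh = make_lib("Veh", {"chr1": rng.integers(0, 500_000, size=50_000)})
        vpa = make_lib("VPA", {"chr1": rng.integers(0, 500_000, size=60_000)})
        clusters = [GenomicInterval("chr1", i * 10_000, i * 10_000 + 2000)
                    for i in range(40)]
        out = classify_differential(clusters, veh, vpa)
        assert len(out) == len(clusters)
        for cl in out:
            assert cl.status in ("vpa_induced", "vehicle_specific", "shared")
            assert cl.n_veh <= veh.n_total and cl.n_vpa <= vpa.n_total
            if cl.status == "vpa_induced":
                assert cl.n_vpa / vpa.n_total > cl.n_veh / veh.n_total


class TestModelResults:
    def test_fit_summary_and_bed(self, tmp_path):
        rng = np.random.default_rng(2)
        chrom_len = 200_000
        bg_v = rng.integers(0, chrom_len, size=5000)
        bg_a = rng.integers(0, chrom_len, size=5000)
        region_v = rng.integers(100_000, 101_000, size=400)
        region_a = rng.integers(100_000, 101_000, size=2000)
        veh = make_lib("Veh", {"chr1": np.concatenate([bg_v, region_v])})
        vpa = make_lib("VPA", {"chr1": np.concatenate([bg_a, region_a])})
        model = DhssAccessibilityModel(veh, vpa, {"chr1": chrom_len})
        res = model.fit(seed=4)
        assert res.clusters, "planted region should be called"
        assert any(c.status == "vpa_induced"
                   and c.interval.start <= 100_000 < c.interval.end + 1000
                   for c in res.clusters)
        text = res.summary()
        assert "z cutoff" in text and "VPA-induced" in text
        out = tmp_path / "clusters.bed"
        res.to_bed(out)
        lines = out.read_text().strip().splitlines()
        assert len(lines) == len(res.clusters)
        assert lines[0].split("\t")[3] in ("vpa_induced", "vehicle_specific",
                                           "shared")

    def test_explicit_cutoff_bypasses_calibration(self):
        veh = uniform_lib("Veh", 50_000, 2000, 1)
        vpa = uniform_lib("VPA", 50_000, 2000, 2)
        res = DhssAccessibilityModel(veh, vpa, {"chr1": 50_000}).fit(
            seed=0, z_cutoff=5.5)
        assert res.z_cutoff == 5.5
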