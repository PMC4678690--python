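import numpy as np
import pytest

from dhssremodel.cage import (
    CageTag,
    TssActivityModel,
    cluster_cage,
    classify_tss,
    exon1_ratio,
    filter_tpm,
    promoter_overlap,
    promoter_region,
    tss_profile,
)
from dhssremodel.intervals import GeneModel, GenomicInterval, TagLibrary


def tag(chrom, start, end, strand, cond="Veh"):
    return CageTag(GenomicInterval(chrom, start, end, strand), cond)


TOTALS = {"Veh": 1_000_000, "VPA": 1_000_000}


class TestClusterCage:
    def test_overlap_chains_merge(self):
        tags = [tag("chr1", 100, 120, "+"), tag("chr1", 115, 140, "+"),
                tag("chr1", 200, 220, "+")]
        clusters = cluster_cage(tags, TOTALS)
        spans = [(c.interval.start, c.interval.end) for c in clusters]
        assert spans == [(100, 140), (200, 220)]

    def test_strands_kept_separate(self):
        tags = [tag("chr1", 100, 120, "+"), tag("chr1", 100, 120, "-")]
        assert len(cluster_cage(tags, TOTALS)) == 2

    def test_abutting_tags_do_not_merge(self):
        tags = [tag("chr1", 100, 120, "+"), tag("chr1", 120, 140, "+")]
        assert len(cluster_cage(tags, TOTALS)) == 2

    def test_unstranded_tag_rejected(self):
        with pytest.raises(ValueError):
            CageTag(GenomicInterval("chr1", 0, 10, "."), "Veh")

    def test_counts_tpm_and_peak(self):
        tags = [tag("chr1", 100, 121, "+", "Veh"),
                tag("chr1", 100, 121, "+", "VPA"),
                tag("chr1", 100, 121, "+", "VPA"),
                tag("chr1", 110, 131, "+", "VPA")]
        (c,) = cluster_cage(tags, TOTALS)
        assert (c.count_veh, c.count_vpa) == (1, 3)
        assert c.tpm_vpa == pytest.approx(3 * 1e6 / TOTALS["VPA"])
        assert c.peak_position == 100  # modal 5' position

    def test_matches_transitive_closure_oracle(self, rng):
        tags = []
        for _ in range(500):
            s = int(rng.integers(0, 20_000))
            tags.append(tag("chr1", s, s + int(rng.integers(5, 50)), "+",
                            "Veh" if rng.random() < 0.5 else "VPA"))
        clusters = cluster_cage(tags, TOTALS)
        # O(n^2) union-find oracle over the overlap graph
        parent = list(range(len(tags)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(tags)):
            for j in range(i + 1, len(tags)):
                a, b = tags[i].interval, tags[j].interval
                if a.start < b.end and b.start < a.end:
                    parent[find(i)] = find(j)
        n_components = len({find(i) for i in range(len(tags))})
        assert len(clusters) == n_components
        assert sum(c.count_veh + c.count_vpa for c in clusters) == len(tags)


class TestFilterTpm:
    def _cluster(self, tpm_veh, tpm_vpa):
        from dhssremodel.cage import TssCluster
        return TssCluster(GenomicInterval("chr1", 0, 10, "+"), 1, 1,
                          tpm_veh, tpm_vpa, 0)

    @pytest.mark.parametrize("tv,ta,kept", [
        (9.0, 11.0, True),   # either-sample rule
        (9.0, 9.0, False),
        (10.0, 0.0, True),   # inclusive threshold
    ])
    def test_either_sample_rule(self, tv, ta, kept):
        out = filter_tpm([self._cluster(tv, ta)])
        assert bool(out) is kept


class TestClassifyTss:
    def test_strong_up_called_induced(self):
        tags = ([tag("chr1", 100, 121, "+", "VPA")] * 100
                + [tag("chr1", 100, 121, "+", "Veh")] * 10)
        clusters = cluster_cage(tags, TOTALS)
        classify_tss(clusters, TOTALS)
        assert clusters[0].status == "induced"

    def test_equal_counts_non_induced(self):
        tags = ([tag("chr1", 100, 121, "+", "VPA")] * 20
                + [tag("chr1", 100, 121, "+", "Veh")] * 20)
        clusters = cluster_cage(tags, TOTALS)
        classify_tss(clusters, TOTALS)
        assert clusters[0].status == "non_induced"

    def test_statuses_partition(self, rng):
        tags = []
        for i in range(50):
            base = i * 1000
            n_v = int(rng.integers(1, 40))
            n_a = int(rng.integers(1, 40))
            tags += [tag("chr1", base, base + 21, "+", "Veh")] * n_v
            tags += [tag("chr1", base, base + 21, "+", "VPA")] * n_a
        clusters = cluster_cage(tags, TOTALS)
        classify_tss(clusters, TOTALS)
        statuses = {c.status for c in clusters}
        assert statuses <= {"induced", "downregulated", "non_induced"}


class TestPromoters:
    def _gene(self, strand="+", cds=None):
        if strand == "+":
            iv = GenomicInterval("chr1", 10_000, 20_000, "+")
            exons = [GenomicInterval("chr1", 10_000, 10_500, "+")]
            cds = 10_200 if cds is None else cds
        else:
            iv = GenomicInterval("chr1", 10_000, 20_000, "-")
            exons = [GenomicInterval("chr1", 19_500, 20_000, "-")]
            cds = 19_800 if cds is None else cds
        return GeneModel("g", iv, cds, exons)

    def test_plus_strand_promoter_span(self):
        p = promoter_region(self._gene("+"))
        assert (p.start, p.end) == (9_000, 10_200)

    def test_minus_strand_promoter_span(self):
        p = promoter_region(self._gene("-"))
        # 1 kb upstream on minus strand is to the right of the TSS (19999)
        assert (p.start, p.end) == (19_801, 21_000)

    def test_cluster_at_tss_flagged(self):
        from dhssremodel.cage import TssCluster
        cl = TssCluster(GenomicInterval("chr1", 9_990, 10_050, "+"),
                        5, 5, 50.0, 50.0, 10_000)
        fractions, flags = promoter_overlap([cl], [self._gene("+")])
        assert flags == [True]

    def test_cluster_2kb_upstream_not_flagged(self):
        from dhssremodel.cage import TssCluster
        cl = TssCluster(GenomicInterval("chr1", 7_900, 8_000, "+"),
                        5, 5, 50.0, 50.0, 7_950)
        _, flags = promoter_overlap([cl], [self._gene("+")])
        assert flags == [False]

    def test_strand_mismatch_not_flagged(self):
        from dhssremodel.cage import TssCluster
        cl = TssCluster(GenomicInterval("chr1", 9_990, 10_050, "-"),
                        5, 5, 50.0, 50.0, 10_000)
        _, flags = promoter_overlap([cl], [self._gene("+")])
        assert flags == [False]

    def test_random_layout_matches_pairwise_oracle(self, rng):
        from dhssremodel.cage import TssCluster
        genes = []
        for i in range(30):
            s = int(rng.integers(2_000, 500_000))
            strand = "+" if rng.random() < 0.5 else "-"
            iv = GenomicInterval("chr1", s, s + 5_000, strand)
            cds = s + 300 if strand == "+" else s + 4_700
            genes.append(GeneModel(f"g{i}", iv, cds,
                                   [GenomicInterval("chr1", s, s + 5_000, strand)]))
        clusters = []
        for _ in range(200):
            s = int(rng.integers(0, 500_000))
            strand = "+" if rng.random() < 0.5 else "-"
            clusters.append(TssCluster(GenomicInterval("chr1", s, s + 60, strand),
                                       1, 1, 10.0, 10.0, s))
        _, flags = promoter_overlap(clusters, genes)
        for cl, flag in zip(clusters, flags):
            brute = any(
                p.strand == cl.interval.strand
                and p.start < cl.interval.end and cl.interval.start < p.end
                for p in (promoter_region(g) for g in genes))
            assert flag == brute


class TestExon1Ratio:
    def _gene(self):
        exons = [GenomicInterval("chr1", 1000, 1200, "+"),
                 GenomicInterval("chr1", 2000, 2400, "+")]
        return GeneModel("g", GenomicInterval("chr1", 1000, 2400, "+"), 1050, exons)

    def test_ratio(self):
        tags = ([tag("chr1", 1100, 1121, "+")] * 8
                + [tag("chr1", 2100, 2121, "+")] * 2)
        out = exon1_ratio([self._gene()], tags)
        assert out["Veh"] == [pytest.approx(0.8)]

    def test_below_threshold_excluded(self):
        tags = [tag("chr1", 1100, 1121, "+")] * 9
        assert exon1_ratio([self._gene()], tags)["Veh"] == []

    def test_all_intronic_gives_zero(self):
        tags = [tag("chr1", 1500, 1521, "+")] * 10
        assert exon1_ratio([self._gene()], tags)["Veh"] == [0.0]


class TestTssProfile:
    def _promoters(self, n=20, strand="+"):
        genes = []
        for i in range(n):
            s = 50_000 + i * 20_000
            iv = GenomicInterval("chr1", s, s + 5_000, strand)
            genes.append(GeneModel(f"g{i}", iv, s + 200 if strand == "+" else s + 4_800,
                                   [GenomicInterval("chr1", s, s + 5_000, strand)]))
        return genes

    def test_uniform_field_is_flat(self, rng):
        lib = TagLibrary("d", {"chr1": rng.integers(0, 500_000, size=200_000)})
        prof = tss_profile(lib, self._promoters())
        assert prof.n_promoters_retained == 20
        rel_spread = (prof.mean_tpm.max() - prof.mean_tpm.min()) / prof.mean_tpm.mean()
        assert rel_spread < 0.2

    def test_planted_tss_enrichment_peaks_at_center(self, rng):
        genes = self._promoters()
        positions = [rng.integers(0, 500_000, size=50_000)]
        for g in genes:
            positions.append(rng.integers(g.tss - 100, g.tss + 100, size=2000))
        lib = TagLibrary("d", {"chr1": np.concatenate(positions)})
        prof = tss_profile(lib, genes)
        center = np.argmax(prof.mean_tpm)
        assert prof.bin_offsets[center] in (-500, 0)

    def test_spike_promoter_excluded(self, rng):
        genes = self._promoters()
        base = rng.integers(0, 500_000, size=100_000)
        spike = np.full(50_000, genes[0].tss + 10)  # one promoter, one huge bin
        lib = TagLibrary("d", {"chr1": np.concatenate([base, spike])})
        prof = tss_profile(lib, genes)
        assert prof.n_promoters_retained == len(genes) - 1

    def test_chrm_promoters_excluded(self, rng):
        genes = self._promoters()
        mgene = GeneModel("m", GenomicInterval("chrM", 6_000, 10_000, "+"), 6_100,
                          [GenomicInterval("chrM", 6_000, 10_000, "+")])
        lib = TagLibrary("d", {"chr1": rng.integers(0, 500_000, size=10_000)})
        prof = tss_profile(lib, genes + [mgene])
        assert prof.n_promoters_retained == len(genes)

    def test_minus_strand_orientation_flip(self):
        # tags strictly downstream of a minus-strand TSS must land in
        # positive-offset bins
        g = self._promoters(1, strand="-")[0]
        lib = TagLibrary("d", {"chr1": np.arange(g.tss - 1000, g.tss - 900)})
        prof = tss_profile(lib, [g])
        hot = prof.bin_offsets[np.argmax(prof.mean_tpm)]
        assert hot >= 500

    def test_invalid_flank(self, rng):
        lib = TagLibrary("d", {"chr1": np.array([1])})
        with pytest.raises(ValueError):
            tss_profile(lib, self._promoters(), flank=5100)


class TestTssActivityModel:
    def test_fit_summary_and_tpm_consistency(self, rng):
        tags = []
        for i in range(30):
            base = 1000 + i * 5000
            n_v = int(rng.integers(5, 50))
            n_a = n_v * (8 if i < 3 else 1)
            tags += [tag("chr1", base, base + 21, "+", "Veh")] * n_v
            tags += [tag("chr1", base, base + 21, "+", "VPA")] * n_a
        totals = {"Veh": sum(t.condition == "Veh" for t in tags),
                  "VPA": sum(t.condition == "VPA" for t in tags)}
        res = TssActivityModel(tags, totals).fit(min_tpm=10.0)
        assert "TSS clusters" in res.summary()
        for c in res.clusters:
            assert c.tpm_veh == pytest.approx(c.count_veh * 1e6 / totals["Veh"])
            assert c.tpm_vpa == pytest.approx(c.count_vpa * 1e6 / totals["VPA"])
        assert sum(c.count_veh for c in res.clusters) <= totals["Veh"]
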