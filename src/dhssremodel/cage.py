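"""CAGE transcription start site clustering and differential expression.

CAGE tags map the capped 5' ends of mRNAs, so their 5' positions are
base-resolution TSS signals.  Overlapping tag spans on the same strand are
merged transitively into single-linkage TSS clusters, normalised to tags
per million (TPM) against the library-wide mapped totals, filtered at
>= 10 TPM in either sample, and tested for condition specificity with the
same one-tailed Fisher + Benjamini-Hochberg scheme as the DHSS clusters.

The module also carries the promoter-centric annotations: the promoter
region of a coding gene runs from 1 kb upstream of the TSS to the
translation start; first-exon tag ratios quantify how focused
transcription is at the annotated 5' end; and ``tss_profile`` computes the
averaged DNase tag density in 500 bp bins around promoters, with the
published exclusion rules (chrM promoters and promoters with any bin more
than 10x that bin's cross-promoter mean).
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import Counter

import numpy as np

from .intervals import (
    GenomicInterval,
    GeneModel,
    IntervalIndex,
    TagLibrary,
    count_tags,
    read_bed,
)
from .stats import bh_adjust, fisher_one_tailed


@dataclass(frozen=True)
class CageTag:
    """One mapped CAGE tag span (stranded) with its condition label."""

    interval: GenomicInterval
    condition: str

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError("CAGE tags must be stranded")

    @property
    def five_prime(self) -> int:
        iv = self.interval
        return iv.start if iv.strand == "+" else iv.end - 1


@dataclass
class TssCluster:
    """A single-linkage cluster of overlapping CAGE tags on one strand."""

    interval: GenomicInterval
    count_veh: int
    count_vpa: int
    tpm_veh: float
    tpm_vpa: float
    peak_position: int
    status: str = "non_induced"  # induced | downregulated | non_induced
    p_up: float = 1.0
    q_up: float = 1.0
    p_down: float = 1.0
    q_down: float = 1.0


@dataclass
class TssProfile:
    """Binned average DNase tag TPM around promoters."""

    bin_offsets: np.ndarray  # bin start offsets relative to the TSS
    mean_tpm: np.ndarray
    n_promoters_retained: int
    bin_size: int = 500


def read_cage_bed(path, condition: str) -> list[CageTag]:
    """Load stranded BED6 tag spans for one condition."""
    tags = []
    for iv in read_bed(path, stranded=True):
        tags.append(CageTag(iv, condition))
    return tags


def cluster_cage(tags: list[CageTag], totals: dict[str, int],
                 veh_label: str = "Veh", vpa_label: str = "VPA",
                 ) -> list[TssCluster]:
    """Single-linkage clustering of overlapping tag spans, per strand.

    ``totals`` maps condition label to the library-wide mapped-tag total
    used for TPM.  Peak position is the modal 5' position (leftmost on
    ties).
    """
    for lab in (veh_label, vpa_label):
        if totals.get(lab, 0) <= 0:
            raise ValueError(f"missing or non-positive total for {lab!r}")
    groups: dict[tuple[str, str], list[CageTag]] = {}
    for t in tags:
        groups.setdefault((t.interval.chrom, t.interval.strand), []).append(t)
    clusters: list[TssCluster] = []
    for (chrom, strand), members in sorted(groups.items()):
        members.sort(key=lambda t: (t.interval.start, t.interval.end))
        block: list[CageTag] = []
        block_end = -1
        for t in members + [None]:  # sentinel flushes the last block
            if t is not None and (not block or t.interval.start < block_end):
                block.append(t)
                block_end = max(block_end, t.interval.end)
                continue
            if block:
                start = min(b.interval.start for b in block)
                counts = Counter(b.condition for b in block)
                fives = Counter(b.five_prime for b in block)
                peak = min(p for p, c in fives.items()
                           if c == max(fives.values()))
                cv, ca = counts.get(veh_label, 0), counts.get(vpa_label, 0)
                clusters.append(TssCluster(
                    GenomicInterval(chrom, start, block_end, strand),
                    cv, ca,
                    cv * 1e6 / totals[veh_label],
                    ca * 1e6 / totals[vpa_label],
                    peak))
            if t is not None:
                block = [t]
                block_end = t.interval.end
    return clusters


def filter_tpm(clusters: list[TssCluster], min_tpm: float = 10.0,
               ) -> list[TssCluster]:
    """Keep clusters reaching ``min_tpm`` in either condition."""
    return [c for c in clusters if c.tpm_veh >= min_tpm or c.tpm_vpa >= min_tpm]


def classify_tss(clusters: list[TssCluster], totals: dict[str, int],
                 alpha: float = 0.05, veh_label: str = "Veh",
                 vpa_label: str = "VPA") -> list[TssCluster]:
    """One-tailed Fisher + BH per direction; statuses partition the set."""
    if not clusters:
        return clusters
    n_veh_tot, n_vpa_tot = totals[veh_label], totals[vpa_label]
    p_up = np.array([
        fisher_one_tailed(((c.count_vpa, n_vpa_tot - c.count_vpa),
                           (c.count_veh, n_veh_tot - c.count_veh)), "greater")
        for c in clusters])
    p_down = np.array([
        fisher_one_tailed(((c.count_veh, n_veh_tot - c.count_veh),
                           (c.count_vpa, n_vpa_tot - c.count_vpa)), "greater")
        for c in clusters])
    q_up = bh_adjust(p_up)
    q_down = bh_adjust(p_down)
    for i, c in enumerate(clusters):
        c.p_up, c.q_up = float(p_up[i]), float(q_up[i])
        c.p_down, c.q_down = float(p_down[i]), float(q_down[i])
        if c.q_up < alpha:
            c.status = "induced"
        elif c.q_down < alpha:
            c.status = "downregulated"
        else:
            c.status = "non_induced"
    return clusters


def promoter_region(gene: GeneModel, upstream: int = 1000,
                    noncoding_downstream: int = 500) -> GenomicInterval:
    """Promoter span: 1 kb upstream of the TSS to the translation start.

    For non-coding genes (no CDS) the surrogate [TSS - 1 kb, TSS + 500 bp)
    in transcript orientation is used.
    """
    t = gene.tss
    strand = gene.interval.strand
    if gene.cds_start is not None:
        if strand == "+":
            start, end = t - upstream, gene.cds_start
        else:
            start, end = gene.cds_start + 1, t + upstream + 1
    else:
        if strand == "+":
            start, end = t - upstream, t + noncoding_downstream
        else:
            start, end = t - noncoding_downstream + 1, t + upstream + 1
    start = max(0, start)
    if end <= start:  # CDS abutting/overrunning the TSS window
        end = start + 1
    return GenomicInterval(gene.interval.chrom, start, end, strand)


def promoter_overlap(clusters: list[TssCluster], genes: list[GeneModel],
                     ) -> tuple[dict[str, float], list[bool]]:
    """Flag clusters overlapping a same-strand promoter region.

    Returns per-status overlap fractions and the per-cluster flags.
    """
    promoters = [(promoter_region(g), g) for g in genes]
    index = IntervalIndex([p for p, _ in promoters])
    flags: list[bool] = []
    for c in clusters:
        hit = any(p.strand == c.interval.strand
                  for p in index.overlapping(c.interval))
        flags.append(hit)
    fractions: dict[str, float] = {}
    for status in ("induced", "downregulated", "non_induced"):
        grp = [f for c, f in zip(clusters, flags) if c.status == status]
        fractions[status] = (sum(grp) / len(grp)) if grp else float("nan")
    return fractions, flags


def exon1_ratio(genes: list[GeneModel], tags: list[CageTag],
                min_tags: int = 10) -> dict[str, list[float]]:
    """Per-gene first-exon tag share, separately per condition.

    A gene enters a condition's list when at least ``min_tags`` of that
    condition's tags fall (by 5' position) anywhere in the gene span; the
    ratio is first-exon tags / gene tags.  Genes without exons are skipped.
    """
    conditions = sorted({t.condition for t in tags})
    by_cond_chrom: dict[tuple[str, str], list[int]] = {}
    for t in tags:
        by_cond_chrom.setdefault((t.condition, t.interval.chrom), []).append(
            t.five_prime)
    sorted_pos = {k: np.sort(np.array(v, dtype=np.int64))
                  for k, v in by_cond_chrom.items()}
    out: dict[str, list[float]] = {c: [] for c in conditions}
    for g in genes:
        if not g.exons:
            continue
        e1 = g.first_exon
        for cond in conditions:
            pos = sorted_pos.get((cond, g.interval.chrom))
            if pos is None:
                continue
            n_gene = int(np.searchsorted(pos, g.interval.end)
                         - np.searchsorted(pos, g.interval.start))
            if n_gene < min_tags:
                continue
            n_e1 = int(np.searchsorted(pos, e1.end)
                       - np.searchsorted(pos, e1.start))
            out[cond].append(n_e1 / n_gene)
    return out


def tss_profile(dhss: TagLibrary, promoters: list[GeneModel],
                flank: int = 5000, bin_size: int = 500,
                outlier_fold: float = 10.0,
                exclude_chroms: tuple[str, ...] = ("chrM",)) -> TssProfile:
    """Average DNase tag TPM in ``bin_size`` bins within ±``flank`` of TSSs.

    Bins are orientation-flipped for minus-strand promoters so upstream is
    always to the left.  Promoters on excluded chromosomes are dropped
    up front; a second pass drops promoters with any bin exceeding
    ``outlier_fold`` times that bin's cross-promoter mean.
    """
    if flank % bin_size != 0:
        raise ValueError("flank must be a multiple of the bin size")
    n_bins = 2 * flank // bin_size
    offsets = np.arange(-flank, flank, bin_size)
    rows = []
    for g in promoters:
        if g.interval.chrom in exclude_chroms:
            continue
        t = g.tss
        pos = dhss.chrom_positions(g.interval.chrom)
        if g.interval.strand == "+":
            edges = t + np.arange(-flank, flank + bin_size, bin_size)
            counts = np.diff(np.searchsorted(pos, edges))
        else:
            # bin k covers offsets [-flank + k*bin, ...) downstream-flipped
            edges = (t + 1) - np.arange(-flank, flank + bin_size, bin_size)
            counts = np.diff(np.searchsorted(pos, edges[::-1]))[::-1]
        rows.append(counts * 1e6 / dhss.n_total)
    if not rows:
        return TssProfile(offsets, np.zeros(n_bins), 0, bin_size)
    mat = np.vstack(rows)
    bin_means = mat.mean(axis=0)
    with np.errstate(invalid="ignore"):
        keep = ~np.any((bin_means > 0) & (mat > outlier_fold * bin_means), axis=1)
    retained = mat[keep]
    mean_tpm = (retained.mean(axis=0) if retained.size
                else np.zeros(n_bins))
    return TssProfile(offsets, mean_tpm, int(keep.sum()), bin_size)


class TssActivityModel:
    """Promoter activity model over two CAGE libraries.

    Built from the pooled stranded tags and the per-condition library
    totals; ``fit`` clusters, filters and classifies, returning a
    :class:`TssResults`.
    """

    def __init__(self, tags: list[CageTag], totals: dict[str, int],
                 veh_label: str = "Veh", vpa_label: str = "VPA"):
        self.tags = tags
        self.totals = dict(totals)
        self.veh_label = veh_label
        self.vpa_label = vpa_label

    def fit(self, min_tpm: float = 10.0, alpha: float = 0.05) -> "TssResults":
        clusters = cluster_cage(self.tags, self.totals,
                                self.veh_label, self.vpa_label)
        kept = filter_tpm(clusters, min_tpm)
        classify_tss(kept, self.totals, alpha, self.veh_label, self.vpa_label)
        return TssResults(self, kept, min_tpm=min_tpm, alpha=alpha,
                          n_raw_clusters=len(clusters))


@dataclass
class TssResults:
    model: TssActivityModel
    clusters: list[TssCluster]
    min_tpm: float
    alpha: float
    n_raw_clusters: int

    def status_counts(self) -> dict[str, int]:
        counts = {"induced": 0, "downregulated": 0, "non_induced": 0}
        for c in self.clusters:
            counts[c.status] += 1
        return counts

    def summary(self) -> str:
        counts = self.status_counts()
        return "\n".join([
            "CAGE TSS clusters — single-linkage, Fisher/BH differential calls",
            "=" * 66,
            f"raw clusters            {self.n_raw_clusters:>10d}",
            f"clusters >= {self.min_tpm:g} TPM      {len(self.clusters):>10d}",
            f"  induced (VPA up)      {counts['induced']:>10d}",
            f"  downregulated         {counts['downregulated']:>10d}",
            f"  non-induced           {counts['non_induced']:>10d}",
        ])

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for c in self.clusters:
                iv = c.interval
                fh.write("\t".join(map(str, [
                    iv.chrom, iv.start, iv.end, c.status, 0, iv.strand,
                    c.count_veh, c.count_vpa,
                    f"{c.tpm_veh:.4f}", f"{c.tpm_vpa:.4f}",
                    f"{min(c.q_up, c.q_down):.6g}",
                ])) + "\n")
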