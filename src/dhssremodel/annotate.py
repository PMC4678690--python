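"""Region-set annotation and enrichment statistics.

Covers repeat-class assignment (longest-overlap winner plus an "any
overlap" variant), genomic-category labelling against gene models with
fixed precedence promoter > gene body > intergenic, nearest-feature
distance binning at the 1 kb / 1 Mb thresholds, and the overlap tests:
Fisher enrichment of one region set against a background, the analytic
binomial test for enhancer overlap under uniform placement, and a
Kolmogorov-Smirnov comparison of observed nearest distances against
those of uniformly re-placed intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .intervals import (
    NO_TARGET,
    GenomicInterval,
    GeneModel,
    IntervalIndex,
    NearestIndex,
    RepeatFeature,
    merge_intervals,
    overlap_length,
)
from .cage import promoter_region
from .stats import binomial_test_greater, fisher_one_tailed, ks_two_sample

PROXIMAL_MAX = 1_000
DISTAL_MIN = 1_000_000


@dataclass
class RegionAnnotation:
    region: GenomicInterval
    repeat_class: str | None = None
    repeat_family: str | None = None
    genomic_category: str = "intergenic"
    distance_to_nearest: dict[str, int] = field(default_factory=dict)


@dataclass
class DistanceBinSummary:
    """Counts of queries by nearest-target distance bin."""

    proximal: int = 0      # d < 1 kb
    semi_distal: int = 0   # 1 kb <= d <= 1 Mb
    distal: int = 0        # d > 1 Mb
    no_target: int = 0

    @property
    def total(self) -> int:
        return self.proximal + self.semi_distal + self.distal + self.no_target


def assign_repeat(region: GenomicInterval, repeats,
                  ) -> tuple[str, str] | None:
    """Longest-overlap repeat (class, family); deterministic tie-breaks.

    ``repeats`` is a list of :class:`RepeatFeature` or an
    :class:`IntervalIndex` over them.  Ties go to the longer repeat, then
    the leftmost start.
    """
    index = repeats if isinstance(repeats, IntervalIndex) else IntervalIndex(repeats)
    best = None
    best_key = None
    for rep in index.overlapping(region):
        ov = overlap_length(region, rep.interval)
        if ov <= 0:
            continue
        key = (ov, len(rep.interval), -rep.interval.start)
        if best_key is None or key > best_key:
            best, best_key = rep, key
    if best is None:
        return None
    return best.repeat_class, best.family


def any_overlap_class(region: GenomicInterval, repeats, wanted_class: str) -> bool:
    """True iff any overlapping repeat has ``wanted_class``."""
    index = repeats if isinstance(repeats, IntervalIndex) else IntervalIndex(repeats)
    return any(rep.repeat_class == wanted_class
               for rep in index.overlapping(region)
               if overlap_length(region, rep.interval) > 0)


class GeneAnnotator:
    """Caches promoter and gene-span indexes for category queries."""

    def __init__(self, genes: list[GeneModel]):
        self._promoters = IntervalIndex([promoter_region(g) for g in genes])
        self._bodies = IntervalIndex([g.interval for g in genes])

    def category(self, region: GenomicInterval) -> str:
        if self._promoters.overlapping(region):
            return "promoter"
        if self._bodies.overlapping(region):
            return "gene_body"
        return "intergenic"


def genomic_category(region: GenomicInterval, genes) -> str:
    """promoter > gene_body > intergenic, strand-blind overlap."""
    ann = genes if isinstance(genes, GeneAnnotator) else GeneAnnotator(genes)
    return ann.category(region)


def distance_bins(queries: list[GenomicInterval],
                  targets: list[GenomicInterval],
                  proximal_max: int = PROXIMAL_MAX,
                  distal_min: int = DISTAL_MIN) -> DistanceBinSummary:
    """Bin each query by its edge-to-edge distance to the nearest target."""
    index = NearestIndex(targets)
    out = DistanceBinSummary()
    for q in queries:
        d = index.distance(q)
        if d == NO_TARGET:
            out.no_target += 1
        elif d < proximal_max:
            out.proximal += 1
        elif d <= distal_min:
            out.semi_distal += 1
        else:
            out.distal += 1
    return out


def overlap_fisher(set_a_hits: int, set_a_total: int,
                   bg_hits: int, bg_total: int) -> tuple[float, float]:
    """Enrichment of hits in set A over background: (odds ratio, p).

    Odds ratio uses the Haldane 0.5 correction when any cell is zero.
    """
    if set_a_hits > set_a_total or bg_hits > bg_total:
        raise ValueError("hits may not exceed totals")
    a, b = set_a_hits, set_a_total - set_a_hits
    c, d = bg_hits, bg_total - bg_hits
    p = fisher_one_tailed(((a, b), (c, d)), "greater")
    if min(a, b, c, d) == 0:
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    return (a * d) / (b * c), p


def enhancer_binomial(queries: list[GenomicInterval],
                      enhancers: list[GenomicInterval],
                      chrom_sizes: dict[str, int]) -> float:
    """Binomial test of query/enhancer overlap against uniform placement.

    The null probability p0 that one uniformly placed interval of the mean
    query length overlaps the merged enhancer set is computed analytically:
    per chromosome the favourable start positions cover at most
    coverage + n_enhancers * (mean_len - 1) bases.
    """
    if not queries:
        raise ValueError("no query regions")
    merged = merge_intervals(enhancers)
    if not merged:
        return 1.0
    index = IntervalIndex(merged)
    k = sum(1 for q in queries if index.overlapping(q))
    mean_len = float(np.mean([len(q) for q in queries]))
    genome = sum(chrom_sizes.values())
    favourable = 0.0
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for e in merged:
        by_chrom.setdefault(e.chrom, []).append(e)
    for chrom, evs in by_chrom.items():
        size = chrom_sizes.get(chrom)
        if size is None:
            continue
        cov = sum(len(e) for e in evs)
        favourable += min(size, cov + len(evs) * (mean_len - 1.0))
    p0 = min(1.0, favourable / genome)
    return binomial_test_greater(k, len(queries), p0)


def place_uniform_intervals(lengths: np.ndarray, chrom_sizes: dict[str, int],
                            rng: np.random.Generator) -> list[GenomicInterval]:
    """Uniformly placed intervals with the given lengths (chromosome chosen
    proportionally to its length)."""
    chroms = sorted(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=np.float64)
    probs = sizes / sizes.sum()
    picks = rng.choice(len(chroms), size=len(lengths), p=probs)
    out = []
    for ln, ci in zip(lengths, picks):
        size = int(sizes[ci])
        ln = int(min(ln, size))
        start = int(rng.integers(0, max(1, size - ln + 1)))
        out.append(GenomicInterval(chroms[ci], start, start + ln))
    return out


def distance_ks_vs_random(queries: list[GenomicInterval],
                          targets: list[GenomicInterval],
                          chrom_sizes: dict[str, int],
                          n_random: int = 1000,
                          seed: int | np.random.Generator = 0,
                          ) -> tuple[float, float]:
    """KS test: observed nearest distances vs uniformly re-placed intervals.

    Random intervals resample the query length distribution with the
    seeded generator; queries on chromosomes without targets are excluded
    from both samples.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    index = NearestIndex(targets)
    obs = [index.distance(q) for q in queries]
    obs = [d for d in obs if d != NO_TARGET]
    if not obs:
        raise ValueError("no query has a same-chromosome target")
    lengths = rng.choice([len(q) for q in queries], size=n_random, replace=True)
    rand = [index.distance(iv)
            for iv in place_uniform_intervals(lengths, chrom_sizes, rng)]
    rand = [d for d in rand if d != NO_TARGET]
    return ks_two_sample(obs, rand)


def annotate_regions(regions: list[GenomicInterval],
                     repeats: list[RepeatFeature] | None = None,
                     genes: list[GeneModel] | None = None,
                     distance_sets: dict[str, list[GenomicInterval]] | None = None,
                     ) -> list[RegionAnnotation]:
    """Full per-region annotation used by the pipeline's TSV outputs."""
    rep_index = IntervalIndex(repeats) if repeats else None
    annot = GeneAnnotator(genes) if genes else None
    near = {name: NearestIndex(t) for name, t in (distance_sets or {}).items()}
    out = []
    for region in regions:
        ra = RegionAnnotation(region)
        if rep_index is not None:
            hit = assign_repeat(region, rep_index)
            if hit is not None:
                ra.repeat_class, ra.repeat_family = hit
        if annot is not None:
            ra.genomic_category = annot.category(region)
        for name, idx in near.items():
            ra.distance_to_nearest[name] = idx.distance(region)
        out.append(ra)
    return out
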