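"""Seeded synthetic genome, annotation and two-condition tag libraries.

The generator builds a toy genome with known planted structure so every
pipeline stage can be validated against ground truth:

* a uniform-random ACGT genome with a mappability track covering a
  configurable fraction of positions;
* non-overlapping gene models with exons and a CDS, RepeatMasker-style
  repeats with a realistic class mix, intergenic enhancer regions, and a
  forkhead-like consensus written into a fraction of SINE elements;
* DNase tag libraries for a vehicle and a VPA condition drawn from a
  piecewise-constant intensity: homogeneous background over mappable
  positions, a fold increase inside planted accessible regions (both
  conditions), and an extra VPA-only fold in the induced subset;
* CAGE tag libraries concentrated at promoters with sharp/broad shapes
  and planted up/down-regulated promoter sets.

Every product is a pure function of (config, seed): per-stage generators
are derived from the config seed with fixed stream offsets, so repeated
runs are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .intervals import (
    GenomicInterval,
    GeneModel,
    MappabilityTrack,
    RepeatFeature,
    TagLibrary,
    merge_intervals,
    write_bed,
    write_bed12_genes,
    write_repeats,
)
from .cage import CageTag

REPEAT_CLASS_MIX = {"SINE": 0.55, "LINE": 0.25, "LTR": 0.15, "DNA": 0.05}

REPEAT_LENGTHS = {  # sampling ranges, bp
    "SINE": (100, 300),
    "LINE": (400, 1500),
    "LTR": (300, 600),
    "DNA": (100, 400),
}

#: Forkhead-like fixtures in the two JASPAR dialects (synthetic matrices,
#: core consensus TGTTTAC as bound by Fox-family factors).
FOX_PFM_TEXT = """\
>SYNFOX1 synthetic-forkhead-1
A [  2  1  0  0  0  1 40  1 ]
C [  2  1  0  0  0  1  0 38 ]
G [ 34  1 40  0  0  0  0  1 ]
T [  2 37  0 40 40 38  0  0 ]
>SYNFOX2 synthetic-forkhead-2
1 36 0 0 0 38 2
1 1 0 0 0 1 36
36 1 0 0 0 0 1
2 2 40 40 40 1 1
"""

FOX_CONSENSUS = "GTGTTTAC"  # embedded into motif-carrying SINEs


@dataclass
class SimConfig:
    """Generator parameters; defaults define the standard study conditions."""

    seed: int = 0
    n_chroms: int = 3
    chrom_len: int = 2_000_000
    n_genes: int = 120
    n_repeats: int = 3_000
    repeat_class_mix: dict = field(default_factory=lambda: dict(REPEAT_CLASS_MIX))
    motif_fraction_sine: float = 0.3
    n_enhancers: int = 60
    n_dhss_regions: int = 300
    induced_fraction: float = 0.25
    base_rate: float = 5.0          # background tags per kb per library
    region_fold: float = 10.0       # accessibility fold inside planted regions
    induced_extra_fold: float = 5.0  # extra VPA-only fold in induced regions
    n_tags_dhss: int = 200_000
    n_tags_cage: int = 100_000
    cage_up_fraction: float = 0.1
    cage_down_fraction: float = 0.1
    cage_fold: float = 8.0
    cage_promoter_fraction: float = 0.9
    mappable_fraction: float = 0.9
    region_min_len: int = 500
    region_max_len: int = 1_500
    region_min_gap: int = 5_000

    def __post_init__(self) -> None:
        fracs = (self.motif_fraction_sine, self.induced_fraction,
                 self.cage_up_fraction, self.cage_down_fraction,
                 self.cage_promoter_fraction, self.mappable_fraction)
        if any(not (0.0 <= f <= 1.0) for f in fracs):
            raise ValueError("fractions must lie in [0, 1]")
        if min(self.chrom_len, self.n_tags_dhss, self.n_tags_cage) <= 0:
            raise ValueError("sizes and totals must be positive")

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]

    def chrom_sizes(self) -> dict[str, int]:
        return {c: self.chrom_len for c in self.chrom_names()}


@dataclass
class SyntheticTruth:
    """Ground-truth ledger of everything the generator planted."""

    planted_regions: list[GenomicInterval] = field(default_factory=list)
    region_labels: list[str] = field(default_factory=list)  # shared | vpa_induced
    up_promoters: list[str] = field(default_factory=list)
    down_promoters: list[str] = field(default_factory=list)
    sharp_promoters: list[str] = field(default_factory=list)
    motif_sines: list[GenomicInterval] = field(default_factory=list)
    enhancer_regions: list[GenomicInterval] = field(default_factory=list)

    @property
    def induced_regions(self) -> list[GenomicInterval]:
        return [iv for iv, lab in zip(self.planted_regions, self.region_labels)
                if lab == "vpa_induced"]

    @property
    def shared_regions(self) -> list[GenomicInterval]:
        return [iv for iv, lab in zip(self.planted_regions, self.region_labels)
                if lab == "shared"]

    def to_json(self, path) -> None:
        def ser(ivs):
            return [[iv.chrom, iv.start, iv.end] for iv in ivs]
        payload = {
            "planted_regions": ser(self.planted_regions),
            "region_labels": self.region_labels,
            "up_promoters": self.up_promoters,
            "down_promoters": self.down_promoters,
            "sharp_promoters": self.sharp_promoters,
            "motif_sines": ser(self.motif_sines),
            "enhancer_regions": ser(self.enhancer_regions),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            d = json.load(fh)

        def de(rows):
            return [GenomicInterval(c, s, e) for c, s, e in rows]
        return cls(de(d["planted_regions"]), d["region_labels"],
                   d["up_promoters"], d["down_promoters"],
                   d["sharp_promoters"], de(d["motif_sines"]),
                   de(d["enhancer_regions"]))


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


# stream offsets per stage keep stages independent of each other
_GENOME, _ANNOT, _DHSS, _CAGE, _QPCR = range(5)


def make_genome(config: SimConfig,
                ) -> tuple[dict[str, np.ndarray], dict[str, int], MappabilityTrack]:
    """Uniform-random genome plus mappability track.

    Sequences are returned as uint8 arrays over b"ACGT" (mutable so the
    annotation step can embed motif instances); the mappability track
    masks random 200 bp blocks to reach ``1 - mappable_fraction`` masked.
    """
    rng = _rng(config, _GENOME)
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    genome: dict[str, np.ndarray] = {}
    track: dict[str, list[GenomicInterval]] = {}
    block = 200
    for chrom in config.chrom_names():
        genome[chrom] = alphabet[rng.integers(0, 4, size=config.chrom_len)]
        n_blocks = config.chrom_len // block
        masked = rng.random(n_blocks) > config.mappable_fraction
        ivs = []
        for b in np.flatnonzero(~masked):
            ivs.append(GenomicInterval(chrom, b * block, min((b + 1) * block,
                                                             config.chrom_len)))
        tail = n_blocks * block
        if tail < config.chrom_len:
            ivs.append(GenomicInterval(chrom, tail, config.chrom_len))
        track[chrom] = merge_intervals(ivs)
    return genome, config.chrom_sizes(), MappabilityTrack(track)


def _place_nonoverlapping(rng: np.random.Generator, chroms: list[str],
                          chrom_len: int, n: int, min_len: int, max_len: int,
                          min_gap: int = 0, max_tries: int = 200_000,
                          avoid: list[GenomicInterval] | None = None,
                          ) -> list[GenomicInterval]:
    """Random intervals that neither overlap each other (plus gap) nor
    the optional avoid set."""
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    if avoid:
        for iv in avoid:
            placed.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out: list[GenomicInterval] = []
    tries = 0
    while len(out) < n:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {n} intervals after {max_tries} tries; "
                "reduce the count or lengths")
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        length = int(rng.integers(min_len, max_len + 1))
        start = int(rng.integers(0, chrom_len - length))
        lo, hi = start - min_gap, start + length + min_gap
        if any(s < hi and e > lo for s, e in placed[chrom]):
            continue
        placed[chrom].append((start, start + length))
        out.append(GenomicInterval(chrom, start, start + length))
    return out


def _make_gene(rng: np.random.Generator, span: GenomicInterval) -> GeneModel:
    strand = "+" if rng.random() < 0.5 else "-"
    n_exons = int(rng.integers(3, 9))
    length = len(span)
    # split the span into alternating exons/introns
    cuts = np.sort(rng.choice(np.arange(1, length), size=2 * n_exons - 2,
                              replace=False))
    bounds = np.concatenate([[0], cuts, [length]])
    exons = []
    for i in range(0, bounds.size - 1, 2):
        s, e = int(bounds[i]), int(bounds[i + 1])
        if e > s:
            exons.append(GenomicInterval(span.chrom, span.start + s,
                                         span.start + e, strand))
    iv = GenomicInterval(span.chrom, span.start, span.end, strand)
    genomic = sorted(exons, key=lambda e: e.start)
    first = genomic[0] if strand == "+" else genomic[-1]
    # translation start a little into the first exon
    if strand == "+":
        cds = min(first.start + int(rng.integers(30, 120)), first.end - 1)
    else:
        cds = max(first.end - 1 - int(rng.integers(30, 120)), first.start)
    return GeneModel(f"gene{span.chrom}_{span.start}", iv, cds, exons)


def make_annotation(config: SimConfig, genome: dict[str, np.ndarray],
                    ) -> tuple[list[GeneModel], list[RepeatFeature],
                               list[GenomicInterval], SyntheticTruth]:
    """Genes, repeats, enhancers and the truth ledger.

    Motif-carrying SINEs get the forkhead consensus written into the
    genome sequence at a random internal offset (the genome arrays are
    modified in place).
    """
    rng = _rng(config, _ANNOT)
    chroms = config.chrom_names()
    truth = SyntheticTruth()

    gene_spans = _place_nonoverlapping(rng, chroms, config.chrom_len,
                                       config.n_genes, 5_000, 30_000,
                                       min_gap=1_000)
    genes = [_make_gene(rng, span) for span in gene_spans]

    classes = list(config.repeat_class_mix)
    probs = np.array([config.repeat_class_mix[c] for c in classes])
    probs = probs / probs.sum()
    picks = rng.choice(len(classes), size=config.n_repeats, p=probs)
    repeats: list[RepeatFeature] = []
    consensus = np.frombuffer(FOX_CONSENSUS.encode(), dtype=np.uint8)
    for ci in picks:
        cls = classes[int(ci)]
        lo, hi = REPEAT_LENGTHS.get(cls, (100, 400))
        length = int(rng.integers(lo, hi + 1))
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        start = int(rng.integers(0, config.chrom_len - length))
        iv = GenomicInterval(chrom, start, start + length)
        family = "B1" if (cls == "SINE" and rng.random() < 0.6) else cls.lower()
        repeats.append(RepeatFeature(iv, cls, family,
                                     f"{cls}_{chrom}_{start}"))
        if cls == "SINE" and rng.random() < config.motif_fraction_sine:
            off = int(rng.integers(0, length - consensus.size))
            genome[chrom][start + off:start + off + consensus.size] = consensus
            truth.motif_sines.append(iv)

    gene_index = sorted(gene_spans, key=lambda iv: (iv.chrom, iv.start))
    enhancers = _place_nonoverlapping(rng, chroms, config.chrom_len,
                                      config.n_enhancers, 200, 400,
                                      min_gap=200, avoid=gene_index)
    truth.enhancer_regions = enhancers
    return genes, repeats, enhancers, truth


def plant_regions(config: SimConfig) -> SyntheticTruth:
    """Planted accessible regions with shared / vpa_induced labels."""
    rng = _rng(config, _ANNOT + 100)
    truth = SyntheticTruth()
    regions = _place_nonoverlapping(rng, config.chrom_names(),
                                    config.chrom_len, config.n_dhss_regions,
                                    config.region_min_len,
                                    config.region_max_len,
                                    min_gap=config.region_min_gap)
    n_induced = int(round(config.induced_fraction * len(regions)))
    induced_idx = set(map(int, rng.choice(len(regions), size=n_induced,
                                          replace=False)))
    truth.planted_regions = regions
    truth.region_labels = ["vpa_induced" if i in induced_idx else "shared"
                           for i in range(len(regions))]
    return truth


def _intensity_segments(config: SimConfig, truth: SyntheticTruth,
                        mappability: MappabilityTrack, condition: str,
                        ) -> list[tuple[str, int, int, float]]:
    """Atomic (chrom, start, end, fold) segments of mappable sequence."""
    fold_by_region: dict[tuple[str, int, int], float] = {}
    for iv, lab in zip(truth.planted_regions, truth.region_labels):
        fold = config.region_fold
        if lab == "vpa_induced" and condition == "VPA":
            fold *= config.induced_extra_fold
        fold_by_region[(iv.chrom, iv.start, iv.end)] = fold
    segments: list[tuple[str, int, int, float]] = []
    regions_by_chrom: dict[str, list[tuple[int, int, float]]] = {}
    for (chrom, s, e), f in fold_by_region.items():
        regions_by_chrom.setdefault(chrom, []).append((s, e, f))
    for chrom in regions_by_chrom:
        regions_by_chrom[chrom].sort()
    for chrom, ivs in mappability.intervals.items():
        regs = regions_by_chrom.get(chrom, [])
        for iv in ivs:
            cuts = {iv.start, iv.end}
            for s, e, _ in regs:
                if s < iv.end and e > iv.start:
                    cuts.add(max(s, iv.start))
                    cuts.add(min(e, iv.end))
            edges = sorted(cuts)
            for a, b in zip(edges, edges[1:]):
                fold = 1.0
                for s, e, f in regs:
                    if s <= a and b <= e:
                        fold = f
                        break
                segments.append((chrom, a, b, fold))
    return segments


def simulate_dhss(config: SimConfig, truth: SyntheticTruth,
                  mappability: MappabilityTrack,
                  ) -> tuple[TagLibrary, TagLibrary]:
    """Draw the two DNase tag libraries from the planted intensity."""
    rng = _rng(config, _DHSS)
    libs = []
    for condition in ("Veh", "VPA"):
        segments = _intensity_segments(config, truth, mappability, condition)
        weights = np.array([(e - s) * f for _, s, e, f in segments])
        probs = weights / weights.sum()
        n_total = int(rng.poisson(config.n_tags_dhss))
        counts = rng.multinomial(n_total, probs)
        by_chrom: dict[str, list[np.ndarray]] = {}
        for (chrom, s, e, _), k in zip(segments, counts):
            if k:
                by_chrom.setdefault(chrom, []).append(
                    rng.integers(s, e, size=k))
        positions = {c: np.sort(np.concatenate(parts))
                     for c, parts in sorted(by_chrom.items())}
        libs.append(TagLibrary(condition, positions))
    return libs[0], libs[1]


def simulate_cage(config: SimConfig, truth: SyntheticTruth,
                  genes: list[GeneModel],
                  ) -> tuple[list[CageTag], dict[str, int]]:
    """CAGE tag spans for both conditions plus library totals.

    90 % of expected tags land at promoters (sharp: Normal(TSS, 20 bp);
    broad: Uniform(TSS ± 150 bp), half of promoters each), the rest
    uniformly in the genome.  Per-promoter counts are independent Poisson
    draws, so up-regulated promoters show a VPA/vehicle count ratio of
    ``cage_fold`` (down-regulated the reciprocal) and the realized library
    totals float around ``n_tags_cage`` — as real libraries do.
    """
    rng = _rng(config, _CAGE)
    n_genes = len(genes)
    shuffled = rng.permutation(n_genes)
    n_up = int(round(config.cage_up_fraction * n_genes))
    n_down = int(round(config.cage_down_fraction * n_genes))
    up = set(map(int, shuffled[:n_up]))
    down = set(map(int, shuffled[n_up:n_up + n_down]))
    sharp = rng.random(n_genes) < 0.5
    base_weight = rng.gamma(2.0, 1.0, size=n_genes) + 0.1
    truth.up_promoters = [genes[i].name for i in sorted(up)]
    truth.down_promoters = [genes[i].name for i in sorted(down)]
    truth.sharp_promoters = [g.name for g, s in zip(genes, sharp) if s]

    chroms = config.chrom_names()
    tags: list[CageTag] = []
    totals: dict[str, int] = {}
    tag_len = 21
    # expected per-promoter rates, anchored to the vehicle library size
    lam_base = (base_weight / base_weight.sum()
                * config.cage_promoter_fraction * config.n_tags_cage)
    for condition in ("Veh", "VPA"):
        lam = lam_base.copy()
        if condition == "VPA":
            for i in up:
                lam[i] *= config.cage_fold
            for i in down:
                lam[i] /= config.cage_fold
        counts = rng.poisson(lam)
        n_prom = int(counts.sum())
        for gi, k in enumerate(counts):
            if k == 0:
                continue
            g = genes[gi]
            t = g.tss
            if sharp[gi]:
                offs = np.round(rng.normal(0.0, 20.0, size=k)).astype(np.int64)
            else:
                offs = rng.integers(-150, 151, size=k)
            # offsets follow transcript orientation
            if g.interval.strand == "+":
                fives = t + offs
            else:
                fives = t - offs
            fives = np.clip(fives, 0, config.chrom_len - 1)
            for f in fives:
                f = int(f)
                if g.interval.strand == "+":
                    s, e = f, min(f + tag_len, config.chrom_len)
                else:
                    s, e = max(0, f - tag_len + 1), f + 1
                tags.append(CageTag(GenomicInterval(g.interval.chrom, s, e,
                                                    g.interval.strand),
                                    condition))
        # uniform background, random strand
        n_bg = int(rng.poisson(
            (1.0 - config.cage_promoter_fraction) * config.n_tags_cage))
        bg_chrom = rng.integers(0, len(chroms), size=n_bg)
        bg_pos = rng.integers(0, config.chrom_len, size=n_bg)
        bg_strand = rng.random(n_bg) < 0.5
        for ci, pos, plus in zip(bg_chrom, bg_pos, bg_strand):
            pos = int(pos)
            if plus:
                s, e, st = pos, min(pos + tag_len, config.chrom_len), "+"
            else:
                s, e, st = max(0, pos - tag_len + 1), pos + 1, "-"
            tags.append(CageTag(GenomicInterval(chroms[int(ci)], s, e, st),
                                condition))
        totals[condition] = n_prom + n_bg
    return tags, totals


def simulate_qpcr(config: SimConfig, truth: SyntheticTruth,
                  n_primers: int = 8, n_replicates: int = 3) -> list[dict]:
    """Synthetic DNase qPCR validation panel.

    Primers anneal either inside planted induced regions ("induced") or at
    random genomic sites ("random"); accessible chromatin is digested, so
    its dCt (digested - undigested) is higher, and more so under VPA at
    induced sites.
    """
    rng = _rng(config, _QPCR)
    rows = []
    effects = {  # mean dCt per (category, condition)
        ("induced", "Veh"): 2.0, ("induced", "VPA"): 5.0,
        ("random", "Veh"): 0.5, ("random", "VPA"): 1.0,
    }
    for category in ("induced", "random"):
        for p in range(n_primers):
            for condition in ("Veh", "VPA"):
                for _ in range(n_replicates):
                    base = rng.uniform(20.0, 26.0)
                    dct = rng.normal(effects[(category, condition)], 0.4)
                    rows.append({
                        "primer_id": f"{category}_{p + 1}",
                        "condition": condition,
                        "ct_digested": round(base + max(0.0, dct), 3),
                        "ct_undigested": round(base, 3),
                    })
    return rows


def write_fasta(genome: dict[str, np.ndarray], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom, arr in genome.items():
            fh.write(f">{chrom}\n")
            seq = arr.tobytes().decode()
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_bundle(config: SimConfig, outdir) -> dict:
    """Generate everything and write the full input bundle to ``outdir``.

    Emits genome.fa, chrom.sizes, mappability.bed, DNase and CAGE tag BED
    files per condition, genes.bed12, repeats.bed, enhancers.bed,
    motifs.jaspar, qpcr.tsv and truth.json; returns the path map plus the
    in-memory objects.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    genome, chrom_sizes, mappability = make_genome(config)
    genes, repeats, enhancers, truth = make_annotation(config, genome)
    planted = plant_regions(config)
    truth.planted_regions = planted.planted_regions
    truth.region_labels = planted.region_labels
    veh, vpa = simulate_dhss(config, truth, mappability)
    cage_tags, cage_totals = simulate_cage(config, truth, genes)
    qpcr = simulate_qpcr(config, truth)

    paths = {k: out / v for k, v in {
        "genome": "genome.fa", "chrom_sizes": "chrom.sizes",
        "mappability": "mappability.bed",
        "dhss_veh": "dhss_veh.bed", "dhss_vpa": "dhss_vpa.bed",
        "cage_veh": "cage_veh.bed", "cage_vpa": "cage_vpa.bed",
        "genes": "genes.bed12", "repeats": "repeats.bed",
        "enhancers": "enhancers.bed", "motifs": "motifs.jaspar",
        "qpcr": "qpcr.tsv", "truth": "truth.json",
    }.items()}

    write_fasta(genome, paths["genome"])
    with open(paths["chrom_sizes"], "w") as fh:
        for chrom, size in chrom_sizes.items():
            fh.write(f"{chrom}\t{size}\n")
    flat = [iv for ivs in mappability.intervals.values() for iv in ivs]
    write_bed(flat, paths["mappability"])
    for lib, key in ((veh, "dhss_veh"), (vpa, "dhss_vpa")):
        with open(paths[key], "w") as fh:
            for chrom in sorted(lib.positions):
                for p in lib.positions[chrom]:
                    fh.write(f"{chrom}\t{p}\t{p + 1}\n")
    for condition, key in (("Veh", "cage_veh"), ("VPA", "cage_vpa")):
        with open(paths[key], "w") as fh:
            for t in cage_tags:
                if t.condition == condition:
                    iv = t.interval
                    fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t."
                             f"\t0\t{iv.strand}\n")
    write_bed12_genes(genes, paths["genes"])
    write_repeats(repeats, paths["repeats"])
    write_bed(enhancers, paths["enhancers"])
    with open(paths["motifs"], "w") as fh:
        fh.write(FOX_PFM_TEXT)
    with open(paths["qpcr"], "w") as fh:
        fh.write("primer_id\tcondition\tct_digested\tct_undigested\n")
        for row in qpcr:
            fh.write(f"{row['primer_id']}\t{row['condition']}"
                     f"\t{row['ct_digested']}\t{row['ct_undigested']}\n")
    truth.to_json(paths["truth"])

    return {
        "paths": {k: str(v) for k, v in paths.items()},
        "config": asdict(config),
        "genome": genome, "chrom_sizes": chrom_sizes,
        "mappability": mappability, "genes": genes, "repeats": repeats,
        "enhancers": enhancers, "truth": truth,
        "dhss": (veh, vpa), "cage": (cage_tags, cage_totals),
    }
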