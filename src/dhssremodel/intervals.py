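"""Genomic coordinate primitives and flat-file readers/writers.

Every coordinate in the package is 0-based, half-open ``[start, end)`` on a
named chromosome — the BED convention.  GTF-like inputs (1-based inclusive)
are converted on read.  Sequencing tags are reduced to their 5' end position
at load time; a tag belongs to a window iff its 5' end lies inside it.
Chromosome names are matched by exact string equality (no "chr" aliasing).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np

STRANDS = ("+", "-", ".")

REPEAT_CLASSES = ("SINE", "LINE", "LTR", "DNA", "Other")


class BedParseError(ValueError):
    """Raised for malformed BED-like lines; carries the offending line number."""


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """A 0-based half-open span ``[start, end)`` on a chromosome.

    ``strand`` is ``"+"``, ``"-"`` or ``"."`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class TagLibrary:
    """One condition's uniquely mapped 5'-end tag positions.

    ``positions`` maps chromosome name to a sorted int64 array of 0-based
    5' end positions; ``n_total`` is the library-wide mapped-tag total used
    for all normalisation (TPM, Fisher margins).
    """

    condition: str
    positions: dict[str, np.ndarray]
    n_total: int = 0

    def __post_init__(self) -> None:
        total = 0
        for chrom, pos in self.positions.items():
            arr = np.asarray(pos, dtype=np.int64)
            if arr.ndim != 1:
                raise ValueError("positions must be 1-D per chromosome")
            if arr.size > 1 and np.any(np.diff(arr) < 0):
                arr = np.sort(arr)
            self.positions[chrom] = arr
            total += arr.size
        if self.n_total == 0:
            self.n_total = total
        elif self.n_total != total:
            raise ValueError(
                f"n_total={self.n_total} does not match stored positions ({total})"
            )

    @classmethod
    def from_bed(cls, path, condition: str) -> "TagLibrary":
        """Load 5' tag positions from a BED file (strand-aware 5' end)."""
        by_chrom: dict[str, list[int]] = {}
        for iv in read_bed(path, stranded=True):
            five = iv.start if iv.strand != "-" else iv.end - 1
            by_chrom.setdefault(iv.chrom, []).append(five)
        return cls(condition, {c: np.sort(np.array(p, dtype=np.int64))
                               for c, p in sorted(by_chrom.items())})

    def chrom_positions(self, chrom: str) -> np.ndarray:
        return self.positions.get(chrom, np.empty(0, dtype=np.int64))


@dataclass
class GeneModel:
    """A gene/transcript model with strand, TSS, CDS start and exons.

    ``exons`` are stored in transcript orientation (5'->3'); on the minus
    strand the first exon is the genomically rightmost one.  ``cds_start``
    is the genomic base of the translation start (None for non-coding).
    """

    name: str
    interval: GenomicInterval
    cds_start: int | None = None
    exons: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError("gene models must be stranded")
        if self.exons:
            genomic = sorted(self.exons, key=lambda e: e.start)
            for a, b in zip(genomic, genomic[1:]):
                if a.end > b.start:
                    raise ValueError(f"overlapping exons in gene {self.name}")
            self.exons = genomic if self.interval.strand == "+" else genomic[::-1]

    @property
    def tss(self) -> int:
        """The transcription start base (0-based)."""
        if self.interval.strand == "+":
            return self.interval.start
        return self.interval.end - 1

    @property
    def first_exon(self) -> GenomicInterval | None:
        return self.exons[0] if self.exons else None


@dataclass(frozen=True)
class RepeatFeature:
    """A RepeatMasker-style annotated repeat."""

    interval: GenomicInterval
    repeat_class: str
    family: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        if self.repeat_class not in REPEAT_CLASSES:
            raise ValueError(
                f"repeat_class must be one of {REPEAT_CLASSES}, got "
                f"{self.repeat_class!r}"
            )


@dataclass
class MappabilityTrack:
    """Merged per-chromosome intervals of uniquely mappable k-mer starts."""

    intervals: dict[str, list[GenomicInterval]]

    def __post_init__(self) -> None:
        merged = {}
        for chrom, ivs in self.intervals.items():
            merged[chrom] = merge_intervals(ivs)
        self.intervals = merged
        # cached start/end arrays for vectorised overlap queries
        self._starts = {c: np.array([iv.start for iv in ivs], dtype=np.int64)
                        for c, ivs in self.intervals.items()}
        self._ends = {c: np.array([iv.end for iv in ivs], dtype=np.int64)
                      for c, ivs in self.intervals.items()}

    @classmethod
    def from_bed(cls, path) -> "MappabilityTrack":
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in read_bed(path):
            by_chrom.setdefault(iv.chrom, []).append(iv)
        return cls(by_chrom)

    def coverage_in(self, chrom: str, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        """Mappable bases inside each ``[start, end)`` query, vectorised."""
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        if chrom not in self._starts or self._starts[chrom].size == 0:
            return np.zeros(starts.shape, dtype=np.int64)
        s, e = self._starts[chrom], self._ends[chrom]
        # cumulative mappable bases up to each track interval boundary
        cum = np.concatenate([[0], np.cumsum(e - s)])

        def covered_upto(x):
            # first interval with end > x; earlier intervals count in full
            i = np.searchsorted(e, x, side="right")
            idx = np.minimum(i, s.size - 1)
            partial = np.where(i < s.size, np.clip(x - s[idx], 0, None), 0)
            return cum[i] + partial

        return covered_upto(ends) - covered_upto(starts)

    def total_coverage(self) -> int:
        return int(sum(int(np.sum(self._ends[c] - self._starts[c]))
                       for c in self._starts))


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_bed(path, stranded: bool = False) -> list[GenomicInterval]:
    """Read a BED3/BED6 file into intervals (file order preserved)."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: fewer than 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            strand = "."
            if stranded and len(fields) >= 6 and fields[5] in ("+", "-"):
                strand = fields[5]
            try:
                out.append(GenomicInterval(chrom, start, end, strand))
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed(intervals, path) -> None:
    """Write intervals as BED3 (unstranded) or BED6 lines."""
    with open(path, "w") as fh:
        for iv in intervals:
            if iv.strand == ".":
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")


def read_chrom_sizes(path) -> dict[str, int]:
    """Two-column ``chrom<TAB>length`` text file."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) < 2:
                raise BedParseError(f"{path}:{lineno}: need chrom and length")
            sizes[fields[0]] = int(fields[1])
    return sizes


def read_bed12_genes(path) -> list[GeneModel]:
    """Read BED12 gene models; thickStart==thickEnd marks non-coding."""
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise BedParseError(f"{path}:{lineno}: BED12 needs 12 columns")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            name, strand = f[3], f[5]
            thick_start, thick_end = int(f[6]), int(f[7])
            n_exons = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != n_exons or len(offsets) != n_exons:
                raise BedParseError(f"{path}:{lineno}: exon count mismatch")
            exons = [GenomicInterval(chrom, start + o, start + o + s, strand)
                     for o, s in zip(offsets, sizes)]
            cds_start: int | None
            if thick_start == thick_end:
                cds_start = None
            elif strand == "+":
                cds_start = thick_start
            else:
                cds_start = thick_end - 1
            genes.append(GeneModel(name, GenomicInterval(chrom, start, end, strand),
                                   cds_start, exons))
    return genes


def write_bed12_genes(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            iv = g.interval
            exons = sorted(g.exons, key=lambda e: e.start)
            sizes = ",".join(str(len(e)) for e in exons)
            offsets = ",".join(str(e.start - iv.start) for e in exons)
            if g.cds_start is None:
                thick_start = thick_end = iv.start
            elif iv.strand == "+":
                thick_start, thick_end = g.cds_start, iv.end
            else:
                thick_start, thick_end = iv.start, g.cds_start + 1
            fh.write("\t".join(map(str, [
                iv.chrom, iv.start, iv.end, g.name, 0, iv.strand,
                thick_start, thick_end, 0, len(exons), sizes, offsets,
            ])) + "\n")


def read_repeats(path) -> list[RepeatFeature]:
    """BED with three extra columns: repeat class, family, name."""
    out: list[RepeatFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise BedParseError(f"{path}:{lineno}: need class column")
            iv = GenomicInterval(f[0], int(f[1]), int(f[2]))
            family = f[4] if len(f) > 4 else ""
            name = f[5] if len(f) > 5 else ""
            try:
                out.append(RepeatFeature(iv, f[3], family, name))
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_repeats(repeats: list[RepeatFeature], path) -> None:
    with open(path, "w") as fh:
        for r in repeats:
            iv = r.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{r.repeat_class}"
                     f"\t{r.family}\t{r.name}\n")


# ---------------------------------------------------------------------------
# interval algebra
# ---------------------------------------------------------------------------

def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Shared bases between two half-open intervals; 0 across chromosomes."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def merge_intervals(intervals) -> list[GenomicInterval]:
    """Union of intervals as a sorted, non-overlapping list (strand dropped)."""
    if not intervals:
        return []
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    out: list[GenomicInterval] = []
    cur_chrom, cur_start, cur_end = ivs[0].chrom, ivs[0].start, ivs[0].end
    for iv in ivs[1:]:
        if iv.chrom == cur_chrom and iv.start <= cur_end:
            cur_end = max(cur_end, iv.end)
        else:
            out.append(GenomicInterval(cur_chrom, cur_start, cur_end))
            cur_chrom, cur_start, cur_end = iv.chrom, iv.start, iv.end
    out.append(GenomicInterval(cur_chrom, cur_start, cur_end))
    return out


def count_tags(library: TagLibrary, interval: GenomicInterval) -> int:
    """Tags whose 5' end lies in ``[start, end)``, by binary search."""
    pos = library.chrom_positions(interval.chrom)
    return int(np.searchsorted(pos, interval.end, side="left")
               - np.searchsorted(pos, interval.start, side="left"))


def count_tags_many(library: TagLibrary, chrom: str,
                    starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Vectorised :func:`count_tags` for many windows on one chromosome."""
    pos = library.chrom_positions(chrom)
    return (np.searchsorted(pos, ends, side="left")
            - np.searchsorted(pos, starts, side="left")).astype(np.int64)


NO_TARGET = -1


class NearestIndex:
    """Sorted per-chromosome index answering nearest-gap queries in O(log n)."""

    def __init__(self, targets):
        self._starts: dict[str, np.ndarray] = {}
        self._prefix_max_end: dict[str, np.ndarray] = {}
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for t in targets:
            by_chrom.setdefault(t.chrom, []).append(t)
        for chrom, ivs in by_chrom.items():
            ivs.sort(key=lambda iv: (iv.start, iv.end))
            starts = np.array([iv.start for iv in ivs], dtype=np.int64)
            ends = np.array([iv.end for iv in ivs], dtype=np.int64)
            self._starts[chrom] = starts
            self._prefix_max_end[chrom] = np.maximum.accumulate(ends)

    def distance(self, query: GenomicInterval) -> int:
        starts = self._starts.get(query.chrom)
        if starts is None or starts.size == 0:
            return NO_TARGET
        pmax = self._prefix_max_end[query.chrom]
        i = int(np.searchsorted(starts, query.end, side="left"))
        best = None
        if i > 0:
            # rightmost reach of any target starting before query.end
            if pmax[i - 1] > query.start:
                return 0
            best = query.start - int(pmax[i - 1])
        if i < starts.size:
            right = int(starts[i]) - query.end
            best = right if best is None else min(best, right)
        return int(max(0, best))


def nearest_distance(query: GenomicInterval, targets: list[GenomicInterval]) -> int:
    """Minimal edge-to-edge gap to any same-chromosome target (0 if overlap).

    Returns :data:`NO_TARGET` when no target shares the query's chromosome.
    For many queries against one target set build a :class:`NearestIndex`.
    """
    return NearestIndex(targets).distance(query)


class IntervalIndex:
    """Per-chromosome sorted index for overlap queries over a static set."""

    def __init__(self, intervals):
        self.by_chrom: dict[str, list] = {}
        for item in intervals:
            iv = item.interval if hasattr(item, "interval") else item
            self.by_chrom.setdefault(iv.chrom, []).append(item)
        self._starts: dict[str, list[int]] = {}
        self._max_len: dict[str, int] = {}
        for chrom, items in self.by_chrom.items():
            items.sort(key=lambda it: (it.interval if hasattr(it, "interval") else it).start)
            ivs = [(it.interval if hasattr(it, "interval") else it) for it in items]
            self._starts[chrom] = [iv.start for iv in ivs]
            self._max_len[chrom] = max((len(iv) for iv in ivs), default=0)

    def overlapping(self, query: GenomicInterval) -> list:
        """All stored items whose interval overlaps the query."""
        items = self.by_chrom.get(query.chrom)
        if not items:
            return []
        starts = self._starts[query.chrom]
        lo = bisect.bisect_left(starts, query.start - self._max_len[query.chrom])
        hi = bisect.bisect_left(starts, query.end)
        out = []
        for it in items[lo:hi]:
            iv = it.interval if hasattr(it, "interval") else it
            if iv.end > query.start and iv.start < query.end:
                out.append(it)
        return out
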