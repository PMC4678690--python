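"""PWM construction and relative-score motif scanning.

JASPAR-format count matrices are converted to log-odds weight matrices
against a uniform background with a split pseudocount, and sequences are
scanned on both strands.  A window's "similarity" is the relative score
(score - min) / (max - min) of its log-odds sum, the convention behind
percentage thresholds in classic TFBS scanning toolkits; hits are windows
at or above the threshold (default 0.8, i.e. 80 % similarity).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .intervals import GenomicInterval
from .stats import wilcoxon_greater

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = {0: 3, 1: 2, 2: 1, 3: 0}


@dataclass
class PositionFrequencyMatrix:
    """A 4 x W count matrix (rows A, C, G, T)."""

    motif_id: str
    name: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.float64)
        if self.counts.shape[0] != 4 or self.counts.shape[1] < 1:
            raise ValueError("counts must be 4 x W with W >= 1")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if np.any(self.counts.sum(axis=0) <= 0):
            raise ValueError("every column needs a positive sum")

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.counts, axis=0))


@dataclass
class ScoredMotif:
    """Log-odds weights plus attainable score bounds and the hit threshold."""

    motif_id: str
    name: str
    log_odds: np.ndarray
    min_score: float
    max_score: float
    threshold_rel: float = 0.8

    @property
    def width(self) -> int:
        return self.log_odds.shape[1]


@dataclass(frozen=True)
class MotifHit:
    region_id: str
    position: int
    strand: str
    rel_score: float


def read_jaspar(path) -> list[PositionFrequencyMatrix]:
    """Parse JASPAR PFM text, with or without ``A [ ... ]`` row labels."""
    motifs: list[PositionFrequencyMatrix] = []
    header: tuple[str, str] | None = None
    rows: list[list[float]] = []

    def flush():
        nonlocal header, rows
        if header is None:
            return
        if len(rows) != 4:
            raise ValueError(
                f"{path}: motif {header[0]} has {len(rows)} rows, expected 4")
        widths = {len(r) for r in rows}
        if len(widths) != 1:
            raise ValueError(f"{path}: motif {header[0]} row length mismatch")
        motifs.append(PositionFrequencyMatrix(header[0], header[1], np.array(rows)))
        header, rows = None, []

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                parts = line[1:].split(None, 1)
                header = (parts[0], parts[1] if len(parts) > 1 else parts[0])
                continue
            if header is None:
                raise ValueError(f"{path}: matrix row before any '>' header")
            body = line
            if body[0] in "ACGTacgt" and (len(body) == 1 or not body[1].isdigit()):
                body = body[1:]
            body = body.replace("[", " ").replace("]", " ")
            rows.append([float(x) for x in body.split()])
    flush()
    return motifs


def pfm_to_pwm(pfm: PositionFrequencyMatrix, pseudocount: float = 0.8,
               threshold_rel: float = 0.8) -> ScoredMotif:
    """Log-odds PWM against uniform background with split pseudocount.

    p_bj = (count_bj + pseudocount/4) / (colsum_j + pseudocount);
    weight = log2(p_bj / 0.25).
    """
    counts = pfm.counts
    colsum = counts.sum(axis=0)
    probs = (counts + pseudocount * 0.25) / (colsum + pseudocount)
    weights = np.log2(probs / 0.25)
    return ScoredMotif(pfm.motif_id, pfm.name, weights,
                       float(weights.min(axis=0).sum()),
                       float(weights.max(axis=0).sum()),
                       threshold_rel)


def _encode(sequence: str) -> np.ndarray:
    """A,C,G,T -> 0..3; anything else (incl. N) -> -1."""
    arr = np.frombuffer(sequence.upper().encode(), dtype=np.uint8)
    code = np.full(256, -1, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        code[ord(b)] = i
    return code[arr]


def scan_region(sequence: str, motif: ScoredMotif,
                region_id: str = "") -> list[MotifHit]:
    """Score every window of the motif width on both strands.

    Windows containing non-ACGT characters are skipped.  Hits are windows
    whose relative score reaches the motif's threshold.
    """
    span = motif.max_score - motif.min_score
    if span <= 0:
        raise ValueError(f"degenerate motif {motif.motif_id}: min == max score")
    w = motif.width
    enc = _encode(sequence)
    n_win = enc.size - w + 1
    if n_win <= 0:
        return []
    hits: list[MotifHit] = []
    # forward strand: sum weights at encoded bases per offset
    valid = enc >= 0
    win_valid = np.ones(n_win, dtype=bool)
    fwd = np.zeros(n_win)
    rev = np.zeros(n_win)
    safe = np.where(valid, enc, 0)
    for j in range(w):
        col = safe[j:j + n_win]
        win_valid &= valid[j:j + n_win]
        fwd += motif.log_odds[col, j]
        # reverse-complement: motif column w-1-j reads complement base
        comp = np.array([3, 2, 1, 0], dtype=np.int8)[col]
        rev += motif.log_odds[comp, w - 1 - j]
    for scores, strand in ((fwd, "+"), (rev, "-")):
        rel = (scores - motif.min_score) / span
        for pos in np.flatnonzero(win_valid & (rel >= motif.threshold_rel)):
            hits.append(MotifHit(region_id, int(pos), strand, float(rel[pos])))
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


def fetch_sequence(genome, region: GenomicInterval) -> str:
    """Region sequence from a dict of strings or a pyfaidx.Fasta."""
    try:
        seq = genome[region.chrom]
    except KeyError as exc:
        raise KeyError(f"chromosome {region.chrom} absent from genome") from exc
    chrom_len = len(seq)
    if region.end > chrom_len:
        raise ValueError(
            f"region {region.chrom}:{region.start}-{region.end} exceeds "
            f"chromosome length {chrom_len}")
    return str(seq[region.start:region.end])


def count_hits(regions: list[GenomicInterval], genome,
               motif: ScoredMotif) -> np.ndarray:
    """Per-region hit counts of one motif (both strands)."""
    return np.array([len(scan_region(fetch_sequence(genome, r), motif))
                     for r in regions], dtype=np.int64)


def compare_groups(regions_a: list[GenomicInterval],
                   regions_b: list[GenomicInterval],
                   genome, motifs: list[ScoredMotif],
                   ) -> list[dict]:
    """Per-motif hit counts in two region groups and one-tailed Wilcoxon p.

    Tests whether group A regions carry more matches than group B (the
    "A stochastically greater" direction).
    """
    out = []
    for motif in motifs:
        counts_a = count_hits(regions_a, genome, motif)
        counts_b = count_hits(regions_b, genome, motif)
        p = wilcoxon_greater(counts_a, counts_b)
        out.append({
            "motif_id": motif.motif_id,
            "name": motif.name,
            "counts_a": counts_a,
            "counts_b": counts_b,
            "p_value": p,
        })
    return out


def write_hits_bed(hits: list[tuple[GenomicInterval, MotifHit]],
                   motif_width: int, path) -> None:
    """Hits as BED6 with the relative score scaled x1000 in the score column."""
    with open(path, "w") as fh:
        for region, h in hits:
            start = region.start + h.position
            fh.write("\t".join(map(str, [
                region.chrom, start, start + motif_width, h.region_id,
                int(round(h.rel_score * 1000)), h.strand,
            ])) + "\n")
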