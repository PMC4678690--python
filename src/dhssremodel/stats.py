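"""Statistical primitives used throughout the pipeline.

All tests are implemented here directly on log-gamma / error-function
primitives rather than delegating to a statistics framework, so that the
exact tail conventions (one-tailed enrichment directions, continuity
corrections, BH step-up) are pinned down and unit-tested against
independent oracles.  Fisher's exact test works entirely in log space:
the Foxa2/SINE contingency table has a margin of ~1.5 million, where
direct factorials overflow.

p-values are reported at full floating precision; there is no flooring
at 2.2e-16 (that floor in published work is an artifact of the statistics
environment used there).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb, erfc, sqrt

import numpy as np
from scipy.special import betainc, gammaln, kolmogorov, logsumexp, stdtr


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts ``[[a, b], [c, d]]`` with rows = group and columns = outcome."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("at least one margin must be positive")


@dataclass(frozen=True)
class QpcrMeasurement:
    """One qPCR reaction pair: digested vs undigested template."""

    ct_digested: float
    ct_undigested: float
    primer_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        if not (np.isfinite(self.ct_digested) and np.isfinite(self.ct_undigested)):
            raise ValueError("Ct values must be finite")
        if self.ct_digested < 0 or self.ct_undigested < 0:
            raise ValueError("Ct values must be >= 0")


def _as_table(t) -> ContingencyTable2x2:
    if isinstance(t, ContingencyTable2x2):
        return t
    (a, b), (c, d) = t
    return ContingencyTable2x2(int(a), int(b), int(c), int(d))


def _log_hypergeom_pmf(x: np.ndarray, r1: int, r2: int, c1: int) -> np.ndarray:
    """log P(X = x) for X ~ Hypergeom(row margins r1, r2; column margin c1)."""
    x = np.asarray(x, dtype=np.float64)
    n = r1 + r2
    return (gammaln(r1 + 1) - gammaln(x + 1) - gammaln(r1 - x + 1)
            + gammaln(r2 + 1) - gammaln(c1 - x + 1) - gammaln(r2 - (c1 - x) + 1)
            - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1)))


def fisher_one_tailed(table, direction: str = "greater") -> float:
    """One-tailed Fisher's exact test on a 2x2 table, in log space.

    ``direction="greater"`` tests enrichment of outcome column 1 in row 1
    (P(X >= a) under the hypergeometric null); ``"less"`` is the lower tail.
    Degenerate margins give p = 1.
    """
    t = _as_table(table)
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    r1, r2 = t.a + t.b, t.c + t.d
    c1 = t.a + t.c
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    if lo == hi:  # single attainable table
        return 1.0
    if direction == "greater":
        support = np.arange(t.a, hi + 1)
    else:
        support = np.arange(lo, t.a + 1)
    logp = logsumexp(_log_hypergeom_pmf(support, r1, r2, c1))
    return float(min(1.0, np.exp(logp)))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order."""
    p = np.asarray(pvalues, dtype=np.float64)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _rank_with_ties(values: np.ndarray) -> np.ndarray:
    """Midranks (average ranks for ties), 1-based."""
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(values.size, dtype=np.float64)
    sv = values[order]
    i = 0
    while i < sv.size:
        j = i
        while j + 1 < sv.size and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


EXACT_WILCOXON_MAX_N = 12


def wilcoxon_greater(x, y) -> float:
    """One-tailed Wilcoxon rank-sum p for "x stochastically greater than y".

    Exact enumeration over all rank assignments when the pooled sample has
    at most 12 observations and no ties; otherwise the normal approximation
    with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    nx, ny = x.size, y.size
    n = nx + ny
    pooled = np.concatenate([x, y])
    ranks = _rank_with_ties(pooled)
    w_obs = ranks[:nx].sum()
    has_ties = np.unique(pooled).size < n
    if n <= EXACT_WILCOXON_MAX_N and not has_ties:
        count = 0
        total = 0
        for assign in combinations(range(1, n + 1), nx):
            total += 1
            if sum(assign) >= w_obs:
                count += 1
        return count / total
    mean = nx * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = nx * ny / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:  # all values identical
        return 1.0
    z = (w_obs - mean - 0.5) / sqrt(var)
    return 0.5 * erfc(z / sqrt(2.0))


def ks_two_sample(x, y) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov D and asymptotic p.

    D is the supremum ECDF distance; p uses the Kolmogorov limiting
    distribution with effective sample size n_x n_y / (n_x + n_y).
    """
    x = np.sort(np.asarray(x, dtype=np.float64))
    y = np.sort(np.asarray(y, dtype=np.float64))
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    grid = np.concatenate([x, y])
    cdf_x = np.searchsorted(x, grid, side="right") / x.size
    cdf_y = np.searchsorted(y, grid, side="right") / y.size
    d = float(np.max(np.abs(cdf_x - cdf_y)))
    en = sqrt(x.size * y.size / (x.size + y.size))
    p = float(np.clip(kolmogorov(en * d), 0.0, 1.0))
    return d, p


def welch_t_two_tailed(x, y, equal_var: bool = False) -> float:
    """Two-tailed two-sample t test p-value, unequal variance by default.

    The Welch statistic with Satterthwaite degrees of freedom; the pooled
    (Student) variant is exposed for completeness.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    nx, ny = x.size, y.size
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    diff = x.mean() - y.mean()
    if equal_var:
        sp2 = ((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2)
        se2 = sp2 * (1 / nx + 1 / ny)
        df = nx + ny - 2
    else:
        se2 = vx / nx + vy / ny
        if se2 > 0:
            df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
        else:
            df = nx + ny - 2
    if se2 == 0:
        return 1.0 if diff == 0 else 0.0
    t = diff / sqrt(se2)
    return float(2.0 * stdtr(df, -abs(t)))


def binomial_test_greater(k: int, n: int, p0: float) -> float:
    """Upper-tail P(X >= k) for X ~ Binomial(n, p0), in log space."""
    if not (0 <= k <= n):
        raise ValueError("need 0 <= k <= n")
    if not (0.0 <= p0 <= 1.0):
        raise ValueError("p0 must lie in [0, 1]")
    if k == 0:
        return 1.0
    if p0 == 0.0:
        return 0.0
    if p0 == 1.0:
        return 1.0
    tail = np.arange(k, n + 1, dtype=np.float64)
    if tail.size <= 100_000:
        logpmf = (gammaln(n + 1) - gammaln(tail + 1) - gammaln(n - tail + 1)
                  + tail * np.log(p0) + (n - tail) * np.log1p(-p0))
        return float(min(1.0, np.exp(logsumexp(logpmf))))
    # very long tails: exact identity P(X >= k) = I_{p0}(k, n - k + 1)
    return float(betainc(k, n - k + 1, p0))


def binomial_moments(n_trials: int, p: float) -> tuple[float, float]:
    """Mean and standard deviation of Binomial(n_trials, p)."""
    if n_trials < 0:
        raise ValueError("n_trials must be >= 0")
    if not (0.0 <= p <= 1.0):
        raise ValueError("p must lie in [0, 1]")
    e = n_trials * p
    return e, sqrt(n_trials * p * (1.0 - p))


def delta_ct(m: QpcrMeasurement) -> float:
    """qPCR accessibility statistic: Ct(digested) - Ct(undigested)."""
    return m.ct_digested - m.ct_undigested


def read_qpcr_tsv(path) -> list[QpcrMeasurement]:
    """Read 4-column TSV: primer_id, condition, ct_digested, ct_undigested."""
    out: list[QpcrMeasurement] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("primer_id"):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise ValueError(f"{path}:{lineno}: need 4 columns")
            out.append(QpcrMeasurement(float(f[2]), float(f[3]), f[0], f[1]))
    return out


def exact_wilcoxon_min_p(nx: int, ny: int) -> float:
    """Smallest attainable exact one-tailed rank-sum p (complete separation)."""
    return 1.0 / comb(nx + ny, nx)
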