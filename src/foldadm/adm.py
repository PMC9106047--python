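"""Average distance map (ADM) construction and compact-region detection.

An ADM is a contact-map-like boolean matrix built from sequence alone: a
pair (i, j) is plotted when the corpus-average distance d(type_i, type_j, M)
for its separation range M lies below a per-range cutoff.  Cutoffs are
calibrated so that the per-range plot density matches a target density
(by default the true Cα contact density of the statistics corpus at 8 Å).

A dense triangular block along the diagonal marks a segment predicted to
compact early in folding; its plot density is the η-value, and the region
with the highest η is called the primary region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .distance_stats import DistanceStatsTable, range_of
from .io_formats import STANDARD_AA, SequenceRecord

DEFAULT_MIN_LEN = 8
DEFAULT_MARGIN = 0.05


@dataclass
class ADMap:
    """Boolean strictly-upper-triangular plot matrix plus the cutoffs used."""

    n: int
    plot: np.ndarray  # (n, n) bool, plot[i, j] defined for i < j (0-based)
    cutoffs: dict[int, float]

    def density(self) -> float:
        """Overall plot density over all n(n−1)/2 pairs."""
        total = self.n * (self.n - 1) // 2
        return float(np.triu(self.plot, 1).sum()) / total if total else 0.0


@dataclass
class CompactRegion:
    start: int  # 1-based inclusive
    end: int
    eta: float
    rank: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def calibrate_cutoffs(
    stats: DistanceStatsTable, target_density: dict[int, float]
) -> dict[int, float]:
    """Per-range cutoff distances achieving the target plot densities.

    The cutoff for range M is the target-density quantile of the
    count-weighted distribution of table means in that range, so that the
    fraction of pair-type occurrences with mean below the cutoff equals the
    target within one table-entry granularity.  A range requested but absent
    from the table inherits the nearest lower range's cutoff.
    """
    cutoffs: dict[int, float] = {}
    available = stats.ranges()
    if not available:
        raise ValueError("cannot calibrate cutoffs on an empty stats table")
    for m in sorted(target_density):
        target = target_density[m]
        if not 0.0 <= target <= 1.0:
            raise ValueError(f"target density for range {m} outside [0, 1]: {target}")
        rows = [
            (mean, cnt)
            for (_, _, mm), (mean, _, cnt) in stats.entries.items()
            if mm == m and cnt > 0
        ]
        if not rows:
            lower = [mm for mm in available if mm < m]
            src = max(lower) if lower else min(available)
            warnings.warn(
                f"range {m} absent from stats table; inheriting cutoff of range {src}"
            )
            cutoffs[m] = cutoffs.get(src, _quantile_cutoff(stats, src, target))
            continue
        cutoffs[m] = _weighted_quantile(rows, target)
    return cutoffs


def _quantile_cutoff(stats: DistanceStatsTable, m: int, target: float) -> float:
    rows = [
        (mean, cnt)
        for (_, _, mm), (mean, _, cnt) in stats.entries.items()
        if mm == m and cnt > 0
    ]
    return _weighted_quantile(rows, target)


def _weighted_quantile(rows: list[tuple[float, int]], target: float) -> float:
    means = np.array([mu for mu, _ in rows])
    counts = np.array([c for _, c in rows], float)
    order = np.argsort(means)
    means, counts = means[order], counts[order]
    if target <= 0.0:
        return float(np.nextafter(means[0], -np.inf))
    cumfrac = np.cumsum(counts) / counts.sum()
    idx = int(np.searchsorted(cumfrac, target))
    idx = min(idx, len(means) - 1)
    # plot rule is strict (mean < cutoff): nudge just above the quantile mean
    return float(np.nextafter(means[idx], np.inf))


def build_adm(
    seq: SequenceRecord | str,
    stats: DistanceStatsTable,
    cutoffs: dict[int, float],
) -> ADMap:
    """Construct the ADM of a sequence from statistics and per-range cutoffs.

    plot(i, j) = [ d(type_i, type_j, M) < cutoff(M) ] with M = range_of(j − i);
    missing statistics keys and nonstandard residues produce no plot.  Ranges
    missing from ``cutoffs`` inherit the nearest lower supplied range.
    """
    s = seq.sequence if isinstance(seq, SequenceRecord) else str(seq).upper()
    n = len(s)
    plot = np.zeros((n, n), dtype=bool)
    filled = dict(cutoffs)
    if filled:
        supplied = sorted(filled)
        for m in range(1, range_of(max(n - 1, 1)) + 1):
            if m not in filled:
                lower = [mm for mm in supplied if mm < m]
                filled[m] = filled[max(lower)] if lower else filled[min(supplied)]
    for i in range(n - 1):
        if s[i] not in STANDARD_AA:
            continue
        for j in range(i + 1, n):
            if s[j] not in STANDARD_AA:
                continue
            m = range_of(j - i)
            mean = stats.mean(s[i], s[j], m)
            if mean is not None and m in filled and mean < filled[m]:
                plot[i, j] = True
    return ADMap(n=n, plot=plot, cutoffs=filled)


def eta(adm: ADMap, start: int, end: int) -> float:
    """Plot density η of the diagonal triangle spanned by [start, end] (1-based).

    η = (# plotted pairs with start ≤ i < j ≤ end) / (L(L−1)/2), L the
    segment length; it indexes the strength of predicted compactness.
    """
    if not 1 <= start < end <= adm.n:
        raise ValueError(f"invalid segment [{start}, {end}] for n={adm.n}")
    block = adm.plot[start - 1 : end, start - 1 : end]
    L = end - start + 1
    return float(np.triu(block, 1).sum()) / (L * (L - 1) // 2)


def detect_regions(
    adm: ADMap,
    min_len: int = DEFAULT_MIN_LEN,
    margin: float = DEFAULT_MARGIN,
) -> list[CompactRegion]:
    """Compact (high plot density) diagonal segments, ranked by η.

    All O(n²) diagonal segments of length ≥ min_len are scored exhaustively;
    segments with η ≥ global map density + margin are selected greedily by
    descending η (ties to the smaller start), suppressing overlaps.  Rank 1
    is the primary region.
    """
    if min_len < 4:
        raise ValueError("min_len must be at least 4")
    if margin < 0:
        raise ValueError("margin must be nonnegative")
    n = adm.n
    if n < min_len:
        return []
    threshold = adm.density() + margin
    # cumulative 2D sum for O(1) triangle counts
    upper = np.triu(adm.plot, 1).astype(np.int64)
    csum = upper.cumsum(axis=0).cumsum(axis=1)

    def block_count(s: int, e: int) -> int:  # 0-based inclusive
        total = csum[e, e]
        if s > 0:
            total -= csum[s - 1, e] + csum[e, s - 1] - csum[s - 1, s - 1]
        return int(total)

    candidates = []
    for s in range(n - min_len + 1):
        for e in range(s + min_len - 1, n):
            L = e - s + 1
            dens = block_count(s, e) / (L * (L - 1) // 2)
            if dens >= threshold:
                candidates.append((dens, s, e))
    # ties: smaller start, then the maximal (longer) segment
    candidates.sort(key=lambda t: (-t[0], t[1], -t[2]))
    chosen: list[CompactRegion] = []
    occupied = np.zeros(n, dtype=bool)
    for dens, s, e in candidates:
        if occupied[s : e + 1].any():
            continue
        occupied[s : e + 1] = True
        chosen.append(CompactRegion(start=s + 1, end=e + 1, eta=dens, rank=0))
    chosen.sort(key=lambda r: (-r.eta, r.start))
    for rank, region in enumerate(chosen, start=1):
        region.rank = rank
    return chosen
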