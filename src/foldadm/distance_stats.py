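"""Inter-residue average-distance statistics d(A, B, M).

For every unordered pair of residue types (A, B) and every sequence-
separation range M, the mean and population standard deviation of the
Cα–Cα distance is accumulated over a corpus of known structures.  These
statistics are the raw material of both the average distance map (ADM)
and the pairwise harmonic potential.

The separation k = |i − j| is binned into ranges:

    M = 1 : 1 ≤ k ≤ 8
    M = 2 : 9 ≤ k ≤ 20
    M = 3 : 21 ≤ k ≤ 30
    M = 4 : 31 ≤ k ≤ 40, and so on in decades.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import STANDARD_AA, ProteinChain


def range_of(k: int) -> int:
    """Sequence-separation range index M for a separation k = |i − j| ≥ 1."""
    if k <= 0:
        raise ValueError(f"sequence separation must be positive, got {k}")
    if k <= 8:
        return 1
    if k <= 20:
        return 2
    return 3 + (k - 21) // 10


@dataclass
class DistanceStatsTable:
    """d(A, B, M) lookup: (aaA ≤ aaB, M) → (mean Å, population SD Å, count).

    ``densities`` optionally carries per-range calibration target densities
    (plot-density targets for ADM cutoff tuning) measured on the same corpus.
    """

    entries: dict[tuple[str, str, int], tuple[float, float, int]] = field(
        default_factory=dict
    )
    densities: dict[int, float] = field(default_factory=dict)

    @staticmethod
    def key(aa1: str, aa2: str, m: int) -> tuple[str, str, int]:
        a, b = sorted((aa1, aa2))
        return (a, b, m)

    def get(self, aa1: str, aa2: str, m: int):
        """(mean, sd, count) for a pair-type/range key, or None if unobserved."""
        return self.entries.get(self.key(aa1, aa2, m))

    def mean(self, aa1: str, aa2: str, m: int) -> float | None:
        entry = self.get(aa1, aa2, m)
        return None if entry is None else entry[0]

    def ranges(self) -> list[int]:
        return sorted({m for _, _, m in self.entries})

    def range_pooled(self, m: int) -> tuple[float, float, int] | None:
        """Count-weighted pooled (mean, SD, count) over all pair types in range m.

        Used as the backoff distribution for pair types never observed in the
        corpus.  Pooled variance combines within- and between-key moments.
        """
        rows = [v for (_, _, mm), v in self.entries.items() if mm == m and v[2] > 0]
        if not rows:
            return None
        counts = np.array([c for _, _, c in rows], float)
        means = np.array([mu for mu, _, _ in rows])
        sds = np.array([sd for _, sd, _ in rows])
        total = counts.sum()
        pooled_mean = float((counts * means).sum() / total)
        pooled_var = float((counts * (sds**2 + means**2)).sum() / total) - pooled_mean**2
        return pooled_mean, float(np.sqrt(max(pooled_var, 0.0))), int(total)

    def total_count(self) -> int:
        return sum(c for _, _, c in self.entries.values())


def compute_stats(corpus: list[ProteinChain]) -> DistanceStatsTable:
    """Accumulate d(A, B, M) over every residue pair of every chain.

    Pairs involving nonstandard residue letters are excluded.  Sequence
    separation uses sequential positions on the stored chain (chain breaks
    do not interrupt the separation count).  SD is the population SD.
    """
    if not corpus:
        raise ValueError("empty corpus")
    # accumulate count, Σd, Σd² per key, then finalise
    acc: dict[tuple[str, str, int], list[float]] = {}
    for chain in corpus:
        if len(chain) < 2:
            raise ValueError(f"chain {chain.id!r} has fewer than 2 residues")
        coords = chain.ca_coords
        seq = chain.sequence
        n = len(seq)
        for i in range(n - 1):
            if seq[i] not in STANDARD_AA:
                continue
            d = np.linalg.norm(coords[i + 1 :] - coords[i], axis=1)
            for j in range(i + 1, n):
                if seq[j] not in STANDARD_AA:
                    continue
                key = DistanceStatsTable.key(seq[i], seq[j], range_of(j - i))
                slot = acc.setdefault(key, [0.0, 0.0, 0.0])
                dist = d[j - i - 1]
                slot[0] += 1.0
                slot[1] += dist
                slot[2] += dist * dist
    table = DistanceStatsTable()
    for key, (cnt, s1, s2) in acc.items():
        mean = s1 / cnt
        var = max(s2 / cnt - mean * mean, 0.0)
        table.entries[key] = (mean, float(np.sqrt(var)), int(cnt))
    return table


def contact_map(chain: ProteinChain, threshold: float) -> np.ndarray:
    """Boolean symmetric Cα contact map at a distance threshold (diagonal False)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    diff = chain.ca_coords[:, None, :] - chain.ca_coords[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    cmap = dist <= threshold
    np.fill_diagonal(cmap, False)
    return cmap


def contact_density_by_range(
    corpus: list[ProteinChain], threshold: float = 8.0
) -> dict[int, float]:
    """Fraction of residue pairs in contact, pooled over the corpus, per range M.

    This is the calibration target used to tune ADM cutoffs: the ADM plot
    density per range is matched to the true contact density of structures.
    Ranges with no eligible pairs are omitted.
    """
    if not corpus:
        raise ValueError("empty corpus")
    contacts: dict[int, int] = {}
    totals: dict[int, int] = {}
    for chain in corpus:
        cmap = contact_map(chain, threshold)
        n = len(chain)
        for i in range(n - 1):
            for j in range(i + 1, n):
                m = range_of(j - i)
                totals[m] = totals.get(m, 0) + 1
                if cmap[i, j]:
                    contacts[m] = contacts.get(m, 0) + 1
    return {m: contacts.get(m, 0) / t for m, t in sorted(totals.items())}
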