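"""Synthetic structure corpora, sequences and alignments for testing.

Everything here is generated programmatically and deterministically from a
seed: ideal helices, self-avoiding bead chains, planted-proximity corpora
(chains in which chosen residue-type pairs at a chosen separation range
are geometrically constrained to sit closer than background pairs), toy
alignments with planted conserved-hydrophobic columns, and a stats table
with a single planted attractive pair for Monte Carlo recovery tests.
Each stochastic generator also emits its ground truth so recovery tests
need no re-derivation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .distance_stats import DistanceStatsTable, range_of
from .io_formats import ProteinChain, SequenceRecord, Alignment, write_ca_chain
from .msa_chr import HYDROPHOBIC_SET
from .potential_mc import (
    BOND_LENGTH,
    HARD_CORE,
    Conformation,
    grow_self_avoiding,
)

#: default letters used for unconstrained (background) positions; none are
#: hydrophobic, so planted hydrophobic signals stay unambiguous
BACKGROUND_ALPHABET = "DEGKNQST"


# ---------------------------------------------------------------------------
# Deterministic geometric fixtures


def ideal_helix(n: int, rise: float = 1.5, radius: float = 2.3,
                turn_deg: float = 100.0) -> ProteinChain:
    """Cα trace of an ideal α-helix (poly-alanine).

    Defaults (1.5 Å rise, 2.3 Å radius, 100°/residue) give the canonical
    ~3.8 Å consecutive Cα–Cα distance and 3.6 residues per turn.
    """
    if n < 2:
        raise ValueError("helix needs at least 2 residues")
    t = np.arange(n) * np.deg2rad(turn_deg)
    coords = np.column_stack(
        [radius * np.cos(t), radius * np.sin(t), np.arange(n) * rise]
    )
    return ProteinChain("helix", "A" * n, coords)


def self_avoiding_chain(
    n: int, bond: float = BOND_LENGTH, core: float = HARD_CORE, seed: int | None = None
) -> Conformation:
    """Random self-avoiding bead chain with exact bond lengths."""
    if seed is None:
        raise ValueError("a seed is required")
    rng = np.random.default_rng(seed)
    return Conformation(grow_self_avoiding(n, bond, core, rng))


def write_chain(chain: ProteinChain) -> str:
    """PDB-format ATOM records for a fixture chain (io_formats-readable)."""
    return write_ca_chain(chain)


# ---------------------------------------------------------------------------
# Planted-proximity corpus


@dataclass
class PlantedCorpusSpec:
    """Recipe for a corpus with a planted short-distance pair-type signal.

    Within ``planted_segment`` of every chain, residues carry the planted
    types and all pairs at separation range ``planted_range`` are pulled
    toward ``planted_mean``; all other same-range pairs are pushed toward
    ``background_mean`` (where the chain geometry permits).  Pair targets
    are jittered by ``noise_sd``.
    """

    n_chains: int = 12
    chain_length: int = 40
    planted_pair_types: tuple[str, str] = ("I", "L")
    planted_range: int = 1
    planted_mean: float = 5.5
    background_mean: float = 12.0
    noise_sd: float = 1.0
    seed: int | None = None
    planted_segment: tuple[int, int] = (16, 24)  # 1-based inclusive

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if self.planted_mean >= self.background_mean:
            raise ValueError("planted_mean must be below background_mean")
        if self.chain_length < 2 or self.n_chains < 1:
            raise ValueError("corpus dimensions too small")
        s, e = self.planted_segment
        if not 1 <= s < e <= self.chain_length:
            raise ValueError("planted_segment outside the chain")
        if self.planted_mean < 1.2 * BOND_LENGTH or self.noise_sd < 0:
            raise ValueError("infeasible planted geometry")


@dataclass
class PlantedGroundTruth:
    """What the generator planted, for recovery assertions."""

    spec: PlantedCorpusSpec
    planted_keys: list[tuple[str, str, int]]
    segment: tuple[int, int]
    query: SequenceRecord


def planted_corpus(
    spec: PlantedCorpusSpec,
) -> tuple[list[ProteinChain], PlantedGroundTruth]:
    """Generate the corpus and its ground truth.

    Coordinates are produced by constraint projection: starting from a
    persistent random walk, pair distances are iteratively adjusted toward
    their targets with the virtual bonds re-projected to length b after
    every sweep, giving bounded runtime regardless of the target geometry.
    """
    rng = np.random.default_rng(spec.seed)
    a_type, b_type = spec.planted_pair_types
    chains = []
    for c in range(spec.n_chains):
        seq = _planted_sequence(spec, rng)
        coords = _persistent_walk(spec.chain_length, rng)
        constraints = _pair_constraints(spec, rng)
        coords = _project_constraints(coords, constraints, rng)
        chains.append(ProteinChain(f"planted{c}", seq, coords))
    planted_letters = sorted({a_type, b_type})
    planted_keys = sorted(
        {
            DistanceStatsTable.key(x, y, spec.planted_range)
            for x in planted_letters
            for y in planted_letters
        }
    )
    query = SequenceRecord("planted_query", chains[0].sequence)
    truth = PlantedGroundTruth(
        spec=spec,
        planted_keys=planted_keys,
        segment=spec.planted_segment,
        query=query,
    )
    return chains, truth


def _planted_sequence(spec: PlantedCorpusSpec, rng: np.random.Generator) -> str:
    s0, e0 = spec.planted_segment[0] - 1, spec.planted_segment[1] - 1
    letters = []
    background = [aa for aa in BACKGROUND_ALPHABET if aa not in spec.planted_pair_types]
    for i in range(spec.chain_length):
        if s0 <= i <= e0:
            letters.append(spec.planted_pair_types[int(rng.integers(2))])
        else:
            letters.append(background[int(rng.integers(len(background)))])
    return "".join(letters)


def _persistent_walk(n: int, rng: np.random.Generator,
                     bond: float = BOND_LENGTH) -> np.ndarray:
    """Near-extended random walk: slowly turning direction, exact bonds."""
    coords = np.zeros((n, 3))
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    for i in range(1, n):
        direction = direction + 0.25 * rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        coords[i] = coords[i - 1] + bond * direction
    return coords


def _pair_constraints(
    spec: PlantedCorpusSpec, rng: np.random.Generator
) -> list[tuple[int, int, float]]:
    """(i, j, target distance) list; only geometrically reachable targets."""
    s0, e0 = spec.planted_segment[0] - 1, spec.planted_segment[1] - 1
    out = []
    n = spec.chain_length
    for i in range(n - 1):
        for j in range(i + 2, n):  # k = 1 pairs are fixed by the bond
            k = j - i
            if range_of(k) != spec.planted_range:
                continue
            inside = s0 <= i <= e0 and s0 <= j <= e0
            base = spec.planted_mean if inside else spec.background_mean
            target = base + rng.normal(0.0, spec.noise_sd)
            reach = 0.93 * BOND_LENGTH * k
            target = float(np.clip(target, 0.45 * base, reach))
            out.append((i, j, target))
    return out


def _project_constraints(
    coords: np.ndarray,
    constraints: list[tuple[int, int, float]],
    rng: np.random.Generator,
    n_sweeps: int = 150,
    rate: float = 0.25,
    bond: float = BOND_LENGTH,
) -> np.ndarray:
    coords = coords.copy()
    for _ in range(n_sweeps):
        for i, j, target in constraints:
            v = coords[j] - coords[i]
            d = np.linalg.norm(v)
            if d < 1e-9:
                v = rng.normal(size=3)
                d = np.linalg.norm(v)
            shift = 0.5 * rate * (d - target) / d * v
            coords[i] += shift
            coords[j] -= shift
        # re-project bonds sequentially from the N terminus
        for i in range(1, len(coords)):
            v = coords[i] - coords[i - 1]
            d = np.linalg.norm(v)
            if d < 1e-9:
                v, d = rng.normal(size=3), 1.0
                d = np.linalg.norm(v)
            coords[i] = coords[i - 1] + bond * v / d
    return coords


# ---------------------------------------------------------------------------
# Planted single-pair attraction (for Monte Carlo / F-value recovery)


@dataclass
class PlantedPairStats:
    """Stats table with one strongly attractive long-range pair planted."""

    table: DistanceStatsTable
    sequence: SequenceRecord
    pair_positions: tuple[int, int]  # 1-based residue positions


def planted_pair_stats(
    n: int = 30,
    pair_positions: tuple[int, int] = (6, 24),
    rbar: float = 5.0,
    sigma: float = 0.5,
    background_sigma: float = 50.0,
) -> PlantedPairStats:
    """A sequence and stats table with exactly one strong long-range attraction.

    The two planted positions carry unique residue types (W, F); the key for
    their pair type at their separation range gets (rbar, sigma).  Every
    other pair-type/range key occurring in the sequence is present with a
    neutral broad entry (coil-like mean, huge σ → negligible force), so the
    range-level backoff never substitutes the planted parameters.
    """
    i, j = pair_positions
    if not 1 <= i < j <= n:
        raise ValueError("pair positions outside the chain")
    seq = ["G"] * n
    seq[i - 1], seq[j - 1] = "W", "F"
    sequence = SequenceRecord("planted_pair", "".join(seq))
    table = DistanceStatsTable()
    s = sequence.sequence
    for a in range(n - 1):
        for b in range(a + 2, n):
            k = b - a
            m = range_of(k)
            key = DistanceStatsTable.key(s[a], s[b], m)
            if key not in table.entries:
                # coil-like mean, far too soft to bias sampling
                table.entries[key] = (3.8 * np.sqrt(k), background_sigma, 100)
    planted_key = DistanceStatsTable.key("W", "F", range_of(j - i))
    table.entries[planted_key] = (rbar, sigma, 100)
    return PlantedPairStats(table=table, sequence=sequence, pair_positions=(i, j))


# ---------------------------------------------------------------------------
# Toy alignments


def toy_msa(
    query: SequenceRecord,
    n_seqs: int = 6,
    conserved_positions: list[int] | None = None,
    mutation_rate: float = 0.3,
    seed: int | None = None,
) -> Alignment:
    """Gapless toy MSA with hydrophobicity preserved at chosen positions.

    The query is record 0.  At conserved positions every sequence keeps the
    query's (hydrophobic) residue; elsewhere each non-query sequence mutates
    with probability ``mutation_rate`` to a random non-hydrophobic letter.
    """
    if seed is None:
        raise ValueError("a seed is required")
    conserved = set(conserved_positions or [])
    for p in conserved:
        if not 1 <= p <= len(query.sequence):
            raise ValueError(f"conserved position {p} outside the query")
        if query.sequence[p - 1] not in HYDROPHOBIC_SET:
            raise ValueError(f"query residue at {p} is not hydrophobic")
    rng = np.random.default_rng(seed)
    non_hydrophobic = [aa for aa in BACKGROUND_ALPHABET]
    records = [(query.id, query.sequence)]
    for k in range(1, n_seqs):
        row = []
        for p, aa in enumerate(query.sequence, start=1):
            if p in conserved or rng.random() >= mutation_rate:
                row.append(aa)
            else:
                row.append(non_hydrophobic[int(rng.integers(len(non_hydrophobic)))])
        records.append((f"homolog{k}", "".join(row)))
    return Alignment(records, query_index=0)
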