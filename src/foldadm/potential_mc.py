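"""Distance-statistics-derived harmonic potentials and bead-model Monte Carlo.

Each residue pair (i, j) with sequence separation ≥ k_min feels a harmonic
potential

    v_ij(r) = (r − r̄_ij)² / (2 σ_ij²)      [kT units]

whose minimum lies at the corpus-average distance r̄_ij for that pair type
and separation range; the Boltzmann weight exp(−v_ij) is then exactly the
Gaussian density with mean r̄_ij and SD σ_ij, so sampling with this
potential reproduces the distance statistics.  The additive normalisation
constant is dropped — only energy differences enter the Metropolis rule.

The chain is a bead model: one bead per residue at the Cα position, fixed
virtual bond length b = 3.8 Å, hard-core exclusion between beads at least
two apart.  Moves are single-bead crankshaft rotations (interior beads)
and free terminal rotations, both bond-length preserving.  Sampling the
resulting denatured-state ensemble yields the contact frequency g(i, j):
the fraction of recorded conformations with ‖x_i − x_j‖ below a contact
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .distance_stats import DistanceStatsTable, range_of
from .io_formats import SequenceRecord

BOND_LENGTH = 3.8  # Å, virtual Cα–Cα bond
HARD_CORE = 4.0  # Å, minimum non-adjacent bead separation
SIGMA_MIN = 0.5  # Å, floor on σ to avoid singular potentials
K_MIN = 2  # pairs with |i − j| < K_MIN are governed by the bond, not the potential
CONTACT_THRESHOLD = 8.0  # Å
DEFAULT_STEPS = 60_000
RECORD_EVERY = 10
BURN_IN_FRACTION = 0.1
ENERGY_CHECK_EVERY = 1_000


@dataclass
class HarmonicPairPotential:
    """v(r) = (r − r̄)²/(2σ²); v(r̄) = 0 and v(r̄ ± σ) = ½ kT."""

    rbar: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    def __call__(self, r: float) -> float:
        return pair_energy(r, self)


def pair_energy(r: float, pot: HarmonicPairPotential) -> float:
    """Harmonic pair energy in kT at Cα–Cα distance r (Å)."""
    if r <= 0:
        raise ValueError("distance must be positive")
    return (r - pot.rbar) ** 2 / (2.0 * pot.sigma**2)


@dataclass
class Conformation:
    """Bead Cα positions of a chain conformation."""

    coords: np.ndarray  # (n, 3) Å

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)

    def __len__(self) -> int:
        return len(self.coords)

    def validate(self, bond: float = BOND_LENGTH, core: float = HARD_CORE) -> None:
        bonds = np.linalg.norm(np.diff(self.coords, axis=0), axis=1)
        if not np.allclose(bonds, bond, atol=1e-6):
            raise ValueError("bond lengths deviate from the fixed virtual bond")
        d = _pairwise_distances(self.coords)
        n = len(self.coords)
        iu, ju = np.triu_indices(n, k=2)
        if n > 2 and d[iu, ju].min() < core - 1e-9:
            raise ValueError("hard-core overlap between non-adjacent beads")


@dataclass
class ContactStats:
    """Sampled contact frequencies g(i, j) plus run diagnostics."""

    g: np.ndarray  # (n, n) symmetric, zero diagonal band
    n_samples: int
    contact_threshold: float
    acceptance_ratio: float = float("nan")
    energy_drift: float = 0.0  # max |incremental − recomputed| energy, kT
    trajectory: list[np.ndarray] = field(default_factory=list, repr=False)

    def contact_degree(self) -> np.ndarray:
        """C_i = Σ_j g(i, j), the per-residue total contact frequency."""
        return self.g.sum(axis=1)


def _pairwise_distances(coords: np.ndarray) -> np.ndarray:
    diff = coords[:, None, :] - coords[None, :, :]
    return np.linalg.norm(diff, axis=-1)


# ---------------------------------------------------------------------------
# Pair-parameter assembly (with backoff for unobserved keys)


def build_pair_potentials(
    seq: str,
    stats: DistanceStatsTable | None,
    k_min: int = K_MIN,
    sigma_min: float = SIGMA_MIN,
    backoff: str = "range",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-pair (rbar, sigma, active) matrices for a sequence.

    ``backoff='range'`` substitutes the count-weighted range-level pooled
    mean/SD for pair-type keys absent from the table; a wholly absent range
    (or ``backoff='none'`` on a missing key) deactivates the pair, which
    then contributes no energy.  σ is floored at sigma_min.
    """
    if backoff not in ("range", "none"):
        raise ValueError(f"unknown backoff mode {backoff!r}")
    n = len(seq)
    rbar = np.zeros((n, n))
    sigma = np.ones((n, n))
    active = np.zeros((n, n), dtype=bool)
    if stats is None:
        return rbar, sigma, active
    pooled_cache: dict[int, tuple[float, float, int] | None] = {}
    for i in range(n):
        for j in range(i + k_min, n):
            m = range_of(j - i)
            entry = stats.get(seq[i], seq[j], m)
            if entry is None and backoff == "range":
                if m not in pooled_cache:
                    pooled_cache[m] = stats.range_pooled(m)
                entry = pooled_cache[m]
            if entry is None:
                continue
            mean, sd, _ = entry
            rbar[i, j] = rbar[j, i] = mean
            sigma[i, j] = sigma[j, i] = max(sd, sigma_min)
            active[i, j] = active[j, i] = True
    return rbar, sigma, active


def chain_energy(
    conf: Conformation,
    seq: str | SequenceRecord,
    stats: DistanceStatsTable | None,
    k_min: int = K_MIN,
    sigma_min: float = SIGMA_MIN,
    backoff: str = "range",
    hard_core: float | None = HARD_CORE,
) -> float:
    """Total chain energy in kT: Σ pair terms, +∞ on hard-core overlap."""
    s = seq.sequence if isinstance(seq, SequenceRecord) else str(seq)
    rbar, sigma, active = build_pair_potentials(s, stats, k_min, sigma_min, backoff)
    return _total_energy(conf.coords, rbar, sigma, active, hard_core)


def _total_energy(coords, rbar, sigma, active, hard_core) -> float:
    d = _pairwise_distances(coords)
    n = len(coords)
    if hard_core is not None and n > 2:
        iu, ju = np.triu_indices(n, k=2)
        if d[iu, ju].min() < hard_core:
            return float("inf")
    iu, ju = np.triu_indices(n, k=1)
    mask = active[iu, ju]
    dd = d[iu, ju][mask]
    return float(
        (((dd - rbar[iu, ju][mask]) ** 2) / (2.0 * sigma[iu, ju][mask] ** 2)).sum()
    )


# ---------------------------------------------------------------------------
# Self-avoiding initial chain


def grow_self_avoiding(
    n: int,
    bond: float = BOND_LENGTH,
    core: float = HARD_CORE,
    rng: np.random.Generator | None = None,
    max_restarts: int = 200,
    max_tries_per_bead: int = 60,
) -> np.ndarray:
    """Grow an n-bead chain with exact bond lengths and hard-core exclusion."""
    if n < 2:
        raise ValueError("need at least 2 beads")
    rng = np.random.default_rng() if rng is None else rng
    for _ in range(max_restarts):
        coords = np.zeros((n, 3))
        coords[1] = coords[0] + bond * _random_unit(rng)
        ok = True
        for i in range(2, n):
            placed = False
            for _ in range(max_tries_per_bead):
                candidate = coords[i - 1] + bond * _random_unit(rng)
                d = np.linalg.norm(coords[: i - 1] - candidate, axis=1)
                if d.min() >= core:
                    coords[i] = candidate
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            return coords
    raise RuntimeError(
        f"failed to grow a self-avoiding {n}-bead chain after {max_restarts} restarts"
    )


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _rotate_about_axis(v: np.ndarray, axis: np.ndarray, theta: float) -> np.ndarray:
    """Rodrigues rotation of vector v about unit axis by angle theta."""
    return (
        v * np.cos(theta)
        + np.cross(axis, v) * np.sin(theta)
        + axis * np.dot(axis, v) * (1.0 - np.cos(theta))
    )


# ---------------------------------------------------------------------------
# Metropolis Monte Carlo


def mc_sample(
    seq: str | SequenceRecord,
    stats: DistanceStatsTable | None,
    n_steps: int = DEFAULT_STEPS,
    seed: int | None = None,
    record_every: int = RECORD_EVERY,
    contact_threshold: float = CONTACT_THRESHOLD,
    burn_in_fraction: float = BURN_IN_FRACTION,
    k_min: int = K_MIN,
    bond: float = BOND_LENGTH,
    core: float | None = HARD_CORE,
    sigma_min: float = SIGMA_MIN,
    backoff: str = "range",
    keep_trajectory: bool = False,
    initial: Conformation | None = None,
) -> ContactStats:
    """Metropolis sampling of the bead-model denatured ensemble at kT = 1.

    One step is one attempted single-bead move.  Frames recorded every
    ``record_every`` steps after a burn-in of ``burn_in_fraction`` of the
    run accumulate the contact frequencies g(i, j).  Fully reproducible
    from ``seed``; passing ``stats=None`` with ``backoff='none'`` samples
    the zero-potential reference chain.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be positive")
    if seed is None:
        raise ValueError("a seed is required for reproducible sampling")
    s = seq.sequence if isinstance(seq, SequenceRecord) else str(seq)
    n = len(s)
    if n < 2:
        raise ValueError("sequence too short to sample")
    rng = np.random.default_rng(seed)
    rbar, sigma, active = build_pair_potentials(s, stats, k_min, sigma_min, backoff)
    inv2s2 = 1.0 / (2.0 * sigma**2)
    coords = (
        initial.coords.copy()
        if initial is not None
        else grow_self_avoiding(n, bond, core if core is not None else 0.0, rng)
    )
    energy = _total_energy(coords, rbar, sigma, active, core)
    burn_in = int(round(burn_in_fraction * n_steps))
    counts = np.zeros((n, n), dtype=np.int64)
    n_frames = 0
    n_accepted = 0
    max_drift = 0.0
    trajectory: list[np.ndarray] = []
    idx = np.arange(n)
    for step in range(1, n_steps + 1):
        m = int(rng.integers(n))
        if m == 0:
            new_pos = coords[1] + bond * _random_unit(rng)
        elif m == n - 1:
            new_pos = coords[n - 2] + bond * _random_unit(rng)
        else:
            axis = coords[m + 1] - coords[m - 1]
            norm = np.linalg.norm(axis)
            axis = axis / norm if norm > 1e-9 else _random_unit(rng)
            theta = rng.uniform(-np.pi, np.pi)
            new_pos = coords[m - 1] + _rotate_about_axis(
                coords[m] - coords[m - 1], axis, theta
            )
        d_new = np.linalg.norm(coords - new_pos, axis=1)
        accept = True
        if core is not None:
            far = np.abs(idx - m) >= 2
            if far.any() and d_new[far].min() < core:
                accept = False
        if accept:
            d_old = np.linalg.norm(coords - coords[m], axis=1)
            act = active[m]
            delta = float(
                (((d_new[act] - rbar[m, act]) ** 2 - (d_old[act] - rbar[m, act]) ** 2)
                 * inv2s2[m, act]).sum()
            )
            if delta > 0 and rng.random() >= np.exp(-delta):
                accept = False
        if accept:
            coords[m] = new_pos
            energy += delta
            n_accepted += 1
        if step % ENERGY_CHECK_EVERY == 0:
            full = _total_energy(coords, rbar, sigma, active, None)
            max_drift = max(max_drift, abs(full - energy))
            energy = full
        if step > burn_in and step % record_every == 0:
            d = _pairwise_distances(coords)
            counts += d <= contact_threshold
            n_frames += 1
            if keep_trajectory:
                trajectory.append(coords.copy())
    g = counts / n_frames if n_frames else counts.astype(float)
    # the diagonal band |i − j| < k_min is bond geometry, not contacts
    band = np.abs(idx[:, None] - idx[None, :]) < k_min
    g[band] = 0.0
    return ContactStats(
        g=g,
        n_samples=n_frames,
        contact_threshold=contact_threshold,
        acceptance_ratio=n_accepted / n_steps,
        energy_drift=max_drift,
        trajectory=trajectory,
    )


def reference_ensemble(
    seq: str | SequenceRecord,
    n_steps: int = DEFAULT_STEPS,
    seed: int | None = None,
    **kwargs,
) -> ContactStats:
    """Zero-potential null ensemble: bonds and hard core only.

    Serves as the baseline against which contact frequencies are
    standardised into F-values.
    """
    kwargs.pop("stats", None)
    kwargs.pop("backoff", None)
    return mc_sample(
        seq, stats=None, n_steps=n_steps, seed=seed, backoff="none", **kwargs
    )
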