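"""Per-residue F-value burial-tendency profiles from sampled contact statistics.

A residue that forms many contacts in the sampled denatured ensemble tends
to be buried early in folding.  The contact degree C_i = Σ_j g(i, j) under
the statistics-derived potential is standardised, residue by residue,
against replicate runs of the zero-potential reference ensemble:

    F(i) = (C_i − mean_r C_i^null(r)) / sd_r C_i^null(r)

an index corresponding to the z-value.  Peaks of the F profile — local
maxima rising above both flanking valleys by more than the intrinsic
fluctuation of the plot — mark predicted folding-initiation residues, and
are cross-referenced against conserved hydrophobic residues (CHRs) within
a ±5-residue window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .potential_mc import ContactStats

PEAK_WINDOW = 5  # residues, the ±window for peak–CHR matching


@dataclass
class FProfile:
    sequence: str
    F: np.ndarray  # per-residue standardized burial tendency
    F_sd: np.ndarray  # intrinsic fluctuation (SD over replicate runs)
    peaks: list[int] = field(default_factory=list)  # 1-based indices

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        self.F_sd = np.asarray(self.F_sd, dtype=float)
        if len(self.F) != len(self.sequence) or len(self.F_sd) != len(self.sequence):
            raise ValueError("profile arrays must match sequence length")
        if np.any(self.F_sd < 0):
            raise ValueError("F_sd must be nonnegative")


def f_values(
    g_pot: ContactStats,
    g_null_replicates: list[ContactStats],
    sequence: str = "",
    g_pot_replicates: list[ContactStats] | None = None,
    mode: str = "reference",
) -> FProfile:
    """Standardise contact degrees into the F-value profile.

    ``mode='reference'`` (default) is the z-score against the replicate
    zero-potential null ensembles; ``mode='internal'`` standardises C_i
    against the distribution of contact degrees over residues within the
    potential run itself.  ``g_pot_replicates`` (independent-seed runs with
    the potential) provide the per-residue intrinsic fluctuation F_sd;
    without them F_sd is 0 and peak finding falls back to a scalar.
    """
    c_pot = g_pot.contact_degree()
    n = len(c_pot)
    seq = sequence or "X" * n
    if len(seq) != n:
        raise ValueError("sequence length does not match contact matrix")
    if mode == "internal":
        mu, sd = float(c_pot.mean()), float(c_pot.std())
        if sd == 0:
            raise ValueError("degenerate contact-degree distribution")
        F = (c_pot - mu) / sd
        null_mu, null_sd = np.full(n, mu), np.full(n, sd)
    elif mode == "reference":
        if len(g_null_replicates) < 3:
            raise ValueError("need at least 3 null replicates to estimate the baseline")
        if any(r.g.shape != g_pot.g.shape for r in g_null_replicates):
            raise ValueError("null replicate shape mismatch")
        c_null = np.array([r.contact_degree() for r in g_null_replicates])
        null_mu = c_null.mean(axis=0)
        null_sd = c_null.std(axis=0, ddof=1)
        if np.any(null_sd == 0):
            bad = list(np.nonzero(null_sd == 0)[0] + 1)
            raise ValueError(
                f"zero null variance at residues {bad}; "
                "run more or longer reference ensembles"
            )
        F = (c_pot - null_mu) / null_sd
    else:
        raise ValueError(f"unknown standardization mode {mode!r}")
    if g_pot_replicates:
        reps = np.array(
            [(r.contact_degree() - null_mu) / null_sd for r in g_pot_replicates]
        )
        F_sd = reps.std(axis=0, ddof=1) if len(reps) > 1 else np.zeros(n)
    else:
        F_sd = np.zeros(n)
    profile = FProfile(sequence=seq, F=F, F_sd=F_sd)
    profile.peaks = find_peaks(profile)
    return profile


def find_peaks(profile: FProfile, fallback_fluct: float = 0.5) -> list[int]:
    """Peaks of the F plot under the valley-prominence rule (1-based indices).

    A peak is an interior local maximum (leftmost index of a plateau) whose
    height exceeds both flanking valleys — the minimum of F between it and
    the adjacent candidate maximum, or the terminus — by more than the
    intrinsic fluctuation: the maximum local F_sd over the valley-to-valley
    window, or ``fallback_fluct`` where F_sd is identically zero there.
    """
    F = profile.F
    n = len(F)
    if n < 3:
        return []
    candidates = _plateau_local_maxima(F)
    peaks = []
    for k, p in enumerate(candidates):
        left_bound = candidates[k - 1] if k > 0 else 0
        right_bound = candidates[k + 1] if k + 1 < len(candidates) else n - 1
        left_valley = F[left_bound:p + 1].min() if p > left_bound else F[0]
        right_valley = F[p:right_bound + 1].min() if right_bound > p else F[-1]
        window_sd = profile.F_sd[left_bound : right_bound + 1]
        fluct = float(window_sd.max()) if window_sd.size and window_sd.max() > 0 else fallback_fluct
        if F[p] - left_valley > fluct and F[p] - right_valley > fluct:
            peaks.append(p + 1)
    return peaks


def _plateau_local_maxima(F: np.ndarray) -> list[int]:
    """Interior local maxima; a flat plateau contributes its leftmost index."""
    n = len(F)
    out = []
    i = 1
    while i < n - 1:
        j = i
        while j + 1 < n and F[j + 1] == F[i]:
            j += 1
        if F[i] > F[i - 1] and j < n - 1 and F[i] > F[j + 1]:
            out.append(i)
        i = j + 1
    return out


def chr_near_peaks(
    peaks: list[int], chr_positions: list[int], window: int = PEAK_WINDOW
) -> list[tuple[int, int, int]]:
    """All (peak, CHR, offset) pairs with |CHR − peak| ≤ window residues.

    Offset is signed (CHR − peak); results sorted by |offset|, then peak,
    then CHR position.  The window boundary is inclusive.
    """
    matches = [
        (p, c, c - p)
        for p in peaks
        for c in chr_positions
        if abs(c - p) <= window
    ]
    matches.sort(key=lambda t: (abs(t[2]), t[0], t[1]))
    return matches
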