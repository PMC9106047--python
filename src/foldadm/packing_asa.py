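"""Residue-level accessible surface area and ΔASA packing-pair detection.

Residues are modelled as single Cα-centred spheres; the accessible surface
of each sphere is estimated Shrake–Rupley style on a deterministic
spiral (Fibonacci) lattice of directions, so results are seed-free.  Two
residues are "packed" when removing either one uncovers surface on the
other: ΔASA(i, j) = [ASA_i without j − ASA_i] + [ASA_j without i − ASA_j],
reported when it exceeds a threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import ProteinChain

RESIDUE_RADIUS = 3.0  # Å, Cα-sphere residue model
PROBE_RADIUS = 1.4  # Å, water probe
N_DIRECTIONS = 256
DELTA_ASA_THRESHOLD = 1.0  # Å²


@dataclass
class PackingPair:
    i: int  # 1-based residue indices, i < j
    j: int
    delta_asa: float  # Å² buried on pair contact

    def __post_init__(self) -> None:
        if self.i >= self.j:
            raise ValueError("packing pair requires i < j")
        if self.delta_asa < 0:
            raise ValueError("delta_asa must be nonnegative")


def spiral_directions(n: int) -> np.ndarray:
    """n near-uniform unit vectors on the sphere via the Fibonacci spiral."""
    k = np.arange(n)
    z = 1.0 - (2.0 * k + 1.0) / n
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(1.0 - z**2)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def asa(
    centers: np.ndarray,
    radii: np.ndarray | float,
    probe: float = PROBE_RADIUS,
    n_dirs: int = N_DIRECTIONS,
) -> np.ndarray:
    """Per-sphere solvent-accessible area in Å².

    Each sphere's accessible surface (radius r_i + probe) is sampled at
    ``n_dirs`` fixed lattice points; a point is exposed when outside every
    other sphere's accessible surface.  Exposed area = exposed fraction ×
    4π(r_i + probe)².
    """
    occluders = _occlusion_table(centers, radii, probe, n_dirs)
    centers = np.asarray(centers, float)
    radii = np.broadcast_to(np.asarray(radii, float), (len(centers),))
    areas = np.empty(len(centers))
    for i, occ in enumerate(occluders):
        exposed = (occ.sum(axis=1) == 0).mean() if occ.size else 1.0
        areas[i] = exposed * 4.0 * np.pi * (radii[i] + probe) ** 2
    return areas


def _occlusion_table(centers, radii, probe, n_dirs):
    """Per sphere: boolean (n_dirs, n_neighbors... n) table of which sphere
    occludes which surface sample point (self column always False)."""
    if probe < 0:
        raise ValueError("probe radius must be nonnegative")
    if n_dirs < 92:
        raise ValueError("need at least 92 sampling directions")
    centers = np.asarray(centers, float)
    n = len(centers)
    radii = np.broadcast_to(np.asarray(radii, float), (n,))
    dirs = spiral_directions(n_dirs)
    expanded = radii + probe
    tables = []
    for i in range(n):
        points = centers[i] + expanded[i] * dirs  # (n_dirs, 3)
        d2 = ((points[:, None, :] - centers[None, :, :]) ** 2).sum(-1)  # (n_dirs, n)
        occ = d2 < (expanded**2)[None, :] - 1e-9
        occ[:, i] = False
        tables.append(occ)
    return tables


def packing_pairs(
    chain: ProteinChain,
    threshold: float = DELTA_ASA_THRESHOLD,
    probe: float = PROBE_RADIUS,
    n_dirs: int = N_DIRECTIONS,
    radius: float = RESIDUE_RADIUS,
) -> list[PackingPair]:
    """Residue pairs packed by the ΔASA criterion, sorted by descending ΔASA.

    ΔASA(i, j) sums the surface each residue regains when the other is
    deleted from the structure; only mutually occluding pairs can score,
    and every unordered pair appears at most once.
    """
    if len(chain) < 2:
        raise ValueError("need at least 2 residues")
    centers = chain.ca_coords
    n = len(chain)
    tables = _occlusion_table(centers, radius, probe, n_dirs)
    point_area = 4.0 * np.pi * (radius + probe) ** 2 / n_dirs
    delta = np.zeros((n, n))
    for i, occ in enumerate(tables):
        n_occluders = occ.sum(axis=1)  # per sample point
        # removing j frees exactly the points occluded by j alone
        solo = occ[n_occluders == 1]
        if solo.size:
            delta[i] += solo.sum(axis=0) * point_area
    pairs = [
        PackingPair(i + 1, j + 1, float(delta[i, j] + delta[j, i]))
        for i in range(n)
        for j in range(i + 1, n)
        if delta[i, j] + delta[j, i] >= threshold
    ]
    pairs.sort(key=lambda p: (-p.delta_asa, p.i, p.j))
    return pairs


def asa_chain(chain: ProteinChain, probe: float = PROBE_RADIUS,
              n_dirs: int = N_DIRECTIONS, radius: float = RESIDUE_RADIUS) -> np.ndarray:
    """Per-residue ASA of a chain under the Cα-sphere residue model."""
    return asa(chain.ca_coords, radius, probe, n_dirs)
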