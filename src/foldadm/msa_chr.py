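"""Conserved hydrophobic residues (CHRs) from a multiple sequence alignment.

The hydrophobic set is {Ala, Phe, Ile, Leu, Met, Val, Trp, Tyr}.  An
ungapped query position is a CHR when the residue there is hydrophobic and
the fraction of non-gap residues in its alignment column that are
hydrophobic reaches a conservation threshold (default 1.0: hydrophobicity
maintained across every aligned homolog).  CHR positions are the anchors
compared against F-value peaks, and runs of CHRs inside helices render
hydrophobic-periodicity motifs such as φxxxφxxxφ.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .io_formats import STANDARD_AA, Alignment

HYDROPHOBIC_SET = frozenset("AFILMVWY")
PHI = "φ"


def hydrophobic(aa: str) -> bool:
    """True iff the one-letter residue is in the hydrophobic set {A,F,I,L,M,V,W,Y}."""
    aa = aa.upper()
    if aa not in STANDARD_AA:
        warnings.warn(f"nonstandard residue letter {aa!r} treated as non-hydrophobic")
        return False
    return aa in HYDROPHOBIC_SET


@dataclass
class CHRSet:
    """CHR positions (1-based on the ungapped query) with provenance."""

    positions: list[int]
    column_of: dict[int, int]  # query position → alignment column (1-based)
    fraction: dict[int, float]  # query position → hydrophobic column fraction
    threshold: float

    def __post_init__(self) -> None:
        if self.positions != sorted(self.positions):
            raise ValueError("CHR positions must be sorted ascending")


def conserved_hydrophobic_columns(aln: Alignment, min_fraction: float = 1.0) -> CHRSet:
    """CHR positions of the alignment's query sequence.

    Gaps are excluded from the column denominator; columns where the query
    is gapped (and gap-only columns) are skipped.
    """
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    query_aligned = aln.records[aln.query_index][1]
    positions: list[int] = []
    column_of: dict[int, int] = {}
    fraction: dict[int, float] = {}
    qpos = 0
    for col in range(aln.n_columns):
        q_aa = query_aligned[col]
        if q_aa == "-":
            continue
        qpos += 1
        column = [seq[col] for _, seq in aln.records if seq[col] != "-"]
        if not column:
            continue
        frac = sum(aa in HYDROPHOBIC_SET for aa in column) / len(column)
        column_of[qpos] = col + 1
        fraction[qpos] = frac
        if q_aa in HYDROPHOBIC_SET and frac >= min_fraction:
            positions.append(qpos)
    return CHRSet(
        positions=positions,
        column_of=column_of,
        fraction=fraction,
        threshold=min_fraction,
    )


def motif_pattern(chr_positions: list[int], start: int, end: int) -> str:
    """Render a segment's CHR arrangement as a φ/x motif string.

    Positions are 1-based on the query; the returned string has length
    end − start + 1 with 'φ' at CHR positions and 'x' elsewhere, the
    notation used for helix hydrophobic-periodicity motifs.
    """
    if start > end:
        raise ValueError("empty segment")
    inside = set(chr_positions) & set(range(start, end + 1))
    if set(chr_positions) - set(range(start, end + 1)):
        raise ValueError("CHR positions outside the segment")
    return "".join(PHI if p in inside else "x" for p in range(start, end + 1))
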