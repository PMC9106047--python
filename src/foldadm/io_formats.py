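"""Readers and writers for the on-disk formats used throughout the package.

Structures enter as PDB-format ATOM records (Cα only is retained), sequences
as FASTA, homolog sets as aligned FASTA, and the inter-residue distance
statistics as a 6-column TSV.  Residue indexing everywhere downstream is
1-based inclusive on the query sequence; author PDB numbering is kept only
as an annotation.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import protein_letters_3to1

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
#: letters tolerated in input sequences but excluded from all statistics
NONSTANDARD_AA = "XBZUO"


@dataclass
class ProteinChain:
    """One polypeptide chain reduced to its Cα trace.

    ``sequence`` holds one-letter residue types, ``ca_coords`` the matching
    Cα positions in Å and ``numbering`` the author residue numbers from the
    source file (annotation only; analysis positions are 1-based sequential).
    """

    id: str
    sequence: str
    ca_coords: np.ndarray  # (n, 3) float array, Å
    numbering: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.ca_coords = np.asarray(self.ca_coords, dtype=float)
        if not self.numbering:
            self.numbering = list(range(1, len(self.sequence) + 1))
        if self.ca_coords.shape != (len(self.sequence), 3):
            raise ValueError(
                f"chain {self.id!r}: {len(self.sequence)} residues but "
                f"coordinate array of shape {self.ca_coords.shape}"
            )
        if len(self.numbering) != len(self.sequence):
            raise ValueError(f"chain {self.id!r}: numbering length mismatch")
        if not np.all(np.isfinite(self.ca_coords)):
            raise ValueError(f"chain {self.id!r}: non-finite coordinates")
        if any(b <= a for a, b in zip(self.numbering, self.numbering[1:])):
            raise ValueError(f"chain {self.id!r}: numbering not strictly increasing")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SequenceRecord:
    id: str
    sequence: str

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - set(STANDARD_AA) - set(NONSTANDARD_AA)
        if bad:
            raise ValueError(f"record {self.id!r}: invalid letters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Alignment:
    """A multiple sequence alignment with one designated query record."""

    records: list[tuple[str, str]]
    query_index: int = 0

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("empty alignment")
        n = len(self.records[0][1])
        if any(len(s) != n for _, s in self.records):
            raise ValueError("ragged alignment: aligned sequences differ in length")
        if not 0 <= self.query_index < len(self.records):
            raise ValueError("query_index out of range")

    @property
    def n_columns(self) -> int:
        return len(self.records[0][1])

    @property
    def query(self) -> SequenceRecord:
        qid, aligned = self.records[self.query_index]
        return SequenceRecord(qid, aligned.replace("-", ""))


# ---------------------------------------------------------------------------
# PDB-format Cα reading / writing


def read_ca_chain(pdb_text: str, chain_id: str) -> ProteinChain:
    """Extract the Cα trace of one chain from PDB-format text.

    Only ATOM records of the first model are considered; for disordered
    atoms the altloc 'A' conformer is kept.  Residues without a Cα are
    skipped with a warning.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("x", io.StringIO(pdb_text))
    try:
        model = next(structure.get_models())
    except StopIteration:
        raise ValueError("no ATOM records found") from None
    chains = {c.id: c for c in model}
    if chain_id not in chains:
        raise ValueError(
            f"chain {chain_id!r} not found; available chains: {sorted(chains)}"
        )
    seq: list[str] = []
    coords: list[np.ndarray] = []
    numbering: list[int] = []
    for res in chains[chain_id]:
        het, resseq, _ = res.id
        if het.strip():  # HETATM / water
            continue
        if "CA" not in res:
            warnings.warn(
                f"residue {res.resname} {resseq} in chain {chain_id} has no CA; skipped"
            )
            continue
        atom = res["CA"]
        if atom.is_disordered():
            atom = atom.disordered_get("A") if atom.disordered_has_id("A") else atom
        seq.append(protein_letters_3to1.get(res.resname.strip(), "X"))
        coords.append(atom.get_coord())
        numbering.append(resseq)
    if not seq:
        raise ValueError(f"chain {chain_id!r} contains no CA atoms")
    return ProteinChain(chain_id, "".join(seq), np.array(coords, float), numbering)


def read_all_ca_chains(pdb_text: str) -> list[ProteinChain]:
    """All chains of the first model, each reduced to its Cα trace."""
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("x", io.StringIO(pdb_text))
    try:
        model = next(structure.get_models())
    except StopIteration:
        raise ValueError("no ATOM records found") from None
    chains = []
    for chain in model:
        try:
            chains.append(read_ca_chain(pdb_text, chain.id))
        except ValueError:
            continue  # chain without CA atoms (e.g. waters only)
    if not chains:
        raise ValueError("no chains with CA atoms found")
    return chains


_AA_1TO3 = {v: k for k, v in protein_letters_3to1.items()}


def write_ca_chain(chain: ProteinChain) -> str:
    """Render a chain as minimal PDB-format ATOM records (Cα only)."""
    lines = []
    cid = (chain.id[:1] or "A").upper()
    for i, (aa, xyz, num) in enumerate(
        zip(chain.sequence, chain.ca_coords, chain.numbering), start=1
    ):
        res3 = _AA_1TO3.get(aa, "UNK")
        lines.append(
            f"ATOM  {i:5d}  CA  {res3:<3s} {cid}{num:4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00           C"
        )
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# FASTA / aligned FASTA


def read_fasta(text: str) -> list[SequenceRecord]:
    """Parse FASTA text; order preserved, case-normalised to upper."""
    records = [
        SequenceRecord(rec.id, str(rec.seq).strip().upper())
        for rec in SeqIO.parse(io.StringIO(text), "fasta")
    ]
    if not records:
        raise ValueError("no FASTA records found")
    return records


def write_fasta(records: list[SequenceRecord]) -> str:
    return "".join(f">{r.id}\n{r.sequence}\n" for r in records)


def read_alignment(text: str, query_id: str | None = None) -> Alignment:
    """Parse an aligned FASTA file; the query defaults to the first record."""
    try:
        aln = AlignIO.read(io.StringIO(text), "fasta")
    except ValueError as exc:
        raise ValueError(f"could not parse alignment: {exc}") from exc
    records = [(rec.id, str(rec.seq).upper()) for rec in aln]
    qidx = 0
    if query_id is not None:
        ids = [rid for rid, _ in records]
        if query_id not in ids:
            raise ValueError(f"query {query_id!r} not in alignment; ids: {ids}")
        qidx = ids.index(query_id)
    return Alignment(records, qidx)


def write_alignment(aln: Alignment) -> str:
    return "".join(f">{rid}\n{seq}\n" for rid, seq in aln.records)


# ---------------------------------------------------------------------------
# Distance-statistics table TSV

STATS_COLUMNS = ["aa1", "aa2", "range", "mean_A", "sd_A", "count"]


def read_stats_table(tsv_text: str):
    """Read a distance-statistics TSV into a :class:`DistanceStatsTable`.

    Lines starting with ``#`` are comments; ``# density M value`` comments
    carry the per-range calibration target densities emitted by build-stats.
    """
    from .distance_stats import DistanceStatsTable

    densities: dict[int, float] = {}
    body_lines = []
    for line in tsv_text.splitlines():
        stripped = line.strip()
        if stripped.startswith("#"):
            parts = stripped[1:].split()
            if len(parts) == 3 and parts[0] == "density":
                densities[int(parts[1])] = float(parts[2])
            continue
        if stripped:
            body_lines.append(line)
    if not body_lines:
        raise ValueError("empty stats table")
    df = pd.read_csv(io.StringIO("\n".join(body_lines)), sep="\t")
    missing = set(STATS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"stats table missing columns: {sorted(missing)}")
    table = DistanceStatsTable()
    for a1, a2, m, mean, sd, cnt in df[STATS_COLUMNS].itertuples(index=False):
        a, b = sorted((str(a1), str(a2)))
        key = (a, b, int(m))
        if key in table.entries:
            raise ValueError(f"duplicate stats key {key}")
        if sd < 0 or cnt < 0:
            raise ValueError(f"negative sd or count for key {key}")
        table.entries[key] = (float(mean), float(sd), int(cnt))
    table.densities = densities
    return table


def write_stats_table(table) -> str:
    """Serialise a DistanceStatsTable (inverse of :func:`read_stats_table`)."""
    lines = []
    for m in sorted(table.densities):
        lines.append(f"# density {m} {table.densities[m]:.10g}")
    lines.append("\t".join(STATS_COLUMNS))
    for (a, b, m) in sorted(table.entries):
        mean, sd, count = table.entries[(a, b, m)]
        lines.append(f"{a}\t{b}\t{m}\t{mean:.10g}\t{sd:.10g}\t{count}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Report TSVs


def write_region_report(regions) -> str:
    """Region report TSV: start, end, eta, rank, primary_flag."""
    lines = ["start\tend\teta\trank\tprimary_flag"]
    for r in regions:
        lines.append(f"{r.start}\t{r.end}\t{r.eta:.6f}\t{r.rank}\t{int(r.rank == 1)}")
    return "\n".join(lines) + "\n"


def write_fprofile(profile) -> str:
    """F-profile TSV: index, residue, F, F_sd, peak_flag."""
    peaks = set(profile.peaks)
    lines = ["index\tresidue\tF\tF_sd\tpeak_flag"]
    for i, (aa, f, sd) in enumerate(
        zip(profile.sequence, profile.F, profile.F_sd), start=1
    ):
        lines.append(f"{i}\t{aa}\t{f:.6f}\t{sd:.6f}\t{int(i in peaks)}")
    return "\n".join(lines) + "\n"


def write_contact_matrix(stats) -> str:
    """Contact-frequency TSV with one ``i j g`` row per upper-triangle pair."""
    n = stats.g.shape[0]
    lines = ["i\tj\tg"]
    for i in range(n):
        for j in range(i + 1, n):
            lines.append(f"{i + 1}\t{j + 1}\t{stats.g[i, j]:.6f}")
    return "\n".join(lines) + "\n"
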