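"""Reading, writing and atom selection for conformational ensembles and MSAs.

Ensembles are stored as an F×A×3 coordinate array (Å) plus an ordered list of
:class:`AtomRecord`. Multi-model PDB files (one ``MODEL`` per frame) are the
on-disk carrier; reading and writing go through biotite, with an extra
per-model consistency check so a malformed file is rejected with the first
offending model named. Residue numbers are author numbering from the file,
1-based, and ranges are inclusive.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile
from Bio import SeqIO

STANDARD_RESIDUES = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR "
    "TRP TYR VAL".split()
)

# canonical intra-residue ordering used by selections
BACKBONE_ORDER = ("N", "CA", "C", "O")


class StructureIOError(ValueError):
    """Raised for malformed structure or alignment input."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the shared topology of an ensemble."""

    chain: str
    res_seq: int
    res_name: str
    atom_name: str
    element: str = ""

    @property
    def is_standard(self) -> bool:
        return self.res_name in STANDARD_RESIDUES


@dataclass
class ConformationEnsemble:
    """F frames × A atoms × 3 coordinates (Å) with a shared topology.

    Parameters
    ----------
    coords:
        Array of shape (F, A, 3); finite, Å.
    atoms:
        Length-A list of :class:`AtomRecord`; identical for every frame.
    frame_interval_ps:
        Time between frames in picoseconds, if known (metadata only).
    source_id:
        Label of the originating system (used in occupancy tables).
    """

    coords: np.ndarray
    atoms: list[AtomRecord]
    frame_interval_ps: float | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise StructureIOError(
                f"coords must be (F, A, 3), got {self.coords.shape}"
            )
        if self.coords.shape[0] < 1:
            raise StructureIOError("ensemble needs at least one frame")
        if self.coords.shape[1] != len(self.atoms):
            raise StructureIOError(
                f"{self.coords.shape[1]} coordinate columns vs "
                f"{len(self.atoms)} atom records"
            )
        if not np.all(np.isfinite(self.coords)):
            raise StructureIOError("non-finite coordinates in ensemble")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def atom_index(self, chain: str, res_seq: int, atom_name: str) -> int:
        for i, a in enumerate(self.atoms):
            if a.chain == chain and a.res_seq == res_seq and a.atom_name == atom_name:
                return i
        raise KeyError(f"atom {chain}:{res_seq}:{atom_name} not in ensemble")


@dataclass
class Msa:
    """A multiple sequence alignment: equal-length rows over 20 aa + '-'."""

    ids: list[str]
    rows: list[str]
    nonstandard_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise StructureIOError("ids and rows differ in length")
        if self.rows:
            ncol = len(self.rows[0])
            for sid, row in zip(self.ids, self.rows):
                if len(row) != ncol:
                    raise StructureIOError(
                        f"sequence {sid!r} has length {len(row)}, expected {ncol}"
                    )

    @property
    def n_seq(self) -> int:
        return len(self.rows)

    @property
    def n_col(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def column(self, j: int) -> str:
        return "".join(row[j] for row in self.rows)

    def to_array(self) -> np.ndarray:
        return np.array([list(r) for r in self.rows], dtype="U1")


def _scan_model_atom_counts(text: str) -> list[int]:
    """Count ATOM/HETATM records per MODEL block (whole file = one model if none)."""
    counts: list[int] = []
    current = 0
    in_model = False
    saw_model = False
    for line in text.splitlines():
        rec = line[:6].strip()
        if rec == "MODEL":
            saw_model = True
            in_model = True
            current = 0
        elif rec == "ENDMDL":
            counts.append(current)
            in_model = False
        elif rec in ("ATOM", "HETATM"):
            current += 1
    if not saw_model:
        return [current] if current else []
    if in_model:  # MODEL without ENDMDL
        counts.append(current)
    return counts


def read_multimodel_pdb(
    path: str | Path,
    frame_interval_ps: float | None = None,
    source_id: str | None = None,
) -> ConformationEnsemble:
    """Read a (multi-model) PDB file into a :class:`ConformationEnsemble`.

    One frame per ``MODEL`` record; a single-structure file yields F = 1.
    Atom order is taken from the first model and every further model must
    match it. Highest-occupancy altloc is kept (ties resolve to 'A').
    """
    path = Path(path)
    text = path.read_text()
    counts = _scan_model_atom_counts(text)
    if not counts:
        raise StructureIOError(f"{path}: no ATOM/HETATM records found")
    for k, c in enumerate(counts[1:], start=2):
        if c != counts[0]:
            raise StructureIOError(
                f"{path}: MODEL {k} has {c} atoms, expected {counts[0]} "
                f"(atom sets must match across models)"
            )
    pdb = PDBFile.read(io.StringIO(text))
    try:
        stack = pdb.get_structure(altloc="occupancy")
    except Exception as exc:  # biotite reports the offending line
        raise StructureIOError(f"{path}: unreadable coordinates ({exc})") from exc
    if isinstance(stack, bst.AtomArray):  # single model
        stack = bst.stack([stack])
    atoms = [
        AtomRecord(
            chain=str(stack.chain_id[i]),
            res_seq=int(stack.res_id[i]),
            res_name=str(stack.res_name[i]),
            atom_name=str(stack.atom_name[i]),
            element=str(stack.element[i]),
        )
        for i in range(stack.array_length())
    ]
    nonstd = sorted({a.res_name for a in atoms if not a.is_standard})
    if nonstd:
        warnings.warn(
            f"{path.name}: nonstandard residues {nonstd} parsed and flagged",
            stacklevel=2,
        )
    return ConformationEnsemble(
        coords=np.asarray(stack.coord, dtype=float),
        atoms=atoms,
        frame_interval_ps=frame_interval_ps,
        source_id=source_id if source_id is not None else path.stem,
    )


def write_multimodel_pdb(ens: ConformationEnsemble, path: str | Path) -> None:
    """Write an ensemble as a multi-model PDB (coordinates at 3 decimals)."""
    n = ens.n_atoms
    arr = bst.AtomArray(n)
    arr.chain_id = np.array([a.chain for a in ens.atoms])
    arr.res_id = np.array([a.res_seq for a in ens.atoms])
    arr.res_name = np.array([a.res_name for a in ens.atoms])
    arr.atom_name = np.array([a.atom_name for a in ens.atoms])
    arr.element = np.array(
        [a.element or a.atom_name[:1] for a in ens.atoms]
    )
    arr.hetero = np.array([a.res_name not in STANDARD_RESIDUES for a in ens.atoms])
    stack = bst.stack([arr] * ens.n_frames)
    stack.coord = np.asarray(ens.coords, dtype=np.float32)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def select_atoms(
    ens: ConformationEnsemble,
    chain: str | None = None,
    res_range: tuple[int, int] | None = None,
    atom_names: Iterable[str] | None = None,
) -> ConformationEnsemble:
    """Filter an ensemble by chain, inclusive residue range and atom names.

    Frame count and frame order are preserved. Within the selection, atoms
    are ordered residue-ascending then N, CA, C, O (then any other names
    alphabetically), the layout the loop coordinate matrix expects.
    """
    if res_range is not None and res_range[0] > res_range[1]:
        raise StructureIOError(
            f"empty residue range {res_range[0]}-{res_range[1]}"
        )
    names = set(atom_names) if atom_names is not None else None

    def keep(a: AtomRecord) -> bool:
        if chain is not None and a.chain != chain:
            return False
        if res_range is not None and not (res_range[0] <= a.res_seq <= res_range[1]):
            return False
        if names is not None and a.atom_name not in names:
            return False
        return True

    idx = [i for i, a in enumerate(ens.atoms) if keep(a)]
    if not idx:
        raise StructureIOError(
            f"empty selection: chain={chain!r} residues={res_range} "
            f"atoms={sorted(names) if names else 'any'}"
        )

    def sort_key(i: int) -> tuple:
        a = ens.atoms[i]
        try:
            rank = BACKBONE_ORDER.index(a.atom_name)
        except ValueError:
            rank = len(BACKBONE_ORDER)
        return (a.chain, a.res_seq, rank, a.atom_name)

    idx.sort(key=sort_key)
    return ConformationEnsemble(
        coords=ens.coords[:, idx, :],
        atoms=[ens.atoms[i] for i in idx],
        frame_interval_ps=ens.frame_interval_ps,
        source_id=ens.source_id,
    )


def read_fasta_alignment(path: str | Path) -> Msa:
    """Read an aligned FASTA file; rows must be equal length.

    Characters outside the 20 standard amino acids and '-' (e.g. 'X') are
    accepted but the sequence id is flagged in ``Msa.nonstandard_ids``.
    """
    path = Path(path)
    ids: list[str] = []
    rows: list[str] = []
    nonstd: list[str] = []
    standard = set("ACDEFGHIKLMNPQRSTVWY-")
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        ids.append(rec.id)
        rows.append(seq)
        if set(seq) - standard:
            nonstd.append(rec.id)
    if not rows:
        raise StructureIOError(f"{path}: no sequences found")
    ncol = len(rows[0])
    for sid, row in zip(ids, rows):
        if len(row) != ncol:
            raise StructureIOError(
                f"{path}: sequence {sid!r} has length {len(row)}, "
                f"expected {ncol} (alignment must be flush)"
            )
    return Msa(ids=ids, rows=rows, nonstandard_ids=nonstd)


def write_fasta_alignment(msa: Msa, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, row in zip(msa.ids, msa.rows):
            fh.write(f">{sid}\n{row}\n")


def rcl_position_labels(
    p1_res_seq: int = 358, first: int = 17, last_prime: int = 1
) -> dict[int, str]:
    """Map author residue numbers to serpin P-position labels.

    P-numbering counts outward from the scissile bond: P17…P1 run N-terminal
    of it and P1'… C-terminal. With the default α1-antitrypsin numbering the
    reactive-centre loop spans P17 = E342 through P1' = S359 (P1 = 358).
    The map is a labelling table only, never used in selection logic.
    """
    labels: dict[int, str] = {}
    for k in range(first, 0, -1):
        labels[p1_res_seq - k + 1] = f"P{k}"
    for k in range(1, last_prime + 1):
        labels[p1_res_seq + k] = f"P{k}'"
    return labels
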