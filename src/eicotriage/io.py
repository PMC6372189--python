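"""Primitive types and file I/O for the triage pipeline.

The pipeline works with four kinds of external data: protein sequences
(FASTA), reference multiple sequence alignments (aligned FASTA or
Stockholm), Calpha-only structures (PDB ATOM records), and tab-separated
annotation/report tables.  Everything is held in small frozen dataclasses
with 1-based inclusive residue numbering, which is how enzymologists write
catalytic positions (e.g. "R38 of human PTGES").

Selenocysteine (U) is a first-class residue letter: glutathione peroxidases
carry a catalytic selenocysteine that plain sequencing reports as cysteine,
and the screening stage treats C and U as functionally cognate.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import AlignIO, SeqIO

logger = logging.getLogger(__name__)

#: The 20 standard amino acids plus selenocysteine (U) and unknown (X).
ALPHABET = "ACDEFGHIKLMNPQRSTVWYUX"
_ALPHABET_SET = frozenset(ALPHABET)

#: Ambiguity codes collapsed to X on input (with a warning).
_AMBIGUOUS = {"B", "Z", "J"}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M", "SEC": "U",
}
ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
    "U": "SEC", "X": "UNK",
}


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def _normalize_residues(raw: str, *, record_id: str) -> str:
    """Upper-case, strip a terminal '*', map B/Z/J to X, validate."""
    s = raw.upper()
    if s.endswith("*"):
        s = s[:-1]
    out = []
    for offset, ch in enumerate(s):
        if ch in _AMBIGUOUS:
            logger.warning(
                "record %s: ambiguity code %s at offset %d mapped to X",
                record_id, ch, offset + 1,
            )
            ch = "X"
        if ch not in _ALPHABET_SET:
            raise FormatError(
                f"record {record_id!r}: illegal residue character {ch!r} "
                f"at offset {offset + 1}"
            )
        out.append(ch)
    if not out:
        raise FormatError(f"record {record_id!r}: empty sequence")
    return "".join(out)


@dataclass(frozen=True)
class ProteinSequence:
    """A protein sequence identified by an accession-like id."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "residues",
            _normalize_residues(self.residues, record_id=self.id),
        )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class Alignment:
    """A gapped multiple sequence alignment.

    ``rows`` is an ordered list of ``(sequence id, gapped string)``; every
    gapped string has the same length and de-gapping a row reproduces the
    source sequence.
    """

    rows: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        rows = tuple((rid, s.upper().replace(".", "-")) for rid, s in self.rows)
        if not rows:
            raise FormatError("alignment has no rows")
        width = len(rows[0][1])
        for rid, s in rows:
            if len(s) != width:
                raise FormatError(
                    f"ragged alignment: row {rid!r} has length {len(s)}, "
                    f"expected {width}"
                )
            for ch in s:
                if ch != "-" and ch not in _ALPHABET_SET:
                    raise FormatError(
                        f"row {rid!r}: illegal alignment character {ch!r}"
                    )
        object.__setattr__(self, "rows", rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0][1])

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(rid for rid, _ in self.rows)

    def row(self, rid: str) -> str:
        for r, s in self.rows:
            if r == rid:
                return s
        raise KeyError(rid)

    def degapped(self, rid: str) -> ProteinSequence:
        return ProteinSequence(id=rid, residues=self.row(rid).replace("-", ""))

    def column(self, j: int) -> str:
        """Residues (and gaps) of 0-based column ``j``."""
        return "".join(s[j] for _, s in self.rows)


@dataclass(frozen=True)
class CalphaStructure:
    """An ordered Calpha trace: (residue number, residue letter, x, y, z)."""

    id: str
    chain: str
    residues: tuple[tuple[int, str, float, float, float], ...]

    def __post_init__(self) -> None:
        if not self.residues:
            raise FormatError(f"structure {self.id!r}: no residues")
        prev = None
        for num, letter, x, y, z in self.residues:
            if prev is not None and num <= prev:
                raise FormatError(
                    f"structure {self.id!r}: residue numbers not strictly "
                    f"increasing at {num}"
                )
            if letter not in _ALPHABET_SET:
                raise FormatError(
                    f"structure {self.id!r}: illegal residue letter {letter!r}"
                )
            if not all(math.isfinite(v) for v in (x, y, z)):
                raise FormatError(
                    f"structure {self.id!r}: non-finite coordinate at "
                    f"residue {num}"
                )
            prev = num

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def numbers(self) -> tuple[int, ...]:
        return tuple(r[0] for r in self.residues)

    @property
    def letters(self) -> str:
        return "".join(r[1] for r in self.residues)

    def coords(self):
        import numpy as np

        return np.array([[x, y, z] for _, _, x, y, z in self.residues], float)

    def coord_of(self, resnum: int):
        for num, _letter, x, y, z in self.residues:
            if num == resnum:
                return (x, y, z)
        raise KeyError(resnum)

    def letter_of(self, resnum: int) -> str:
        for num, letter, *_ in self.residues:
            if num == resnum:
                return letter
        raise KeyError(resnum)


@dataclass(frozen=True)
class DomainArchitecture:
    """Ordered domain intervals along a protein (1-based inclusive)."""

    domains: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        prev_start = 0
        for name, start, end in self.domains:
            if start > end:
                raise ValueError(f"domain {name}: start {start} > end {end}")
            if start < 1:
                raise ValueError(f"domain {name}: start {start} < 1")
            if start < prev_start:
                raise ValueError("domains not ordered by start position")
            prev_start = start

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(d[0] for d in self.domains)


@dataclass(frozen=True)
class FunctionalResidueSet:
    """Annotated functional positions on a reference sequence.

    Each entry is ``(position, expected residue letter, role tag)``; the
    expected letter must match the reference residue at that position, which
    is checked when a reference sequence is supplied.
    """

    reference_id: str
    residues: tuple[tuple[int, str, str], ...]

    def validate_against(self, reference: ProteinSequence) -> None:
        if reference.id != self.reference_id:
            raise ValueError(
                f"reference id mismatch: {reference.id!r} != "
                f"{self.reference_id!r}"
            )
        for pos, letter, _role in self.residues:
            if not 1 <= pos <= len(reference):
                raise ValueError(
                    f"functional residue position {pos} outside reference "
                    f"length {len(reference)}"
                )
            actual = reference.residues[pos - 1]
            if actual != letter:
                raise ValueError(
                    f"functional residue {letter}{pos} does not match "
                    f"reference residue {actual} at that position"
                )

    def __len__(self) -> int:
        return len(self.residues)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[ProteinSequence]:
    """Read a FASTA file into a list of :class:`ProteinSequence`.

    Residues are upper-cased; a terminal ``*`` is stripped; B/Z/J are
    collapsed to X with a warning; any other non-alphabet character raises
    :class:`FormatError` naming the record and offset.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    out = []
    for rec in records:
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        out.append(ProteinSequence(id=rec.id, residues=str(rec.seq),
                                   description=desc))
    return out


def write_fasta(sequences: Iterable[ProteinSequence], path, width: int = 60) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for seq in sequences:
            header = seq.id if not seq.description else f"{seq.id} {seq.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(seq.residues), width):
                fh.write(seq.residues[i:i + width] + "\n")


def read_msa(path, dialect: str = "aligned-fasta") -> Alignment:
    """Read a multiple sequence alignment (aligned FASTA or Stockholm).

    ``.`` gap characters are normalized to ``-``; Stockholm annotation
    (``#=GC`` etc.) is ignored.  Ragged rows raise :class:`FormatError`.
    """
    fmt = {"aligned-fasta": "fasta", "stockholm": "stockholm"}.get(dialect)
    if fmt is None:
        raise ValueError(f"unknown MSA dialect {dialect!r}")
    path = Path(path)
    try:
        aln = AlignIO.read(str(path), fmt)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    return Alignment(rows=tuple((rec.id, str(rec.seq)) for rec in aln))


def write_msa(alignment: Alignment, path, dialect: str = "aligned-fasta") -> None:
    path = Path(path)
    if dialect == "aligned-fasta":
        with path.open("w") as fh:
            for rid, row in alignment.rows:
                fh.write(f">{rid}\n{row}\n")
    elif dialect == "stockholm":
        with path.open("w") as fh:
            fh.write("# STOCKHOLM 1.0\n")
            for rid, row in alignment.rows:
                fh.write(f"{rid} {row}\n")
            fh.write("//\n")
    else:
        raise ValueError(f"unknown MSA dialect {dialect!r}")


def read_calpha_pdb(path, chain: str | None = None, structure_id: str | None = None) -> CalphaStructure:
    """Read the Calpha trace of one chain from a PDB-format file.

    Only ``ATOM`` records with atom name CA are kept, from the first MODEL
    only, with altloc blank or 'A'.  ``chain`` defaults to the first chain
    encountered.  Three-letter codes map via the standard table (MSE -> M,
    SEC -> U, anything unknown -> X).  Insertion codes are tolerated on
    parse but dropped from the reported numbering (duplicate numbers after
    dropping the icode keep the first occurrence).
    """
    path = Path(path)
    residues: list[tuple[int, str, float, float, float]] = []
    seen: set[int] = set()
    wanted_chain = chain
    in_first_model = True
    model_seen = False
    with path.open() as fh:
        for line in fh:
            rec = line[:6]
            if rec == "MODEL ":
                if model_seen:
                    in_first_model = False
                model_seen = True
                continue
            if rec == "ENDMDL":
                in_first_model = False
                continue
            if not in_first_model or rec != "ATOM  ":
                continue
            atom_name = line[12:16].strip()
            if atom_name != "CA":
                continue
            altloc = line[16]
            if altloc not in (" ", "A"):
                continue
            line_chain = line[21]
            if wanted_chain is None:
                wanted_chain = line_chain
            if line_chain != wanted_chain:
                continue
            resname = line[17:20].strip()
            letter = THREE_TO_ONE.get(resname, "X")
            resnum = int(line[22:26])
            if resnum in seen:
                continue
            seen.add(resnum)
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
            residues.append((resnum, letter, x, y, z))
    if not residues:
        raise FormatError(
            f"{path}: no CA atoms found for chain {wanted_chain!r}"
        )
    return CalphaStructure(
        id=structure_id or path.stem,
        chain=wanted_chain or "A",
        residues=tuple(residues),
    )


def write_calpha_pdb(structure: CalphaStructure, path) -> None:
    """Write a Calpha-only PDB file that round-trips through the reader."""
    path = Path(path)
    with path.open("w") as fh:
        for i, (num, letter, x, y, z) in enumerate(structure.residues, 1):
            resname = ONE_TO_THREE[letter]
            fh.write(
                f"ATOM  {i:5d}  CA  {resname:>3s} {structure.chain}"
                f"{num:4d}    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
                f"           C\n"
            )
        fh.write("TER\nEND\n")


def read_functional_residues(path, reference_id: str) -> FunctionalResidueSet:
    """Read a functional-residue TSV with columns position/residue/role."""
    path = Path(path)
    residues = []
    with path.open() as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            residues.append(
                (int(row["position"]), row["residue"].upper(),
                 row.get("role", ""))
            )
    return FunctionalResidueSet(reference_id=reference_id,
                                residues=tuple(residues))


def write_functional_residues(frs: FunctionalResidueSet, path) -> None:
    with Path(path).open("w") as fh:
        fh.write("position\tresidue\trole\n")
        for pos, letter, role in frs.residues:
            fh.write(f"{pos}\t{letter}\t{role}\n")


def write_report_tsv(records: Sequence[dict], path, columns: Sequence[str] | None = None) -> None:
    """Write a list of flat record dicts as a TSV report.

    The header is the union of keys in first-seen order (or ``columns``).
    Values containing a tab or newline are rejected: they would corrupt the
    delimiter structure.
    """
    path = Path(path)
    if columns is None:
        cols: list[str] = []
        for rec in records:
            for key in rec:
                if key not in cols:
                    cols.append(key)
        columns = cols
    with path.open("w") as fh:
        fh.write("\t".join(columns) + "\n")
        for rec in records:
            cells = []
            for col in columns:
                val = rec.get(col, "")
                text = "" if val is None else str(val)
                if "\t" in text or "\n" in text:
                    raise ValueError(
                        f"field {col!r} contains a delimiter character: "
                        f"{text!r}"
                    )
                cells.append(text)
            fh.write("\t".join(cells) + "\n")


def read_report_tsv(path) -> list[dict]:
    with Path(path).open() as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        return [dict(row) for row in reader]
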