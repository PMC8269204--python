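"""Sequence and alignment I/O with strict alphabet validation.

Protein sequences are restricted to the 20 canonical amino acids plus 'X'
(unknown).  Other ambiguity codes ('B', 'Z', 'J', 'U', 'O') are rejected at
parse time so that downstream positional-probability arithmetic stays
well-defined; 'X' contributes the background probability wherever an emission
probability is needed.

All residue coordinates reported by this package are 1-based inclusive,
following the convention used for active-site annotations of halogenases
(e.g. "Trp1, amino acids 50 to 55").
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

from Bio import AlignIO, SeqIO

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
VALID_RESIDUES = frozenset(AMINO_ACIDS + "X")
GAP_CHARS = frozenset("-.")


class ParseError(ValueError):
    """Malformed sequence input (bad header, illegal residue, ...)."""


class AlignmentError(ValueError):
    """Rows of an alignment are inconsistent (ragged, too few, ...)."""


@dataclass(frozen=True)
class SequenceRecord:
    """A single protein sequence.

    ``residues`` contains only uppercase characters from the 20-letter amino
    acid alphabet plus 'X'; ``id`` contains no whitespace.
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ParseError(f"sequence id {self.id!r} is empty or contains whitespace")
        if not self.residues:
            raise ParseError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - VALID_RESIDUES
        if bad:
            raise ParseError(
                f"sequence {self.id!r} contains illegal residue(s) {sorted(bad)}; "
                f"allowed: 20 amino acids plus X"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class MultipleAlignment:
    """An MSA: equal-length rows over the residue alphabet plus '-' gaps."""

    ids: list[str]
    rows: list[str]
    descriptions: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.rows) < 1:
            raise AlignmentError("alignment has no rows")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            ragged = [i for i, r in zip(self.ids, self.rows) if len(r) != len(self.rows[0])]
            raise AlignmentError(f"ragged alignment rows: {ragged}")
        if not self.descriptions:
            self.descriptions = [""] * len(self.rows)
        for rid, row in zip(self.ids, self.rows):
            bad = set(row) - VALID_RESIDUES - GAP_CHARS
            if bad:
                raise AlignmentError(f"row {rid!r} contains illegal character(s) {sorted(bad)}")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    def ungapped(self, i: int) -> SequenceRecord:
        """Row *i* with gaps stripped, as a validated SequenceRecord."""
        return SequenceRecord(self.ids[i], self.rows[i].replace("-", ""), self.descriptions[i])

    def column(self, col: int) -> str:
        """1-based column as a string of per-row characters."""
        if not 1 <= col <= self.n_cols:
            raise IndexError(f"column {col} outside 1..{self.n_cols}")
        return "".join(r[col - 1] for r in self.rows)


def _normalize_residues(seq_id: str, raw: str) -> str:
    seq = raw.upper().rstrip("*")
    # internal stop characters are never valid in a protein product
    if "*" in seq:
        raise ParseError(f"sequence {seq_id!r} has an internal stop character")
    return seq


def read_fasta(path) -> list[SequenceRecord]:
    """Read a protein FASTA file into validated records.

    Lowercase input is uppercased and trailing '*' stop characters stripped.
    Order is preserved.  Illegal residues raise :class:`ParseError` naming the
    offending record.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise ParseError(f"{path}: FASTA entry with empty header")
        desc = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
        records.append(SequenceRecord(rec.id, _normalize_residues(rec.id, str(rec.seq)), desc))
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: list[SequenceRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id} {rec.description}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(rec.residues), 60):
                fh.write(rec.residues[i : i + 60] + "\n")


def read_alignment(path, dialect: str = "aligned-fasta") -> MultipleAlignment:
    """Read an MSA from aligned FASTA or Stockholm.

    Stockholm '.' gap characters are normalized to '-'.  Ragged rows raise
    :class:`AlignmentError` listing the offending row ids.
    """
    fmt = {"aligned-fasta": "fasta", "stockholm": "stockholm"}.get(dialect)
    if fmt is None:
        raise ValueError(f"unknown alignment dialect {dialect!r}")
    if fmt == "fasta":
        # Bio.AlignIO refuses ragged FASTA outright; parse leniently so we can
        # report which rows are ragged.
        ids, rows, descs = [], [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            ids.append(rec.id)
            descs.append(rec.description[len(rec.id):].strip())
            rows.append(str(rec.seq).upper().replace(".", "-"))
        if not ids:
            raise AlignmentError(f"{path}: no alignment rows found")
        return MultipleAlignment(ids, rows, descs)
    aln = AlignIO.read(str(path), fmt)
    ids = [r.id for r in aln]
    rows = [str(r.seq).upper().replace(".", "-") for r in aln]
    return MultipleAlignment(ids, rows)


def write_alignment(msa: MultipleAlignment, path, dialect: str = "aligned-fasta") -> None:
    if dialect == "aligned-fasta":
        with open(path, "w") as fh:
            for rid, row, desc in zip(msa.ids, msa.rows, msa.descriptions):
                fh.write(f">{rid} {desc}".rstrip() + "\n")
                for i in range(0, len(row), 60):
                    fh.write(row[i : i + 60] + "\n")
    elif dialect == "stockholm":
        with open(path, "w") as fh:
            fh.write("# STOCKHOLM 1.0\n")
            width = max(len(i) for i in msa.ids) + 2
            for rid, row in zip(msa.ids, msa.rows):
                fh.write(f"{rid:<{width}}{row}\n")
            fh.write("//\n")
    else:
        raise ValueError(f"unknown alignment dialect {dialect!r}")


def write_tsv(path, header: list[str], rows, comment_lines: list[str] | None = None) -> None:
    """Write a TSV with optional '#'-prefixed audit header lines."""
    buf = io.StringIO()
    for line in comment_lines or []:
        buf.write(f"# {line}\n")
    buf.write("\t".join(header) + "\n")
    for row in rows:
        buf.write("\t".join(str(v) for v in row) + "\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())
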