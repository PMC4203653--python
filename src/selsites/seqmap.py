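"""Codon multiple-sequence-alignment handling and coordinate mapping.

Everything user-facing works in 1-based codon positions (the numbering codeml
and the Datamonkey tables use); nucleotide columns never leak into exported
tables.  The alignment-filter view reproduces the "keep only the selected
codons at their original positions" display used when marking selected sites
onto the 2D alignment.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "CodonAlignment",
    "SiteMask",
    "FilteredAlignment",
    "read_alignment",
    "write_alignment",
    "alignment_filter",
    "column_to_reference_position",
    "translate_reference",
]

GAP = "-"


class AlignmentFormatError(ValueError):
    pass


@dataclass
class CodonAlignment:
    """An in-frame nucleotide alignment: equal-length gapped sequences whose
    column count is divisible by three (unless built with codon_frame=False
    for protein alignments)."""

    records: list[tuple[str, str]]
    codon_frame: bool = True

    def __post_init__(self) -> None:
        if not self.records:
            raise AlignmentFormatError("alignment has no sequences")
        lengths = {len(seq) for _, seq in self.records}
        if len(lengths) != 1:
            raise AlignmentFormatError(f"ragged alignment: sequence lengths {sorted(lengths)}")
        ids = [rid for rid, _ in self.records]
        if len(set(ids)) != len(ids):
            raise AlignmentFormatError("duplicate sequence ids")
        if self.codon_frame and self.length % 3 != 0:
            raise AlignmentFormatError(
                f"alignment length {self.length} not divisible by 3 "
                "(pass codon_frame=False for protein alignments)"
            )

    @property
    def length(self) -> int:
        return len(self.records[0][1])

    @property
    def n_codons(self) -> int:
        return self.length // 3

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.records]

    def codon(self, seq_id: str, position: int) -> str:
        """The codon at 1-based alignment codon ``position`` for one sequence."""
        seq = dict(self.records)[seq_id]
        return seq[(position - 1) * 3 : position * 3]


@dataclass(frozen=True)
class SiteMask:
    """1-based alignment codon positions to keep or highlight."""

    positions: tuple[int, ...]

    def __init__(self, positions):
        object.__setattr__(self, "positions", tuple(sorted(set(int(p) for p in positions))))

    def validate(self, aln: CodonAlignment) -> None:
        for p in self.positions:
            if not 1 <= p <= aln.n_codons:
                raise ValueError(
                    f"mask position {p} outside alignment codon range 1..{aln.n_codons}"
                )


def read_alignment(
    path: str | Path, format: str = "fasta", codon_frame: bool = True
) -> CodonAlignment:
    """Read a FASTA or sequential PHYLIP alignment.

    The PHYLIP dialect is the relaxed sequential layout accepted by PAML:
    a ``<nseq> <ncols>`` header, then one whitespace-delimited name (up to 50
    chars) and sequence per entry, with the sequence allowed to wrap.
    """
    path = Path(path)
    if format == "fasta":
        records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    elif format == "phylip":
        records = _read_phylip_sequential(path)
    else:
        raise ValueError(f"unknown alignment format {format!r}; use 'fasta' or 'phylip'")
    return CodonAlignment(records=records, codon_frame=codon_frame)


def _read_phylip_sequential(path: Path) -> list[tuple[str, str]]:
    tokens = path.read_text(encoding="utf-8").split()
    if len(tokens) < 2:
        raise AlignmentFormatError(f"{path}: missing PHYLIP header")
    try:
        nseq, ncols = int(tokens[0]), int(tokens[1])
    except ValueError:
        raise AlignmentFormatError(f"{path}: malformed PHYLIP header") from None
    records: list[tuple[str, str]] = []
    i = 2
    for _ in range(nseq):
        if i >= len(tokens):
            raise AlignmentFormatError(f"{path}: truncated PHYLIP file")
        name = tokens[i]
        if len(name) > 50:
            raise AlignmentFormatError(f"{path}: sequence name longer than 50 chars: {name!r}")
        i += 1
        chunks: list[str] = []
        total = 0
        while total < ncols:
            if i >= len(tokens):
                raise AlignmentFormatError(f"{path}: sequence {name!r} shorter than {ncols}")
            chunks.append(tokens[i])
            total += len(tokens[i])
            i += 1
        seq = "".join(chunks).upper()
        if len(seq) != ncols:
            raise AlignmentFormatError(
                f"{path}: sequence {name!r} has {len(seq)} columns, header says {ncols}"
            )
        records.append((name, seq))
    return records


def write_alignment(aln: CodonAlignment, path: str | Path, format: str = "fasta") -> None:
    path = Path(path)
    if format == "fasta":
        recs = [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in aln.records]
        SeqIO.write(recs, str(path), "fasta")
    elif format == "phylip":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f" {len(aln.records)} {aln.length}\n")
            for rid, seq in aln.records:
                fh.write(f"{rid}  {seq}\n")
    else:
        raise ValueError(f"unknown alignment format {format!r}")


@dataclass
class FilteredAlignment:
    """Alignment-filter view: selected codon columns with their ORIGINAL
    1-based positions as labels (keep-only mode), or the full alignment plus
    a marker row (highlight mode)."""

    labels: tuple[int, ...]
    records: list[tuple[str, tuple[str, ...]]]  # id -> codons, one per label
    mode: str = "keep-only"
    marker_row: str | None = None
    full_alignment: CodonAlignment | None = None

    def to_csv(self, path: str | Path | None = None) -> str:
        """CSV export: header of original codon positions, one row per
        sequence.  Round-trips through :meth:`from_csv`."""
        buf = io.StringIO()
        writer = csv.writer(buf, lineterminator="\n")
        writer.writerow(["id", *self.labels])
        for rid, codons in self.records:
            writer.writerow([rid, *codons])
        text = buf.getvalue()
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_csv(cls, source: str | Path) -> "FilteredAlignment":
        text = Path(source).read_text(encoding="utf-8") if isinstance(source, Path) else source
        rows = list(csv.reader(io.StringIO(text)))
        labels = tuple(int(x) for x in rows[0][1:])
        records = [(r[0], tuple(r[1:])) for r in rows[1:]]
        return cls(labels=labels, records=records)

    def to_fasta(self) -> str:
        """FASTA export; in highlight mode a marker pseudo-record (id
        ``#mask``) carries '*' over masked codon columns."""
        lines: list[str] = []
        if self.mode == "highlight":
            assert self.full_alignment is not None and self.marker_row is not None
            lines.append(">#mask")
            lines.append(self.marker_row)
            for rid, seq in self.full_alignment.records:
                lines.append(f">{rid}")
                lines.append(seq)
        else:
            for rid, codons in self.records:
                lines.append(f">{rid}")
                lines.append("".join(codons))
        return "\n".join(lines) + "\n"


def alignment_filter(
    aln: CodonAlignment, mask: SiteMask, mode: str = "keep-only"
) -> FilteredAlignment:
    """Project the alignment onto masked codon positions.

    keep-only: the output holds exactly the masked codon columns, each
    labeled with its original position.  highlight: the full alignment is
    kept and a marker row flags the masked columns.
    """
    if mode not in ("keep-only", "highlight"):
        raise ValueError(f"mode must be 'keep-only' or 'highlight', got {mode!r}")
    mask.validate(aln)
    labels = mask.positions
    records = [
        (rid, tuple(seq[(p - 1) * 3 : p * 3] for p in labels)) for rid, seq in aln.records
    ]
    if mode == "highlight":
        masked = set(labels)
        marker = "".join("***" if p in masked else "..." for p in range(1, aln.n_codons + 1))
        return FilteredAlignment(
            labels=labels, records=records, mode="highlight",
            marker_row=marker, full_alignment=aln,
        )
    return FilteredAlignment(labels=labels, records=records, mode="keep-only")


def column_to_reference_position(
    aln: CodonAlignment, reference_id: str, codon_column: int
) -> int | None:
    """Map a 1-based alignment codon column to the reference's ungapped codon
    index, or None when the reference is gapped there.

    A codon containing any gap character counts as a gap codon.
    """
    if reference_id not in aln.ids:
        raise KeyError(f"unknown sequence id {reference_id!r}; have {aln.ids}")
    if not 1 <= codon_column <= aln.n_codons:
        raise ValueError(f"codon column {codon_column} outside 1..{aln.n_codons}")
    seq = dict(aln.records)[reference_id]
    count = 0
    for col in range(1, codon_column + 1):
        codon = seq[(col - 1) * 3 : col * 3]
        if GAP not in codon:
            count += 1
        elif col == codon_column:
            return None
    if GAP in seq[(codon_column - 1) * 3 : codon_column * 3]:
        return None
    return count


def translate_reference(
    aln: CodonAlignment, reference_id: str, allow_internal_stop: bool = False
) -> str:
    """Ungapped protein sequence of one alignment member (standard code).

    A terminal stop codon is dropped; an internal stop raises unless
    ``allow_internal_stop`` (then rendered '*')."""
    if reference_id not in aln.ids:
        raise KeyError(f"unknown sequence id {reference_id!r}; have {aln.ids}")
    seq = dict(aln.records)[reference_id].replace(GAP, "")
    protein = str(Seq(seq).translate())
    if protein.endswith("*"):
        protein = protein[:-1]
    if "*" in protein and not allow_internal_stop:
        raise ValueError(
            f"internal stop codon in {reference_id!r} at protein position "
            f"{protein.index('*') + 1}"
        )
    return protein
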