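"""Family alignment handling: reading, cropping to the reference window,
and per-column residue access.

The comparison is always between one *reference* sequence and the remaining
*family* records of a multiple sequence alignment. Columns where the
reference carries a gap contribute no reference residue, so they are cropped
off; reference positions are numbered 1..L after cropping, matching the
residue numbering biologists use.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from Bio import AlignIO

from ._errors import InputFormatError, MappingError

log = logging.getLogger(__name__)

STANDARD_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")
ALPHABET = STANDARD_RESIDUES | {"X", "-"}

_FORMAT_NAMES = {"aligned_fasta": "fasta", "clustal": "clustal"}


@dataclass(frozen=True)
class Alignment:
    """An MSA with a designated reference record.

    All sequences have equal length; the reference id occurs exactly once.
    """

    records: tuple[tuple[str, str], ...]
    reference_id: str

    def __post_init__(self) -> None:
        lengths = {len(seq) for _, seq in self.records}
        if len(lengths) > 1:
            ragged = [rid for rid, seq in self.records if len(seq) != len(self.records[0][1])]
            raise InputFormatError(f"ragged sequence lengths for ids: {ragged}")
        hits = [rid for rid, _ in self.records if rid == self.reference_id]
        if len(hits) != 1:
            raise MappingError(
                f"reference id {self.reference_id!r} occurs {len(hits)} times in alignment"
            )

    @property
    def n_columns(self) -> int:
        return len(self.records[0][1]) if self.records else 0

    @property
    def reference_row(self) -> str:
        return next(seq for rid, seq in self.records if rid == self.reference_id)

    @property
    def family_records(self) -> tuple[tuple[str, str], ...]:
        return tuple((rid, seq) for rid, seq in self.records if rid != self.reference_id)


@dataclass(frozen=True)
class CroppedAlignment:
    """Alignment restricted to the reference's non-gap columns.

    ``positions`` is the contiguous 1..L reference numbering; ``colmap[i]``
    is the 0-based original column of position ``positions[i]``. The
    reference sequence contains no gaps after cropping.
    """

    records: tuple[tuple[str, str], ...]
    reference_id: str
    colmap: tuple[int, ...]

    @property
    def L(self) -> int:
        return len(self.colmap)

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(range(1, self.L + 1))

    @property
    def reference_seq(self) -> str:
        return next(seq for rid, seq in self.records if rid == self.reference_id)

    @property
    def family_records(self) -> tuple[tuple[str, str], ...]:
        return tuple((rid, seq) for rid, seq in self.records if rid != self.reference_id)


def _normalize(seq: str, rid: str) -> str:
    out = []
    warned: set[str] = set()
    for ch in seq.upper().replace(".", "-"):
        if ch in ALPHABET:
            out.append(ch)
        else:
            if ch not in warned:
                log.warning("record %s: letter %r outside alphabet, mapped to 'X'", rid, ch)
                warned.add(ch)
            out.append("X")
    return "".join(out)


def read_alignment(path: str | Path, reference_id: str, format: str = "aligned_fasta") -> Alignment:
    """Read an aligned FASTA or Clustal file.

    Sequences are uppercased, ``.`` gaps become ``-``, and any letter outside
    the 20 standard residues plus ``X``/``-`` is mapped to ``X`` with a
    logged warning.
    """
    if format not in _FORMAT_NAMES:
        raise InputFormatError(f"unknown alignment format {format!r}; use aligned_fasta or clustal")
    try:
        msa = AlignIO.read(str(path), _FORMAT_NAMES[format])
    except ValueError as exc:
        raise InputFormatError(f"{path}: cannot parse as {format}: {exc}") from exc
    records = tuple((rec.id, _normalize(str(rec.seq), rec.id)) for rec in msa)
    return Alignment(records=records, reference_id=reference_id)


def write_cropped_fasta(ca: CroppedAlignment, path: str | Path) -> None:
    """Write the cropped alignment as aligned FASTA (reference first)."""
    ordered = [(ca.reference_id, ca.reference_seq)] + [
        (rid, seq) for rid, seq in ca.records if rid != ca.reference_id
    ]
    with open(path, "w") as fh:
        for rid, seq in ordered:
            fh.write(f">{rid}\n{seq}\n")


def crop_to_reference(aln: Alignment | CroppedAlignment) -> CroppedAlignment:
    """Keep exactly the columns where the reference is non-gap.

    Idempotent: cropping a cropped alignment returns it unchanged (the
    reference has no gaps left to remove, and the colmap is preserved).
    """
    if isinstance(aln, CroppedAlignment):
        return aln
    ref_row = aln.reference_row
    keep = [i for i, ch in enumerate(ref_row) if ch != "-"]
    if not keep:
        raise InputFormatError(f"reference {aln.reference_id!r} is all gaps")
    records = tuple(
        (rid, "".join(seq[i] for i in keep)) for rid, seq in aln.records
    )
    return CroppedAlignment(records=records, reference_id=aln.reference_id, colmap=tuple(keep))


def column_residues(
    ca: CroppedAlignment, r: int, filtered: bool = True
) -> list[str]:
    """Family residues at reference position ``r`` (1-based).

    The reference itself is excluded. With ``filtered=True`` (default),
    gaps and ``X`` are dropped; order follows record order either way.
    """
    if not 1 <= r <= ca.L:
        raise IndexError(f"position {r} out of range 1..{ca.L}")
    col = [seq[r - 1] for _, seq in ca.family_records]
    if filtered:
        col = [ch for ch in col if ch in STANDARD_RESIDUES]
    return col
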