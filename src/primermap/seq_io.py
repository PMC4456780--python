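"""FASTA input/output and basic DNA string operations.

Sequences are held as plain uppercase strings over the unambiguous DNA
alphabet {A, C, G, T}.  Parsing is delegated to Biopython's FASTA reader;
this module adds the validation layer the design pipeline relies on:
normalization (case folding, U->T), alphabet checking with positional
error messages, and rejection of duplicate record identifiers.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "SequenceRecord",
    "FastaError",
    "read_fasta",
    "write_fasta",
    "reverse_complement",
    "gc_content",
]

_VALID = frozenset("ACGT")
_INVALID_RE = re.compile(r"[^ACGT]")


class FastaError(ValueError):
    """Raised for malformed FASTA input or invalid DNA strings."""


@dataclass(frozen=True)
class SequenceRecord:
    """One FASTA entry.

    Attributes
    ----------
    id : str
        First whitespace-delimited token of the header line; unique
        within a loaded dataset.
    seq : str
        Uppercase DNA over {A, C, G, T}, length >= 1.
    description : str
        Remainder of the header after the id (may be empty); kept for
        figure titles.
    """

    id: str
    seq: str
    description: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if not self.id:
            raise FastaError("record id must be non-empty")
        if not self.seq:
            raise FastaError(f"record '{self.id}' has an empty sequence")
        bad = _INVALID_RE.search(self.seq)
        if bad:
            raise FastaError(
                f"record '{self.id}': invalid character {bad.group()!r} "
                f"at position {bad.start() + 1}"
            )

    def __len__(self) -> int:
        return len(self.seq)


def normalize_sequence(raw: str, record_id: str = "<sequence>") -> str:
    """Uppercase, map U->T, and validate against {A, C, G, T}.

    Soft-masking (lowercase) is discarded by the case fold.  Ambiguity
    codes (N, R, Y, ...) are rejected: primer design over ambiguous
    bases is undefined here, so we fail loudly with the 1-based position
    of the first offending character.
    """
    seq = raw.upper().replace("U", "T")
    bad = _INVALID_RE.search(seq)
    if bad:
        raise FastaError(
            f"record '{record_id}': invalid character {bad.group()!r} "
            f"at position {bad.start() + 1}"
        )
    return seq


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a multi-FASTA file into validated records, in file order.

    Accepts wrapped lines, trailing whitespace, and both LF and CRLF
    dialects (Biopython handles the dialects).  Raises
    :class:`FastaError` on an empty file, an empty sequence, a
    non-IUPAC-unambiguous character, or a duplicate id.
    """
    path = Path(path)
    if not path.exists():
        raise FastaError(f"input file not found: {path}")
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with open(path) as handle:
        for entry in SeqIO.parse(handle, "fasta"):
            if not entry.id:
                raise FastaError(f"{path}: record with empty id")
            if entry.id in seen:
                raise FastaError(f"{path}: duplicate record id '{entry.id}'")
            seen.add(entry.id)
            raw = str(entry.seq).strip()
            if not raw:
                raise FastaError(
                    f"{path}: record '{entry.id}' has a zero-length sequence"
                )
            desc = entry.description
            if desc.startswith(entry.id):
                desc = desc[len(entry.id):].strip()
            records.append(
                SequenceRecord(
                    id=entry.id,
                    seq=normalize_sequence(raw, entry.id),
                    description=desc,
                )
            )
    if not records:
        raise FastaError(f"{path}: no records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                wrap: int = 70) -> Path:
    """Write records as FASTA with the given line-wrap width."""
    path = Path(path)
    with open(path, "w") as handle:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            handle.write(f">{header}\n")
            for i in range(0, len(rec.seq), wrap):
                handle.write(rec.seq[i:i + wrap] + "\n")
    return path


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement of an unambiguous DNA string."""
    if not seq:
        raise FastaError("cannot reverse-complement an empty sequence")
    bad = _INVALID_RE.search(seq)
    if bad:
        raise FastaError(
            f"invalid character {bad.group()!r} at position {bad.start() + 1}"
        )
    return str(Seq(seq).reverse_complement())


def gc_content(seq: str) -> float:
    """G+C percentage of ``seq`` on a 0-100 scale.

    Computed with exact rational arithmetic before the final float
    conversion, so e.g. a 3-mer with one G yields exactly
    ``float(Fraction(100, 3))``.
    """
    if not seq:
        raise FastaError("cannot compute GC content of an empty sequence")
    gc = seq.count("G") + seq.count("C")
    return float(Fraction(100 * gc, len(seq)))
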