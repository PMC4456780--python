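"""Map accepted primers back onto their targets and build alignment views.

Every designed primer is by construction an exact substring (forward) or
exact reverse-complement substring (reverse) of its target, so mapping
is pure coordinate bookkeeping.  The re-extraction check in
:func:`map_primer` — the recorded slice, or its reverse complement, must
reproduce the primer sequence — is the correctness gate for the whole
design pipeline: a failure indicates an internal bug, never user error.
"""

from __future__ import annotations

from dataclasses import dataclass

from .design import PrimerCandidate
from .seq_io import SequenceRecord, reverse_complement

__all__ = ["AlignmentView", "MappingError", "map_primer",
           "build_alignment_view", "format_alignment_text"]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
GAP = "-"


class MappingError(RuntimeError):
    """Internal-consistency failure: a primer does not match its target."""


@dataclass(frozen=True)
class AlignmentView:
    """A pairwise text view of one primer on its target.

    ``target_line`` is the displayed target slice; ``primer_line`` has
    the same length, gap-padded outside the primer span.  Inside the
    span, forward primers show the target characters verbatim and
    reverse primers show their complement (the primer drawn 3'->5' on
    the target's coordinate system; orientation is annotated by
    ``direction``).  All coordinates are 1-based on the target.
    """

    target_id: str
    window_start: int
    window_end: int
    target_line: str
    primer_line: str
    primer_name: str
    direction: str
    primer_start: int
    primer_end: int
    tick_positions: tuple[int, ...]


def map_primer(cand: PrimerCandidate, record: SequenceRecord) -> tuple[int, int, str]:
    """Return (start, end, strand) for ``cand`` on ``record``, verified.

    Strand is '+' for forward primers and '-' for reverse.  Verifies by
    re-extraction that the recorded slice (or its reverse complement)
    equals the primer sequence, raising :class:`MappingError` otherwise.
    """
    if cand.target_id != record.id:
        raise MappingError(
            f"primer targets '{cand.target_id}' but record is '{record.id}'"
        )
    slice_ = record.seq[cand.start - 1:cand.end]
    if cand.direction == "forward":
        ok = slice_ == cand.seq
        strand = "+"
    else:
        ok = reverse_complement(slice_) == cand.seq
        strand = "-"
    if not ok:
        raise MappingError(
            f"re-extraction failed for primer {cand.name or cand.start} on "
            f"{record.id} at {cand.start}..{cand.end} ({cand.direction})"
        )
    return cand.start, cand.end, strand


def build_alignment_view(cand: PrimerCandidate, record: SequenceRecord,
                         flank: int = 25) -> AlignmentView:
    """Build the text view of one primer with ``flank`` nt of context.

    The display window is the primer span extended by ``flank`` on each
    side, clamped to [1, L]; tick labels mark the window edges and the
    primer edges.
    """
    if flank < 0:
        raise ValueError("flank must be non-negative")
    map_primer(cand, record)  # verification gate
    L = len(record.seq)
    w_start = max(1, cand.start - flank)
    w_end = min(L, cand.end + flank)
    target_line = record.seq[w_start - 1:w_end]
    if cand.direction == "forward":
        shown = cand.seq
    else:
        # primer laid along the target axis: complement of the slice
        shown = record.seq[cand.start - 1:cand.end].translate(_COMPLEMENT)
    primer_line = (
        GAP * (cand.start - w_start) + shown + GAP * (w_end - cand.end)
    )
    ticks = tuple(sorted({w_start, cand.start, cand.end, w_end}))
    return AlignmentView(
        target_id=record.id,
        window_start=w_start,
        window_end=w_end,
        target_line=target_line,
        primer_line=primer_line,
        primer_name=cand.name or str(cand.start),
        direction=cand.direction,
        primer_start=cand.start,
        primer_end=cand.end,
        tick_positions=ticks,
    )


def format_alignment_text(view: AlignmentView, width: int = 60) -> str:
    """CLUSTAL-like plain-text rendering of an alignment view."""
    label_t = view.target_id[:18].ljust(20)
    label_p = f"{view.primer_name}({view.direction[0].upper()})"[:18].ljust(20)
    lines = [
        f"# {view.target_id}  primer {view.primer_name} "
        f"[{view.primer_start}..{view.primer_end}] ({view.direction})",
        "",
    ]
    for off in range(0, len(view.target_line), width):
        t_chunk = view.target_line[off:off + width]
        p_chunk = view.primer_line[off:off + width]
        pos = view.window_start + off
        lines.append(f"{label_t}{t_chunk}  {pos + len(t_chunk) - 1}")
        lines.append(f"{label_p}{p_chunk}")
        lines.append(" " * 20 + "".join("*" if p != GAP else " " for p in p_chunk))
    return "\n".join(lines) + "\n"
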