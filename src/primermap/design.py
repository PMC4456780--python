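"""Primer enumeration, filtering, and specificity screening.

For each target sequence, candidate forward primers are every substring
lying inside the 5' search window and candidate reverse primers every
substring (taken as the reverse complement of the covered slice) lying
inside the 3' window, at every length in the configured range.
Candidates are then audited against four compositional filters (length,
GC% range, Tm range, 3' GC clamp) and finally screened for specificity:
a primer is accepted only if its strand-aware exact-match count over the
screening scope equals its own binding site and nothing else.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal

from .seq_io import SequenceRecord, gc_content, reverse_complement
from .thermo import ThermoParameters, calc_tm

__all__ = [
    "DesignParameters",
    "PrimerCandidate",
    "PrimerSet",
    "enumerate_candidates",
    "passes_filters",
    "count_occurrences",
    "design_primers",
]

log = logging.getLogger(__name__)

Direction = Literal["forward", "reverse"]


class ParameterError(ValueError):
    """Raised when design parameters violate their invariants."""


@dataclass(frozen=True)
class DesignParameters:
    """The user-tunable design knob set.

    Defaults are conventional PCR values: 150 nt search windows at each
    end, 18-24 nt primers, 40-60 GC%, 52-65 C Tm, a 3' GC clamp
    required, and specificity screened against the whole input file.
    """

    input_path: str | Path | None = None
    five_prime_window: int = 150
    three_prime_window: int = 150
    len_max: int = 24
    len_min: int = 18
    gc_clamp: bool = True
    gc_max: float = 60.0
    gc_min: float = 40.0
    tm_max: float = 65.0
    tm_min: float = 52.0
    specificity_whole_file: bool = True

    def __post_init__(self) -> None:
        for name in ("five_prime_window", "three_prime_window", "len_max", "len_min"):
            value = getattr(self, name)
            if not isinstance(value, int) or value <= 0:
                raise ParameterError(f"{name} must be a positive integer, got {value!r}")
        if self.len_min > self.len_max:
            raise ParameterError(
                f"len_min ({self.len_min}) exceeds len_max ({self.len_max})"
            )
        if self.gc_min > self.gc_max:
            raise ParameterError(
                f"gc_min ({self.gc_min}) exceeds gc_max ({self.gc_max})"
            )
        if self.tm_min > self.tm_max:
            raise ParameterError(
                f"tm_min ({self.tm_min}) exceeds tm_max ({self.tm_max})"
            )
        if min(self.five_prime_window, self.three_prime_window) < self.len_min:
            raise ParameterError(
                "search windows must be at least len_min nucleotides wide"
            )


@dataclass
class PrimerCandidate:
    """One oligo candidate with its audit trail.

    ``start``/``end`` are 1-based inclusive coordinates of the covered
    target slice (5'-most covered base first, regardless of direction).
    ``seq`` is given 5'->3' in synthesis orientation: for reverse
    primers it is the reverse complement of the covered slice.
    ``rejection_reasons`` lists every filter that failed; the candidate
    is accepted iff the list is empty after auditing.
    """

    target_id: str
    direction: Direction
    start: int
    end: int
    seq: str
    tm: float
    gc: float
    name: str = ""
    rejection_reasons: list[str] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def accepted(self) -> bool:
        return not self.rejection_reasons


@dataclass
class PrimerSet:
    """All accepted primers for one target, ordered by start position."""

    target_id: str
    target_length: int
    primers: list[PrimerCandidate] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.primers)


def enumerate_candidates(
    record: SequenceRecord,
    params: DesignParameters,
    direction: Direction,
    thermo: ThermoParameters | None = None,
) -> list[PrimerCandidate]:
    """Every (start, length) candidate inside the direction's window.

    The forward window spans target positions 1..five_prime_window; the
    reverse window spans the final three_prime_window bases.  Windows
    larger than the record are clamped to its length.  A window too
    narrow for even the shortest primer yields an empty list with a
    logged warning rather than an error: short records are legitimate.
    """
    L = len(record.seq)
    if direction == "forward":
        lo, hi = 1, min(params.five_prime_window, L)
    elif direction == "reverse":
        lo, hi = max(1, L - min(params.three_prime_window, L) + 1), L
    else:
        raise ValueError(f"unknown direction {direction!r}")
    window = hi - lo + 1
    if window < params.len_min:
        log.warning(
            "record %s: %s window (%d nt) narrower than len_min (%d); no candidates",
            record.id, direction, window, params.len_min,
        )
        return []
    out: list[PrimerCandidate] = []
    for start in range(lo, hi + 1):
        for length in range(params.len_min, params.len_max + 1):
            end = start + length - 1
            if end > hi:
                break
            slice_ = record.seq[start - 1:end]
            seq = slice_ if direction == "forward" else reverse_complement(slice_)
            out.append(
                PrimerCandidate(
                    target_id=record.id,
                    direction=direction,
                    start=start,
                    end=end,
                    seq=seq,
                    tm=calc_tm(seq, thermo),
                    gc=gc_content(seq),
                )
            )
    return out


def passes_filters(cand: PrimerCandidate, params: DesignParameters) -> PrimerCandidate:
    """Audit one candidate against the compositional filters.

    Appends a reason for each failing filter among {length, gc_range,
    tm_range, gc_clamp}; pure predicate, never raises.  The GC clamp
    inspects the 3'-terminal base in synthesis orientation.
    """
    reasons = list(cand.rejection_reasons)
    if not (params.len_min <= cand.length <= params.len_max):
        reasons.append("length")
    if not (params.gc_min <= cand.gc <= params.gc_max):
        reasons.append("gc_range")
    if not (params.tm_min <= cand.tm <= params.tm_max):
        reasons.append("tm_range")
    if params.gc_clamp and cand.seq[-1] not in "GC":
        reasons.append("gc_clamp")
    return replace_reasons(cand, reasons)


def replace_reasons(cand: PrimerCandidate, reasons: list[str]) -> PrimerCandidate:
    return replace(cand, rejection_reasons=reasons)


def _count_overlapping(text: str, pattern: str) -> int:
    count = 0
    pos = text.find(pattern)
    while pos != -1:
        count += 1
        pos = text.find(pattern, pos + 1)
    return count


def count_occurrences(oligo: str, records: Iterable[SequenceRecord]) -> int:
    """Strand-aware exact-match count of ``oligo`` over ``records``.

    Counts matches of the oligo itself plus matches of its reverse
    complement, with overlapping matches included.  A palindromic oligo
    therefore counts every site twice, by definition.
    """
    if not oligo:
        raise ValueError("oligo must be non-empty")
    rc = reverse_complement(oligo)
    total = 0
    for rec in records:
        total += _count_overlapping(rec.seq, oligo)
        total += _count_overlapping(rec.seq, rc)
    return total


def expected_self_count(oligo: str) -> int:
    """Occurrence count a unique binding site contributes.

    A self-complementary oligo's single site matches on both strands,
    so it contributes 2; any other oligo contributes 1.
    """
    return 2 if oligo == reverse_complement(oligo) else 1


def _assign_names(primers: list[PrimerCandidate]) -> list[PrimerCandidate]:
    """Name primers by start position, disambiguating collisions.

    Base name is the start coordinate; when a forward and a reverse
    primer share a start, an F/R suffix is appended; when primers of
    the same direction share a start (different lengths), the length is
    appended after a dot.
    """
    by_start: dict[int, list[PrimerCandidate]] = {}
    for p in primers:
        by_start.setdefault(p.start, []).append(p)
    named: list[PrimerCandidate] = []
    for start, group in by_start.items():
        dirs = {p.direction for p in group}
        for p in group:
            name = str(start)
            if len(dirs) > 1:
                name += "F" if p.direction == "forward" else "R"
            if sum(1 for q in group if q.direction == p.direction) > 1:
                name += f".{p.length}"
            named.append(replace(p, name=name))
    return named


def design_primers(
    records: list[SequenceRecord],
    params: DesignParameters,
    thermo: ThermoParameters | None = None,
    collect_rejected: list[PrimerCandidate] | None = None,
) -> list[PrimerSet]:
    """Run the full design pipeline over a dataset.

    Per record: enumerate both directions, audit the compositional
    filters, then keep only candidates whose strand-aware occurrence
    count over the screening scope (the whole file when
    ``specificity_whole_file``, else the record alone) equals their own
    binding site exactly.  Output order is deterministic: by record
    order, then start, then direction (forward first).  Records yielding
    no primer produce an empty set plus a logged warning.
    """
    if not records:
        raise ValueError("no records to design primers for")
    sets: list[PrimerSet] = []
    for rec in records:
        accepted: list[PrimerCandidate] = []
        n_candidates = 0
        attrition: dict[str, int] = {}
        for direction in ("forward", "reverse"):
            for cand in enumerate_candidates(rec, params, direction, thermo):
                n_candidates += 1
                audited = passes_filters(cand, params)
                if not audited.accepted:
                    for reason in audited.rejection_reasons:
                        attrition[reason] = attrition.get(reason, 0) + 1
                    if collect_rejected is not None:
                        collect_rejected.append(audited)
                    continue
                scope = records if params.specificity_whole_file else [rec]
                if count_occurrences(audited.seq, scope) != expected_self_count(audited.seq):
                    attrition["specificity"] = attrition.get("specificity", 0) + 1
                    if collect_rejected is not None:
                        collect_rejected.append(
                            replace_reasons(audited, ["specificity"])
                        )
                    continue
                accepted.append(audited)
        accepted.sort(key=lambda p: (p.start, 0 if p.direction == "forward" else 1,
                                     p.length))
        accepted = _assign_names(accepted)
        accepted.sort(key=lambda p: (p.start, 0 if p.direction == "forward" else 1,
                                     p.length))
        if not accepted:
            log.warning("record %s: no primers passed (candidates=%d, attrition=%s)",
                        rec.id, n_candidates, attrition)
        else:
            log.info("record %s: %d/%d candidates accepted (attrition=%s)",
                     rec.id, len(accepted), n_candidates, attrition)
        sets.append(PrimerSet(target_id=rec.id, target_length=len(rec.seq),
                              primers=accepted))
    return sets
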