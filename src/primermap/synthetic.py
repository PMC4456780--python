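"""Deterministic synthetic FASTA generation for tests and demos.

Sequences are i.i.d. bases with a configurable GC probability — no
repeats, isochores, or other genome structure — which is exactly what
the design pipeline needs for exercising windows, filters, and
specificity screening without any external data.  Every generator run
is reproducible from its seed, and a JSON manifest records the spec and
the realized per-record statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .seq_io import SequenceRecord, write_fasta

__all__ = ["GeneratorSpec", "generate_records", "random_fasta", "planted_dataset"]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of one synthetic dataset.

    ``plant`` entries are (record_index, position, oligo) with position
    1-based; the oligo overwrites the bases at that position, which is
    how constructed duplicate-binding-site cases are made.
    """

    n_records: int = 10
    length_range: tuple[int, int] = (300, 600)
    gc_target: float = 50.0
    seed: int = 0
    plant: tuple[tuple[int, int, str], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.n_records < 1:
            raise ValueError("n_records must be >= 1")
        lo, hi = self.length_range
        if not (1 <= lo <= hi):
            raise ValueError(f"invalid length_range {self.length_range}")
        if not (0.0 <= self.gc_target <= 100.0):
            raise ValueError("gc_target must be a percentage in [0, 100]")


def generate_records(spec: GeneratorSpec) -> tuple[list[SequenceRecord], dict]:
    """Generate the records for ``spec`` plus a manifest dictionary.

    Per-base sampling: G or C with probability gc_target/100 (split
    evenly between the two), A or T otherwise.  The manifest carries
    the seed, the spec, each record's realized length and GC count, and
    the total length — the generator's own bookkeeping that round-trip
    tests check FASTA I/O against.
    """
    rng = np.random.default_rng(spec.seed)
    p_gc = spec.gc_target / 100.0
    probs = np.array([(1 - p_gc) / 2, p_gc / 2, p_gc / 2, (1 - p_gc) / 2])
    lo, hi = spec.length_range
    records: list[SequenceRecord] = []
    entries = []
    for i in range(spec.n_records):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(_BASES, size=length, p=probs))
        for rec_idx, pos, oligo in spec.plant:
            if rec_idx == i:
                if not (1 <= pos and pos + len(oligo) - 1 <= length):
                    raise ValueError(
                        f"plant position {pos} (+{len(oligo)} nt) out of range "
                        f"for record {i} of length {length}"
                    )
                seq = seq[:pos - 1] + oligo.upper() + seq[pos - 1 + len(oligo):]
        rec = SequenceRecord(id=f"syn{i:04d}", seq=seq,
                             description=f"synthetic length={length}")
        records.append(rec)
        entries.append({
            "id": rec.id,
            "length": length,
            "gc_count": seq.count("G") + seq.count("C"),
        })
    manifest = {
        "seed": spec.seed,
        "n_records": spec.n_records,
        "length_range": list(spec.length_range),
        "gc_target": spec.gc_target,
        "plant": [list(p) for p in spec.plant],
        "records": entries,
        "total_length": sum(e["length"] for e in entries),
    }
    return records, manifest


def random_fasta(spec: GeneratorSpec, fasta_path: str | Path,
                 manifest_path: str | Path | None = None) -> tuple[Path, Path]:
    """Write the dataset for ``spec`` as FASTA plus a JSON manifest.

    Same spec, same output bytes: all randomness flows from the spec's
    seed through one generator, with no global state.
    """
    fasta_path = Path(fasta_path)
    if manifest_path is None:
        manifest_path = fasta_path.with_suffix(fasta_path.suffix + ".manifest.json")
    manifest_path = Path(manifest_path)
    records, manifest = generate_records(spec)
    write_fasta(records, fasta_path)
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return fasta_path, manifest_path


def planted_dataset(seed: int = 11, n_records: int = 6,
                    length: int = 400) -> tuple[list[SequenceRecord], dict]:
    """A fixed-layout dataset with a duplicated oligo across two records.

    Record 0 and record 1 both carry the same 20-mer (taken from record
    0's own 5' window), so any candidate covering it fails whole-file
    specificity while still passing record-scoped screening.  Used by
    end-to-end oracle tests; returns (records, manifest).
    """
    base_spec = GeneratorSpec(n_records=n_records, length_range=(length, length),
                              gc_target=50.0, seed=seed)
    records, _ = generate_records(base_spec)
    shared = records[0].seq[40:60]
    spec = GeneratorSpec(
        n_records=n_records, length_range=(length, length), gc_target=50.0,
        seed=seed, plant=((1, 101, shared),),
    )
    return generate_records(spec)
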