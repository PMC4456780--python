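"""Nearest-neighbor melting-temperature calculation for primer oligos.

Duplex stability is modeled as the sum of stacked-dinucleotide enthalpy
and entropy terms plus duplex-initiation terms (split by the identity of
each terminal base pair) and a one-time entropic symmetry correction for
self-complementary oligos.  The melting temperature of a bimolecular
duplex at total strand concentration C_T is

    Tm(K) = 1000 * dH / (dS + R * ln(C_T / x))

with x = 4 for non-self-complementary duplexes and x = 1 for
self-complementary ones, dH in kcal/mol and dS in cal/(mol K).  A simple
monovalent-salt adjustment of 16.6 * log10([Na+]) degrees C is added to
move from the 1 M NaCl reference state of the parameter table to the
working salt concentration.

The bundled parameter table is the unified duplex set of SantaLucia
(1998); it ships as a plain-text file (``data/santalucia1998_unified.tsv``,
schema documented in the file header) so alternate published sets can be
swapped in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

from .seq_io import normalize_sequence, reverse_complement

__all__ = ["ThermoParameters", "ThermoError", "nn_sums", "calc_tm",
           "load_default_parameters"]

GAS_CONSTANT = 1.987  # cal/(mol*K)

_DINUCLEOTIDES = tuple(a + b for a in "ACGT" for b in "ACGT")


class ThermoError(ValueError):
    """Raised for sequences or parameters the NN model cannot handle."""


@dataclass(frozen=True)
class ThermoParameters:
    """Nearest-neighbor parameter set plus solution conditions.

    Attributes
    ----------
    nn_dH, nn_dS : dict
        Stacking enthalpies (kcal/mol) and entropies (cal/(mol K)) for
        all 16 dinucleotides, 5'->3' on the reported strand.
    init_dH_gc, init_dS_gc : float
        Initiation contribution per G:C terminal base pair.
    init_dH_at, init_dS_at : float
        Initiation contribution per A:T terminal base pair.
    sym_dH, sym_dS : float
        Symmetry correction, applied once for self-complementary oligos.
    R : float
        Gas constant, cal/(mol K).
    C_T : float
        Total oligo strand concentration, mol/L.  Default 250 nM.
    Na : float
        Monovalent cation concentration, mol/L.  Default 50 mM.
    """

    nn_dH: dict[str, float]
    nn_dS: dict[str, float]
    init_dH_gc: float
    init_dS_gc: float
    init_dH_at: float
    init_dS_at: float
    sym_dH: float = 0.0
    sym_dS: float = -1.4
    R: float = GAS_CONSTANT
    C_T: float = 2.5e-7
    Na: float = 0.05

    def __post_init__(self) -> None:
        missing = [nn for nn in _DINUCLEOTIDES if nn not in self.nn_dH]
        missing += [nn for nn in _DINUCLEOTIDES if nn not in self.nn_dS]
        if missing:
            raise ThermoError(f"NN table missing dinucleotides: {sorted(set(missing))}")
        if self.C_T <= 0:
            raise ThermoError(f"non-physical oligo concentration C_T={self.C_T}")
        if self.Na <= 0:
            raise ThermoError(f"non-physical salt concentration Na={self.Na}")

    def with_conditions(self, C_T: float | None = None,
                        Na: float | None = None) -> "ThermoParameters":
        """Copy of this parameter set with altered solution conditions."""
        kwargs = {}
        if C_T is not None:
            kwargs["C_T"] = C_T
        if Na is not None:
            kwargs["Na"] = Na
        return replace(self, **kwargs)


def _parse_table(text: str) -> dict:
    nn_dH: dict[str, float] = {}
    nn_dS: dict[str, float] = {}
    fields: dict[str, float] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 4:
            raise ThermoError(f"parameter table line {lineno}: expected 4 fields")
        kind, key, dh, ds = parts[0], parts[1], float(parts[2]), float(parts[3])
        if kind == "NN":
            nn_dH[key] = dh
            nn_dS[key] = ds
        elif kind == "INIT" and key == "GC":
            fields["init_dH_gc"], fields["init_dS_gc"] = dh, ds
        elif kind == "INIT" and key == "AT":
            fields["init_dH_at"], fields["init_dS_at"] = dh, ds
        elif kind == "SYM":
            fields["sym_dH"], fields["sym_dS"] = dh, ds
        else:
            raise ThermoError(f"parameter table line {lineno}: unknown row '{kind} {key}'")
    return {"nn_dH": nn_dH, "nn_dS": nn_dS, **fields}


def load_parameters(path: str | Path, **conditions) -> ThermoParameters:
    """Load a NN parameter table from a plain-text file."""
    text = Path(path).read_text()
    return ThermoParameters(**_parse_table(text), **conditions)


def load_default_parameters(**conditions) -> ThermoParameters:
    """Load the bundled SantaLucia 1998 unified parameter set."""
    text = (
        resources.files("primermap.data")
        .joinpath("santalucia1998_unified.tsv")
        .read_text()
    )
    return ThermoParameters(**_parse_table(text), **conditions)


_DEFAULT: ThermoParameters | None = None


def _default() -> ThermoParameters:
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = load_default_parameters()
    return _DEFAULT


def is_self_complementary(seq: str) -> bool:
    return seq == reverse_complement(seq)


def nn_sums(seq: str, params: ThermoParameters | None = None) -> tuple[float, float]:
    """Total duplex dH (kcal/mol) and dS (cal/(mol K)) for ``seq``.

    Sums initiation terms for both termini, every adjacent dinucleotide
    stack, and the symmetry correction when the oligo equals its own
    reverse complement.
    """
    params = params or _default()
    seq = normalize_sequence(seq)
    if len(seq) < 2:
        raise ThermoError("sequence too short for NN model (need length >= 2)")
    dH = dS = 0.0
    for terminal in (seq[0], seq[-1]):
        if terminal in "GC":
            dH += params.init_dH_gc
            dS += params.init_dS_gc
        else:
            dH += params.init_dH_at
            dS += params.init_dS_at
    for i in range(len(seq) - 1):
        nn = seq[i:i + 2]
        dH += params.nn_dH[nn]
        dS += params.nn_dS[nn]
    if is_self_complementary(seq):
        dH += params.sym_dH
        dS += params.sym_dS
    return dH, dS


def calc_tm(seq: str, params: ThermoParameters | None = None) -> float:
    """Melting temperature (degrees C) of ``seq`` under the NN model.

    Oligos shorter than 8 nt are rejected: they are outside the primer
    regime this model is parameterized for.
    """
    params = params or _default()
    seq = normalize_sequence(seq)
    if len(seq) < 8:
        raise ThermoError(
            f"oligo of length {len(seq)} rejected: primers must be >= 8 nt"
        )
    dH, dS = nn_sums(seq, params)
    x = 1.0 if is_self_complementary(seq) else 4.0
    tm_k = (1000.0 * dH) / (dS + params.R * math.log(params.C_T / x))
    tm_c = tm_k - 273.15 + 16.6 * math.log10(params.Na)
    if not math.isfinite(tm_c):
        raise ThermoError(f"non-finite Tm for sequence {seq!r}")
    return tm_c
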