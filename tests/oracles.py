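"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive and shares no code with the
package: its own complement table, its own GC arithmetic, its own
literal copy of the unified nearest-neighbor parameters, and plain
double loops for enumeration and occurrence counting.  The only package
function the design-pipeline oracle calls is ``calc_tm`` (whose own
correctness is pinned separately against the literal table below), so
that accepted/rejected decisions use identical Tm inputs.
"""

import math

from primermap.thermo import calc_tm

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

# unified duplex NN parameters, typed here independently of the package
# data file (dH kcal/mol, dS cal/(mol*K))
ORACLE_DH = {
    "AA": -7.9, "TT": -7.9, "AT": -7.2, "TA": -7.2,
    "CA": -8.5, "TG": -8.5, "GT": -8.4, "AC": -8.4,
    "CT": -7.8, "AG": -7.8, "GA": -8.2, "TC": -8.2,
    "CG": -10.6, "GC": -9.8, "GG": -8.0, "CC": -8.0,
}
ORACLE_DS = {
    "AA": -22.2, "TT": -22.2, "AT": -20.4, "TA": -21.3,
    "CA": -22.7, "TG": -22.7, "GT": -22.4, "AC": -22.4,
    "CT": -21.0, "AG": -21.0, "GA": -22.2, "TC": -22.2,
    "CG": -27.2, "GC": -24.4, "GG": -19.9, "CC": -19.9,
}


def oracle_revcomp(seq):
    return "".join(_COMP[b] for b in reversed(seq))


def oracle_gc(seq):
    return 100.0 * sum(1 for b in seq if b in "GC") / len(seq)


def oracle_nn_sums(seq):
    dh = ds = 0.0
    for terminal in (seq[0], seq[-1]):
        if terminal in "GC":
            dh += 0.1
            ds += -2.8
        else:
            dh += 2.3
            ds += 4.1
    for i in range(len(seq) - 1):
        dh += ORACLE_DH[seq[i:i + 2]]
        ds += ORACLE_DS[seq[i:i + 2]]
    if seq == oracle_revcomp(seq):
        ds += -1.4
    return dh, ds


def oracle_tm(seq, c_t=2.5e-7, na=0.05):
    dh, ds = oracle_nn_sums(seq)
    x = 1.0 if seq == oracle_revcomp(seq) else 4.0
    tm_k = 1000.0 * dh / (ds + 1.987 * math.log(c_t / x))
    return tm_k - 273.15 + 16.6 * math.log10(na)


def oracle_count(oligo, sequences):
    """Overlapping strand-aware occurrence count by sliding window."""
    rc = oracle_revcomp(oligo)
    n = 0
    for seq in sequences:
        for i in range(len(seq) - len(oligo) + 1):
            window = seq[i:i + len(oligo)]
            if window == oligo:
                n += 1
            if window == rc:
                n += 1
    return n


def oracle_enumerate(record, params, direction):
    """Naive double loop over (start, length) inside the window.

    Returns tuples (start, end, seq) in start-then-length order.
    """
    L = len(record.seq)
    out = []
    if direction == "forward":
        lo, hi = 1, min(params.five_prime_window, L)
    else:
        lo, hi = max(1, L - min(params.three_prime_window, L) + 1), L
    if hi - lo + 1 < params.len_min:
        return out
    for start in range(lo, hi + 1):
        for length in range(params.len_min, params.len_max + 1):
            end = start + length - 1
            if end > hi:
                continue
            slice_ = record.seq[start - 1:end]
            seq = slice_ if direction == "forward" else oracle_revcomp(slice_)
            out.append((start, end, seq))
    return out


def oracle_passes(seq, params):
    """Second implementation of the four compositional filters."""
    failed = []
    if not (params.len_min <= len(seq) <= params.len_max):
        failed.append("length")
    gc = oracle_gc(seq)
    if gc < params.gc_min or gc > params.gc_max:
        failed.append("gc_range")
    tm = calc_tm(seq)
    if tm < params.tm_min or tm > params.tm_max:
        failed.append("tm_range")
    if params.gc_clamp and seq[-1] not in ("G", "C"):
        failed.append("gc_clamp")
    return failed


def oracle_design(records, params):
    """End-to-end naive pipeline: enumerate, filter, specificity-screen.

    Returns, per record, the sorted list of accepted
    (start, end, direction, seq) tuples.
    """
    result = []
    all_seqs = [r.seq for r in records]
    for rec in records:
        scope = all_seqs if params.specificity_whole_file else [rec.seq]
        accepted = []
        for direction in ("forward", "reverse"):
            for start, end, seq in oracle_enumerate(rec, params, direction):
                if oracle_passes(seq, params):
                    continue
                self_count = 2 if seq == oracle_revcomp(seq) else 1
                if oracle_count(seq, scope) != self_count:
                    continue
                accepted.append((start, end, direction, seq))
        accepted.sort(key=lambda t: (t[0], 0 if t[2] == "forward" else 1,
                                     t[1] - t[0] + 1))
        result.append(accepted)
    return result
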