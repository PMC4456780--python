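# Methods

## Thermodynamic model

Primer melting temperatures come from the two-state nearest-neighbor
model: the duplex ΔH and ΔS are sums over adjacent dinucleotide stacks,
plus one initiation term per terminal base pair (split by G·C vs A·T
terminus) and a one-time entropic symmetry correction (−1.4 cal
mol⁻¹ K⁻¹) when the oligo equals its own reverse complement. The
bundled table is the SantaLucia (1998) unified duplex parameter set —
numerically identical to the Allawi & SantaLucia (1997) set that
Biopython ships as `DNA_NN3` — stored as a documented plain-text file
(`src/primermap/data/santalucia1998_unified.tsv`) so alternate
published sets can be swapped in via `thermo.load_parameters`. All 16
dinucleotides are listed explicitly and the loader enforces
completeness; the table is symmetric under reverse complement because
both readings name the same duplex stack, and a unit test pins the
shipped values against an independently typed copy.

Tm of a bimolecular duplex at total strand concentration C_T:

    Tm(K) = 1000·ΔH / (ΔS + R·ln(C_T/x)),   x = 4 (non-self-compl.), 1 (self-compl.)

converted to °C and adjusted by the Schildkraut–Lifson monovalent-salt
term 16.6·log10([Na⁺]). Defaults: C_T = 250 nM, [Na⁺] = 50 mM —
ordinary PCR-adjacent conditions. The simple logarithmic salt term was
chosen over entropy-based corrections to keep the formula closed-form
and directly comparable across implementations; users comparing against
tools that correct the entropy (e.g. length-dependent 0.368·N·ln[Na⁺])
should expect a systematic, length-dependent offset of a few tenths of
a degree. Mismatches, dangling ends, divalent cations, and
hairpin/dimer ΔG screening are out of scope. Oligos shorter than 8 nt
are rejected as outside the primer regime; `nn_sums` needs length ≥ 2.

In the physical regime (ΔH < 0 and ΔS + R·ln(C_T/4) < 0 for all
primer-like sequences under this table) Tm increases strictly with
C_T; the property suite verifies the observed direction numerically
rather than assuming the sign.

## Design procedure

Coordinates are 1-based inclusive throughout, matching the
start-position naming of primers and the map ruler. The forward search
window is positions 1…b and the reverse window the final c bases;
windows larger than the sequence are clamped to its length, so setting
b and c to the sequence length scans everything. Enumeration is the
full (start, length) grid within the window — every length in
[len_min, len_max] at every admissible start — rather than one fixed
length per start; an exhaustive double-loop oracle in the test suite
pins this choice. A window narrower than len_min yields an empty
candidate list with a logged warning, not an error, since short records
are legitimate input.

Filters are pure predicates that append a reason per failing rule
(length, gc_range, tm_range, gc_clamp) to the candidate's audit trail;
the GC clamp inspects the 3′-terminal base in synthesis orientation.
GC% is computed with exact rational arithmetic before the final float
conversion so boundary comparisons are reproducible.

Specificity is exact full-length matching: a candidate is accepted iff
its strand-aware occurrence count (oligo plus reverse complement,
overlapping matches included) over the screening scope equals its own
binding site — 1 for ordinary oligos, 2 for self-complementary ones,
whose single site matches on both strands. Overlap counting is the
stricter reading and was chosen deliberately. A 3′-seed/mismatch
binding model is a non-goal. The scope switch (whole file vs the
record alone) implies whole-file-accepted primers are always a subset
of record-scoped ones, and a dataset containing two copies of a record
can never yield a whole-file-specific primer; both properties are
tested.

Defaults (all overridable, echoed by `--help` and logged at run time):
5′/3′ windows 150 nt, lengths 18–24 nt, GC clamp on, GC 40–60 %, Tm
52–65 °C, whole-file specificity. These are conventional PCR values;
no ranking or "best primer" selection is performed — all passing
candidates are reported and downstream users filter.

Primer names are the start position in bp. Full-grid enumeration makes
bare start positions collide: a forward/reverse collision at the same
start gets an F/R suffix, and same-direction collisions (different
lengths at one start) additionally get a ".length" suffix, keeping
names unique within a set while staying recognizably positional.

## Mapping and rendering

Every designed primer is by construction an exact substring (forward)
or exact reverse-complement substring (reverse) of its target, so
mapping is coordinate bookkeeping plus a re-extraction verification:
the recorded slice, or its reverse complement, must equal the primer
sequence. This check is the pipeline's internal-consistency gate — an
external aligner would add nondeterminism without information, and no
gapped alignment is possible for exact substrings. A failure is
reported as an internal error, never a user error.

Alignment panels show the primer on its local context (default flank
25 nt, clamped at sequence ends) with ticks at the window and primer
edges; reverse primers are drawn on the target's coordinate system as
the complement of the slice, with orientation carried by the direction
annotation and the map glyph's arrowhead. Distribution maps draw the
target as a number line from 1 to L with one labeled arrow per primer,
right-pointing for forward and left-pointing for reverse; overlapping
glyphs are packed onto rows by greedy first-fit on start coordinate so
no two collide.

Raster outputs (PNG/JPEG/GIF panels, PNG maps) are for humans; every
image gets a JSON sidecar describing ruler extent and glyph geometry.
Pixel-level golden-image tests are brittle across rasterizer versions,
so the sidecar is the testable surface, and identical inputs produce
byte-identical sidecars. Panel dimensions and fonts are simple
documented defaults (Pillow's built-in bitmap font, 7×12 px cells).

## Synthetic data

The generator emits i.i.d. bases with a configurable GC probability
(split evenly between G and C), seeded through a single
`numpy.random.default_rng` with no global state; the JSON manifest
records the spec and realized per-record lengths and GC counts, and
identical specs produce identical bytes. A planting mechanism
overwrites a stated oligo at a stated 1-based position, which is how
duplicate-binding-site datasets for specificity tests are constructed.
What this emulates: arbitrary-scale multi-FASTA input with controllable
composition. What it does not: repeats, isochores, codon structure, or
any real-genome correlation — so green tests demonstrate correctness of
enumeration, filtering, screening, and rendering logic, not primer
performance on real genomes.

## Verification design

Each layer is checked against an independent route: FASTA round-trips
against the generator's own bookkeeping; the NN sums and Tm against a
standalone hand-summation oracle with its own literal table copy, and
against Biopython's `Tm_NN` configured on the same published unified
table with matched solution conditions (effective duplex concentration
C_T/4 = 62.5 nM, Schildkraut salt term) — the cross-implementation
linear-fit R² over 400 designed primers is the headline acceptance
statistic; enumeration, filtering, and the end-to-end pipeline against
naive brute-force re-implementations; mapping against exhaustive
substring search. Problem sizes in the automated checks (tens of
records, hundreds of nucleotides, 400 primers for the Tm comparison,
200 seeded monotonicity runs) were chosen to exercise every code path
with comfortable statistical margins while keeping the default suite
fast.

## Known limitations

- Ambiguity codes are rejected outright; soft-masking (lowercase) is
  folded away and the masking information discarded.
- Specificity is exact-match only; near-matches with a perfect 3′ seed
  are not flagged.
- No primer pairing, amplicon construction, dimer/hairpin screening,
  multiplexing, or penalty-based ranking.
- The salt correction ignores divalent cations (Mg²⁺), which matter in
  real PCR buffers.
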