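# primermap

Batch PCR primer design from multi-FASTA input, with nearest-neighbor
melting-temperature calculation, within-dataset specificity screening,
and graphical primer maps.

Designing primers one gene at a time stops scaling the moment a project
involves validating RNA-seq candidates, genotyping panels, multi-gene
families, primer walking, or assembly PCR. `primermap` takes any number
of DNA sequences in FASTA format and, for each one, designs forward and
reverse primers inside user-set 5′ and 3′ search windows, then renders
a per-primer alignment panel and a per-sequence distribution map so the
position and spread of every primer can be checked at a glance.

## The algorithm

For each target of length *L*:

1. **Enumerate** every substring of length `len_min`…`len_max` whose
   span lies inside the 5′ window (positions 1…*b*) as a forward
   candidate, and every substring inside the final *c* bases as a
   reverse candidate (its primer sequence is the reverse complement of
   the covered slice).
2. **Filter** each candidate on length, GC% range, Tm range, and — if
   requested — a 3′ **GC clamp** (the synthesis-end base must be G or
   C). Every failing rule is recorded in the candidate's audit trail.
3. **Screen specificity**: a candidate is accepted only if its exact,
   strand-aware occurrence count (matches of the oligo plus matches of
   its reverse complement, overlaps included) over the screening scope
   — the whole input file, or the target alone — equals its own single
   binding site.
4. **Map and render**: each accepted primer is verified by
   re-extraction against its target coordinates, then drawn as a panel
   showing the primer on its local sequence context and as an arrowed
   glyph (pointing in the direction of synthesis, named by start
   position) on a number-line map of the whole target.

Melting temperatures use the unified nearest-neighbor model. For an
oligo with total duplex enthalpy ΔH (kcal/mol) and entropy ΔS
(cal mol⁻¹ K⁻¹) summed from the SantaLucia (1998) unified dinucleotide
table plus initiation and symmetry terms:

```
Tm(°C) = 1000·ΔH / (ΔS + R·ln(C_T/x)) − 273.15 + 16.6·log10([Na+])
```

with R = 1.987 cal mol⁻¹ K⁻¹, total strand concentration
C_T = 250 nM, x = 4 (x = 1 for self-complementary oligos), and
[Na⁺] = 50 mM. See `docs/methods.md` for assumptions and numerical
details.

## Worked example

No input data is needed — a seeded generator ships with the tool:

```
$ primermap synthetic --seed 3 --n-records 2 --out demo.fasta
wrote demo.fasta and demo.fasta.manifest.json

$ primermap -a demo.fasta --out-dir demo_out --panel-format png
INFO primermap.design: record syn0000: 82/1820 candidates accepted (attrition={'gc_range': 837, 'gc_clamp': 832, 'tm_range': 1101})
INFO primermap.design: record syn0001: 143/1820 candidates accepted (attrition={'tm_range': 1051, 'gc_clamp': 874, 'gc_range': 818})
INFO primermap: done: 225 primers across 2 records
```

Each record yielded 1820 raw candidates (two 150-nt windows × lengths
18–24); the attrition table says how many failed each filter (a
candidate can fail several). The accepted primers land in
`demo_out/report.tsv`:

```
target_id  name  direction  start  end  length  seq                     tm     gc
syn0000    14    forward    14     35   22      GTCGGCATCCTGCTAGCAGTAG  52.63  59.09
syn0000    15    forward    15     36   22      TCGGCATCCTGCTAGCAGTAGC  54.44  59.09
```

`name` is the primer's start position on its target; `tm` (°C) and `gc`
(%) are the values the filters saw. Alongside the report,
`demo_out/` contains one alignment panel per primer
(`syn0000_14.png`, …), one distribution map per target
(`syn0000_map.png`), and a JSON sidecar per image describing ruler
extent and glyph geometry for machine checking.

All of the paper-style short flags are supported: `-a` input, `-b`/`-c`
5′/3′ search windows, `-d`/`-e` max/min length, `-f` GC clamp (Y/N),
`-g`/`-h` upper/lower GC%, `-i`/`-j` upper/lower Tm, `-k` whole-file
vs per-sequence specificity (Y/N). Because `-h` is the lower-GC-bound
flag, help is on `--help`, where every default is printed. A YAML
config file (`--config`) can stand in for flags; flags win on conflict.

Exit codes: 0 success (even if some records yield no primers),
2 usage error, 3 invalid input, 4 I/O failure, 5 internal
consistency error.

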