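# Unified nearest-neighbor duplex parameters for DNA/DNA hybridization
# (SantaLucia, PNAS 95:1460-1465, 1998), 1 M NaCl reference state.
#
# Schema (tab-separated, '#' starts a comment):
#   NN   <dinucleotide 5'->3'>  <dH kcal/mol>  <dS cal/(mol*K)>
#   INIT <GC|AT>                <dH kcal/mol>  <dS cal/(mol*K)>
#   SYM  -                      <dH kcal/mol>  <dS cal/(mol*K)>
#
# All 16 dinucleotides are listed explicitly; the table is symmetric under
# reverse complement (dH(xy) == dH(revcomp(xy)), likewise dS), because a
# stack read 5'->3' on one strand is the reverse-complement stack read
# 5'->3' on the other strand of the same duplex.
NN	AA	-7.9	-22.2
NN	TT	-7.9	-22.2
NN	AT	-7.2	-20.4
NN	TA	-7.2	-21.3
NN	CA	-8.5	-22.7
NN	TG	-8.5	-22.7
NN	GT	-8.4	-22.4
NN	AC	-8.4	-22.4
NN	CT	-7.8	-21.0
NN	AG	-7.8	-21.0
NN	GA	-8.2	-22.2
NN	TC	-8.2	-22.2
NN	CG	-10.6	-27.2
NN	GC	-9.8	-24.4
NN	GG	-8.0	-19.9
NN	CC	-8.0	-19.9
# Duplex initiation, split by the identity of each terminal base pair.
INIT	GC	0.1	-2.8
INIT	AT	2.3	4.1
# Entropic symmetry correction applied once when the oligo is
# self-complementary.
SYM	-	0.0	-1.4
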