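# Mini pentose phosphate toy: transketolase/transaldolase carbon shuffling
# with reversible steps; one free flux plus exchanges.
@substrate X.ext
@uptake upt
@unbalanced X.ext
upt: X.ext (abcde) -> X5P (abcde)
iso: X5P (abcde) <-> R5P (abcde)
tkt1: X5P (abcde) + R5P (fghij) <-> S7P (abfghij) + GAP (cde)
tkt2: X5P (abcde) + E4P (fghi) <-> F6P (abfghi) + GAP (cde)
tal: S7P (abcdefg) + GAP (hij) <-> F6P (abchij) + E4P (defg)
outF: F6P ->
outG: GAP ->
outR: R5P ->
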