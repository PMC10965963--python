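# Cleavage/condensation toy: A is split into one-carbon units that
# recombine (with carbon order swapped) in parallel to a direct route.
@substrate A.ext
@uptake upt
@unbalanced A.ext
upt: A.ext (ab) -> A (ab)
split: A (ab) -> B (a) + C (b)
cond: B (a) + C (b) -> D (ba)
direct: A (ab) -> D (ab)
outD: D ->
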