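# Two-carbon linear chain; identity carbon maps.
@substrate A.ext
@uptake upt
@unbalanced A.ext
upt: A.ext (ab) -> A (ab)
r1: A (ab) -> B (ab)
r2: B (ab) -> C (ab)
outC: C ->
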