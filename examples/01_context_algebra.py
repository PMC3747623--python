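"""Mutation-context algebra: enumeration, subcontexts, strand complement.

A mutation context {X>Y|pos,W} pins a substitution to a position inside a
short word; subcontexts are the same mutation seen through every contiguous
subword still covering that position.
"""

import contextmut as cm

ctx = cm.MutationContext.parse("{C>T|2,ACG}")
print(f"context: {ctx}  (substitution {ctx.substitution}, {ctx.substitution.classification})")
print("proper subcontexts:", ", ".join(str(s) for s in cm.subcontexts(ctx)))
# every mutation matching {C>T|2,ACG} also matches each of these

rc = cm.reverse_complement(ctx)
print(f"reverse complement: {rc}  (same mutation read on the other strand)")

universe = cm.enumerate_contexts(2, 4)
print(f"full 2-4 bp context universe: {len(universe)} contexts "
      "(96 two-bp + 576 three-bp + 3072 four-bp)")
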