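"""Recover a planted hypermutable context from mutation-bias statistics.

Mutation bias contrasts a context against its bare mutated base.  Because
the base's event count includes the context's own sites, a planted rate
multiplier m with context coverage q is seen as bias m/(1+(m-1)q); the
closed form inverts to recover m itself.
"""

import contextmut as cm

cpg = cm.MutationContext.parse("{C>T|1,CG}")
config = cm.SimulationConfig(length=100_000, seed=4, multipliers={cpg: 8.0},
                             outgroup_divergence=0.0, gap_rate=0.0, multiallelic_rate=0.0)
block, roster, truth = cm.simulate(config)

events = cm.call_mutations([block], roster)
freqs = cm.alignment_word_table([block], roster)  # conserved-region measure
counts = cm.count_contexts(events)

bias = cm.mutation_bias(cpg, counts, freqs)
mc, argmin = cm.minimal_contrast(cpg, counts, freqs)
print(f"{cpg}: N={counts.n(cpg)}")
print(f"  mutation bias        {bias:.3f}  (truth expectation {truth.expected_bias[cpg]:.3f})")
print(f"  minimal contrast     {mc:.3f}  vs subcontext {argmin}")
print(f"  implied multiplier   {cm.estimate_multiplier(cpg, counts, freqs):.2f}  (planted 8.0)")
# bias ~3.3 is the ceiling-compressed signature of the x8 multiplier: with
# ~20% of C sites followed by G, an 8-fold CpG rate also inflates the C>T
# baseline the bias is measured against
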