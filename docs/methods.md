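# Methods

## Data model and calling procedure

The unit of observation is an alignment column of N focal genomes (default
world: N = 37) plus at least two outgroup genomes.  The ancestral state is
reconstructed by strict agreement of all outgroups — a two-outgroup
parsimony with no probabilistic reconstruction.  A column yields exactly
one mutation event when the four conditions hold (outgroup agreement;
ancestral allele segregating among the focal genomes; exactly two clean
focal variants; ±3 flanking columns monomorphic and ungapped across every
row).  Each variable column contributes one event regardless of its
derived-allele count: the estimand is the mutation, not per-genome allele
observations.  The derived-allele count is recorded for downstream use but
enters no statistic here.

Interpretation choices where the procedure is underdetermined:

- "No substitutions or gaps" in the flank condition is read as
  *monomorphic and ungapped across focal and outgroup rows* — the flanks
  define the ancestral context, which must be unambiguous.  This is the
  strictest consistent reading (`flank-scope = all rows`).
- A gap or ambiguity code in any focal genome makes the column
  non-callable (`min_focal_present` defaults to all focal genomes
  present).  The alternative reading (two clean variants among present
  genomes) is available via the `min_focal_present` argument of
  `call_mutations`.
- Flank windows are alignment columns, not reference coordinates; by the
  flank condition itself the window is gap-free, so the two views coincide
  within it.
- Events need a reference coordinate; columns where the reference row is
  gapped are non-callable.
- Blocks missing any roster member (absent, not merely gapped) produce no
  calls and no conserved columns.

## Contrast estimation

For context c and subcontext s, `Contrast(c,s) = (N_c/P_W)/(N_s/P_W′)`
with P taken among words of the same length.  Algebraically the estimator
telescopes: for any nested chain the product of stepwise contrasts equals
the direct contrast exactly, which the tests assert to 1e-9 relative
tolerance (floating round-off only).

Denominator choice: word frequencies default to the conserved-region
measure — maximal runs of columns where the outgroups agree, no row is
gapped or unread, and the ancestral base matches a focal variant — counted
on the ancestral base with an overlapping window, never spanning a run
boundary.  The complete-alignment measure (ancestral-consensus row of
every block) is available via `measure="complete"`; on clean, fully
conserved synthetic data the two coincide.

Undefined ratios (subcontext with zero events or zero word frequency) are
flagged, not smoothed; a pseudocount argument exists for exploratory use
but defaults to 0 since the statistics are reported as raw ratios.  A
`min_count` report filter flags low-N contexts without dropping them.
Minimal-contrast ties on |value−1| break deterministically to the shorter
subcontext word, then lexicographically smaller word, then smaller
position; the rule is arbitrary but frozen and tested.

Complementary contexts are computed and reported separately — mutation
processes need not be strand-symmetric, and pooling would hide asymmetric
signals.  `scatter_data` assigns each context a pair id shared with its
reverse complement so pairing is inspectable; pooling, if wanted, is a
caller-side aggregation over that id.

## Representation score

`Exp(W) = P(prefix_{k−1}) · P(suffix_{k−1}) / P(middle_{k−2})`, the
maximal-order Markov estimate, with the empty middle word's frequency
defined as 1 so that k = 2 reduces to the independence product.  "Based on
all subwords" admits other estimators; this one is isolated behind
`expected_frequency` so an alternative can be swapped in.  C is computed
from frequencies, not counts, and is therefore invariant under duplicating
the input sequence.

## Synthetic worlds

The generator emulates the data model, not population genetics: a star
genealogy with one round of mutation, because every estimator consumes
only per-column allele patterns.  Defaults state the emulated world:

| parameter | default | why |
|---|---|---|
| length | 100 kb | desk-scale yet ~3k events at default rates |
| base composition | A .2979, C .2022, G .2021, T .2978 | the focal species' intergenic alignment composition |
| n_focal / n_outgroups | 37 / 2 | the population-alignment design |
| base_rate | 0.01 /site/derived base | gives per-2-mer-context counts of ~30–80 at 100 kb, enough for ratio statistics |
| outgroup_divergence | 0.01 | low-divergence outgroups |
| gap_rate / multiallelic_rate | 0.001 / 0.0005 | occasional filter-exercising noise |

Planted hotspots are a map {context → multiplier}; the longest matching
context wins at a site (equal lengths: canonical string order, later
wins).  Planted events are thinned to ≥4 bp spacing and ≥3 bp from the
edges, and all noise is injected ≥4 bp from planted events, so the planted
truth is exactly callable: caller recall and precision are 1.0 by
construction on noise-free runs, and recall stays 1.0 under noise.  The
spacing thinning is context-blind, so it cancels from all contrast ratios.

**Expected bias is not the multiplier.**  Mutation bias contrasts a
context against its 1-bp subcontext, whose event count includes the
context's own sites.  For multiplier m and coverage q (the fraction of the
mutated base's sites lying in the context), the expected bias is
b = m / (1 + (m−1) q), bounded above by 1/q — with q ≈ 0.2 for a
dinucleotide context, an 8× multiplier appears as bias ≈ 3.3 and *no*
multiplier can push a dinucleotide bias past ≈ 5.  `SimulationTruth`
therefore records the exact expectation evaluated on the realized
ancestral sequence, and `multiplier_from_bias(b, q) = b(1−q)/(1−bq)`
inverts the closed form; recovery tests check the bias against its
expectation and the inverted multiplier against the planted value, each
within 3 delta-method standard errors.  What a green recovery test
establishes: the calling conditions, context counting and ratio estimator
are jointly unbiased under the generator's model.  What it does not:
robustness to misalignment, outgroup homoplasy (parallel outgroup
mutation would mispolarize events), selection, or genealogical correlation
between haplotypes — none of which the star-model generator emulates.

Single-strand planting is deliberate: a multiplier applies to the stated
context only, so planting `{C>T|1,CG}` elevates that context and not its
reverse complement.  Strand-symmetric worlds arise from the symmetric
baseline (uniform per-substitution rates, near-symmetric composition),
which is what the paired-dots property tests use.

## Numerical and degenerate-input choices

- Bias/contrast standard errors used in tests are delta-method:
  SE(b) = b·√((1−p̂)/N_c) with p̂ = N_c/N_s, from the conditional binomial
  N_c | N_s.
- `contrast(ctx, ctx) = 1` by convention, so the bias of a length-1
  context is exactly 1.
- Zero events with an observed word give contrast 0; events in an
  unobserved word raise a data-inconsistency error.
- Composition differences display at 1-decimal rounding,
  (all − conserved)/all × 100; empty conserved masks report NA.
- Published two-species reference values (spectrum fractions,
  representation scores) ship as packaged TSVs transcribed from the
  printed tables; they are comparison inputs, never recomputed.  The
  printed human transition fractions sum to 0.644 against a printed total
  of 0.645 (rounding in the source table); the package asserts only the
  internally consistent totals.

## Known limitations

- Ancestral reconstruction is agreement-only; sites where outgroups carry
  a shared derived allele are silently mispolarized in real data (the
  generator never creates them).
- Discontiguous contexts (CNG-style) are out of scope, as are words
  beyond 4 bp.
- No confidence intervals on reported contrasts; the statistics are point
  ratios, and the test-suite SE formulas are for calibration checks, not
  inference.
- MAF handling assumes the reference row is present in every block;
  chain/net lifting and alignment production are out of scope.
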