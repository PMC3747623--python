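"""Shared fixtures: seeded simulations reused across test modules, and
independent brute-force oracles the fast implementations are checked
against."""

from __future__ import annotations

import numpy as np
import pytest

import contextmut as cm
from contextmut.calling import MutationEvent
from contextmut.contexts import BASES, MutationContext


# ---------------------------------------------------------------- oracles
def brute_subcontexts(ctx: MutationContext) -> set[MutationContext]:
    """All proper contiguous subwords containing the mutated position, by
    exhaustive (start, end) enumeration."""
    k = len(ctx.word)
    i = ctx.pos - 1
    out = set()
    for start in range(k):
        for end in range(start + 1, k + 1):
            if (start, end) == (0, k):
                continue  # proper subwords only
            if start <= i < end:
                out.add(MutationContext(ctx.word[start:end], i - start + 1, ctx.derived))
    return out


def brute_count_contexts(events, min_len=1, max_len=4) -> dict[MutationContext, int]:
    """Per-event, per-enumerated-context matching recount."""
    counts: dict[MutationContext, int] = {}
    universe = cm.enumerate_contexts(min_len, max_len)
    for e in events:
        word7 = e.left_flank + e.ancestral + e.right_flank
        for ctx in universe:
            if ctx.derived != e.derived:
                continue
            start = 3 - (ctx.pos - 1)
            if start < 0 or start + len(ctx.word) > 7:
                continue
            if word7[start : start + len(ctx.word)] == ctx.word:
                counts[ctx] = counts.get(ctx, 0) + 1
    return counts


def brute_word_counts(seq: str, k: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k].upper()
        if all(b in BASES for b in w):
            counts[w] = counts.get(w, 0) + 1
    return counts


def naive_column_caller(block, roster) -> list[MutationEvent]:
    """Independent per-column re-check of the four calling conditions using
    the string column iterator (no bit tricks)."""
    cols = list(cm.iterate_columns(block, roster))
    n = len(cols)
    events = []

    def mono_clean(j):
        symbols = set(cols[j][1].values())
        return len(symbols) == 1 and symbols <= set(BASES)

    for j in range(3, n - 3):
        coord, symbols = cols[j]
        og = {symbols[o] for o in roster.outgroups}
        if len(og) != 1 or not og <= set(BASES):
            continue  # condition 1
        anc = og.pop()
        focal = [symbols[f] for f in roster.focal]
        variants = set(focal)
        if not variants <= set(BASES) or len(variants) != 2:
            continue  # condition 3 (gaps/N reject outright)
        if anc not in variants:
            continue  # condition 2
        if not all(mono_clean(j + off) for off in (-3, -2, -1, 1, 2, 3)):
            continue  # condition 4
        if coord is None:
            continue
        derived = (variants - {anc}).pop()
        left = "".join(next(iter(set(cols[j + off][1].values()))) for off in (-3, -2, -1))
        right = "".join(next(iter(set(cols[j + off][1].values()))) for off in (1, 2, 3))
        events.append(
            MutationEvent(block.ref_chrom, coord, anc, derived, left, right, focal.count(derived))
        )
    return events


def bias_standard_error(bias: float, n_ctx: int, n_sub: int) -> float:
    """Delta-method SE of a bias/contrast estimate: conditional on the
    subcontext count, the context count is binomial."""
    p = n_ctx / n_sub
    return bias * np.sqrt(max(1.0 - p, 0.0) / max(n_ctx, 1))


# ------------------------------------------------------------ simulations
@pytest.fixture(scope="session")
def null_sim():
    """Context-independent 100 kb simulation of 37 haplotypes, default noise
    levels, fixed seed: the calibration world."""
    cfg = cm.SimulationConfig(length=100_000, seed=11)
    block, roster, truth = cm.simulate(cfg)
    return cfg, block, roster, truth


@pytest.fixture(scope="session")
def null_stats(null_sim):
    cfg, block, roster, truth = null_sim
    mask = cm.conserved_mask([block], roster)
    freqs = cm.alignment_word_table([block], roster, mask=mask)
    events = cm.call_mutations([block], roster)
    counts = cm.count_contexts(events)
    return events, counts, freqs


@pytest.fixture(scope="session")
def planted_sim():
    """Noise-free 100 kb simulation with two planted hotspots: C>T in CpG
    (x8) and A>C at the third position of CCA (x3)."""
    multipliers = {
        cm.MutationContext.parse("{C>T|1,CG}"): 8.0,
        cm.MutationContext.parse("{A>C|3,CCA}"): 3.0,
    }
    cfg = cm.SimulationConfig(
        length=100_000,
        seed=7,
        multipliers=multipliers,
        outgroup_divergence=0.0,
        gap_rate=0.0,
        multiallelic_rate=0.0,
    )
    block, roster, truth = cm.simulate(cfg)
    return cfg, block, roster, truth


@pytest.fixture(scope="session")
def planted_stats(planted_sim):
    cfg, block, roster, truth = planted_sim
    mask = cm.conserved_mask([block], roster)
    freqs = cm.alignment_word_table([block], roster, mask=mask)
    events = cm.call_mutations([block], roster)
    counts = cm.count_contexts(events)
    return events, counts, freqs


@pytest.fixture(scope="session")
def random_events():
    """1000 random mutation events with arbitrary clean flanks."""
    rng = np.random.default_rng(42)
    events = []
    for i in range(1000):
        codes = rng.integers(0, 4, size=7)
        anc = BASES[codes[3]]
        derived = BASES[(codes[3] + rng.integers(1, 4)) % 4]
        left = "".join(BASES[c] for c in codes[:3])
        right = "".join(BASES[c] for c in codes[4:])
        events.append(MutationEvent("chr", i * 10, anc, derived, left, right, int(rng.integers(1, 37))))
    return events
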