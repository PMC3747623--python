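"""Synthetic population alignments with known context-dependent mutagenesis.

The generator emulates the data model behind the pipeline: an ancestral
intergenic sequence, two low-divergence outgroups that retain the ancestral
state (plus optional private divergence), and N focal haplotypes carrying
biallelic derived alleles.  Per site and derived base, the event
probability is ``base_rate x multiplier(ctx)``, where the multiplier comes
from the longest planted context whose word matches the ancestral sequence
at that site (1 where none matches).  Each event is given to a uniformly
drawn derived-allele count in 1..N-1, so the biallelic logic is always
exercised.  A star genealogy (no coalescent structure) is used throughout:
the estimators consume only per-column allele patterns.

Planted events are spaced at least 4 bp apart and kept 3 bp from the
sequence edges, and all noise (outgroup private divergence, gaps,
multiallelic columns) is injected at least 4 bp away from planted events,
so every planted event is callable and caller recall/precision on a
noise-free truth is exactly 1.

Because mutation bias contrasts a context against its 1-bp subcontext,
whose event count includes the planted-context sites, the expected bias of
a planted multiplier ``m`` is not ``m`` but ``m / (1 + (m - 1) q)``, where
``q`` is the fraction of the mutated base's sites covered by the context
word; the truth table records this exact expectation, and
:func:`multiplier_from_bias` inverts it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .alignio import AlignmentBlock, SpeciesRoster
from .contexts import MutationContext
from .contrast import ContextCounts
from .words import WordFrequencyTable

_BASES = "ACGT"

# Defaults state the emulated world: 37 focal genomes with two outgroups, an
# intergenic base composition matching the focal species' alignments
# (A/T-rich: a,t ~ 0.298, c,g ~ 0.202), ~1% private outgroup divergence and
# occasional gap/multiallelic noise to exercise the filters.
_DEFAULT_COMPOSITION = (0.2979, 0.2022, 0.2021, 0.2978)


@dataclass
class SimulationConfig:
    length: int = 100_000
    base_composition: tuple[float, float, float, float] = _DEFAULT_COMPOSITION
    n_focal: int = 37
    n_outgroups: int = 2
    base_rate: float = 0.01  # expected events per site per derived base
    multipliers: Mapping[MutationContext, float] = field(default_factory=dict)
    outgroup_divergence: float = 0.01
    gap_rate: float = 0.001
    multiallelic_rate: float = 0.0005
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.base_composition) - 1.0) > 1e-9:
            raise ValueError("base composition must sum to 1")
        if min(self.base_rate, self.outgroup_divergence, self.gap_rate, self.multiallelic_rate) < 0:
            raise ValueError("rates must be nonnegative")
        if any(m <= 0 for m in self.multipliers.values()):
            raise ValueError("multipliers must be positive")
        if self.n_focal < 2 or self.n_outgroups < 2:
            raise ValueError("need >=2 focal haplotypes and >=2 outgroups")


@dataclass
class SimulationTruth:
    """What was planted: per-event records, the multiplier map, and the exact
    expected mutation bias per planted context."""

    events: pd.DataFrame  # pos, ancestral, derived, derived_count, multiplier, context
    multipliers: dict[MutationContext, float]
    expected_bias: dict[MutationContext, float]


def _focal_names(n: int) -> list[str]:
    return [f"focal_{i:02d}" for i in range(1, n + 1)]


def _context_site_matches(anc: np.ndarray, ctx: MutationContext) -> np.ndarray:
    """Boolean array: sites whose ancestral window matches ctx's word with the
    mutated base at the site."""
    word = np.array([_BASES.index(b) for b in ctx.word], dtype=np.int8)
    k, p = len(word), ctx.pos - 1
    match = np.zeros(len(anc), dtype=bool)
    lo, hi = p, len(anc) - (k - 1 - p)  # window must fit around the site
    if hi <= lo:
        return match
    window_ok = np.ones(hi - lo, dtype=bool)
    for j in range(k):
        window_ok &= anc[lo - p + j : hi - p + j] == word[j]
    match[lo:hi] = window_ok
    return match


def simulate(config: SimulationConfig) -> tuple[AlignmentBlock, SpeciesRoster, SimulationTruth]:
    """Generate one aligned block plus its roster and truth table.

    Deterministic: the same config (including seed) yields byte-identical
    rows."""
    rng = np.random.default_rng(config.seed)
    L, N = config.length, config.n_focal
    anc = rng.choice(4, size=L, p=np.asarray(config.base_composition)).astype(np.int8)

    # per-site, per-derived-base rates; longest planted context wins,
    # equal lengths resolved by canonical string order (later wins)
    rates = np.zeros((L, 4))
    for d in range(4):
        rates[:, d] = np.where(anc == d, 0.0, config.base_rate)
    mult_at = np.ones((L, 4))
    ctx_at = np.full((L, 4), "", dtype=object)
    for ctx in sorted(config.multipliers, key=lambda c: (c.length, str(c))):
        m = config.multipliers[ctx]
        d = _BASES.index(ctx.derived)
        sites = _context_site_matches(anc, ctx)
        rates[sites, d] = config.base_rate * m
        mult_at[sites, d] = m
        ctx_at[sites, d] = str(ctx)

    # draw events; a site with several hits keeps the smallest uniform draw
    u = rng.random((L, 4))
    hits = u < rates
    any_hit = hits.any(axis=1)
    u_masked = np.where(hits, u, np.inf)
    derived = np.argmin(u_masked, axis=1)
    candidates = np.flatnonzero(any_hit)

    # enforce callability: >=3 bp from edges, >=4 bp between events
    kept: list[int] = []
    last = -(10)
    for pos in candidates:
        if pos < 3 or pos >= L - 3:
            continue
        if pos - last >= 4:
            kept.append(int(pos))
            last = int(pos)
    kept_arr = np.array(kept, dtype=np.int64)

    # focal haplotypes: ancestral everywhere, derived allele in a uniform
    # 1..N-1 subset at each event site
    H = np.tile(anc, (N, 1))
    derived_counts = rng.integers(1, N, size=len(kept)) if kept else np.empty(0, dtype=int)
    records = []
    for pos, c in zip(kept, derived_counts):
        d = int(derived[pos])
        carriers = rng.choice(N, size=int(c), replace=False)
        H[carriers, pos] = d
        records.append(
            (pos, _BASES[anc[pos]], _BASES[d], int(c), float(mult_at[pos, d]), ctx_at[pos, d])
        )

    O = np.tile(anc, (config.n_outgroups, 1))

    # noise only at sites >= 4 bp from any planted event
    near_event = np.zeros(L, dtype=bool)
    for pos in kept:
        near_event[max(0, pos - 3) : pos + 4] = True
    allowed = ~near_event

    if config.outgroup_divergence > 0:
        for i in range(config.n_outgroups):
            div = allowed & (rng.random(L) < config.outgroup_divergence)
            shift = rng.integers(1, 4, size=int(div.sum()))
            O[i, div] = (O[i, div] + shift) % 4

    GAP = 4
    if config.multiallelic_rate > 0:
        tri_sites = np.flatnonzero(allowed & (rng.random(L) < config.multiallelic_rate))
        for pos in tri_sites:
            d1, d2 = [(anc[pos] + s) % 4 for s in rng.permutation([1, 2, 3])[:2]]
            rows_ = rng.permutation(N)
            c1 = int(rng.integers(1, N - 1))
            c2 = int(rng.integers(1, N - c1))
            H[rows_[:c1], pos] = d1
            H[rows_[c1 : c1 + c2], pos] = d2
        allowed = allowed.copy()
        allowed[tri_sites] = False
    if config.gap_rate > 0:
        gap_sites = np.flatnonzero(allowed & (rng.random(L) < config.gap_rate))
        all_rows = N + config.n_outgroups
        which_row = rng.integers(0, all_rows, size=len(gap_sites))
        for pos, r in zip(gap_sites, which_row):
            if r < N:
                H[r, pos] = GAP
            else:
                O[r - N, pos] = GAP

    alphabet = np.frombuffer(b"ACGT-", dtype=np.uint8)
    focal_names = _focal_names(N)
    og_names = [f"outgroup_{i}" for i in range(1, config.n_outgroups + 1)]
    rows = {name: alphabet[H[i]].tobytes().decode() for i, name in enumerate(focal_names)}
    rows.update({name: alphabet[O[i]].tobytes().decode() for i, name in enumerate(og_names)})
    roster = SpeciesRoster(tuple(focal_names), tuple(og_names), focal_names[0])
    block = AlignmentBlock("sim", "simchr", 0, rows)

    truth_events = pd.DataFrame(
        records, columns=["pos", "ancestral", "derived", "derived_count", "multiplier", "context"]
    )
    expected = {
        ctx: expected_bias(ctx, anc, config) for ctx in config.multipliers
    }
    truth = SimulationTruth(truth_events, dict(config.multipliers), expected)
    return block, roster, truth


def expected_bias(ctx: MutationContext, anc: np.ndarray, config: SimulationConfig) -> float:
    """Exact expected mutation bias of ``ctx`` on the realized ancestral
    sequence under the planted rate model.

    Computed as (E N_ctx / P_W) / (E N_base / P_b) with expected counts
    summed over the per-site rates; uniform spacing/edge thinning cancels in
    the ratio."""
    L = len(anc)
    d = _BASES.index(ctx.derived)
    b = _BASES.index(ctx.ancestral)
    rates = np.where(anc == d, 0.0, config.base_rate)
    for other in sorted(config.multipliers, key=lambda c: (c.length, str(c))):
        if other.derived != ctx.derived:
            continue
        sites = _context_site_matches(anc, other)
        rates[sites] = config.base_rate * config.multipliers[other]
    ctx_sites = _context_site_matches(anc, ctx)
    base_sites = anc == b
    en_ctx = rates[ctx_sites].sum()
    en_base = rates[base_sites].sum()
    k = ctx.length
    p_w = ctx_sites.sum() / (L - k + 1)
    p_b = base_sites.sum() / L
    if en_base == 0 or p_w == 0:
        return float("nan")
    return (en_ctx / p_w) / (en_base / p_b)


def context_coverage(ctx: MutationContext, freqs: WordFrequencyTable) -> float:
    """q: the fraction of the mutated base's occurrences that sit at
    position ``pos`` of the context word, estimated from word counts."""
    n_base = freqs.count(ctx.ancestral)
    if n_base == 0:
        return float("nan")
    return freqs.count(ctx.word) / n_base


def multiplier_from_bias(bias: float, coverage: float) -> float:
    """Invert bias = m / (1 + (m-1) q): the planted rate multiplier implied
    by an observed mutation bias and context coverage q (requires
    bias * q < 1)."""
    denom = 1.0 - bias * coverage
    if denom <= 0:
        return float("inf")
    return bias * (1.0 - coverage) / denom


def estimate_multiplier(
    ctx: MutationContext, counts: ContextCounts, freqs: WordFrequencyTable
) -> float:
    """Planted-multiplier estimate from observed bias and coverage."""
    from .contrast import mutation_bias

    return multiplier_from_bias(mutation_bias(ctx, counts, freqs), context_coverage(ctx, freqs))


# -- hand-readable micro-fixtures -------------------------------------------

_FIXTURES: dict[str, dict] = {}


def _fixture(name: str, focal: list[str], outgroups: list[str], expected_events: int, note: str):
    _FIXTURES[name] = {
        "focal": focal,
        "outgroups": outgroups,
        "expected_events": expected_events,
        "note": note,
    }


# 4 focal rows + 2 outgroups, 15 columns; the variable column is column 7
# (0-based), flanked by 3 clean monomorphic columns on each side.
_fixture(
    "clean_biallelic",
    focal=[
        "AAGTACGCGTATTGA",
        "AAGTACGCGTATTGA",
        "AAGTACGTGTATTGA",
        "AAGTACGTGTATTGA",
    ],
    outgroups=[
        "AAGTACGCGTATTGA",
        "AAGTACGCGTATTGA",
    ],
    expected_events=1,
    note="one C>T event at column 7 with flanks ACG / GTA",
)
_fixture(
    "triallelic",
    focal=[
        "AAGTACGCGTATTGA",
        "AAGTACGAGTATTGA",
        "AAGTACGTGTATTGA",
        "AAGTACGTGTATTGA",
    ],
    outgroups=[
        "AAGTACGCGTATTGA",
        "AAGTACGCGTATTGA",
    ],
    expected_events=0,
    note="three focal variants violate the two-variant condition",
)
_fixture(
    "flank_gap",
    focal=[
        "AAGTACGCGTATTGA",
        "AAGTACGCGTATTGA",
        "AAGTACGTGTATTGA",
        "AAGTACGTGTATTGA",
    ],
    outgroups=[
        "AAGTACGCGTATTGA",
        "AAGTA-GCGTATTGA",
    ],
    expected_events=0,
    note="a gap 2 bp upstream in one outgroup breaks the flank condition",
)
_fixture(
    "outgroup_disagree",
    focal=[
        "AAGTACGCGTATTGA",
        "AAGTACGCGTATTGA",
        "AAGTACGTGTATTGA",
        "AAGTACGTGTATTGA",
    ],
    outgroups=[
        "AAGTACGCGTATTGA",
        "AAGTACGAGTATTGA",
    ],
    expected_events=0,
    note="outgroups disagree, so the ancestral state is unknown",
)
_fixture(
    "no_ancestral_match",
    focal=[
        "AAGTACGTGTATTGA",
        "AAGTACGTGTATTGA",
        "AAGTACGGGTATTGA",
        "AAGTACGGGTATTGA",
    ],
    outgroups=[
        "AAGTACGCGTATTGA",
        "AAGTACGCGTATTGA",
    ],
    expected_events=0,
    note="no focal genome carries the ancestral base",
)
_fixture(
    "monomorphic",
    focal=["AAGTACGCGTATTGA"] * 4,
    outgroups=["AAGTACGCGTATTGA"] * 2,
    expected_events=0,
    note="no variation at all",
)


def fixture_names() -> list[str]:
    return sorted(_FIXTURES)


def make_fixture(name: str) -> tuple[AlignmentBlock, SpeciesRoster, dict]:
    """A tiny hand-readable alignment exercising one caller condition, with
    the expected caller outcome in the returned metadata dict."""
    try:
        spec = _FIXTURES[name]
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; known: {fixture_names()}") from None
    focal_names = [f"focal_{i:02d}" for i in range(1, len(spec["focal"]) + 1)]
    og_names = [f"outgroup_{i}" for i in range(1, len(spec["outgroups"]) + 1)]
    rows = dict(zip(focal_names, spec["focal"])) | dict(zip(og_names, spec["outgroups"]))
    roster = SpeciesRoster(tuple(focal_names), tuple(og_names), focal_names[0])
    block = AlignmentBlock(name, "fixchr", 0, rows)
    meta = {"expected_events": spec["expected_events"], "note": spec["note"]}
    return block, roster, meta
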