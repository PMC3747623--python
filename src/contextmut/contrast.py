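"""Contrast, mutation bias and minimal contrast per mutation context.

For a context c = {mut | pos, W} and a subcontext s = {mut | pos', W'} the
contrast is the ratio of conditional mutation probabilities, estimated as

    Contrast(c, s) = (N_c / P_W) / (N_s / P_W')

where N are observed event counts per context and P are within-length word
frequencies.  P_W / P_W' estimates the chance of W' extending to W, so a
contrast above 1 means the extra letters of W raise the mutation rate and a
contrast below 1 means they lower it.

*Mutation bias* is the contrast of a context against its unique length-1
subcontext (the bare mutated base): the total excess or deficiency of the
mutation in that context.  *Minimal contrast* is the subcontext contrast
closest to 1 — the part of the excess that no subcontext explains.

No pseudocounts are applied by default: undefined ratios (zero subcontext
count or frequency) are flagged, not smoothed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .calling import MutationEvent
from .contexts import (
    MutationContext,
    Substitution,
    all_substitutions,
    enumerate_contexts,
    subcontexts,
)
from .words import WordFrequencyTable


class UndefinedContrastError(ZeroDivisionError):
    """The denominator context has zero events or zero word frequency."""


class DataInconsistencyError(ValueError):
    """Events were observed in a word the frequency table claims is absent."""


@dataclass
class ContextCounts:
    """N per context: the number of mutation events matching each context."""

    counts: dict[MutationContext, int] = field(default_factory=dict)

    def n(self, ctx: MutationContext) -> int:
        return self.counts.get(ctx, 0)

    def __len__(self) -> int:
        return len(self.counts)


def event_contexts(event: MutationEvent, min_len: int = 1, max_len: int = 4) -> list[MutationContext]:
    """Every context the event matches: each contiguous window of the
    ancestral 7-mer (lengths ``min_len..max_len``) containing the mutated
    central base, with the position remapped into the window."""
    word7 = event.context_word
    centre = len(event.left_flank)  # 0-based index of the mutated base
    out = []
    for k in range(min_len, max_len + 1):
        for start in range(max(0, centre - k + 1), min(centre, len(word7) - k) + 1):
            out.append(MutationContext(word7[start : start + k], centre - start + 1, event.derived))
    return out


def count_contexts(
    events: Iterable[MutationEvent], min_len: int = 1, max_len: int = 4
) -> ContextCounts:
    """Tally N per context over all events; each event increments each
    matching context exactly once."""
    counts: dict[MutationContext, int] = {}
    for event in events:
        for ctx in event_contexts(event, min_len, max_len):
            counts[ctx] = counts.get(ctx, 0) + 1
    return ContextCounts(counts)


def contrast(
    ctx: MutationContext,
    sub: MutationContext,
    counts: ContextCounts,
    freqs: WordFrequencyTable,
    pseudocount: float = 0.0,
) -> float:
    """Estimated contrast of ``ctx`` against its subcontext ``sub``.

    ``contrast(ctx, ctx)`` is 1 by convention (needed for length-1 bias).
    Raises :class:`UndefinedContrastError` when the subcontext has no events
    or its word is unobserved, and :class:`DataInconsistencyError` when
    events exist in a word of frequency zero."""
    if sub == ctx:
        return 1.0
    if sub not in subcontexts(ctx):
        raise ValueError(f"{sub} is not a subcontext of {ctx}")
    n_ctx = counts.n(ctx) + pseudocount
    n_sub = counts.n(sub) + pseudocount
    p_w = freqs.frequency(ctx.word)
    p_sub = freqs.frequency(sub.word)
    if p_w == 0.0 and n_ctx > 0:
        raise DataInconsistencyError(f"events observed in unobserved word {ctx.word!r}")
    if n_sub == 0 or p_sub == 0.0:
        raise UndefinedContrastError(f"undefined contrast: denominator {sub} has N={n_sub}, P={p_sub}")
    if n_ctx == 0:
        return 0.0
    return (n_ctx / p_w) / (n_sub / p_sub)


def mutation_bias(
    ctx: MutationContext, counts: ContextCounts, freqs: WordFrequencyTable, pseudocount: float = 0.0
) -> float:
    """Contrast of ``ctx`` against its length-1 subcontext (the mutated base
    alone); 1.0 for a length-1 context."""
    base_ctx = MutationContext(ctx.ancestral, 1, ctx.derived)
    return contrast(ctx, base_ctx, counts, freqs, pseudocount)


def subcontext_contrasts(
    ctx: MutationContext, counts: ContextCounts, freqs: WordFrequencyTable, pseudocount: float = 0.0
) -> list[tuple[MutationContext, float | None]]:
    """(subcontext, contrast) for every proper subcontext, ``None`` where
    undefined, in deterministic (length, word, pos) order."""
    out: list[tuple[MutationContext, float | None]] = []
    for sub in subcontexts(ctx):
        try:
            out.append((sub, contrast(ctx, sub, counts, freqs, pseudocount)))
        except UndefinedContrastError:
            out.append((sub, None))
    return out


def minimal_contrast(
    ctx: MutationContext, counts: ContextCounts, freqs: WordFrequencyTable, pseudocount: float = 0.0
) -> tuple[float, MutationContext]:
    """The defined subcontext contrast minimising |value - 1| and its argmin.

    Ties are broken deterministically: shorter subcontext word first, then
    lexicographic word, then smaller position (the iteration order of
    :func:`contextmut.contexts.subcontexts`)."""
    best: tuple[float, MutationContext] | None = None
    for sub, value in subcontext_contrasts(ctx, counts, freqs, pseudocount):
        if value is None:
            continue
        if best is None or abs(value - 1.0) < abs(best[0] - 1.0):
            best = (value, sub)
    if best is None:
        raise UndefinedContrastError(f"all subcontext contrasts of {ctx} are undefined")
    return best


def context_statistics(
    counts: ContextCounts,
    freqs: WordFrequencyTable,
    min_len: int = 2,
    max_len: int = 4,
    min_count: int = 0,
    pseudocount: float = 0.0,
) -> pd.DataFrame:
    """One row per enumerated context: N, mutation bias, minimal contrast,
    the argmin subcontext, how many subcontext contrasts were defined, and a
    flags column (``undefined_bias``, ``undefined_minimal``, ``low_count``).

    Contexts below ``min_count`` events are kept but flagged, never silently
    dropped (the estimator imposes no threshold by itself)."""
    rows = []
    for ctx in enumerate_contexts(min_len, max_len):
        n = counts.n(ctx)
        flags = []
        try:
            bias = mutation_bias(ctx, counts, freqs, pseudocount)
        except (UndefinedContrastError, DataInconsistencyError):
            bias = float("nan")
            flags.append("undefined_bias")
        pairs = subcontext_contrasts(ctx, counts, freqs, pseudocount)
        n_defined = sum(1 for _, v in pairs if v is not None)
        try:
            mc, argmin = minimal_contrast(ctx, counts, freqs, pseudocount)
            argmin_str = str(argmin)
        except UndefinedContrastError:
            mc, argmin_str = float("nan"), ""
            flags.append("undefined_minimal")
        if n < min_count:
            flags.append("low_count")
        rows.append((str(ctx), n, bias, mc, argmin_str, n_defined, ";".join(flags)))
    return pd.DataFrame(
        rows,
        columns=[
            "context",
            "N",
            "mutation_bias",
            "minimal_contrast",
            "argmin_subcontext",
            "n_subcontexts_defined",
            "flags",
        ],
    )


def spectrum_table(events: Sequence[MutationEvent] | Mapping[str, float]) -> pd.DataFrame:
    """Single-nucleotide mutation spectrum: the fraction of events per
    directed substitution, with its transition/transversion class, sorted by
    ascending fraction.

    Accepts either called events or a precomputed {substitution: fraction}
    mapping (e.g. a published spectrum)."""
    if isinstance(events, Mapping):
        fractions = {str(Substitution.parse(k)): float(v) for k, v in events.items()}
    else:
        if not events:
            raise ValueError("spectrum_table requires at least one event")
        total = len(events)
        fractions = {str(s): 0.0 for s in all_substitutions()}
        for e in events:
            fractions[f"{e.ancestral}>{e.derived}"] += 1 / total
    rows = [
        (sub, frac, Substitution.parse(sub).classification)
        for sub, frac in sorted(fractions.items(), key=lambda kv: (kv[1], kv[0]))
    ]
    return pd.DataFrame(rows, columns=["substitution", "fraction", "class"])


def spectrum_sums(spectrum: pd.DataFrame) -> dict[str, float]:
    """Transition and transversion fraction totals of a spectrum table."""
    sums = spectrum.groupby("class")["fraction"].sum()
    return {
        "transitions": float(sums.get("transition", 0.0)),
        "transversions": float(sums.get("transversion", 0.0)),
    }
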