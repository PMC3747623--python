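"""The algebra of mutation contexts.

A *mutation context* ``{X>Y | pos, W}`` is a substitution X>Y pinned to a
1-based position ``pos`` inside a short nucleotide word ``W`` (1-4 bp).  A
context on a contiguous subword of ``W`` that still covers ``pos`` is a
*subcontext*: any mutation matching the context also matches every one of
its subcontexts.  This module provides enumeration of all contexts up to
length 4, the (proper, contiguous) subcontext relation, strand
complementation, and the canonical string form used in all tabular output.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterator

BASES = "ACGT"
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

_CTX_RE = re.compile(r"^\{([ACGT])>([ACGT])\|(\d+),([ACGT]{1,4})\}$")


def complement_base(base: str) -> str:
    return COMPLEMENT[base]


def reverse_complement_word(word: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(word))


@dataclass(frozen=True, slots=True)
class Substitution:
    """A directed point substitution, ancestral -> derived."""

    ancestral: str
    derived: str

    def __post_init__(self) -> None:
        if self.ancestral not in BASES or self.derived not in BASES:
            raise ValueError(f"bases must be one of {BASES}: {self!r}")
        if self.ancestral == self.derived:
            raise ValueError(f"ancestral and derived base are equal: {self!r}")

    @property
    def is_transition(self) -> bool:
        return {self.ancestral, self.derived} in ({"A", "G"}, {"C", "T"})

    @property
    def classification(self) -> str:
        return "transition" if self.is_transition else "transversion"

    def __str__(self) -> str:
        return f"{self.ancestral}>{self.derived}"

    @classmethod
    def parse(cls, text: str) -> "Substitution":
        anc, _, der = text.strip().partition(">")
        return cls(anc, der)


def all_substitutions() -> list[Substitution]:
    """The 12 directed substitutions, ordered by (ancestral, derived)."""
    return [Substitution(a, d) for a in BASES for d in BASES if d != a]


@dataclass(frozen=True, slots=True)
class MutationContext:
    """Substitution ``word[pos] > derived`` at 1-based ``pos`` of ``word``."""

    word: str
    pos: int
    derived: str

    def __post_init__(self) -> None:
        if not (1 <= len(self.word) <= 4) or any(b not in BASES for b in self.word):
            raise ValueError(f"word must be 1-4 bp over ACGT: {self.word!r}")
        if not 1 <= self.pos <= len(self.word):
            raise ValueError(f"pos {self.pos} outside word {self.word!r}")
        if self.derived not in BASES:
            raise ValueError(f"invalid derived base {self.derived!r}")
        if self.derived == self.word[self.pos - 1]:
            raise ValueError(f"derived base equals ancestral base in {self.word!r}@{self.pos}")

    @property
    def ancestral(self) -> str:
        return self.word[self.pos - 1]

    @property
    def substitution(self) -> Substitution:
        return Substitution(self.ancestral, self.derived)

    @property
    def length(self) -> int:
        return len(self.word)

    @property
    def sort_key(self) -> tuple[int, str, int, str]:
        # documented deterministic order: length, word, pos, derived
        return (len(self.word), self.word, self.pos, self.derived)

    def __str__(self) -> str:
        return f"{{{self.ancestral}>{self.derived}|{self.pos},{self.word}}}"

    @classmethod
    def parse(cls, text: str) -> "MutationContext":
        """Parse the canonical form, e.g. ``{C>T|1,CG}``."""
        m = _CTX_RE.match(text.strip().replace(" ", ""))
        if m is None:
            raise ValueError(f"not a mutation context: {text!r}")
        anc, der, pos, word = m.group(1), m.group(2), int(m.group(3)), m.group(4)
        ctx = cls(word, pos, der)
        if ctx.ancestral != anc:
            raise ValueError(f"ancestral base {anc} does not match {word!r}@{pos}")
        return ctx


def _words(k: int) -> Iterator[str]:
    if k == 0:
        yield ""
        return
    for prefix in _words(k - 1):
        for b in BASES:
            yield prefix + b


def enumerate_contexts(min_len: int = 1, max_len: int = 4) -> list[MutationContext]:
    """Every context with word length in ``[min_len, max_len]``, exactly once.

    Order is deterministic: by word length, then word (lexicographic), then
    position, then derived base (lexicographic).
    """
    if not 1 <= min_len <= max_len <= 4:
        raise ValueError(f"lengths must satisfy 1 <= min <= max <= 4, got {min_len}..{max_len}")
    out: list[MutationContext] = []
    for k in range(min_len, max_len + 1):
        for word in _words(k):
            for pos in range(1, k + 1):
                for derived in BASES:
                    if derived != word[pos - 1]:
                        out.append(MutationContext(word, pos, derived))
    return out


@lru_cache(maxsize=8192)
def subcontexts(ctx: MutationContext) -> tuple[MutationContext, ...]:
    """All proper subcontexts of ``ctx``: contexts on every proper contiguous
    subword of the word that still contains the mutated position, with the
    position remapped and the substitution unchanged.  Sorted by
    (length, word, pos)."""
    k = ctx.length
    i = ctx.pos - 1  # 0-based index of the mutated base
    subs = []
    for sub_len in range(1, k):
        for start in range(max(0, i - sub_len + 1), min(i, k - sub_len) + 1):
            sub_word = ctx.word[start : start + sub_len]
            subs.append(MutationContext(sub_word, i - start + 1, ctx.derived))
    subs.sort(key=lambda c: c.sort_key)
    return tuple(subs)


def is_subcontext(sub: MutationContext, ctx: MutationContext) -> bool:
    return sub in subcontexts(ctx)


def reverse_complement(ctx: MutationContext) -> MutationContext:
    """The same mutation read on the opposite strand.  An involution."""
    return MutationContext(
        reverse_complement_word(ctx.word),
        ctx.length - ctx.pos + 1,
        COMPLEMENT[ctx.derived],
    )


def complement_pair_id(ctx: MutationContext) -> str:
    """Canonical id shared by a context and its reverse complement."""
    return min(str(ctx), str(reverse_complement(ctx)))
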