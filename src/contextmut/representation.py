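"""Genomic word over/under-representation.

The representation score of a word W is C = (Obs(W) - Exp(W)) / Exp(W) x
100%, where Obs is the observed within-length frequency and Exp is the
maximal-order Markov expectation built from W's subword frequencies:

    Exp(W) = P(prefix_{k-1}) * P(suffix_{k-1}) / P(middle_{k-2})

with the middle frequency of the empty word taken as 1, so that for k = 2
the expectation reduces to the independence product P(W[1]) * P(W[2]).
A positive C means the word occurs more often than its subword composition
predicts; CpG suppression in vertebrates is the canonical negative example.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .words import WordFrequencyTable


class UndefinedScoreError(ZeroDivisionError):
    """A required subword frequency is zero, so Exp (hence C) is undefined."""


@dataclass(frozen=True, slots=True)
class RepresentationScore:
    word: str
    observed: float
    expected: float

    @property
    def c_percent(self) -> float:
        return (self.observed - self.expected) / self.expected * 100.0

    def __str__(self) -> str:
        return f"C({self.word}) = {self.c_percent:+.2f}%"


def expected_frequency(word: str, table: WordFrequencyTable) -> float:
    """Markov expectation of ``word`` from its (k-1)- and (k-2)-subword
    frequencies."""
    k = len(word)
    if k < 2:
        raise ValueError("expected_frequency requires a word of length >= 2")
    p_prefix = table.frequency(word[:-1])
    p_suffix = table.frequency(word[1:])
    p_middle = 1.0 if k == 2 else table.frequency(word[1:-1])
    if p_prefix == 0.0 or p_suffix == 0.0 or p_middle == 0.0:
        raise UndefinedScoreError(f"zero subword frequency for {word!r}")
    return p_prefix * p_suffix / p_middle


def representation_score(word: str, table: WordFrequencyTable) -> RepresentationScore:
    return RepresentationScore(word, table.frequency(word), expected_frequency(word, table))


def score_words(table: WordFrequencyTable, words: Iterable[str]) -> pd.DataFrame:
    """Representation scores for several words; undefined scores become NaN
    rows rather than errors."""
    rows = []
    for word in words:
        try:
            s = representation_score(word, table)
            rows.append((word, s.observed, s.expected, s.c_percent))
        except UndefinedScoreError:
            rows.append((word, table.frequency(word), float("nan"), float("nan")))
    return pd.DataFrame(rows, columns=["word", "obs_freq", "exp_freq", "C_percent"])
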