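"""Overlapping 1-4 bp word counts and within-length frequencies P_W.

Words are counted on the given (plus) strand with a sliding window of step
one.  A k-word is counted only when all k symbols are clean bases; runs are
broken at ambiguity symbols, at masked-region boundaries and at block
boundaries, so no word ever spans a break.  Frequencies are normalised
within each word length: P_W = count(W) / total number of k-words.

Two alignment-level measures mirror the two denominators the contrast
estimator can use: the "complete" measure counts the ancestral-consensus
row wherever the outgroups agree, the "conserved" measure counts ancestral
bases over the conserved-region mask only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .alignio import AlignmentBlock, SpeciesRoster
from .calling import ConservedMask, conserved_mask

_CODES = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODES[ord(_b)] = _i
    _CODES[ord(_b.lower())] = _i


class UndefinedRatioError(ZeroDivisionError):
    """Raised when a frequency ratio has a zero denominator (distinct from a
    zero-valued ratio)."""


@dataclass
class WordFrequencyTable:
    """Counts and within-length frequencies of all words up to ``max_k``."""

    max_k: int
    counts: dict[str, int] = field(default_factory=dict)
    totals: dict[int, int] = field(default_factory=dict)
    provenance: str = "sequence"

    def count(self, word: str) -> int:
        return self.counts.get(word.upper(), 0)

    def total(self, k: int) -> int:
        return self.totals.get(k, 0)

    def frequency(self, word: str) -> float:
        """P_W among all words of the same length (0.0 if none observed)."""
        total = self.total(len(word))
        return self.count(word) / total if total else 0.0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (len(w), w, c, self.frequency(w), self.provenance)
            for w, c in sorted(self.counts.items(), key=lambda wc: (len(wc[0]), wc[0]))
        ]
        return pd.DataFrame(rows, columns=["k", "word", "count", "frequency", "provenance"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "WordFrequencyTable":
        df = pd.read_csv(path, sep="\t", dtype={"word": str})
        table = cls(max_k=int(df["k"].max()) if len(df) else 4)
        table.counts = dict(zip(df["word"], df["count"].astype(int)))
        table.totals = {int(k): int(g["count"].sum()) for k, g in df.groupby("k")}
        if len(df):
            table.provenance = str(df["provenance"].iloc[0])
        return table


def _count_codes(codes: np.ndarray, max_k: int, table: WordFrequencyTable) -> None:
    """Accumulate overlapping word counts from a 0-3/255 code array."""
    n = len(codes)
    valid = codes < 4
    for k in range(1, max_k + 1):
        if n < k:
            continue
        ids = np.zeros(n - k + 1, dtype=np.int64)
        ok = np.ones(n - k + 1, dtype=bool)
        for j in range(k):
            ids = ids * 4 + codes[j : n - k + 1 + j]
            ok &= valid[j : n - k + 1 + j]
        ids = ids[ok]
        table.totals[k] = table.totals.get(k, 0) + int(ids.size)
        if ids.size:
            counts = np.bincount(ids, minlength=4**k)
            for wid in np.flatnonzero(counts):
                word = _decode(int(wid), k)
                table.counts[word] = table.counts.get(word, 0) + int(counts[wid])


def _decode(wid: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append("ACGT"[wid & 3])
        wid >>= 2
    return "".join(reversed(out))


def count_words(
    sequences: str | Iterable[str], max_k: int = 4, provenance: str = "sequence"
) -> WordFrequencyTable:
    """Count overlapping words over one or several sequences/runs.

    Each element of ``sequences`` is an independent run: words never span
    from one run into the next.  Symbols outside ACGT (case-insensitive)
    break runs implicitly.
    """
    if max_k > 4 or max_k < 1:
        raise ValueError("max_k must be in 1..4")
    if isinstance(sequences, str):
        sequences = [sequences]
    table = WordFrequencyTable(max_k=max_k, provenance=provenance)
    for seq in sequences:
        codes = _CODES[np.frombuffer(seq.encode(), dtype=np.uint8)]
        _count_codes(codes, max_k, table)
    return table


def _ancestral_runs(blocks: Iterable[AlignmentBlock], roster: SpeciesRoster) -> list[str]:
    """Ancestral-consensus row per block: the outgroup-agreement base where it
    exists, an ambiguity placeholder (run break) elsewhere."""
    runs = []
    for block in blocks:
        if block.absent & set(roster.outgroups):
            continue
        mats = [np.frombuffer(block.rows[n].encode(), dtype=np.uint8) for n in roster.outgroups]
        codes = _CODES[mats[0]].copy()
        agree = np.ones(block.n_cols, dtype=bool)
        for m in mats[1:]:
            agree &= mats[0] == m
        codes[~agree | (codes > 3)] = 255
        runs.append("".join("ACGTn"[c] if c < 4 else "n" for c in codes))
    return runs


def alignment_word_table(
    blocks: Iterable[AlignmentBlock],
    roster: SpeciesRoster,
    max_k: int = 4,
    measure: str = "conserved",
    mask: ConservedMask | None = None,
) -> WordFrequencyTable:
    """Word frequencies from an alignment, by either measure.

    ``measure="complete"`` scans the ancestral-consensus row of every block;
    ``measure="conserved"`` scans only maximal runs of conserved columns
    (computing the mask if not supplied).  The conserved measure is the
    default denominator for mutation biases and contrasts.
    """
    blocks = list(blocks)
    if measure == "complete":
        return count_words(_ancestral_runs(blocks, roster), max_k, provenance="complete")
    if measure == "conserved":
        if mask is None:
            mask = conserved_mask(blocks, roster)
        return count_words(mask.conserved_runs(), max_k, provenance="conserved")
    raise ValueError(f"unknown measure {measure!r} (expected 'complete' or 'conserved')")


def frequency_ratio(table: WordFrequencyTable, word: str, subword: str) -> float:
    """P_W / P_W' with each frequency taken among words of its own length.

    Raises :class:`UndefinedRatioError` when P_W' is zero; returns 0.0 when
    only the numerator word is unobserved."""
    p_sub = table.frequency(subword)
    if p_sub == 0.0:
        raise UndefinedRatioError(f"P({subword}) is zero")
    return table.frequency(word) / p_sub
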