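"""Polarized biallelic mutation calling and the conserved-region mask.

A column of the population alignment yields a mutation event iff four
conditions all hold:

1. every outgroup carries the same base ``b`` in {A,C,G,T} — the ancestral
   base, reconstructed by agreement of two (or more) outgroups;
2. among the focal genomes at least one carries ``b`` and at least one
   carries a different base;
3. the focal genomes show exactly two distinct symbols, both clean bases
   (a gap or ambiguity code in any focal genome disqualifies the column);
4. each of the three alignment columns immediately up- and downstream is
   monomorphic across *all* rows (focal and outgroup) with a single clean
   base and no gap — these six bases are the event's ancestral flanks.

The conserved-region mask marks columns where the outgroups agree on a
clean ancestral base, no row carries a gap or ambiguity symbol, and the
ancestral base matches at least one focal variant; word frequencies used
as contrast denominators are counted over these columns.

Columns are processed as bit-coded numpy matrices (one bit per symbol
class), so whole blocks are filtered with vectorised boolean algebra.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .alignio import AlignmentBlock, SpeciesRoster

# symbol classes -> bits: A=1 C=2 G=4 T=8, gap=16, anything else (N...)=32
_BITS = np.full(256, 32, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BITS[ord(_b)] = 1 << _i
_BITS[ord("-")] = 16
_POP = np.array([bin(i).count("1") for i in range(64)], dtype=np.uint8)
_BIT2BASE = {1: "A", 2: "C", 4: "G", 8: "T"}
_BASE_BITS = 15  # mask of the four clean-base bits


@dataclass(frozen=True, slots=True)
class MutationEvent:
    """One polarized biallelic substitution with its ancestral +-3 bp flank."""

    chrom: str
    pos: int  # 0-based reference coordinate
    ancestral: str
    derived: str
    left_flank: str
    right_flank: str
    derived_count: int

    @property
    def context_word(self) -> str:
        """The ancestral 7-mer centred on the mutated base."""
        return self.left_flank + self.ancestral + self.right_flank


@dataclass
class ConservedMask:
    """Per-block conserved-column indicator plus the ancestral base codes
    (0-3 = ACGT; -1 where not conserved)."""

    blocks: dict[str, tuple[np.ndarray, np.ndarray]]

    def mask(self, block_id: str) -> np.ndarray:
        return self.blocks[block_id][0]

    def ancestral_codes(self, block_id: str) -> np.ndarray:
        return self.blocks[block_id][1]

    def conserved_runs(self) -> list[str]:
        """Maximal runs of conserved columns as ancestral-base strings.

        Runs never span block boundaries or non-conserved columns."""
        out: list[str] = []
        bases = np.frombuffer(b"ACGT", dtype=np.uint8)
        for mask, codes in self.blocks.values():
            if not mask.any():
                continue
            edges = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
            for start, stop in zip(edges[::2], edges[1::2]):
                out.append(bases[codes[start:stop]].tobytes().decode())
        return out

    def to_bed(self, path: str | Path, blocks: Iterable[AlignmentBlock], roster: SpeciesRoster) -> None:
        """Write the mask as BED (0-based half-open reference intervals).

        Columns where the reference row is gapped have no reference
        coordinate and are dropped from the BED projection."""
        lines = []
        for block in blocks:
            mask, _ = self.blocks[block.block_id]
            ref = np.frombuffer(block.rows[roster.reference].encode(), dtype=np.uint8)
            nongap = ref != ord("-")
            coords = block.ref_start + np.cumsum(nongap) - 1
            keep = mask & nongap
            if not keep.any():
                continue
            pos = coords[keep]
            breaks = np.flatnonzero(np.diff(pos) != 1)
            starts = np.concatenate(([0], breaks + 1))
            stops = np.concatenate((breaks, [len(pos) - 1]))
            for s, e in zip(starts, stops):
                lines.append(f"{block.ref_chrom}\t{pos[s]}\t{pos[e] + 1}")
        Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def _block_matrix(block: AlignmentBlock, names: Sequence[str]) -> np.ndarray:
    rows = [np.frombuffer(block.rows[n].encode(), dtype=np.uint8) for n in names]
    return _BITS[np.vstack(rows)] if rows else np.empty((0, block.n_cols), dtype=np.uint8)


def _or_reduce(mat: np.ndarray) -> np.ndarray:
    return np.bitwise_or.reduce(mat, axis=0)


def _window_all(flags: np.ndarray, offsets: range) -> np.ndarray:
    """True at columns where ``flags`` holds at every column+offset (edges False)."""
    out = np.ones_like(flags)
    n = len(flags)
    for off in offsets:
        shifted = np.zeros_like(flags)
        if off >= 0:
            shifted[: n - off] = flags[off:] if off else flags
        else:
            shifted[-off:] = flags[:off]
        out &= shifted
    return out


def call_mutations(
    blocks: Iterable[AlignmentBlock],
    roster: SpeciesRoster,
    min_focal_present: int | None = None,
) -> list[MutationEvent]:
    """Apply the four calling conditions to every column of every block.

    ``min_focal_present`` defaults to all focal genomes: a column with any
    focal genome gapped or unread is non-callable.  (Lower values relax
    condition 3 to "exactly two clean variants among the present genomes",
    still requiring the stated number present.)
    """
    n_focal = len(roster.focal)
    if min_focal_present is None:
        min_focal_present = n_focal
    events: list[MutationEvent] = []
    for block in blocks:
        if block.absent & set(roster.focal) or block.absent & set(roster.outgroups):
            continue  # polarization / population incomplete in this block
        if block.n_cols < 7:
            continue
        focal = _block_matrix(block, roster.focal)
        og = _block_matrix(block, roster.outgroups)
        focal_or = _or_reduce(focal)
        og_or = _or_reduce(og)
        roster_or = focal_or | og_or

        og_agree = (_POP[og_or] == 1) & (og_or <= _BASE_BITS)  # condition 1
        anc_bit = np.where(og_agree, og_or, 0)

        n_present = (focal <= _BASE_BITS).sum(axis=0)
        focal_clean_or = np.bitwise_or.reduce(np.where(focal <= _BASE_BITS, focal, 0), axis=0)
        if min_focal_present >= n_focal:
            focal_ok = focal_or <= _BASE_BITS
            variant_or = focal_or
        else:
            focal_ok = n_present >= min_focal_present
            variant_or = focal_clean_or
        biallelic = focal_ok & (_POP[variant_or] == 2) & ((variant_or & anc_bit) != 0)

        flank_mono = (_POP[roster_or] == 1) & (roster_or <= _BASE_BITS)
        left_ok = _window_all(flank_mono, range(-3, 0))
        right_ok = _window_all(flank_mono, range(1, 4))

        callable_ = og_agree & biallelic & left_ok & right_ok
        # no event within 3 columns of a block edge
        callable_[:3] = False
        callable_[-3:] = False

        ref = np.frombuffer(block.rows[roster.reference].encode(), dtype=np.uint8)
        ref_nongap = ref != ord("-")
        coords = block.ref_start + np.cumsum(ref_nongap) - 1
        callable_ &= ref_nongap  # an event needs a reference coordinate

        for j in np.flatnonzero(callable_):
            anc = int(anc_bit[j])
            der = int(variant_or[j] ^ anc)
            der_count = int((focal[:, j] == der).sum())
            flank_bits = roster_or[j - 3 : j + 4]
            left = "".join(_BIT2BASE[int(b)] for b in flank_bits[:3])
            right = "".join(_BIT2BASE[int(b)] for b in flank_bits[4:])
            events.append(
                MutationEvent(
                    block.ref_chrom, int(coords[j]), _BIT2BASE[anc], _BIT2BASE[der], left, right, der_count
                )
            )
    return events


def conserved_mask(blocks: Iterable[AlignmentBlock], roster: SpeciesRoster) -> ConservedMask:
    """Columns where outgroups agree on a clean ancestral base, no row is
    gapped or unread, and the ancestral base matches >=1 focal variant."""
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    code_of_bit = np.full(64, -1, dtype=np.int8)
    for i in range(4):
        code_of_bit[1 << i] = i
    for block in blocks:
        if block.absent & set(roster.names):
            out[block.block_id] = (
                np.zeros(block.n_cols, dtype=bool),
                np.full(block.n_cols, -1, dtype=np.int8),
            )
            continue
        focal = _block_matrix(block, roster.focal)
        og = _block_matrix(block, roster.outgroups)
        focal_or = _or_reduce(focal)
        og_or = _or_reduce(og)
        roster_or = focal_or | og_or
        og_agree = (_POP[og_or] == 1) & (og_or <= _BASE_BITS)
        clean = roster_or <= _BASE_BITS
        anc_bit = np.where(og_agree, og_or, 0)
        matches_focal = (focal_or & anc_bit) != 0
        mask = og_agree & clean & matches_focal
        codes = np.where(mask, code_of_bit[anc_bit], -1).astype(np.int8)
        out[block.block_id] = (mask, codes)
    return ConservedMask(out)


def difference_percent(fraction_all: float, fraction_conserved: float) -> float:
    """Percent composition difference, (all - conserved)/all * 100, rounded to
    one decimal for display."""
    return round((fraction_all - fraction_conserved) / fraction_all * 100, 1)


def composition_summary(
    blocks: Iterable[AlignmentBlock], mask: ConservedMask, roster: SpeciesRoster
) -> pd.DataFrame:
    """Base composition of the complete alignment vs the conserved regions.

    The "all positions" measure counts every clean base over every roster
    row; the conserved measure counts the ancestral base of each conserved
    column.  The difference column is (all - conserved)/all in percent."""
    all_counts = np.zeros(4, dtype=np.int64)
    cons_counts = np.zeros(4, dtype=np.int64)
    blocks = list(blocks)
    for block in blocks:
        mat = _block_matrix(block, [n for n in roster.names if n in block.rows])
        for i in range(4):
            all_counts[i] += int((mat == (1 << i)).sum())
        codes = mask.ancestral_codes(block.block_id)
        cons = codes[codes >= 0]
        if cons.size:
            cons_counts += np.bincount(cons, minlength=4)
    frac_all = all_counts / all_counts.sum() if all_counts.sum() else np.full(4, np.nan)
    frac_cons = cons_counts / cons_counts.sum() if cons_counts.sum() else np.full(4, np.nan)
    diff = [
        difference_percent(a, c) if a > 0 and np.isfinite(c) else float("nan")
        for a, c in zip(frac_all, frac_cons)
    ]
    return pd.DataFrame(
        {
            "base": list("ACGT"),
            "fraction_all": frac_all,
            "fraction_conserved": frac_cons,
            "difference_pct": diff,
        }
    )


def events_to_frame(events: Sequence[MutationEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (e.chrom, e.pos, e.ancestral, e.derived, e.left_flank, e.right_flank, e.derived_count)
            for e in events
        ],
        columns=["chrom", "pos0", "ancestral", "derived", "left_flank", "right_flank", "derived_count"],
    )


def write_events(events: Sequence[MutationEvent], path: str | Path) -> None:
    events_to_frame(events).to_csv(path, sep="\t", index=False)


def read_events(path: str | Path) -> list[MutationEvent]:
    df = pd.read_csv(path, sep="\t", dtype={"left_flank": str, "right_flank": str})
    return [
        MutationEvent(r.chrom, int(r.pos0), r.ancestral, r.derived, r.left_flank, r.right_flank, int(r.derived_count))
        for r in df.itertuples()
    ]
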