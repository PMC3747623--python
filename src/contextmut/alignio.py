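"""Reading and writing population alignments and pipeline files.

Input alignments come either as MAF blocks (the dialect UCSC distributes
multiple-genome alignments in) or as a single aligned-FASTA block, which is
what the synthetic generator emits.  Rows are uppercased at read time; gaps
stay ``-`` and ambiguity codes (``N`` etc.) pass through so downstream
filters can see missingness.  If the reference row of a MAF block is on the
minus strand the whole block is reverse-complemented so the reference is
always plus-strand; coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_RC_TABLE = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def _revcomp_aligned(s: str) -> str:
    return s.translate(_RC_TABLE)[::-1]


@dataclass(frozen=True)
class SpeciesRoster:
    """Which alignment rows are the focal population, which are outgroups,
    and which row carries the reference coordinates."""

    focal: tuple[str, ...]
    outgroups: tuple[str, ...]
    reference: str

    def __post_init__(self) -> None:
        if set(self.focal) & set(self.outgroups):
            raise ValueError("focal and outgroup sets must be disjoint")
        if len(self.outgroups) < 2:
            raise ValueError("at least 2 outgroups are required for polarization")
        if self.reference not in self.focal and self.reference not in self.outgroups:
            # a designated assembly track outside the population is allowed
            pass

    @property
    def names(self) -> tuple[str, ...]:
        extra = () if self.reference in self.focal + self.outgroups else (self.reference,)
        return self.focal + self.outgroups + extra

    @classmethod
    def from_json(cls, path: str | Path) -> "SpeciesRoster":
        import json

        d = json.loads(Path(path).read_text())
        return cls(tuple(d["focal"]), tuple(d["outgroups"]), d["reference"])

    def to_json(self, path: str | Path) -> None:
        import json

        Path(path).write_text(
            json.dumps(
                {"focal": list(self.focal), "outgroups": list(self.outgroups), "reference": self.reference},
                indent=2,
            )
        )


@dataclass
class AlignmentBlock:
    """One alignment block: equal-length rows keyed by roster name.

    ``ref_chrom``/``ref_start`` locate the reference row (0-based, plus
    strand).  Species listed in ``absent`` had no row in this block, which
    is distinct from being present but gapped.
    """

    block_id: str
    ref_chrom: str
    ref_start: int
    rows: dict[str, str]
    absent: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError(f"block {self.block_id}: unequal row lengths {lengths}")

    @property
    def n_cols(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def reference_row(self, roster: SpeciesRoster) -> str:
        return self.rows[roster.reference]


def _match_roster_name(src: str, names: Iterable[str]) -> str | None:
    """MAF src fields look like ``dm3.chr2L``; roster names may be either the
    assembly prefix or the full src."""
    if src in names:
        return src
    prefix = src.split(".", 1)[0]
    return prefix if prefix in names else None


def read_maf(path: str | Path, roster: SpeciesRoster) -> Iterator[AlignmentBlock]:
    """Stream MAF blocks restricted to roster names.

    Roster species without a row in a block are recorded in ``absent``.
    An empty file yields an empty stream.
    """
    seen: set[str] = set()
    with open(path) as handle:
        for i, msa in enumerate(AlignIO.parse(handle, "maf")):
            rows: dict[str, str] = {}
            ref_chrom, ref_start, ref_strand, ref_srcsize = None, 0, 1, 0
            for rec in msa:
                name = _match_roster_name(rec.id, roster.names)
                if name is None:
                    continue
                seen.add(name)
                rows[name] = str(rec.seq).upper()
                if name == roster.reference:
                    ref_chrom = rec.id.split(".", 1)[1] if "." in rec.id else rec.id
                    ref_start = int(rec.annotations["start"])
                    ref_strand = int(rec.annotations.get("strand", 1))
                    ref_srcsize = int(rec.annotations.get("srcSize", 0))
            if ref_chrom is None:
                raise ValueError(f"block {i} at {path}: reference {roster.reference!r} missing")
            if ref_strand == -1:
                # flip the whole block onto the reference plus strand
                rows = {n: _revcomp_aligned(s) for n, s in rows.items()}
                size = sum(1 for c in rows[roster.reference] if c != "-")
                ref_start = ref_srcsize - (ref_start + size)
            absent = frozenset(n for n in roster.names if n not in rows)
            yield AlignmentBlock(f"block{i}", ref_chrom, ref_start, rows, absent)
    missing = set(roster.names) - seen
    if missing:
        import logging

        logging.getLogger(__name__).warning("roster names never seen in %s: %s", path, sorted(missing))


def read_aligned_fasta(
    path: str | Path, roster: SpeciesRoster, ref_chrom: str = "chr", ref_start: int = 0
) -> Iterator[AlignmentBlock]:
    """Read a single-block alignment stored as aligned FASTA (one equal-length
    record per genome), the native output of the synthetic generator."""
    rows = {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(str(path), "fasta")
        if rec.id in roster.names
    }
    if not rows:
        return
    absent = frozenset(n for n in roster.names if n not in rows)
    yield AlignmentBlock("block0", ref_chrom, ref_start, rows, absent)


def write_aligned_fasta(block: AlignmentBlock, path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in block.rows.items()]
    SeqIO.write(records, str(path), "fasta")


def iterate_columns(
    block: AlignmentBlock, reference: str | SpeciesRoster | None = None
) -> Iterator[tuple[int | None, dict[str, str]]]:
    """Yield one record per alignment column: (reference coordinate, symbols).

    The coordinate is 0-based on the reference and is ``None`` for columns
    where the reference row is gapped; it advances only on non-gap reference
    symbols.  Absent species are simply not in the symbol dict.  ``reference``
    may be a row name or a roster; it defaults to the first row.
    """
    if isinstance(reference, SpeciesRoster):
        reference = reference.reference
    if reference is None:
        reference = next(iter(block.rows))
    ref_row = block.rows[reference]
    coord = block.ref_start
    for j in range(block.n_cols):
        symbols = {n: s[j] for n, s in block.rows.items()}
        if ref_row[j] == "-":
            yield None, symbols
        else:
            yield coord, symbols
            coord += 1
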