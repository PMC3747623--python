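"""Pipeline orchestration and cross-species comparison tables.

A :class:`SpeciesStatsBundle` packages everything the comparison layer
needs for one species: the per-context statistics table, the
single-nucleotide spectrum and (optionally) the composition summary, all
indexed by the canonical context string.  :func:`compare` joins two
bundles; :func:`scatter_data` emits the plot-ready (bias, minimal contrast)
table with complement-pair ids, the tabular form of the bias-vs-minimal-
contrast representation.  Published single-species reference values ship as
small packaged TSVs (transcribed from the printed tables, never
recomputed from genomes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .alignio import AlignmentBlock, SpeciesRoster
from .calling import MutationEvent, call_mutations, composition_summary, conserved_mask
from .contexts import MutationContext, complement_pair_id
from .contrast import ContextCounts, context_statistics, count_contexts, spectrum_table
from .words import WordFrequencyTable, alignment_word_table


@dataclass
class SpeciesStatsBundle:
    label: str
    context_stats: pd.DataFrame  # columns as produced by context_statistics
    spectrum: pd.DataFrame | None = None
    composition: pd.DataFrame | None = None
    metadata: dict = field(default_factory=dict)

    def stats_indexed(self) -> pd.DataFrame:
        return self.context_stats.set_index("context")


def build_bundle(
    blocks: Iterable[AlignmentBlock],
    roster: SpeciesRoster,
    label: str,
    min_len: int = 2,
    max_len: int = 4,
    freq_source: str = "conserved",
    metadata: dict | None = None,
) -> SpeciesStatsBundle:
    """Run the full pipeline on one species' alignment: conserved mask,
    word frequencies (conserved-region measure by default), mutation
    calling, context counting and per-context statistics."""
    blocks = list(blocks)
    mask = conserved_mask(blocks, roster)
    freqs = alignment_word_table(blocks, roster, max_k=max_len, measure=freq_source, mask=mask)
    events = call_mutations(blocks, roster)
    counts = count_contexts(events)
    stats = context_statistics(counts, freqs, min_len=min_len, max_len=max_len)
    spectrum = spectrum_table(events) if events else None
    composition = composition_summary(blocks, mask, roster)
    meta = {"label": label, "n_events": len(events), "freq_source": freq_source}
    meta.update(metadata or {})
    return SpeciesStatsBundle(label, stats, spectrum, composition, meta)


def bundle_from_stats_tsv(path: str | Path, label: str) -> SpeciesStatsBundle:
    """Load a bundle from a previously written context-statistics TSV (e.g. a
    published second-species table)."""
    return SpeciesStatsBundle(label, pd.read_csv(path, sep="\t"))


def compare(a: SpeciesStatsBundle, b: SpeciesStatsBundle) -> pd.DataFrame:
    """One row per context with both species' bias and minimal contrast and
    their differences (A - B).  Errors if the context universes differ,
    listing the symmetric difference."""
    sa, sb = a.stats_indexed(), b.stats_indexed()
    if set(sa.index) != set(sb.index):
        diff = sorted(set(sa.index) ^ set(sb.index))
        raise ValueError(f"context universes differ; symmetric difference: {diff[:20]}{'...' if len(diff) > 20 else ''}")
    sb = sb.reindex(sa.index)
    out = pd.DataFrame(
        {
            "context": sa.index,
            "bias_a": sa["mutation_bias"].to_numpy(),
            "bias_b": sb["mutation_bias"].to_numpy(),
            "minimal_contrast_a": sa["minimal_contrast"].to_numpy(),
            "minimal_contrast_b": sb["minimal_contrast"].to_numpy(),
        }
    )
    out["bias_diff"] = out["bias_a"] - out["bias_b"]
    out["minimal_contrast_diff"] = out["minimal_contrast_a"] - out["minimal_contrast_b"]
    out["defined_both"] = (
        out[["bias_a", "bias_b", "minimal_contrast_a", "minimal_contrast_b"]].notna().all(axis=1)
    )
    return out.reset_index(drop=True)


def scatter_data(bundle: SpeciesStatsBundle) -> pd.DataFrame:
    """Plot-ready table: one record per context with defined bias and
    minimal contrast, plus a pair id shared with the reverse-complement
    context (complementary contexts plot as near-coincident dot pairs on
    strand-symmetric data)."""
    df = bundle.context_stats.dropna(subset=["mutation_bias", "minimal_contrast"]).copy()
    df["pair_id"] = [complement_pair_id(MutationContext.parse(c)) for c in df["context"]]
    return df[["context", "mutation_bias", "minimal_contrast", "pair_id"]].reset_index(drop=True)


def _read_packaged(name: str) -> pd.DataFrame:
    with resources.files("contextmut.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_reference_spectrum(species: str) -> dict[str, float]:
    """Published single-nucleotide spectrum fractions for ``dmel`` or
    ``hsap`` (transcribed printed values)."""
    df = _read_packaged("spectrum_reference.tsv")
    sub = df[df["species"] == species]
    if sub.empty:
        raise KeyError(f"unknown species {species!r}; known: {sorted(df['species'].unique())}")
    return dict(zip(sub["substitution"], sub["fraction"]))


def load_reference_representation() -> pd.DataFrame:
    """Published word representation scores C (percent) for both species
    (transcribed printed values)."""
    return _read_packaged("word_representation_reference.tsv")
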