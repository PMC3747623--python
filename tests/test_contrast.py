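"""Contrast estimator, mutation bias, minimal contrast, spectrum."""

import math

import pytest

import contextmut as cm
from contextmut.calling import MutationEvent
from contextmut.contexts import MutationContext
from contextmut.contrast import (
    ContextCounts,
    DataInconsistencyError,
    UndefinedContrastError,
)
from contextmut.words import WordFrequencyTable

from conftest import brute_count_contexts


def table_from(counts: dict[str, int]) -> WordFrequencyTable:
    t = WordFrequencyTable(max_k=max(len(w) for w in counts))
    t.counts = dict(counts)
    totals: dict[int, int] = {}
    for w, c in counts.items():
        totals[len(w)] = totals.get(len(w), 0) + c
    t.totals = totals
    return t


class TestCountContexts:
    def test_single_event_hits_ten_contexts(self):
        event = MutationEvent("c", 0, "C", "T", "ACG", "GTA", 1)
        counts = cm.count_contexts([event])
        assert len(counts) == 10
        assert all(n == 1 for n in counts.counts.values())
        # the 7-mer is ACG C GTA; windows containing the central C
        for text in ("{C>T|1,C}", "{C>T|2,GC}", "{C>T|1,CG}", "{C>T|3,CGC}", "{C>T|1,CGT}",
                     "{C>T|4,ACGC}", "{C>T|1,CGTA}"):
            assert counts.n(MutationContext.parse(text)) == 1

    def test_zero_events(self):
        assert len(cm.count_contexts([])) == 0

    def test_matches_brute_force_oracle_on_1000_events(self, random_events):
        fast = cm.count_contexts(random_events)
        slow = brute_count_contexts(random_events)
        assert fast.counts == slow

    def test_monotone_under_subcontext(self, random_events):
        counts = cm.count_contexts(random_events)
        for ctx in cm.enumerate_contexts(2, 4):
            n = counts.n(ctx)
            for sub in cm.subcontexts(ctx):
                assert n <= counts.n(sub)


class TestContrast:
    def test_arithmetic_example(self):
        # N_ctx=30, N_sub=100, P_W=0.05, P_W'=0.25 -> (30/0.05)/(100/0.25)=1.5
        ctx = MutationContext.parse("{C>T|1,CG}")
        sub = MutationContext.parse("{C>T|1,C}")
        counts = ContextCounts({ctx: 30, sub: 100})
        freqs = table_from({"C": 25, "A": 75, "CG": 5, "CA": 95})
        assert cm.contrast(ctx, sub, counts, freqs) == pytest.approx(1.5)

    def test_proportional_counts_null(self):
        # counts exactly proportional to word frequencies -> contrast 1
        ctx = MutationContext.parse("{C>T|1,CG}")
        sub = MutationContext.parse("{C>T|1,C}")
        # N_ctx/N_sub = 40/100 equals P_CG/P_C = (10/50)/(50/100) = 0.4
        counts = ContextCounts({ctx: 40, sub: 100})
        freqs = table_from({"C": 50, "A": 50, "CG": 10, "CA": 40})
        assert cm.contrast(ctx, sub, counts, freqs) == pytest.approx(1.0)

    def test_zero_numerator_count(self):
        ctx = MutationContext.parse("{C>T|1,CG}")
        sub = MutationContext.parse("{C>T|1,C}")
        counts = ContextCounts({sub: 100})
        freqs = table_from({"C": 25, "A": 75, "CG": 5, "CA": 95})
        assert cm.contrast(ctx, sub, counts, freqs) == 0.0

    def test_zero_denominator_flagged(self):
        ctx = MutationContext.parse("{C>T|1,CG}")
        sub = MutationContext.parse("{C>T|1,C}")
        freqs = table_from({"C": 25, "A": 75, "CG": 5, "CA": 95})
        with pytest.raises(UndefinedContrastError):
            cm.contrast(ctx, sub, ContextCounts({ctx: 1}), freqs)

    def test_events_in_unobserved_word_inconsistent(self):
        ctx = MutationContext.parse("{C>T|1,CG}")
        sub = MutationContext.parse("{C>T|1,C}")
        counts = ContextCounts({ctx: 5, sub: 10})
        freqs = table_from({"C": 25, "A": 75, "CA": 100})
        with pytest.raises(DataInconsistencyError):
            cm.contrast(ctx, sub, counts, freqs)

    def test_non_subcontext_rejected(self):
        ctx = MutationContext.parse("{C>T|1,CG}")
        other = MutationContext.parse("{C>T|1,CA}")
        with pytest.raises(ValueError):
            cm.contrast(ctx, other, ContextCounts(), WordFrequencyTable(2))


class TestChainIdentity:
    def test_contrast_multiplies_along_nested_chains(self, planted_stats):
        """Eq-structure identity: contrast(A,C) = contrast(A,B)*contrast(B,C)
        exactly, for every nested chain A > B > C."""
        _, counts, freqs = planted_stats
        checked = 0
        for ctx in cm.enumerate_contexts(3, 4):
            if counts.n(ctx) == 0:
                continue
            for mid in cm.subcontexts(ctx):
                if mid.length == 1 or counts.n(mid) == 0:
                    continue
                for sub in cm.subcontexts(mid):
                    if sub not in cm.subcontexts(ctx) or counts.n(sub) == 0:
                        continue
                    direct = cm.contrast(ctx, sub, counts, freqs)
                    stepped = cm.contrast(ctx, mid, counts, freqs) * cm.contrast(mid, sub, counts, freqs)
                    assert direct == pytest.approx(stepped, rel=1e-9)
                    checked += 1
            if checked > 2000:
                break
        assert checked > 100

    def test_bias_telescopes_through_any_chain(self, planted_stats):
        _, counts, freqs = planted_stats
        ctx = MutationContext.parse("{C>T|2,ACGT}")
        if counts.n(ctx) == 0:
            pytest.skip("context unobserved in this world")
        mid = MutationContext.parse("{C>T|1,CG}")
        base = MutationContext.parse("{C>T|1,C}")
        bias = cm.mutation_bias(ctx, counts, freqs)
        stepped = cm.contrast(ctx, mid, counts, freqs) * cm.contrast(mid, base, counts, freqs)
        assert bias == pytest.approx(stepped, rel=1e-9)


class TestMutationBias:
    def test_length_one_context_bias_is_unity(self):
        ctx = MutationContext.parse("{C>T|1,C}")
        assert cm.mutation_bias(ctx, ContextCounts({ctx: 5}), table_from({"C": 1})) == 1.0


class TestMinimalContrast:
    def _setup(self, sub_values: dict[str, float], n_ctx: int = 3000):
        """Build counts/freqs so each named subcontext contrast of
        {C>T|2,ACG} equals the requested value (uniform word frequencies,
        so contrast = (N_ctx / N_sub) * P_sub / P_ctx)."""
        import itertools

        ctx = MutationContext.parse("{C>T|2,ACG}")
        t = WordFrequencyTable(max_k=3)
        for k in (1, 2, 3):
            for w in map("".join, itertools.product("ACGT", repeat=k)):
                t.counts[w] = 1
        t.totals = {1: 4, 2: 16, 3: 64}
        counts = {ctx: n_ctx}
        for text, value in sub_values.items():
            sub = MutationContext.parse(text)
            ratio = t.frequency(ctx.word) / t.frequency(sub.word)
            counts[sub] = round(n_ctx / (value * ratio))
        return ctx, ContextCounts(counts), t

    def test_argmin_closest_to_one(self):
        ctx, counts, freqs = self._setup(
            {"{C>T|2,AC}": 1.5, "{C>T|1,CG}": 0.7, "{C>T|1,C}": 1.1}
        )
        value, argmin = cm.minimal_contrast(ctx, counts, freqs)
        assert value == pytest.approx(1.1, rel=1e-3)
        assert str(argmin) == "{C>T|1,C}"

    def test_tie_breaks_to_shorter_then_lexicographic(self):
        # 1.2 and 0.8 give exact integer counts at n_ctx=3000, so the tie
        # |1.2-1| == |0.8-1| is exact
        ctx, counts, freqs = self._setup(
            {"{C>T|2,AC}": 1.2, "{C>T|1,CG}": 0.8, "{C>T|1,C}": 1.2}
        )
        value, argmin = cm.minimal_contrast(ctx, counts, freqs)
        # the shortest subcontext word wins the tie
        assert str(argmin) == "{C>T|1,C}"
        assert value == pytest.approx(1.2, rel=1e-12)

    def test_length_two_minimal_contrast_equals_bias(self, planted_stats):
        _, counts, freqs = planted_stats
        for ctx in cm.enumerate_contexts(2, 2):
            if counts.n(ctx) == 0:
                continue
            value, argmin = cm.minimal_contrast(ctx, counts, freqs)
            assert value == pytest.approx(cm.mutation_bias(ctx, counts, freqs))
            assert argmin.length == 1

    def test_all_undefined_raises(self):
        ctx = MutationContext.parse("{C>T|1,CG}")
        with pytest.raises(UndefinedContrastError):
            cm.minimal_contrast(ctx, ContextCounts(), table_from({"A": 1}))


class TestSpectrum:
    def test_single_event(self):
        event = MutationEvent("c", 0, "C", "T", "ACG", "GTA", 1)
        spectrum = cm.spectrum_table([event])
        by_sub = spectrum.set_index("substitution")["fraction"]
        assert by_sub["C>T"] == 1.0
        assert by_sub.drop("C>T").eq(0.0).all()
        assert len(spectrum) == 12

    def test_sums_partition_unity(self, planted_stats):
        events, _, _ = planted_stats
        sums = cm.spectrum_sums(cm.spectrum_table(events))
        assert sums["transitions"] + sums["transversions"] == pytest.approx(1.0)

    def test_sorted_ascending(self, planted_stats):
        events, _, _ = planted_stats
        spectrum = cm.spectrum_table(events)
        assert spectrum["fraction"].is_monotonic_increasing

    def test_zero_events_error(self):
        with pytest.raises(ValueError):
            cm.spectrum_table([])


class TestStatisticsTable:
    def test_full_table_shape_and_flags(self, planted_stats):
        _, counts, freqs = planted_stats
        stats = cm.context_statistics(counts, freqs)
        assert len(stats) == 3744
        assert set(stats.columns) >= {"context", "N", "mutation_bias", "minimal_contrast",
                                      "argmin_subcontext", "n_subcontexts_defined", "flags"}
        # zero-count contexts have bias 0, not NaN, when the base is observed
        observed = stats[stats["N"] > 0]
        assert observed["mutation_bias"].notna().all()

    def test_min_count_flagging(self, planted_stats):
        _, counts, freqs = planted_stats
        stats = cm.context_statistics(counts, freqs, min_count=5)
        low = stats[stats["N"] < 5]
        assert low["flags"].str.contains("low_count").all()
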