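"""Synthetic-alignment generator: determinism, truth bookkeeping, recovery."""

import numpy as np
import pytest

import contextmut as cm
from contextmut.contexts import MutationContext

from conftest import bias_standard_error


class TestDeterminism:
    def test_same_seed_byte_identical(self):
        cfg = cm.SimulationConfig(length=8000, seed=123)
        block1, _, truth1 = cm.simulate(cfg)
        block2, _, truth2 = cm.simulate(cfg)
        assert block1.rows == block2.rows
        assert truth1.events.equals(truth2.events)

    def test_different_seeds_differ(self):
        b1, _, _ = cm.simulate(cm.SimulationConfig(length=8000, seed=1))
        b2, _, _ = cm.simulate(cm.SimulationConfig(length=8000, seed=2))
        assert b1.rows != b2.rows


class TestConfigValidation:
    def test_composition_must_sum_to_one(self):
        with pytest.raises(ValueError):
            cm.SimulationConfig(base_composition=(0.5, 0.5, 0.5, 0.5))

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            cm.SimulationConfig(base_rate=-0.1)

    def test_nonpositive_multiplier_rejected(self):
        with pytest.raises(ValueError):
            cm.SimulationConfig(multipliers={MutationContext.parse("{C>T|1,CG}"): 0.0})


class TestTruth:
    def test_zero_rate_identical_haplotypes(self):
        cfg = cm.SimulationConfig(length=3000, base_rate=0.0, seed=9,
                                  outgroup_divergence=0.0, gap_rate=0.0, multiallelic_rate=0.0)
        block, roster, truth = cm.simulate(cfg)
        assert len(truth.events) == 0
        reference = block.rows[roster.reference]
        assert all(block.rows[n] == reference for n in roster.names)

    def test_planted_events_present_in_alignment(self, planted_sim):
        _, block, roster, truth = planted_sim
        for row in truth.events.itertuples():
            column = {block.rows[n][row.pos] for n in roster.focal}
            assert column == {row.ancestral, row.derived}
            carriers = sum(block.rows[n][row.pos] == row.derived for n in roster.focal)
            assert carriers == row.derived_count

    def test_events_spaced_for_callability(self, planted_sim):
        cfg, _, _, truth = planted_sim
        pos = truth.events["pos"].to_numpy()
        assert (np.diff(np.sort(pos)) >= 4).all()
        assert pos.min() >= 3 and pos.max() < cfg.length - 3

    def test_hotspot_contexts_recorded(self, planted_sim):
        _, _, _, truth = planted_sim
        hot = truth.events[truth.events["multiplier"] > 1]
        assert (hot["context"].isin({"{C>T|1,CG}", "{A>C|3,CCA}"})).all()
        assert len(hot) > 50


class TestCallerRecovery:
    def test_perfect_recall_precision_noise_free(self, planted_sim):
        _, block, roster, truth = planted_sim
        called = {e.pos: (e.ancestral, e.derived) for e in cm.call_mutations([block], roster)}
        planted = {r.pos: (r.ancestral, r.derived) for r in truth.events.itertuples()}
        assert called == planted  # recall and precision both 1.0

    def test_noise_does_not_hurt_recall(self):
        cfg = cm.SimulationConfig(
            length=30_000, seed=21,
            multipliers={MutationContext.parse("{C>T|1,CG}"): 4.0},
            outgroup_divergence=0.01, gap_rate=0.002, multiallelic_rate=0.001,
        )
        block, roster, truth = cm.simulate(cfg)
        called = {e.pos for e in cm.call_mutations([block], roster)}
        planted = set(truth.events["pos"])
        assert planted <= called  # recall 1.0
        assert called == planted  # noise columns are all filtered out


class TestBiasRecovery:
    def test_planted_bias_matches_truth_expectation(self, planted_sim, planted_stats):
        _, _, _, truth = planted_sim
        _, counts, freqs = planted_stats
        for text in ("{C>T|1,CG}", "{A>C|3,CCA}"):
            ctx = MutationContext.parse(text)
            bias = cm.mutation_bias(ctx, counts, freqs)
            n_ctx = counts.n(ctx)
            n_sub = counts.n(MutationContext(ctx.ancestral, 1, ctx.derived))
            se = bias_standard_error(bias, n_ctx, n_sub)
            assert abs(bias - truth.expected_bias[ctx]) <= 3 * se, text

    def test_recovery_error_shrinks_with_genome_length(self):
        ctx = MutationContext.parse("{C>T|1,CG}")
        errors = []
        for length in (20_000, 200_000):
            cfg = cm.SimulationConfig(
                length=length, seed=31, multipliers={ctx: 8.0},
                outgroup_divergence=0.0, gap_rate=0.0, multiallelic_rate=0.0,
            )
            block, roster, truth = cm.simulate(cfg)
            events = cm.call_mutations([block], roster)
            counts = cm.count_contexts(events)
            freqs = cm.alignment_word_table([block], roster)
            bias = cm.mutation_bias(ctx, counts, freqs)
            errors.append(abs(bias - truth.expected_bias[ctx]))
        assert errors[1] < errors[0]

    def test_multiplier_inversion_closed_form(self):
        # bias = m / (1 + (m-1) q)  <->  m = bias (1-q) / (1 - bias q)
        for m in (0.5, 1.0, 3.0, 8.0):
            for q in (0.01, 0.1, 0.2):
                bias = m / (1 + (m - 1) * q)
                assert cm.multiplier_from_bias(bias, q) == pytest.approx(m, rel=1e-12)


class TestFixtures:
    def test_unknown_fixture_name(self):
        with pytest.raises(KeyError):
            cm.make_fixture("nonexistent")

    def test_fixture_inventory(self):
        names = cm.fixture_names()
        assert {"clean_biallelic", "triallelic", "flank_gap"} <= set(names)
        for name in names:
            block, roster, meta = cm.make_fixture(name)
            assert block.n_cols <= 60 and len(block.rows) <= 6
            assert "expected_events" in meta
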