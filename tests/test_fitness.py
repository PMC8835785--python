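"""Fitness factorization against brute-force enumeration oracles."""

import itertools
import math

import numpy as np
import pytest

from codonevo.fitness import (
    brute_force_fitness,
    draw_reading_assignment,
    fitness_expected,
    fitness_sampled,
    per_label_term,
    restricted_log_fitness,
)
from codonevo.fixtures import make_fixture
from codonevo.model_core import (
    Individual,
    N_CODONS,
    N_LABELS,
    ReadingModel,
    neighbor_index_table,
    random_individual,
)
from conftest import make_rng


def random_code(seed):
    rng = make_rng(seed)
    g = rng.standard_gamma(1.0, size=(N_CODONS, N_LABELS))
    return g / g.sum(axis=1, keepdims=True)


class TestPerLabelTerm:
    def test_full_wobble_block_reaches_one(self):
        ind = make_fixture("m1_perfect_smallL")
        # label 0 owns codons 0..3 (the AAA wobble family) with probability 1
        assert per_label_term(ind.code, 0, 0, ReadingModel.M1, 1.0) == pytest.approx(1.0)

    def test_lone_codon_under_m3_gives_one_tenth(self):
        ind = make_fixture("deterministic_disjoint")
        assert per_label_term(ind.code, 0, 0, ReadingModel.M3, 1.0) == pytest.approx(
            0.1, abs=1e-15
        )

    def test_equals_hand_summed_loop(self):
        code = random_code(3)
        for model in ReadingModel:
            nbrs = neighbor_index_table(model)[17]
            expected = 0.6 / model.neighborhood_size * sum(code[c, 5] for c in nbrs)
            got = per_label_term(code, 5, 17, model, 0.6)
            assert got == pytest.approx(expected, rel=1e-15)

    def test_monotone_in_neighborhood_mass(self):
        """Raising coding probability inside the selected neighborhood never
        lowers the term (checked on unnormalized copies)."""
        code = random_code(4)
        nbrs = neighbor_index_table(ReadingModel.M2)[10]
        bumped = code.copy()
        bumped[nbrs[3], 7] += 0.2
        assert per_label_term(bumped, 7, 10, ReadingModel.M2, 0.5) >= per_label_term(
            code, 7, 10, ReadingModel.M2, 0.5
        )

    def test_rejects_bad_probability(self):
        with pytest.raises(ValueError):
            per_label_term(random_code(1), 0, 0, ReadingModel.M1, 1.5)


class TestSampledFitness:
    def test_disjoint_code_forced_m3_closed_form(self):
        """21 disjoint single-codon assignments read by M3 give F = 0.1^21."""
        ind = make_fixture("deterministic_disjoint")
        ind.reading = np.zeros((N_LABELS, 3))
        ind.reading[:, ReadingModel.M3] = 1.0
        fv = fitness_sampled(ind, make_rng(0))
        assert fv.log_f == pytest.approx(21 * math.log(0.1), rel=1e-12)
        np.testing.assert_allclose(fv.per_label_terms, 0.1, rtol=1e-15)

    def test_disjoint_code_forced_m1_closed_form(self):
        ind = make_fixture("deterministic_disjoint")  # reading already all M1
        fv = fitness_sampled(ind, make_rng(0))
        assert fv.log_f == pytest.approx(21 * math.log(0.25), rel=1e-12)

    def test_log_fitness_never_positive(self):
        for seed in range(10):
            ind = random_individual(make_rng(seed))
            fv = fitness_sampled(ind, make_rng(seed + 100))
            assert fv.log_f <= 0.0
            assert np.all(fv.per_label_terms <= 1.0)
            assert fv.log_f == pytest.approx(
                np.log(fv.per_label_terms).sum(), rel=1e-12
            )

    def test_reading_draw_follows_rows(self):
        ind = make_fixture("deterministic_disjoint")  # reading degenerate on M1
        fv = fitness_sampled(ind, make_rng(5))
        assert set(fv.assignment.tolist()) == {int(ReadingModel.M1)}


class TestBruteForceEquivalence:
    """The core correctness property: the factorized product equals the
    literal sum over all codon combinations."""

    @pytest.mark.parametrize("seed", range(8))
    def test_three_label_exhaustive_all_assignments(self, seed):
        code = random_code(seed)
        rng = make_rng(seed + 50)
        labels = sorted(rng.choice(N_LABELS, size=3, replace=False).tolist())
        path = [int(np.argmax(code[:, l])) for l in labels]
        probs = rng.random(3)
        for models in itertools.product(list(ReadingModel), repeat=3):
            bf = brute_force_fitness(code, labels, path, models, probs)
            log_fact = restricted_log_fitness(code, labels, path, models, probs)
            assert math.log(bf) == pytest.approx(log_fact, rel=1e-12)

    def test_single_label_equals_per_label_term(self):
        code = random_code(11)
        bf = brute_force_fitness(code, [4], [9], [ReadingModel.M2], [0.3])
        assert bf == pytest.approx(
            per_label_term(code, 4, 9, ReadingModel.M2, 0.3), rel=1e-15
        )

    def test_two_labels_distributivity(self):
        code = random_code(12)
        labels, path = [0, 20], [0, 63]  # AAA and TTT: disjoint M1 neighborhoods
        models = [ReadingModel.M1, ReadingModel.M1]
        bf = brute_force_fitness(code, labels, path, models, [0.7, 0.4])
        prod = per_label_term(code, 0, 0, ReadingModel.M1, 0.7) * per_label_term(
            code, 20, 63, ReadingModel.M1, 0.4
        )
        assert bf == pytest.approx(prod, rel=1e-13)

    def test_size_guard(self):
        with pytest.raises(ValueError):
            brute_force_fitness(
                random_code(0), [0, 1, 2, 3, 4], [0] * 5, [ReadingModel.M1] * 5, [1] * 5
            )


class TestExpectedFitness:
    def test_point_mass_reading_equals_sampled(self):
        ind = make_fixture("deterministic_disjoint")  # reading all M1
        expected = fitness_expected(ind)
        sampled = fitness_sampled(ind, make_rng(0))
        assert expected.log_f == pytest.approx(sampled.log_f, rel=1e-12)

    def test_three_label_enumeration_oracle(self):
        """Expected per-label factors equal the draw-probability-weighted
        average of sampled factors over all 27 reading assignments."""
        rng = make_rng(77)
        ind = random_individual(rng)
        full = fitness_expected(ind)
        labels = [2, 9, 17]
        path = [int(np.argmax(ind.code[:, l])) for l in labels]
        total = np.zeros(3)
        for models in itertools.product(list(ReadingModel), repeat=3):
            w = np.prod([ind.reading[l, m] for l, m in zip(labels, models)])
            terms = [
                per_label_term(ind.code, l, c, m, float(ind.reading[l, m]))
                for l, c, m in zip(labels, path, models)
            ]
            # expectation factorizes per label; accumulate each label's share
            for i in range(3):
                total[i] += w * terms[i]
        np.testing.assert_allclose(total, full.per_label_terms[labels], rtol=1e-12)

    def test_value_in_unit_interval(self):
        for seed in range(5):
            fv = fitness_expected(random_individual(make_rng(seed)))
            assert fv.log_f <= 0.0

    def test_deterministic_for_fixed_individual(self):
        ind = random_individual(make_rng(8))
        assert fitness_expected(ind).log_f == fitness_expected(ind).log_f


def test_reading_draw_distribution_matches_rows():
    """Empirical draw frequencies track the reading-matrix rows."""
    rng = make_rng(31)
    reading = np.tile(np.array([[0.6, 0.3, 0.1]]), (N_LABELS, 1))
    draws = np.stack([draw_reading_assignment(reading, rng) for _ in range(4000)])
    freq = np.bincount(draws.ravel(), minlength=3) / draws.size
    np.testing.assert_allclose(freq, [0.6, 0.3, 0.1], atol=0.01)
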