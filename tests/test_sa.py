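import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gwolfsel.objective import FitnessValue
from gwolfsel.sa_refine import (
    OPERATORS,
    SAConfig,
    apply_operator,
    boltzmann_accept,
    roulette_select,
    sa_refine,
)


class TestOperators:
    def test_rotate_left(self, rng):
        np.testing.assert_array_equal(
            apply_operator(np.array([1, 0, 0], np.int8), "r2l", rng), [0, 0, 1]
        )

    def test_rotate_right(self, rng):
        np.testing.assert_array_equal(
            apply_operator(np.array([1, 0, 0], np.int8), "r2r", rng), [0, 1, 0]
        )

    def test_swap_moves_at_most_two_positions(self, rng):
        mask = np.array([1, 0, 0, 1], np.int8)
        out = apply_operator(mask, "swap", rng)
        assert (out != mask).sum() in (0, 2)

    @given(
        st.lists(st.integers(0, 1), min_size=2, max_size=40),
        st.sampled_from(OPERATORS),
        st.integers(0, 10_000),
    )
    def test_popcount_conserved(self, bits, op, seed):
        mask = np.array(bits, dtype=np.int8)
        out = apply_operator(mask, op, np.random.default_rng(seed))
        assert out.sum() == mask.sum()
        assert len(out) == len(mask)

    def test_bitflip_changes_popcount(self, rng):
        mask = np.zeros(10, np.int8)
        out = apply_operator(mask, "bitflip", rng)
        assert out.sum() == 1

    def test_unknown_operator(self, rng):
        with pytest.raises(ValueError):
            apply_operator(np.ones(4, np.int8), "scramble", rng)


class TestRoulette:
    def test_degenerate_always_first(self, rng):
        labels = ("swap", "insertion", "inversion", "r2l", "r2r")
        for _ in range(100):
            assert roulette_select([1, 0, 0, 0, 0], rng, labels) == "swap"

    def test_uniform_frequencies(self, rng):
        counts = np.zeros(5)
        for _ in range(50_000):
            counts[roulette_select(np.ones(5), rng)] += 1
        np.testing.assert_allclose(counts / 50_000, 0.2, atol=0.01)

    def test_weighted_frequencies(self, rng):
        counts = np.zeros(5)
        for _ in range(50_000):
            counts[roulette_select([2, 1, 1, 1, 1], rng)] += 1
        assert counts[0] / 50_000 == pytest.approx(1 / 3, abs=0.01)

    def test_all_zero_rejected(self, rng):
        with pytest.raises(ValueError):
            roulette_select([0, 0], rng)


class TestBoltzmann:
    def test_equal_or_better_always_accepted(self, rng):
        assert boltzmann_accept(0.0, 0.5, rng)
        assert boltzmann_accept(-1.0, 0.5, rng)

    def test_acceptance_frequency_at_delta_equals_T(self, rng):
        n = 20_000
        acc = sum(boltzmann_accept(0.1, 0.1, rng) for _ in range(n)) / n
        assert acc == pytest.approx(np.exp(-1), abs=0.01)

    def test_frozen_limit(self, rng):
        acc = sum(boltzmann_accept(0.5, 1e-6, rng) for _ in range(1000))
        assert acc == 0

    def test_nonpositive_temperature(self, rng):
        with pytest.raises(ValueError):
            boltzmann_accept(0.1, 0.0, rng)


def position_fitness(mask):
    """Position-sensitive toy: sum of indices of selected bits (minimized).

    The five operators conserve popcount, so improvement must come from
    moving 1s to lower indices."""
    mask = np.asarray(mask)
    nf = int(mask.sum())
    value = float((np.flatnonzero(mask)).sum()) / (len(mask) * max(nf, 1))
    return FitnessValue(value, 0.0, nf, len(mask), 0.8)


class TestSARefine:
    def test_returns_start_when_frozen_at_optimum(self, rng):
        start = np.array([1, 1, 0, 0, 0, 0, 0, 0], np.int8)  # optimum of toy
        cfg = SAConfig(t0=1e-5, t_final=0.9e-5, moves_per_temperature=2)
        best, fv = sa_refine(start, position_fitness, cfg, rng)
        np.testing.assert_array_equal(best, start)

    def test_never_worse_than_start(self, rng):
        cfg = SAConfig()
        for seed in range(20):
            local = np.random.default_rng(seed)
            start = (local.random(20) < 0.35).astype(np.int8)
            f0 = position_fitness(start).fit
            best, fv = sa_refine(start, position_fitness, cfg, local)
            assert fv.fit <= f0 + 1e-12

    def test_popcount_invariant_under_default_ops(self, rng):
        start = (rng.random(30) < 0.4).astype(np.int8)
        best, fv = sa_refine(start, position_fitness, SAConfig(), rng)
        assert best.sum() == start.sum()

    def test_improves_position_toy(self):
        """Annealing shifts selected bits toward the low-index optimum."""
        improved = 0
        for seed in range(10):
            local = np.random.default_rng(seed)
            start = np.zeros(20, np.int8)
            start[10:17] = 1
            best, fv = sa_refine(start, position_fitness, SAConfig(), local)
            if fv.fit < position_fitness(start).fit:
                improved += 1
        assert improved >= 8

    def test_temperature_ladder(self):
        cfg = SAConfig(t0=0.1, cooling=0.5, t_final=0.01)
        temps = cfg.temperatures()
        assert temps[0] == 0.1
        assert all(t >= cfg.t_final for t in temps)
        assert np.all(np.diff(temps) < 0)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SAConfig(t0=0.001, t_final=0.1)
        with pytest.raises(ValueError):
            SAConfig(operator_weights={"swap": 0.0, "insertion": 0.0,
                                       "inversion": 0.0, "r2l": 0.0, "r2r": 0.0})
        with pytest.raises(ValueError):
            SAConfig(operator_weights={"teleport": 1.0})
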