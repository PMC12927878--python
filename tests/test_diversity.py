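"""Rarefaction, richness, Bray-Curtis, and the turnover/nestedness partition."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lotic import diversity as dv
from lotic import synthetic
from lotic.errors import EmptyResultError, InvalidInputError, MappingError


def make_table(counts, sites=None, sample_ids=None):
    counts = np.asarray(counts)
    sample_ids = sample_ids or [f"smp{i}" for i in range(counts.shape[1])]
    sites = sites or [f"site{i}" for i in range(counts.shape[1])]
    frame = pd.DataFrame(
        counts, index=[f"asv{i}" for i in range(counts.shape[0])], columns=sample_ids
    )
    return dv.AsvTable(frame, dict(zip(sample_ids, sites)))


class TestDropShallow:
    def test_threshold_keeps_boundary_sample(self):
        t = make_table([[3000, 3155, 5000]])
        kept = dv.drop_shallow(t, 3155)
        assert kept.sample_ids == ["smp1", "smp2"]

    def test_min_one_is_identity(self, rng):
        t = make_table(rng.integers(1, 50, size=(10, 4)))
        assert dv.drop_shallow(t, 1).counts.equals(t.counts)

    def test_matches_brute_force_filter(self, rng):
        counts = rng.integers(0, 30, size=(15, 8))
        t = make_table(counts)
        kept = dv.drop_shallow(t, 100, prune_empty=False)
        brute = [i for i in range(8) if counts[:, i].sum() >= 100]
        assert kept.sample_ids == [f"smp{i}" for i in brute]

    def test_all_dropped_is_error(self):
        with pytest.raises(EmptyResultError):
            dv.drop_shallow(make_table([[1, 2]]), 1000)


class TestRarefy:
    def test_single_asv_sample_is_degenerate(self):
        t = make_table([[500]])
        out = dv.rarefy(t, depth=100, reps=10, seed=0)
        assert out.counts.iloc[0, 0] == 100

    def test_each_repetition_sums_to_depth_exactly(self, rng):
        t = make_table(rng.integers(0, 200, size=(20, 3)) + 1)
        _, reps = dv.rarefy(t, depth=150, reps=25, seed=1, return_reps=True)
        for stack in reps.values():
            assert (stack.sum(axis=1) == 150).all()

    def test_rep_means_match_multinomial_expectation(self):
        t = make_table([[500], [300], [200]])
        _, reps = dv.rarefy(t, depth=100, reps=200, seed=3, return_reps=True)
        means = reps["smp0"].mean(axis=0)
        p = np.array([0.5, 0.3, 0.2])
        se = np.sqrt(100 * p * (1 - p) / 200)
        assert np.all(np.abs(means - 100 * p) <= 4 * se)

    def test_reproducible_and_sample_independent(self):
        t = make_table([[40, 40], [60, 60]], sample_ids=["a", "b"])
        r1 = dv.rarefy(t, depth=50, reps=20, seed=9)
        r2 = dv.rarefy(t, depth=50, reps=20, seed=9)
        assert r1.counts.equals(r2.counts)
        # removing sample b must not change sample a's draws
        ta = make_table([[40], [60]], sample_ids=["a"])
        ra = dv.rarefy(ta, depth=50, reps=20, seed=9)
        assert (ra.counts["a"] == r1.counts["a"]).all()

    def test_shallow_sample_rejected(self):
        with pytest.raises(InvalidInputError):
            dv.rarefy(make_table([[10]]), depth=100)

    def test_nonpositive_depth_rejected(self):
        with pytest.raises(InvalidInputError):
            dv.rarefy(make_table([[10]]), depth=0)


class TestObservedAsvs:
    def test_vectors(self):
        assert dv.observed_asvs([0, 0, 0]) == 0
        assert dv.observed_asvs([5, 0, 1, 0]) == 2

    def test_matches_brute_force(self, rng):
        col = rng.integers(0, 4, 100)
        assert dv.observed_asvs(col) == sum(1 for v in col if v > 0)

    def test_table_series(self):
        t = make_table([[1, 0], [2, 3]])
        assert dv.observed_asvs(t).tolist() == [2, 1]


class TestBrayCurtis:
    def test_identical_is_zero(self):
        x = np.array([0.2, 0.3, 0.5])
        assert dv.bray_curtis(x, x) == pytest.approx(0.0)

    def test_disjoint_is_one(self):
        assert dv.bray_curtis([1.0, 0.0], [0.0, 1.0]) == pytest.approx(1.0)

    def test_hand_value(self):
        assert dv.bray_curtis([0.5, 0.5, 0.0], [0.0, 0.5, 0.5]) == pytest.approx(0.5)

    def test_unnormalized_rejected(self):
        with pytest.raises(InvalidInputError):
            dv.bray_curtis([0.5, 0.4], [0.5, 0.5])

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.integers(0, 2**31 - 1))
    def test_symmetry_and_bounds(self, seed):
        r = np.random.default_rng(seed)
        x = r.random(8)
        y = r.random(8)
        x, y = x / x.sum(), y / y.sum()
        d1, d2 = dv.bray_curtis(x, y), dv.bray_curtis(y, x)
        assert d1 == pytest.approx(d2)
        assert 0.0 <= d1 <= 1.0


def partition_oracle(a, b, c):
    """Independent closed-form partition from shared/unique counts."""
    m = min(b, c)
    sim = m / (a + m) if a + m else 0.0
    sor = (b + c) / (2 * a + b + c)
    return sor, sim, sor - sim


def vectors_from_abc(a, b, c):
    n = a + b + c
    x = np.zeros(n, dtype=int)
    y = np.zeros(n, dtype=int)
    x[: a + b] = 1
    y[:a] = 1
    y[a + b:] = 1
    return x, y


class TestBetaPartition:
    def test_identical_sets(self):
        p = dv.beta_partition_pair([1, 1, 0], [1, 1, 0])
        assert (p.beta_sor, p.beta_sim, p.beta_nes) == (0.0, 0.0, 0.0)

    def test_disjoint_sets(self):
        p = dv.beta_partition_pair([1, 0], [0, 1])
        assert (p.beta_sim, p.beta_sor, p.beta_nes) == (1.0, 1.0, 0.0)

    def test_mixed_example(self):
        # a=2 shared, b=1, c=3 uniques
        x, y = vectors_from_abc(2, 1, 3)
        p = dv.beta_partition_pair(x, y)
        assert p.beta_sim == pytest.approx(1 / 3)
        assert p.beta_sor == pytest.approx(0.5)
        assert p.beta_nes == pytest.approx(1 / 6)

    def test_empty_community_rejected(self):
        with pytest.raises(InvalidInputError):
            dv.beta_partition_pair([0, 0], [1, 0])

    def test_enumeration_oracle_small(self):
        for a in range(6):
            for b in range(6):
                for c in range(6):
                    if a + b == 0 or a + c == 0:
                        continue
                    p = dv.beta_partition_pair(*vectors_from_abc(a, b, c))
                    sor, sim, nes = partition_oracle(a, b, c)
                    assert p.beta_sor == pytest.approx(sor, abs=1e-12)
                    assert p.beta_sim == pytest.approx(sim, abs=1e-12)
                    assert p.beta_nes == pytest.approx(nes, abs=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(st.integers(0, 2**31 - 1))
    def test_partition_additivity(self, seed):
        r = np.random.default_rng(seed)
        x = r.integers(0, 2, 30)
        y = r.integers(0, 2, 30)
        if not x.any() or not y.any():
            return
        p = dv.beta_partition_pair(x, y)
        assert abs(p.beta_sor - (p.beta_sim + p.beta_nes)) < 1e-12
        assert 0.0 <= p.beta_sim <= p.beta_sor <= 1.0
        assert p.beta_nes >= 0.0


class TestConsecutiveSeries:
    def test_identical_samples_give_zero_series(self, toy_transect):
        col = [10, 20, 0, 5]
        t = make_table(
            np.array([col, col, col]).T,
            sites=["A", "B", "C"],
        )
        out = dv.consecutive_series(t, toy_transect)
        assert len(out) == 2
        assert np.allclose(out[["beta_sor", "beta_sim", "beta_nes"]], 0.0)
        assert np.allclose(out["tt_mid_h"], [1.0, 3.0])

    def test_missing_site_sample_is_mapping_error(self, toy_transect):
        t = make_table([[1, 2]], sites=["A", "B"])
        with pytest.raises(MappingError):
            dv.consecutive_series(t, toy_transect)

    def test_turnover_dominates_nestedness_on_synthetic(self, jds3_table, jds3_transect):
        out = dv.consecutive_series(jds3_table, jds3_transect)
        body = out.iloc[3:]  # downstream of the shared headwater reach
        assert body["beta_nes"].median() < 0.25 * body["beta_sim"].median()


class TestWholeRiverTurnover:
    def test_identical_endpoints_degenerate(self, toy_transect):
        col = [3, 1, 4]
        t = make_table(np.array([col, col, col]).T, sites=["A", "B", "C"])
        out = dv.whole_river_turnover(t, toy_transect)
        assert out.degenerate and out.turnover == 0.0

    def test_complete_replacement(self, toy_transect):
        t = make_table(
            [[5, 2, 0], [0, 3, 0], [0, 1, 7], [0, 0, 2]], sites=["A", "B", "C"]
        )
        out = dv.whole_river_turnover(t, toy_transect)
        assert out.turnover == pytest.approx(1.0)
        assert out.percent_contribution == pytest.approx(100.0)

    def test_multisite_bounds(self, jds3_table, jds3_transect):
        out = dv.whole_river_turnover(jds3_table, jds3_transect, method="multisite")
        assert 0.0 < out.turnover <= 1.0
        assert 0.0 < out.percent_contribution <= 100.0

    def test_strong_replacement_scenario(self):
        truth = synthetic.strong_replacement(seed=11)
        tr = synthetic.generate_transect(truth)
        tab = synthetic.generate_asv_table(truth, tr)
        out = dv.whole_river_turnover(tab, tr)
        assert out.turnover >= 0.9
        assert out.percent_contribution >= 90.0


class TestHeadwaterPersistence:
    def test_everything_everywhere(self, toy_transect):
        t = make_table(np.ones((5, 3), dtype=int), sites=["A", "B", "C"])
        out = dv.headwater_persistence(t, toy_transect, n_head=1)
        assert out.fraction == pytest.approx(1.0)

    def test_nothing_persists(self, toy_transect):
        t = make_table([[4, 0, 0], [0, 3, 5]], sites=["A", "B", "C"])
        out = dv.headwater_persistence(t, toy_transect, n_head=1)
        assert out.fraction == pytest.approx(0.0)

    def test_monotone_in_presence_threshold(self, jds3_table, jds3_transect):
        fracs = [
            dv.headwater_persistence(jds3_table, jds3_transect, presence_frac=f).fraction
            for f in (0.5, 0.7, 0.9, 1.0)
        ]
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))

    def test_recovers_planted_core(self, jds3_truth, jds3_table, jds3_transect):
        out = dv.headwater_persistence(jds3_table, jds3_transect)
        assert abs(out.fraction - jds3_truth.persistent_fraction) <= 0.03
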