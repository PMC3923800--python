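import numpy as np
import pytest

import rxnmix as rx
from rxnmix.mixtures import mixtures_to_manifest

T = rx.DEFAULT_TYPES


def dummy_reactions(per_type_counts):
    """Cheap one-peak reaction records for counting tests."""
    out = []
    for t_idx, count in enumerate(per_type_counts):
        for k in range(count):
            out.append(
                rx.ReactionRecord(
                    id=f"t{t_idx}_{k}",
                    rtype=T[t_idx],
                    reactants=(rx.ShiftList.from_pairs([(5.0, 1)]),),
                    product=rx.ShiftList.from_pairs([(3.0, 1)]),
                )
            )
    return out


class TestMixtureClass:
    def test_table_rows(self, registry):
        assert rx.mixture_class(T[0], T[1]) == "A"
        assert rx.mixture_class(T[3], T[4]) == "M"
        assert registry.class_pair("A") == (T[0], T[1])
        assert registry.class_pair("O") == (T[4], T[5])

    def test_symmetry(self):
        assert rx.mixture_class(T[4], T[5]) == rx.mixture_class(T[5], T[4]) == "O"

    def test_same_type_rejected(self):
        with pytest.raises(ValueError):
            rx.mixture_class(T[2], T[2])

    def test_fifteen_distinct_classes(self, registry):
        assert registry.n_classes == 15
        assert len(set(registry.class_labels)) == 15


class TestEnumerate:
    def test_study_scale_counts(self):
        mix = rx.enumerate_mixtures(dummy_reactions((20, 31, 20, 73, 10, 27)))
        assert len(mix) == 12421
        per_class = {}
        for m in mix:
            per_class[m.mclass] = per_class.get(m.mclass, 0) + 1
        assert per_class["A"] == 620
        assert per_class["B"] == 400
        assert sum(per_class.values()) == 12421

    def test_count_identity_against_brute_force(self):
        counts = (3, 2, 4, 1, 2, 3)
        reactions = dummy_reactions(counts)
        mix = rx.enumerate_mixtures(reactions)
        # independent double loop over reaction pairs
        brute = sum(
            1
            for i, a in enumerate(reactions)
            for b in reactions[i + 1 :]
            if a.rtype != b.rtype
        )
        assert len(mix) == brute
        assert all(m.rxn_a != m.rxn_b for m in mix)

    def test_single_type_yields_nothing(self):
        assert rx.enumerate_mixtures(dummy_reactions((5,))) == []

    def test_class_labels_match_types(self, registry):
        reactions = dummy_reactions((2, 2, 2, 2, 2, 2))
        types = {r.id: r.rtype for r in reactions}
        for m in rx.enumerate_mixtures(reactions):
            assert m.mclass == registry.mixture_class(types[m.rxn_a], types[m.rxn_b])


class TestMixtureDescriptor:
    def test_default_is_plain_sum(self):
        a, b = np.eye(120)[30], np.eye(120)[55]
        assert rx.mixture_descriptor(a, b) == pytest.approx(a + b)

    def test_ratio_and_norm(self):
        a, b = np.eye(120)[30], np.eye(120)[55]
        got = rx.mixture_descriptor(a, b, ratio=2, norm=0.5)
        assert got[30] == pytest.approx(1.0)
        assert got[55] == pytest.approx(0.5)

    def test_zero_inputs_stay_zero(self):
        z = np.zeros(120)
        assert rx.mixture_descriptor(z, z, ratio=5, norm=0.3) == pytest.approx(0.0)

    def test_commutative_at_unit_ratio(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=120), rng.normal(size=120)
        assert rx.mixture_descriptor(a, b) == pytest.approx(rx.mixture_descriptor(b, a))

    def test_invalid_parameters(self):
        a = np.zeros(120)
        with pytest.raises(ValueError):
            rx.mixture_descriptor(a, a, ratio=0)
        with pytest.raises(ValueError):
            rx.mixture_descriptor(a, np.zeros(60))


class TestPartitions:
    def test_mixture_level_sizes_and_determinism(self):
        mix = rx.enumerate_mixtures(dummy_reactions((5, 5, 5)))
        train, test = rx.partition_mixture_level(mix, 50, seed=3)
        assert len(train) == 50 and len(test) == len(mix) - 50
        ids = {m.id for m in train} | {m.id for m in test}
        assert len(ids) == len(mix)  # disjoint and exhaustive
        train2, test2 = rx.partition_mixture_level(mix, 50, seed=3)
        assert [m.id for m in train2] == [m.id for m in train]

    def test_mixture_level_singleton_test_set(self):
        mix = rx.enumerate_mixtures(dummy_reactions((2, 2)))
        train, test = rx.partition_mixture_level(mix, len(mix) - 1, seed=0)
        assert len(test) == 1

    def test_mixture_level_bad_size(self):
        mix = rx.enumerate_mixtures(dummy_reactions((2, 2)))
        for bad in (0, len(mix), len(mix) + 1):
            with pytest.raises(ValueError):
                rx.partition_mixture_level(mix, bad, seed=0)

    def test_reaction_level_training_counts(self):
        """Held-out reactions per type imply the printed training-pair counts."""
        reactions = dummy_reactions((20, 31, 20, 73, 10, 27))
        test_counts = dict(zip(T, (4, 8, 4, 17, 2, 6)))
        split = rx.partition_reaction_level(reactions, test_counts, seed=0)
        per_class = {}
        for m in split.train_mixtures:
            per_class[m.mclass] = per_class.get(m.mclass, 0) + 1
        assert per_class["A"] == 16 * 23 == 368
        assert per_class["B"] == 16 * 16 == 256

    def test_reaction_level_no_leakage(self, small_reactions):
        test_counts = {t: 1 for t in T}
        split = rx.partition_reaction_level(small_reactions, test_counts, seed=1)
        train_ids = {m.rxn_a for m in split.train_mixtures} | {
            m.rxn_b for m in split.train_mixtures
        }
        test_ids = {m.rxn_a for m in split.test_mixtures} | {
            m.rxn_b for m in split.test_mixtures
        }
        assert train_ids.isdisjoint(test_ids)

    def test_reaction_level_zero_test_count(self, small_reactions, registry):
        counts = {t: 0 for t in T}
        counts[T[0]] = 2
        counts[T[1]] = 2
        split = rx.partition_reaction_level(small_reactions, counts, seed=2)
        test_types = {r.rtype for r in split.test_reactions}
        assert test_types == {T[0], T[1]}
        # only class A mixtures can occur in the test side
        assert {m.mclass for m in split.test_mixtures} == {"A"}

    def test_reaction_level_infeasible(self, small_reactions):
        with pytest.raises(ValueError):
            rx.partition_reaction_level(small_reactions, {T[0]: 999}, seed=0)


class TestPerturbationBattery:
    @pytest.fixture()
    def mixtures(self):
        return rx.enumerate_mixtures(dummy_reactions((3, 3, 2)))

    def test_fixed_ratio_values_double_the_set(self, mixtures):
        out = rx.perturbation_battery(mixtures, ratio_values=[2, 5])
        assert len(out) == 2 * len(mixtures)
        assert {m.ratio for m in out} == {2.0, 5.0}

    def test_degenerate_ranges_reproduce_input(self, mixtures):
        out = rx.perturbation_battery(
            mixtures, yield_range=(1, 1), norm_range=(1, 1), ratio_range=(1, 1)
        )
        for orig, new in zip(mixtures, out):
            assert (new.ratio, new.norm, new.yield_a, new.yield_b) == (1, 1, 1, 1)
            assert new.rxn_a == orig.rxn_a and new.rxn_b == orig.rxn_b

    def test_sampled_parameters_in_range_and_reproducible(self, mixtures):
        kw = dict(
            yield_range=(0.5, 1.0),
            norm_range=(0.2, 1.0),
            ratio_range=(1.0, 4.0),
            replicates=2,
            seed=11,
        )
        out = rx.perturbation_battery(mixtures, **kw)
        assert len(out) == 2 * len(mixtures)
        for m in out:
            assert 0.5 <= m.yield_a <= 1.0 and 0.5 <= m.yield_b <= 1.0
            assert 0.2 <= m.norm <= 1.0
            assert 1.0 <= m.ratio <= 4.0
        again = rx.perturbation_battery(mixtures, **kw)
        assert [(m.ratio, m.norm, m.yield_a) for m in again] == [
            (m.ratio, m.norm, m.yield_a) for m in out
        ]

    def test_empty_battery_rejected(self, mixtures):
        with pytest.raises(ValueError):
            rx.perturbation_battery([], ratio_values=[2])
        with pytest.raises(ValueError):
            rx.perturbation_battery(mixtures, replicates=0)


def test_manifest_columns(small_problem):
    df = mixtures_to_manifest(small_problem["mixtures"])
    assert list(df.columns) == [
        "mixture_id",
        "rxn_a",
        "rxn_b",
        "class",
        "ratio",
        "norm",
        "yield_a",
        "yield_b",
    ]
    assert len(df) == len(small_problem["mixtures"])
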