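"""Observation store: typed attributes, cached distributions, rollup and
subset export."""

import random

import pytest

from taxbench.results import (
    CONTINUOUS,
    DISCRETE,
    FLAT,
    HIERARCHICAL,
    ObservationStore,
    StoreError,
)


@pytest.fixture
def store():
    s = ObservationStore()
    yield s
    s.close()


@pytest.fixture
def taxo_store(store):
    """Store with a small taxonomy hierarchy: root -> g1, g2 -> species."""
    store.register_type("taxonomy", HIERARCHICAL, DISCRETE)
    root = store.add_attribute("taxonomy", "root")
    g1 = store.add_attribute("taxonomy", "g1", parent=root)
    g2 = store.add_attribute("taxonomy", "g2", parent=root)
    s11 = store.add_attribute("taxonomy", "g1_s1", parent=g1)
    s12 = store.add_attribute("taxonomy", "g1_s2", parent=g1)
    s21 = store.add_attribute("taxonomy", "g2_s1", parent=g2)
    return store, {"root": root, "g1": g1, "g2": g2,
                   "g1_s1": s11, "g1_s2": s12, "g2_s1": s21}


class TestTypes:
    def test_register_flat_and_hierarchical(self, store):
        t1 = store.register_type("NCBI_taxonomy", HIERARCHICAL, DISCRETE)
        t2 = store.register_type("GC_content", FLAT, CONTINUOUS)
        assert t1.structure == HIERARCHICAL and t2.value_domain == CONTINUOUS

    def test_hierarchical_continuous_rejected(self, store):
        with pytest.raises(StoreError):
            store.register_type("depth", HIERARCHICAL, CONTINUOUS)

    def test_duplicate_name_conflict(self, store):
        store.register_type("x", FLAT, DISCRETE)
        with pytest.raises(StoreError, match="already"):
            store.register_type("x", FLAT, DISCRETE)

    def test_parent_on_flat_type_rejected(self, store):
        store.register_type("flat", FLAT, DISCRETE)
        a = store.add_attribute("flat", "a")
        with pytest.raises(StoreError):
            store.add_attribute("flat", "b", parent=a)


class TestObservations:
    def test_add_and_count(self, taxo_store):
        store, attrs = taxo_store
        store.add_observation("r1", 0, 100, attrs["g1_s1"])
        assert store.distribution("taxonomy") == {"g1_s1": 1}

    def test_bad_coordinates_rejected(self, taxo_store):
        store, attrs = taxo_store
        with pytest.raises(StoreError):
            store.add_observation("r1", 100, 100, attrs["g1"])
        with pytest.raises(StoreError):
            store.add_observation("r1", -1, 10, attrs["g1"])

    def test_multiple_annotation_strategies_coexist_per_sequence(self, taxo_store):
        store, attrs = taxo_store
        store.register_type("COG", FLAT, DISCRETE)
        cog = store.add_attribute("COG", "COG1877")
        store.add_observation("r1", 0, 100, attrs["g1_s1"])
        store.add_observation("r1", 10, 40, cog)
        assert store.export_subset({"taxonomy": "g1_s1"}) == ["r1"]
        assert store.export_subset({"COG": "COG1877"}) == ["r1"]

    def test_cache_equals_recount_after_random_interleaving(self, taxo_store):
        store, attrs = taxo_store
        rng = random.Random(201)
        values = list(attrs.values())
        for i in range(10_000):
            a = rng.choice(values)
            start = rng.randint(0, 500)
            store.add_observation(f"r{rng.randint(0, 999)}", start,
                                  start + rng.randint(1, 100), a)
        cached = store.distribution("taxonomy", from_cache=True)
        recount = store.distribution("taxonomy", from_cache=False)
        assert cached == recount
        assert sum(cached.values()) == 10_000


class TestDistribution:
    def test_empty_store_empty_distribution(self, taxo_store):
        store, _ = taxo_store
        assert store.distribution("taxonomy") == {}

    def test_rollup_propagates_to_ancestors(self, taxo_store):
        store, attrs = taxo_store
        for _ in range(3):
            store.add_observation("r1", 0, 10, attrs["g1_s1"])
        rolled = store.distribution("taxonomy", hierarchical_rollup=True)
        assert rolled == {"g1_s1": 3, "g1": 3, "root": 3}

    def test_rollup_on_flat_type_rejected(self, store):
        store.register_type("flat", FLAT, DISCRETE)
        store.add_observation("r1", 0, 1, store.add_attribute("flat", "v"))
        with pytest.raises(StoreError):
            store.distribution("flat", hierarchical_rollup=True)

    def test_rollup_equals_brute_force_subtree_sum(self, taxo_store):
        store, attrs = taxo_store
        rng = random.Random(202)
        direct = {name: 0 for name in attrs}
        for _ in range(2000):
            name = rng.choice(list(attrs))
            direct[name] += 1
            store.add_observation(f"r{rng.randint(0, 99)}", 0, 50, attrs[name])
        children = {"root": ["g1", "g2"], "g1": ["g1_s1", "g1_s2"],
                    "g2": ["g2_s1"]}

        def subtree(v):
            return direct[v] + sum(subtree(c) for c in children.get(v, []))

        rolled = store.distribution("taxonomy", hierarchical_rollup=True)
        for name in attrs:
            assert rolled.get(name, 0) == subtree(name)
        # monotone along the hierarchy
        for parent, kids in children.items():
            for k in kids:
                assert rolled.get(parent, 0) >= rolled.get(k, 0)

    def test_continuous_distribution_binned(self, store):
        store.register_type("GC", FLAT, CONTINUOUS)
        for i, v in enumerate([0.1, 0.2, 0.2, 0.9]):
            store.add_observation(f"r{i}", 0, 100, store.add_attribute("GC", v))
        bins = store.distribution("GC", bins=8)
        assert sum(c for _, _, c in bins) == 4
        assert bins[0][0] == pytest.approx(0.1) and bins[-1][1] == pytest.approx(0.9)


class TestExportSubset:
    def test_hierarchical_match_includes_descendants(self, taxo_store):
        store, attrs = taxo_store
        store.add_observation("r1", 0, 10, attrs["g1_s1"])
        store.add_observation("r2", 0, 10, attrs["g1_s2"])
        store.add_observation("r3", 0, 10, attrs["g2_s1"])
        assert store.export_subset({"taxonomy": "g1"}) == ["r1", "r2"]

    def test_absent_value_empty_not_error(self, taxo_store):
        store, attrs = taxo_store
        store.add_observation("r1", 0, 10, attrs["g1"])
        assert store.export_subset({"taxonomy": "nope"}) == []

    def test_conjunction_equals_brute_force_intersection(self, taxo_store):
        store, attrs = taxo_store
        store.register_type("function", FLAT, DISCRETE)
        funcs = [store.add_attribute("function", f"F{i}") for i in range(4)]
        rng = random.Random(203)
        tax_of, fun_of = {}, {}
        for i in range(300):
            sid = f"r{i}"
            tname = rng.choice(list(attrs))
            f = rng.randrange(4)
            tax_of[sid], fun_of[sid] = tname, f
            store.add_observation(sid, 0, 10, attrs[tname])
            store.add_observation(sid, 20, 30, funcs[f])
        g1_members = {"g1", "g1_s1", "g1_s2"}
        expect = sorted(s for s in tax_of
                        if tax_of[s] in g1_members and fun_of[s] == 2)
        assert store.export_subset({"taxonomy": "g1", "function": "F2"}) == expect

    def test_export_cardinality_matches_rollup_count(self, taxo_store):
        store, attrs = taxo_store
        rng = random.Random(204)
        for i in range(200):  # one taxonomy observation per sequence
            store.add_observation(f"r{i}", 0, 10, attrs[rng.choice(list(attrs))])
        rolled = store.distribution("taxonomy", hierarchical_rollup=True)
        for value in attrs:
            assert len(store.export_subset({"taxonomy": value})) == \
                rolled.get(value, 0)
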