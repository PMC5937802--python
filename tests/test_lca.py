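"""Hit filtering, per-read LCA assignment, and stream combination."""

import random

import pytest

from taxbench.io import UNCLASSIFIED, AlignmentHit, ReadAssignment
from taxbench.lca import LcaParameters, assign_lca, combine_assignments, filter_hits
from taxbench.taxonomy import UnknownTaxidError

from conftest import brute_force_lca, random_tree


def hit(read="r1", subj="s", bitscore=100.0, evalue=1e-20, taxid=None):
    return AlignmentHit(read, subj, 90.0, bitscore, evalue, taxid)


class TestFilterHits:
    P = LcaParameters(top_score_fraction=0.10, min_bitscore=0, max_evalue=1e9)

    def test_top_fraction_window(self):
        hits = [hit(subj=s, bitscore=b) for s, b in [("a", 100), ("b", 95), ("c", 80)]]
        kept = filter_hits(hits, self.P)
        assert [h.bitscore for h in kept] == [100, 95]

    def test_fraction_zero_keeps_only_best_with_ties(self):
        hits = [hit(subj=s, bitscore=b) for s, b in [("a", 100), ("b", 100), ("c", 99)]]
        kept = filter_hits(hits, LcaParameters(0.0, 0, 1e9))
        assert {h.subject_id for h in kept} == {"a", "b"}

    def test_absolute_floors(self):
        hits = [hit(subj="a", bitscore=100, evalue=1e-3),
                hit(subj="b", bitscore=40, evalue=1e-30),
                hit(subj="c", bitscore=100, evalue=1e-30)]
        kept = filter_hits(hits, LcaParameters(1.0, 50, 1e-5))
        assert [h.subject_id for h in kept] == ["c"]

    def test_empty_input_is_empty_output(self):
        assert filter_hits([], self.P) == []

    def test_mixed_read_ids_rejected(self):
        with pytest.raises(ValueError):
            filter_hits([hit(read="r1"), hit(read="r2")], self.P)

    def test_matches_brute_force_scan(self):
        rng = random.Random(21)
        for _ in range(200):
            params = LcaParameters(rng.random(), rng.uniform(0, 80),
                                   rng.choice([1e-5, 1e-2, 1.0]))
            hits = [hit(subj=f"s{i}", bitscore=rng.uniform(0, 200),
                        evalue=rng.choice([0.0, 1e-10, 1e-4, 0.5]))
                    for i in range(rng.randint(0, 15))]
            ok = [h for h in hits
                  if h.bitscore >= params.min_bitscore and h.evalue <= params.max_evalue]
            best = max((h.bitscore for h in ok), default=0.0)
            expect = [h for h in ok
                      if h.bitscore >= (1 - params.top_score_fraction) * best]
            assert filter_hits(hits, params) == expect


class TestAssignLca:
    def test_two_species_same_genus_assigns_genus(self, small_tree):
        hits = [hit(subj="a", bitscore=100, taxid=562),
                hit(subj="b", bitscore=100, taxid=564)]
        (a,) = assign_lca(small_tree, hits, LcaParameters(0.1, 0, 1))
        assert a == ReadAssignment("r1", 561, "lca")

    def test_no_hits_unclassified(self, small_tree):
        assert assign_lca(small_tree, [], LcaParameters()) == []
        # all hits filtered out -> UNCLASSIFIED
        hits = [hit(bitscore=5, taxid=562)]
        (a,) = assign_lca(small_tree, hits, LcaParameters(0.1, 50, 1))
        assert not a.is_classified

    def test_strict_mode_propagates_unknown_taxid(self, small_tree):
        hits = [hit(taxid=99999)]
        with pytest.raises(UnknownTaxidError):
            assign_lca(small_tree, hits, LcaParameters(0.1, 0, 1), taxid_mode="strict")
        (a,) = assign_lca(small_tree, hits, LcaParameters(0.1, 0, 1), taxid_mode="lenient")
        assert not a.is_classified

    def test_output_is_ancestor_of_every_surviving_hit(self, small_tree):
        rng = random.Random(31)
        taxids = list(small_tree.nodes)
        for _ in range(100):
            hits = [hit(subj=f"s{i}", bitscore=rng.uniform(50, 150),
                        taxid=rng.choice(taxids))
                    for i in range(rng.randint(1, 8))]
            params = LcaParameters(rng.random(), 0, 1)
            (a,) = assign_lca(small_tree, hits, params)
            for h in filter_hits(hits, params):
                assert small_tree.is_ancestor(a.taxid, h.taxid)

    def test_composition_of_filter_and_lca_oracles(self):
        rng = random.Random(41)
        pyrng = random.Random(42)
        for _ in range(30):
            tree = random_tree(pyrng, 80)
            taxids = list(tree.nodes)
            params = LcaParameters(rng.random(), rng.uniform(0, 50), 1.0)
            hits = []
            for r in range(5):
                hits += [hit(read=f"r{r}", subj=f"s{i}", bitscore=rng.uniform(0, 150),
                             evalue=1e-9, taxid=pyrng.choice(taxids))
                         for i in range(rng.randint(0, 6))]
            got = {a.read_id: a.taxid for a in assign_lca(tree, hits, params)}
            for r in {h.read_id for h in hits}:
                kept = filter_hits([h for h in hits if h.read_id == r], params)
                if kept:
                    assert got[r] == brute_force_lca(tree, [h.taxid for h in kept])
                else:
                    assert got[r] == UNCLASSIFIED

    def test_raising_top_fraction_never_deepens_lca(self, small_tree):
        rng = random.Random(51)
        taxids = list(small_tree.nodes)
        for _ in range(50):
            hits = [hit(subj=f"s{i}", bitscore=rng.uniform(50, 150),
                        taxid=rng.choice(taxids))
                    for i in range(rng.randint(1, 8))]
            prev_depth = None
            for frac in (0.0, 0.25, 0.5, 1.0):
                (a,) = assign_lca(small_tree, hits, LcaParameters(frac, 0, 1))
                d = small_tree.depth(a.taxid)
                if prev_depth is not None:
                    assert d <= prev_depth
                prev_depth = d


class TestCombine:
    def test_primary_precedence(self):
        out = combine_assignments(
            [ReadAssignment("r1", 562, "kmer")],
            [ReadAssignment("r1", 1280, "lca")])
        assert out == [ReadAssignment("r1", 562, "combined")]

    def test_fallback_fills_unclassified(self):
        out = combine_assignments(
            [ReadAssignment("r2", UNCLASSIFIED, "kmer")],
            [ReadAssignment("r2", 1280, "lca")])
        assert out == [ReadAssignment("r2", 1280, "combined")]

    def test_union_of_universes_each_read_once(self):
        out = combine_assignments(
            [ReadAssignment("a", 1, "kmer"), ReadAssignment("b", UNCLASSIFIED, "kmer")],
            [ReadAssignment("b", 2, "lca"), ReadAssignment("c", 3, "lca")])
        assert {a.read_id: a.taxid for a in out} == {"a": 1, "b": 2, "c": 3}
        assert len(out) == 3

    def test_duplicate_read_in_one_stream_rejected(self):
        dup = [ReadAssignment("r1", 1, "kmer"), ReadAssignment("r1", 2, "kmer")]
        with pytest.raises(ValueError, match="duplicate"):
            combine_assignments(dup, [])

    def test_reserved_policy_not_silently_accepted(self):
        with pytest.raises(ValueError):
            combine_assignments([], [], policy="lca-merge")

    def test_classified_count_set_arithmetic(self):
        rng = random.Random(61)
        for _ in range(50):
            prim, sec = [], []
            for i in range(rng.randint(0, 40)):
                if rng.random() < 0.8:
                    prim.append(ReadAssignment(
                        f"r{i}", rng.choice([UNCLASSIFIED, rng.randint(1, 9)]), "kmer"))
                if rng.random() < 0.8:
                    sec.append(ReadAssignment(
                        f"r{i}", rng.choice([UNCLASSIFIED, rng.randint(1, 9)]), "lca"))
            out = combine_assignments(prim, sec)
            prim_classified = {a.read_id for a in prim if a.is_classified}
            prim_ids = {a.read_id for a in prim}
            sec_classified = {a.read_id for a in sec if a.is_classified}
            expect = len(prim_classified) + \
                len(sec_classified - prim_ids | (sec_classified & (prim_ids - prim_classified)))
            assert sum(a.is_classified for a in out) == expect
            # monotone sensitivity: primary calls survive untouched
            combined = {a.read_id: a.taxid for a in out}
            for a in prim:
                if a.is_classified:
                    assert combined[a.read_id] == a.taxid
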