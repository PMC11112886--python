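import numpy as np
import pytest

import superbarcode as sb
from superbarcode.io_model import SampleRecord
from superbarcode.treedisc import bipartitions

from conftest import make_aln


def tree(nwk: str) -> sb.SupportTree:
    return sb.SupportTree.from_newick(nwk)


def has_split(t: sb.SupportTree, side) -> bool:
    """Split present, whichever side the canonical encoding stored."""
    leaves = frozenset(t.leaf_labels())
    bp = bipartitions(t)
    fs = frozenset(side)
    return fs in bp or (leaves - fs) in bp


def recs(pairs):
    """pairs: list of (sample_id, species[, section[, provenance]])."""
    out = []
    for p in pairs:
        out.append(SampleRecord(*p))
    return out


class TestCollapse:
    def test_full_support_unchanged(self):
        t = tree("((a:1,b:1)100:1,(c:1,d:1)100:1,e:1);")
        c = sb.collapse_low_support(t, 50)
        assert bipartitions(c) == bipartitions(t)

    def test_total_collapse_to_star(self):
        t = tree("((a:1,b:1)10:1,((c:1,d:1)20:1,e:1)30:1,f:1);")
        c = sb.collapse_low_support(t, 50)
        assert bipartitions(c) == {}

    def test_exactly_one_edge_contracted(self):
        t = tree("(((a:1,b:1)90:1,(c:1,d:1)40:1)90:1,e:1,f:1);")
        c = sb.collapse_low_support(t, 50)
        before, after = bipartitions(t), bipartitions(c)
        assert len(before) - len(after) == 1
        assert has_split(t, {"c", "d"}) and not has_split(c, {"c", "d"})

    def test_threshold_is_strict_below(self):
        t = tree("((a:1,b:1)50:1,(c:1,d:1)49:1,e:1);")
        c = sb.collapse_low_support(t, 50)
        assert has_split(c, {"a", "b"})
        assert not has_split(c, {"c", "d"})

    def test_missing_support_collapsed_with_warning(self):
        t = tree("((a:1,b:1):1,(c:1,d:1)90:1,e:1);")
        with pytest.warns(UserWarning):
            c = sb.collapse_low_support(t, 50)
        assert not has_split(c, {"a", "b"})
        assert has_split(c, {"c", "d"})


class TestMonophyly:
    SAMPLES = recs(
        [("a1", "A"), ("a2", "A"), ("b1", "B"), ("b2", "B")]
    )

    def test_both_monophyletic_with_supports(self):
        t = tree("((a1:1,a2:1)90:1,(b1:1,b2:1)80:1);")
        v = {x.species: x for x in sb.monophyly_test(t, self.SAMPLES)}
        assert v["A"].monophyletic and v["A"].support == 90
        assert v["B"].monophyletic and v["B"].support == 80

    def test_interleaved_fail(self):
        t = tree("((a1:1,b1:1)95:1,(a2:1,b2:1)95:1);")
        v = {x.species: x for x in sb.monophyly_test(t, self.SAMPLES)}
        assert not v["A"].monophyletic and not v["B"].monophyletic
        assert v["A"].support is None

    def test_low_support_clade_fails_after_collapse(self):
        t = tree("((a1:1,a2:1)40:1,(b1:1,b2:1)80:1,c1:1);")
        samples = self.SAMPLES + [SampleRecord("c1", "C")]
        v = {x.species: x for x in sb.monophyly_test(t, samples)}
        assert not v["A"].monophyletic
        assert v["B"].monophyletic

    def test_collapse_then_test_commutes(self, rng):
        # random supported trees: verdicts after explicit collapse match
        for seed in range(5):
            st = sb.simulate_species_tree(6, seed)
            nwk = st.to_newick()
            t = tree(nwk)
            # attach random supports to internal edges
            r = np.random.default_rng(seed)
            for nd in t.tree.preorder_node_iter():
                if nd.parent_node is not None and not nd.is_leaf():
                    nd.support = float(r.integers(0, 101))
            leaves = t.leaf_labels()
            samples = [SampleRecord(lf, lf[:3]) for lf in leaves]
            # every leaf is its own species here; instead pair them up
            samples = [
                SampleRecord(lf, f"S{i // 2}") for i, lf in enumerate(sorted(leaves))
            ]
            v1 = sb.monophyly_test(t, samples, collapse=True)
            pre = sb.collapse_low_support(t, 50)
            v2 = sb.monophyly_test(pre, samples, collapse=False)
            assert [(x.species, x.monophyletic) for x in v1] == [
                (x.species, x.monophyletic) for x in v2
            ]

    def test_rerooting_invariance_with_outgroup(self):
        samples = self.SAMPLES
        a = tree("(((a1:1,a2:1)90:1,(b1:1,b2:1)80:1)70:1,og:5);")
        b = tree("((b1:1,b2:1)80:1,(a1:1,a2:1)90:1,og:5);")
        va = sb.monophyly_test(a, samples, outgroup=["og"])
        vb = sb.monophyly_test(b, samples, outgroup=["og"])
        assert [(x.species, x.monophyletic, x.support) for x in va] == [
            (x.species, x.monophyletic, x.support) for x in vb
        ]

    def test_missing_sample_named(self):
        t = tree("((a1:1,a2:1)90:1,(b1:1,x9:1)80:1);")
        with pytest.raises(sb.TreeError, match="b2"):
            sb.monophyly_test(t, self.SAMPLES)

    def test_singletons_not_evaluated(self):
        t = tree("((a1:1,a2:1)90:1,(b1:1,b2:1)80:1,c1:1);")
        samples = self.SAMPLES + [SampleRecord("c1", "C")]
        assert {x.species for x in sb.monophyly_test(t, samples)} == {"A", "B"}


class TestResolutionAndComparison:
    def _verdicts(self, flags, supports=None):
        supports = supports or [100] * len(flags)
        return [
            sb.MonophylyVerdict(f"sp{i}", f, float(s) if f else None, 2)
            for i, (f, s) in enumerate(zip(flags, supports))
        ]

    def test_resolution_rounding(self):
        assert sb.resolution(self._verdicts([True] * 13 + [False] * 8)) == 61.90
        assert sb.resolution(self._verdicts([False] * 5)) == 0.0
        with pytest.raises(sb.TreeError):
            sb.resolution([])

    def test_compare_identical_empty(self):
        v = self._verdicts([True, False, True])
        gained, lost, shift = sb.compare_datasets(v, v)
        assert gained == [] and lost == []
        assert len(shift) == 2

    def test_compare_matches_set_difference_oracle(self, rng):
        for _ in range(10):
            fa = rng.random(12) < 0.6
            fb = rng.random(12) < 0.6
            va, vb = self._verdicts(list(fa)), self._verdicts(list(fb))
            gained, lost, _ = sb.compare_datasets(va, vb)
            assert set(gained) == {f"sp{i}" for i in range(12) if fa[i] and not fb[i]}
            assert set(lost) == {f"sp{i}" for i in range(12) if fb[i] and not fa[i]}

    def test_universe_mismatch_errors(self):
        with pytest.raises(sb.TreeError):
            sb.compare_datasets(self._verdicts([True]), self._verdicts([True, False]))

    def test_support_summary_bins(self):
        v = self._verdicts(
            [True] * 6 + [False], [100, 100, 95, 85, 64, 30, 100]
        )
        hist, sups = sb.support_summary(v)
        assert hist == {"=100": 2, "[90,100)": 1, "[65,90)": 1, "<65": 2}
        assert sups == [100, 100, 95, 85, 64, 30]

    def test_support_summary_empty(self):
        hist, sups = sb.support_summary(self._verdicts([False, False]))
        assert sum(hist.values()) == 0 and sups == []


class TestRepresentatives:
    def test_own_sample_preferred(self):
        t = tree("((a1:1,a2:1,a3:1)90:1,(b1:1,c1:1)80:1);")
        samples = recs(
            [
                ("a1", "A", "s1", "downloaded"),
                ("a2", "A", "s1", "own"),
                ("a3", "A", "s1", "downloaded"),
                ("b1", "B", "s2", "own"),
                ("c1", "C", "s2", "own"),
            ]
        )
        chosen = sb.select_representatives(t, samples)
        assert chosen["A"] == "a2"  # rule 2: own provenance wins

    def test_singleton_kept(self):
        t = tree("((a1:1,a2:1)90:1,b1:1,c1:1);")
        samples = recs([("a1", "A"), ("a2", "A"), ("b1", "B"), ("c1", "C")])
        chosen = sb.select_representatives(t, samples)
        assert chosen["B"] == "b1" and chosen["C"] == "c1"

    def test_planted_stray_individual_excluded(self):
        # species P has p1 inside its section clade and p2 stray in the other
        t = tree(
            "(((p1:1,q1:1)90:1,q2:1)90:1,((p2:1,r1:1)90:1,r2:1)90:1);"
        )
        samples = recs(
            [
                ("p1", "P", "s1", "downloaded"),
                ("p2", "P", "s1", "own"),  # own but a stray from section s1
                ("q1", "Q", "s1", "own"),
                ("q2", "Q", "s1", "own"),
                ("r1", "R", "s2", "own"),
                ("r2", "R", "s2", "own"),
            ]
        )
        chosen = sb.select_representatives(t, samples)
        # rule 3 (stray exclusion) precedes rule 2 (own provenance)
        assert chosen["P"] == "p1"

    def test_all_stray_species_flagged(self):
        t = tree("((q1:1,q2:1)90:1,((p1:1,r1:1)90:1,(p2:1,r2:1)90:1)90:1);")
        samples = recs(
            [
                ("p1", "P", "s1", "own"),
                ("p2", "P", "s1", "own"),
                ("q1", "Q", "s1", "own"),
                ("q2", "Q", "s1", "own"),
                ("r1", "R", "s2", "own"),
                ("r2", "R", "s2", "own"),
            ]
        )
        with pytest.warns(UserWarning, match="stray"):
            chosen = sb.select_representatives(t, samples)
        assert chosen["P"] == "p1"  # first by id retained


class TestCompareTrees:
    def test_identical_trees(self):
        a = tree("((a:1,b:1)90:1,(c:1,d:1)90:1,e:1);")
        b = tree("((a:1,b:1)95:1,(c:1,d:1)85:1,e:1);")
        cmp = sb.compare_trees(a, b)
        assert cmp.rf_distance == 0
        assert cmp.conflicting_bipartitions == []
        assert cmp.shared_bipartitions == 2

    def test_swapped_cherries_rf2(self):
        a = tree("((a:1,b:1)90:1,(c:1,d:1)90:1);")
        b = tree("((a:1,c:1)90:1,(b:1,d:1)90:1);")
        cmp = sb.compare_trees(a, b)
        assert cmp.rf_distance == 2

    def test_rf_agrees_with_dendropy(self, rng):
        import dendropy
        from dendropy.calculate import treecompare

        for seed in range(5):
            ta = sb.simulate_species_tree(12, seed)
            tb = sb.simulate_species_tree(12, seed + 100)
            for t in (ta, tb):
                for nd in t.tree:
                    if not nd.is_leaf() and nd.parent_node is not None:
                        nd.support = 100.0
            cmp = sb.compare_trees(ta, tb)
            ns = dendropy.TaxonNamespace()
            da = dendropy.Tree.get(
                data=ta.to_newick(), schema="newick", taxon_namespace=ns
            )
            db = dendropy.Tree.get(
                data=tb.to_newick(), schema="newick", taxon_namespace=ns
            )
            da.encode_bipartitions()
            db.encode_bipartitions()
            expect = treecompare.symmetric_difference(da, db, is_bipartitions_updated=True)
            assert cmp.rf_distance == expect

    def test_planted_nni_conflict_detected(self):
        # one NNI move around the (c,d)|rest edge; all supports strong
        a = tree("(((a:1,b:1)95:1,c:1)90:1,(d:1,e:1)88:1,f:1);")
        b = tree("(((a:1,c:1)97:1,b:1)91:1,(d:1,e:1)89:1,f:1);")
        cmp = sb.compare_trees(a, b)
        clades = {c for c, _, _ in cmp.conflicting_bipartitions}
        assert ("a", "b") in clades
        # the (d,e) clade is shared, never conflicting
        assert all("d" not in c or "e" in c for c in clades)

    def test_species_level_excludes_non_monophyletic_group(self):
        a = tree("((a1:1,a2:1)90:1,(b1:1,b2:1)90:1,(c1:1,c2:1)90:1,(d1:1,d2:1)90:1);")
        b = tree("((a1:1,b1:1)90:1,(a2:1,b2:1)90:1,(c1:1,c2:1)90:1,(d1:1,d2:1)90:1);")
        samples = recs(
            [(f"{s}{i}", s.upper()) for s in "abcd" for i in (1, 2)]
        )
        with pytest.raises(sb.TreeError):
            # A and B are non-monophyletic in tree b -> only C, D survive (< 4)
            sb.compare_trees(a, b, at="species", samples=samples)

    def test_too_few_shared_leaves_errors(self):
        a = tree("((a:1,b:1)90:1,c:1);")
        b = tree("((a:1,b:1)90:1,c:1);")
        with pytest.raises(sb.TreeError):
            sb.compare_trees(a, b)
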