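"""NJ/UPGMA construction, calibration, and monophyly classification."""

import dendropy
import numpy as np
import pytest

from barcode_audit.errors import DataError
from barcode_audit.distances import DistanceMatrix
from barcode_audit.trees import (
    nj_tree, upgma_tree, calibrate_tree, classify_monophyly, is_ultrametric,
    node_ages, leaf_depths, monophyly_counts,
)


def dm(ids, d):
    d = np.asarray(d, dtype=float)
    return DistanceMatrix(ids=list(ids), d=d, overlap=np.full(d.shape, 658))


def patristic(tree):
    """Leaf-to-leaf path length matrix as a dict of frozensets."""
    pdm = tree.phylogenetic_distance_matrix()
    out = {}
    taxa = list(tree.taxon_namespace)
    for i, t1 in enumerate(taxa):
        for t2 in taxa[i + 1 :]:
            out[frozenset((t1.label, t2.label))] = pdm.patristic_distance(t1, t2)
    return out


def random_additive_matrix(n, rng):
    """Random binary tree with random branch lengths -> additive matrix."""
    taxa = [f"t{i}" for i in range(n)]
    ns = dendropy.TaxonNamespace(taxa)
    items = [dendropy.Node(taxon=ns.get_taxon(t)) for t in taxa]
    while len(items) > 1:
        i, j = sorted(rng.choice(len(items), size=2, replace=False))
        a, b = items[i], items[j]
        parent = dendropy.Node()
        parent.add_child(a)
        parent.add_child(b)
        a.edge.length = float(rng.uniform(0.01, 0.2))
        b.edge.length = float(rng.uniform(0.01, 0.2))
        items = [items[k] for k in range(len(items)) if k not in (i, j)] + [parent]
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.seed_node = items[0]
    tree.is_rooted = True
    pdm = tree.phylogenetic_distance_matrix()
    d = np.zeros((n, n))
    for i, a in enumerate(ns):
        for j, b in enumerate(ns):
            if i != j:
                d[i, j] = pdm.patristic_distance(a, b)
    return taxa, d, tree


class TestNJ:
    def test_three_taxon_closed_form(self):
        # la = (dab + dac - dbc)/2 etc.; patristic distances must round-trip
        d = [[0, 0.10, 0.16], [0.10, 0, 0.14], [0.16, 0.14, 0]]
        tree = nj_tree(dm("abc", d))
        p = patristic(tree)
        assert p[frozenset("ab")] == pytest.approx(0.10, abs=1e-12)
        assert p[frozenset("ac")] == pytest.approx(0.16, abs=1e-12)
        assert p[frozenset("bc")] == pytest.approx(0.14, abs=1e-12)

    def test_recovers_additive_four_taxon_tree(self, rng):
        ids, d, true_tree = random_additive_matrix(4, rng)
        tree = nj_tree(dm(ids, d))
        p = patristic(tree)
        for i in range(4):
            for j in range(i + 1, 4):
                assert p[frozenset((ids[i], ids[j]))] == pytest.approx(
                    d[i, j], abs=1e-9
                )

    def test_agrees_with_scikit_bio_on_additive_matrix(self, rng):
        skbio = pytest.importorskip("skbio")
        ids, d, _ = random_additive_matrix(8, rng)
        ours = patristic(nj_tree(dm(ids, d)))
        theirs_tree = skbio.tree.nj(skbio.DistanceMatrix(d, ids))
        for i in range(8):
            for j in range(i + 1, 8):
                theirs = theirs_tree.find(ids[i]).distance(theirs_tree.find(ids[j]))
                assert ours[frozenset((ids[i], ids[j]))] == pytest.approx(
                    theirs, abs=1e-9
                )

    def test_requires_three_taxa_and_complete_matrix(self):
        with pytest.raises(DataError):
            nj_tree(dm("ab", [[0, 1], [1, 0]]))
        bad = np.array([[0, np.nan, 1.0], [np.nan, 0, 1.0], [1.0, 1.0, 0]])
        with pytest.raises(DataError):
            nj_tree(DistanceMatrix(ids=list("abc"), d=bad, overlap=np.zeros((3, 3))))


class TestUPGMA:
    def test_two_taxa_heights(self):
        tree = upgma_tree(dm("ab", [[0, 0.02], [0.02, 0]]))
        assert leaf_depths(tree) == pytest.approx({"a": 0.01, "b": 0.01})

    def test_ultrametric_round_trip(self):
        # ultrametric input: cophenetic distances must be reproduced exactly
        d = [
            [0, 0.02, 0.10, 0.10],
            [0.02, 0, 0.10, 0.10],
            [0.10, 0.10, 0, 0.06],
            [0.10, 0.10, 0.06, 0],
        ]
        tree = upgma_tree(dm("abcd", d))
        p = patristic(tree)
        for i, a in enumerate("abcd"):
            for j, b in enumerate("abcd"):
                if i < j:
                    assert p[frozenset((a, b))] == pytest.approx(d[i][j], abs=1e-12)

    def test_output_always_ultrametric(self, rng):
        for _ in range(5):
            n = 8
            x = rng.uniform(0.01, 0.2, size=(n, n))
            d = (x + x.T) / 2
            np.fill_diagonal(d, 0)
            tree = upgma_tree(dm([f"t{i}" for i in range(n)], d))
            assert is_ultrametric(tree)


class TestCalibration:
    def _tree(self, height):
        d = 2 * height
        return upgma_tree(dm("ab", [[0, d], [d, 0]]))

    def test_pairwise_rate_arithmetic(self):
        # per-lineage height 0.0075 at 1.5%/Myr pairwise -> age 1 Myr
        cal = calibrate_tree(self._tree(0.0075), pairwise_rate=0.015)
        ages = node_ages(cal)
        assert max(ages.values()) == pytest.approx(1.0, abs=1e-12)

    def test_zero_height_zero_age(self):
        cal = calibrate_tree(self._tree(0.0))
        assert max(node_ages(cal).values()) == pytest.approx(0.0, abs=1e-12)

    def test_doubling_rate_halves_ages(self):
        a1 = max(node_ages(calibrate_tree(self._tree(0.03), pairwise_rate=0.015)).values())
        a2 = max(node_ages(calibrate_tree(self._tree(0.03), pairwise_rate=0.030)).values())
        assert a1 == pytest.approx(2 * a2, rel=1e-12)

    def test_non_ultrametric_rejected(self):
        tree = dendropy.Tree.get(data="(a:1,(b:1,c:3):1);", schema="newick")
        with pytest.raises(DataError):
            calibrate_tree(tree)


def _labeled_tree(newick):
    return dendropy.Tree.get(data=newick, schema="newick")


class TestMonophyly:
    def _labels(self, tree):
        return {
            leaf.taxon.label: leaf.taxon.label.rstrip("0123456789")
            for leaf in tree.leaf_node_iter()
        }

    def test_two_clean_clades(self):
        t = _labeled_tree("((a1:1,a2:1):1,(b1:1,b2:1):1);")
        calls = {c.species: c.status for c in classify_monophyly(t, self._labels(t))}
        assert calls == {"a": "monophyletic", "b": "monophyletic"}

    def test_paraphyly_single_intruder_clade(self):
        t = _labeled_tree("(a1:3,(a2:2,(a3:1,b1:1):1):1);")
        calls = {c.species: c for c in classify_monophyly(t, self._labels(t))}
        assert calls["a"].status == "paraphyletic"
        assert calls["a"].intruder_species == ["b"]

    def test_polyphyly_interleaved(self):
        t = _labeled_tree("((a1:1,b1:1):1,(a2:1,b2:1):1);")
        calls = {c.species: c.status for c in classify_monophyly(t, self._labels(t))}
        assert calls == {"a": "polyphyletic", "b": "polyphyletic"}

    def test_singletons_undefined(self):
        t = _labeled_tree("((a1:1,a2:1):1,b1:2);")
        calls = {c.species: c.status for c in classify_monophyly(t, self._labels(t))}
        assert calls["b"] == "undefined"

    def test_status_counts_partition_species(self):
        t = _labeled_tree("((a1:1,b1:1):1,((a2:1,b2:1):1,(c1:1,c2:1):1):1);")
        calls = classify_monophyly(t, self._labels(t))
        counts = monophyly_counts(calls)
        n_multi = 3  # a, b, c all have >= 2 members
        assert (
            counts["monophyletic"] + counts["paraphyletic"] + counts["polyphyletic"]
            == n_multi
        )

    def test_shared_barcode_with_intruder_flag(self):
        t = _labeled_tree("(a1:3,(a2:2,(a3:1,b1:1):1):1);")
        seqs = {"a1": "A" * 658, "a2": "A" * 658, "a3": "G" + "A" * 657, "b1": "G" + "A" * 657}
        calls = {c.species: c for c in classify_monophyly(t, self._labels(t), sequences=seqs)}
        assert calls["a"].shares_barcode_with_intruder is True

    def test_matches_mrca_oracle_on_random_trees(self, rng):
        """Exhaustive-clade oracle agreement on random labeled trees."""
        from barcode_audit.synthetic import _coalescent_subtree

        for _ in range(20):
            ns = dendropy.TaxonNamespace()
            root, _ = _coalescent_subtree("x", 12, 1.0, np.inf, ns, rng)
            tree = dendropy.Tree(taxon_namespace=ns)
            tree.seed_node = root
            tree.is_rooted = True
            labels = {
                leaf.taxon.label: f"sp{int(rng.integers(3))}"
                for leaf in tree.leaf_node_iter()
            }
            calls = {c.species: c for c in classify_monophyly(tree, labels)}
            tree.encode_bipartitions()
            for sp in set(labels.values()):
                members = [l for l, s in labels.items() if s == sp]
                if len(members) < 2:
                    assert calls[sp].status == "undefined"
                    continue
                mrca = tree.mrca(taxa=[ns.get_taxon(m) for m in members])
                under = {leaf.taxon.label for leaf in mrca.leaf_iter()}
                intruders = under - set(members)
                if not intruders:
                    expected = "monophyletic"
                else:
                    intruder_taxa = [ns.get_taxon(x) for x in intruders]
                    sub_mrca = tree.mrca(taxa=intruder_taxa)
                    sub_leaves = {leaf.taxon.label for leaf in sub_mrca.leaf_iter()}
                    expected = (
                        "paraphyletic" if sub_leaves == intruders else "polyphyletic"
                    )
                assert calls[sp].status == expected, sp
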