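"""Newick handling, monophyly assessment, curation suggestions, neighbor joining."""

import io
import itertools

import dendropy
import numpy as np
import pytest

from barcodecurator.distances import DistanceMatrix, distance_matrix
from barcodecurator.monophyly import (
    NewickParseError,
    assess_monophyly,
    intruder_report,
    map_tips_to_taxa,
    minimal_removal_set,
    nj_tree,
    parse_newick,
)

from conftest import make_records


def taxa_by_first_letter(tree):
    return {leaf.taxon.label: leaf.taxon.label[0]
            for leaf in tree.leaf_node_iter()}


def unrooted_splits(tree):
    """Non-trivial bipartitions as canonical frozensets of tip labels."""
    leaves = sorted(l.taxon.label for l in tree.leaf_node_iter())
    ref, full = leaves[0], frozenset(leaves)
    out = set()
    for node in tree.preorder_internal_node_iter():
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        if len(below) < 2 or len(below) > len(leaves) - 2:
            continue
        out.add(below if ref not in below else full - below)
    return out


def patristic(tree):
    """Tip-to-tip path length matrix as a dict of frozenset pairs."""
    pdm = tree.phylogenetic_distance_matrix()
    out = {}
    taxa = list(tree.taxon_namespace)
    for t1, t2 in itertools.combinations(taxa, 2):
        out[frozenset((t1.label, t2.label))] = pdm.distance(t1, t2)
    return out


class TestParseNewick:
    def test_tips_and_internals_counted(self):
        tree = parse_newick("((a,b),(c,d));")
        assert len(tree.leaf_nodes()) == 4
        assert sum(1 for _ in tree.preorder_internal_node_iter()) == 3

    def test_branch_lengths_and_support_retained(self):
        tree = parse_newick("((a:1,b:2)90:0.5,c:3);")
        lengths = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
        assert lengths == {"a": 1.0, "b": 2.0, "c": 3.0}
        internal = [n for n in tree.preorder_internal_node_iter()
                    if n.parent_node is not None]
        assert internal[0].label == "90"

    def test_unterminated_input_is_an_error(self):
        with pytest.raises(NewickParseError):
            parse_newick("(a,b")

    def test_duplicate_tips_rejected(self):
        with pytest.raises(NewickParseError, match="duplicate"):
            parse_newick("((a,a),b);")

    def test_underscores_preserved(self):
        tree = parse_newick("(ABC123.Genus_species,x);")
        labels = {l.taxon.label for l in tree.leaf_node_iter()}
        assert "ABC123.Genus_species" in labels


class TestMapTips:
    def test_composite_label_split_on_first_dot(self):
        tree = parse_newick("(ABC123.Genus_species,DEF456.Other_taxon);")
        mapping, unresolved = map_tips_to_taxa(tree)
        assert mapping["ABC123.Genus_species"] == "Genus_species"
        assert unresolved == []

    def test_metadata_wins_over_label_parsing(self):
        tree = parse_newick("(ABC123.Wrong_name,x1);")
        mapping, _ = map_tips_to_taxa(
            tree, metadata={"ABC123": "Right name", "x1": "X x"})
        assert mapping["ABC123.Wrong_name"] == "Right name"
        assert mapping["x1"] == "X x"

    def test_unparseable_label_reported(self):
        tree = parse_newick("(plainlabel,A.b);")
        mapping, unresolved = map_tips_to_taxa(tree)
        assert unresolved == ["plainlabel"]
        assert "plainlabel" not in mapping


class TestAssessMonophyly:
    def test_clean_cherries_are_monophyletic(self):
        tree = parse_newick("((a1,a2),(b1,b2));")
        res = assess_monophyly(tree, taxa_by_first_letter(tree))
        assert res["a"].status == res["b"].status == "monophyletic"

    def test_interleaved_clades_both_non_monophyletic(self):
        tree = parse_newick("((a1,b1),(a2,b2));")
        res = assess_monophyly(tree, taxa_by_first_letter(tree))
        assert res["a"].status == res["b"].status == "non_monophyletic"
        assert res["a"].intruders == ["b1", "b2"]

    def test_nested_clade(self):
        tree = parse_newick("((a1,(b1,b2)),a2);")
        res = assess_monophyly(tree, taxa_by_first_letter(tree))
        assert res["b"].status == "monophyletic"
        assert res["a"].status == "non_monophyletic"
        assert res["a"].intruders == ["b1", "b2"]

    def test_singleton_and_absent(self):
        tree = parse_newick("((a1,a2),c1);")
        mapping = taxa_by_first_letter(tree)
        res = assess_monophyly(tree, mapping, taxa=["a", "c", "z"])
        assert res["c"].status == "singleton"
        assert res["z"].status == "absent"
        assert res["c"].intruders == [] and res["z"].n_tips == 0

    def test_child_order_permutation_invariance(self):
        variants = [
            "((a1,b1),(a2,b2));",
            "((b1,a1),(b2,a2));",
            "((a2,b2),(a1,b1));",
        ]
        statuses = []
        for nwk in variants:
            tree = parse_newick(nwk)
            res = assess_monophyly(tree, taxa_by_first_letter(tree))
            statuses.append({t: r.status for t, r in res.items()})
        assert statuses[0] == statuses[1] == statuses[2]

    def test_agrees_with_biopython_oracle_on_random_trees(self):
        """Independent check against Bio.Phylo's monophyly test."""
        from Bio import Phylo

        rng = np.random.default_rng(5)
        for _ in range(20):
            labels = [f"{chr(97 + i % 4)}{i}" for i in range(10)]
            rng.shuffle(labels)
            # random rooted binary tree by sequential joining
            nodes = [l for l in labels]
            while len(nodes) > 1:
                i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
                merged = f"({nodes[i]},{nodes[j]})"
                nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
                nodes.append(merged)
            nwk = nodes[0] + ";"
            tree = parse_newick(nwk)
            mapping = taxa_by_first_letter(tree)
            res = assess_monophyly(tree, mapping)
            ref = Phylo.read(io.StringIO(nwk), "newick")
            for taxon in set(mapping.values()):
                terms = [t for t in ref.get_terminals()
                         if mapping[t.name] == taxon]
                if len(terms) < 2:
                    continue
                expected = ("monophyletic" if ref.is_monophyletic(terms)
                            else "non_monophyletic")
                assert res[taxon].status == expected, (nwk, taxon)


class TestCurationSuggestions:
    def test_single_intruder_suggested(self):
        tree = parse_newick("((a1,a2,b1),(b2,b3));")
        mapping = taxa_by_first_letter(tree)
        res = assess_monophyly(tree, mapping)
        assert res["a"].intruders == ["b1"]
        assert minimal_removal_set(tree, mapping, "a") == ["b1"]

    def test_removal_restores_monophyly_second_round(self):
        tree = parse_newick("(((a1,b1),a2),(b2,b3));")
        mapping = taxa_by_first_letter(tree)
        for taxon in ("a", "b"):
            removals = minimal_removal_set(tree, mapping, taxon)
            res = assess_monophyly(tree, mapping, [taxon],
                                   exclude_tips=removals)
            assert res[taxon].status in ("monophyletic", "singleton")

    def test_removal_set_is_minimal_exhaustive_oracle(self):
        """On random small trees the suggested set has the same size as the
        exhaustive minimum over all tip subsets."""
        import itertools as it

        rng = np.random.default_rng(13)
        for _ in range(15):
            labels = [f"{chr(97 + i % 3)}{i}" for i in range(7)]
            rng.shuffle(labels)
            nodes = list(labels)
            while len(nodes) > 1:
                i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
                merged = f"({nodes[i]},{nodes[j]})"
                nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
                nodes.append(merged)
            tree = parse_newick(nodes[0] + ";")
            mapping = taxa_by_first_letter(tree)
            res = assess_monophyly(tree, mapping)
            for taxon, r in res.items():
                if r.status != "non_monophyletic":
                    continue
                suggested = minimal_removal_set(tree, mapping, taxon)
                # exhaustive: smallest subset whose exclusion restores the taxon
                best = None
                for k in range(len(labels)):
                    for combo in it.combinations(labels, k):
                        trial = assess_monophyly(
                            tree, mapping, [taxon], exclude_tips=combo)[taxon]
                        if trial.status != "non_monophyletic":
                            best = k
                            break
                    if best is not None:
                        break
                assert len(suggested) == best, (nodes[0], taxon)
                after = assess_monophyly(tree, mapping, [taxon],
                                         exclude_tips=suggested)[taxon]
                assert after.status != "non_monophyletic"

    def test_report_lists_non_monophyletic_taxa_only(self):
        # b1 strays into the (a1,a2) clade: a gains an intruder, b loses
        # monophyly, and removing b1 repairs both
        tree = parse_newick("((a1,a2,b1),(b2,b3));")
        mapping = taxa_by_first_letter(tree)
        res = assess_monophyly(tree, mapping)
        report = intruder_report(tree, mapping, res)
        assert list(report["taxon"]) == ["a", "b"]
        assert set(report["suggested_removals"]) == {"b1"}

    def test_monophyletic_taxa_have_no_report_row(self):
        tree = parse_newick("((a1,a2),(b1,b2),c1);")
        mapping = taxa_by_first_letter(tree)
        res = assess_monophyly(tree, mapping)
        assert intruder_report(tree, mapping, res).empty


class TestNeighborJoining:
    def _tree_matrix(self, rng, n):
        """Random additive matrix via a random tree with known patristic distances."""
        labels = [f"t{i}" for i in range(n)]
        newick_nodes = list(labels)
        lengths = {}
        while len(newick_nodes) > 1:
            i, j = sorted(rng.choice(len(newick_nodes), size=2, replace=False))
            li, lj = rng.uniform(0.5, 3.0, size=2).round(3)
            merged = f"({newick_nodes[i]}:{li},{newick_nodes[j]}:{lj})"
            newick_nodes = [x for k, x in enumerate(newick_nodes)
                            if k not in (i, j)]
            newick_nodes.append(merged)
        tree = parse_newick(newick_nodes[0] + ";")
        dist = patristic(tree)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = dist[frozenset((labels[i], labels[j]))]
        return tree, DistanceMatrix(labels, d, np.full((n, n), 1, dtype=np.int64))

    @pytest.mark.parametrize("n", [4, 5, 6, 7, 8])
    def test_exact_on_additive_matrices(self, n):
        rng = np.random.default_rng(100 + n)
        true_tree, dm = self._tree_matrix(rng, n)
        est = nj_tree(dm)
        assert unrooted_splits(est) == unrooted_splits(true_tree)
        est_d = patristic(est)
        for pair, value in patristic(true_tree).items():
            assert est_d[pair] == pytest.approx(value, abs=1e-9)

    def test_topology_matches_skbio_oracle(self):
        skbio = pytest.importorskip("skbio")
        from skbio.tree import nj as sk_nj

        rng = np.random.default_rng(77)
        rs = make_records(*[
            (f"t{i}", f"Sp {i}", "".join(rng.choice(list("ACGT"), size=120)))
            for i in range(12)
        ])
        dm = distance_matrix(rs)
        mine = nj_tree(dm)
        ref = sk_nj(skbio.DistanceMatrix(dm.d, ids=dm.ids))
        ref_tree = parse_newick(str(ref))
        assert unrooted_splits(mine) == unrooted_splits(ref_tree)

    def test_deterministic_on_ties(self):
        d = np.ones((4, 4)) - np.eye(4)
        dm = DistanceMatrix(["a", "b", "c", "d"], d,
                            np.full((4, 4), 10, dtype=np.int64))
        t1 = nj_tree(dm).as_string(schema="newick")
        t2 = nj_tree(dm).as_string(schema="newick")
        assert t1 == t2

    def test_incomparable_pairs_rejected(self):
        d = np.zeros((3, 3))
        d[0, 1] = d[1, 0] = np.nan
        dm = DistanceMatrix(["a", "b", "c"], d, np.zeros((3, 3), dtype=np.int64))
        with pytest.raises(ValueError, match="incomparable"):
            nj_tree(dm)

    def test_too_few_records_rejected(self):
        d = np.zeros((2, 2))
        dm = DistanceMatrix(["a", "b"], d, np.ones((2, 2), dtype=np.int64))
        with pytest.raises(ValueError):
            nj_tree(dm)
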