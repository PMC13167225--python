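"""Tree-based species monophyly assessment and curation support.

Given a rooted tree whose tips are specimen records, a taxon is
*monophyletic* when the most recent common ancestor (MRCA) of its tips has
no descendant tip belonging to another taxon. Taxa with one tip are
*singletons* (monophyly unassessable) and taxa absent from the tree are
*absent*. Trees are assessed rooted-as-read; an optional midpoint-rooting
helper is provided, with the caveat that status can differ between rootings.

Non-monophyly cases feed a curation loop: :func:`intruder_report` lists the
foreign tips inside each taxon's smallest containing clade and suggests a
minimal removal set. Suggestions are advisory — removal happens only
through the user-supplied exclusion list in
:func:`barcodecurator.filters.apply_exclusion_list`, after which a second
assessment round confirms (or not) that non-monophyly was operational.

Trees normally come from external maximum-likelihood inference; for
self-contained synthetic analyses :func:`nj_tree` builds a neighbor-joining
tree from a distance matrix with a deterministic lowest-index tie-break.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
import numpy as np
import pandas as pd

from .distances import DistanceMatrix

__all__ = [
    "MonophylyResult",
    "NewickParseError",
    "parse_newick",
    "write_newick",
    "midpoint_root",
    "map_tips_to_taxa",
    "assess_monophyly",
    "minimal_removal_set",
    "intruder_report",
    "nj_tree",
    "read_taxa_list",
    "write_monophyly_report",
]


class NewickParseError(ValueError):
    """Malformed newick input (position reported when available)."""


def parse_newick(text: str) -> dendropy.Tree:
    """Parse a newick string into a rooted dendropy tree.

    Labels are preserved verbatim (underscores are not unquoted to spaces,
    so composite ``ProcessID.Taxon_name`` labels survive). Duplicate tip
    labels and unbalanced input raise :class:`NewickParseError`.
    """
    if ";" not in text:
        raise NewickParseError("unterminated newick: missing ';' at end of input")
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several DataError subclasses
        raise NewickParseError(f"newick parse error: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dup = {l for l in labels if labels.count(l) > 1}
    if dup:
        raise NewickParseError(f"duplicate tip labels: {sorted(dup)}")
    tree.is_rooted = True  # assessed rooted-as-read
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", unquoted_underscores=True,
               suppress_rooting=True)


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Re-root at the midpoint of the longest tip-to-tip path (in place).

    Monophyly status can differ between the as-read and midpoint rootings;
    the default pipeline uses trees rooted as read.
    """
    tree.reroot_at_midpoint(update_bipartitions=False)
    return tree


def map_tips_to_taxa(
    tree: dendropy.Tree,
    metadata: Mapping[str, str] | None = None,
    split_char: str = ".",
) -> tuple[dict[str, str], list[str]]:
    """Resolve each tip label to a taxon name.

    Resolution order per tip label: (1) the full label in ``metadata``
    (record id -> species); (2) the prefix before the first ``split_char``
    in ``metadata``; (3) composite-label parsing — the part after the first
    ``split_char`` (the ``ProcessID.Taxon_name`` convention). Unresolvable
    labels are returned in the second element, never dropped silently.
    """
    mapping: dict[str, str] = {}
    unresolved: list[str] = []
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label
        prefix, sep, suffix = label.partition(split_char)
        if metadata and label in metadata:
            mapping[label] = metadata[label]
        elif metadata and sep and prefix in metadata:
            mapping[label] = metadata[prefix]
        elif sep and suffix:
            mapping[label] = suffix
        else:
            unresolved.append(label)
    return mapping, unresolved


@dataclass
class MonophylyResult:
    """Assessment of one taxon on one rooted tree."""

    taxon: str
    status: str  # monophyletic | non_monophyletic | singleton | absent
    n_tips: int
    tips: list[str] = field(default_factory=list)
    intruders: list[str] = field(default_factory=list)


class _IndexedTree:
    """Parent/depth indexes over a dendropy tree for fast MRCA queries."""

    def __init__(self, tree: dendropy.Tree):
        self.parent: dict[int, int | None] = {}
        self.depth: dict[int, int] = {}
        self.node_of: dict[int, dendropy.Node] = {}
        self.leaf_label: dict[int, str] = {}
        for node in tree.preorder_node_iter():
            nid = id(node)
            self.node_of[nid] = node
            par = node.parent_node
            self.parent[nid] = id(par) if par is not None else None
            self.depth[nid] = 0 if par is None else self.depth[id(par)] + 1
            if node.is_leaf():
                self.leaf_label[nid] = node.taxon.label
        self.leaf_id = {label: nid for nid, label in self.leaf_label.items()}

    def mrca(self, labels: Iterable[str]) -> int:
        ids = [self.leaf_id[l] for l in labels]
        cur = ids[0]
        for other in ids[1:]:
            a, b = cur, other
            while self.depth[a] > self.depth[b]:
                a = self.parent[a]
            while self.depth[b] > self.depth[a]:
                b = self.parent[b]
            while a != b:
                a, b = self.parent[a], self.parent[b]
            cur = a
        return cur

    def leaves_under(self, nid: int) -> list[str]:
        return [
            leaf.taxon.label
            for leaf in self.node_of[nid].leaf_iter()
        ]


def _assess_one(
    idx: _IndexedTree, taxon: str, tips: list[str], excluded: set[str]
) -> MonophylyResult:
    tips = sorted(t for t in tips if t not in excluded)
    if not tips:
        return MonophylyResult(taxon, "absent", 0)
    if len(tips) == 1:
        return MonophylyResult(taxon, "singleton", 1, tips)
    mrca = idx.mrca(tips)
    clade = [l for l in idx.leaves_under(mrca) if l not in excluded]
    intruders = sorted(set(clade) - set(tips))
    status = "monophyletic" if not intruders else "non_monophyletic"
    return MonophylyResult(taxon, status, len(tips), tips, intruders)


def _members(idx: _IndexedTree,
             tip_to_taxon: Mapping[str, str]) -> dict[str, list[str]]:
    members: dict[str, list[str]] = {}
    for label, taxon in tip_to_taxon.items():
        if label in idx.leaf_id:
            members.setdefault(taxon, []).append(label)
    return members


def assess_monophyly(
    tree: dendropy.Tree,
    tip_to_taxon: Mapping[str, str],
    taxa: Iterable[str] | None = None,
    exclude_tips: Iterable[str] = (),
) -> dict[str, MonophylyResult]:
    """Classify each taxon as monophyletic / non_monophyletic / singleton / absent.

    ``exclude_tips`` simulates removal without pruning the tree (used by the
    greedy curation search and the second-round confirmation).
    """
    idx = _IndexedTree(tree)
    excluded = set(exclude_tips)
    members = _members(idx, tip_to_taxon)
    if taxa is None:
        taxa = sorted(members)
    return {
        taxon: _assess_one(idx, taxon, members.get(taxon, []), excluded)
        for taxon in taxa
    }


def minimal_removal_set(
    tree: dendropy.Tree,
    tip_to_taxon: Mapping[str, str],
    taxon: str,
    _idx: _IndexedTree | None = None,
) -> list[str]:
    """Smallest advisory removal set restoring monophyly for ``taxon``.

    Any restoring removal is determined by the clade that will host the
    surviving members: every foreign tip inside that clade and every member
    outside it must go. Scanning all nodes for the cheapest such clade
    (one linear pass of subtree counts) therefore yields an exact minimum.
    Ties prefer keeping more members, then the shallower node. Suggestions
    support manual review, they are not disposals.
    """
    idx = _idx if _idx is not None else _IndexedTree(tree)
    members = set(_members(idx, tip_to_taxon).get(taxon, []))
    if len(members) < 2:
        return []
    if _assess_one(idx, taxon, sorted(members), set()).status != "non_monophyletic":
        return []

    n_members: dict[int, int] = {}
    n_leaves: dict[int, int] = {}
    for node in reversed(list(idx.node_of.values())):  # children before parents
        nid = id(node)
        if node.is_leaf():
            n_leaves[nid] = 1
            n_members[nid] = int(idx.leaf_label[nid] in members)
        else:
            kids = [id(c) for c in node.child_nodes()]
            n_leaves[nid] = sum(n_leaves[k] for k in kids)
            n_members[nid] = sum(n_members[k] for k in kids)

    best_nid, best_key = None, None
    for order, node in enumerate(idx.node_of.values()):  # preorder
        nid = id(node)
        if n_members[nid] == 0:
            continue
        cost = (n_leaves[nid] - n_members[nid]) + (len(members) - n_members[nid])
        key = (cost, -n_members[nid], order)
        if best_key is None or key < best_key:
            best_nid, best_key = nid, key

    inside = set(idx.leaves_under(best_nid))
    removals = (inside - members) | (members - inside)
    return sorted(removals)


def intruder_report(
    tree: dendropy.Tree,
    tip_to_taxon: Mapping[str, str],
    results: Mapping[str, MonophylyResult],
) -> pd.DataFrame:
    """Curation table: one row per non-monophyletic taxon.

    Columns: taxon, n_tips, intruders, intruder_taxa, suggested_removals.
    """
    idx = _IndexedTree(tree)
    rows = []
    for taxon in sorted(results):
        res = results[taxon]
        if res.status != "non_monophyletic":
            continue
        intruder_taxa = sorted({tip_to_taxon.get(t, "?") for t in res.intruders})
        rows.append(
            {
                "taxon": taxon,
                "n_tips": res.n_tips,
                "intruders": ";".join(res.intruders),
                "intruder_taxa": ";".join(intruder_taxa),
                "suggested_removals": ";".join(
                    minimal_removal_set(tree, tip_to_taxon, taxon, _idx=idx)
                ),
            }
        )
    return pd.DataFrame(
        rows, columns=["taxon", "n_tips", "intruders", "intruder_taxa",
                       "suggested_removals"]
    )


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Neighbor-joining tree from a complete distance matrix.

    Deterministic: among equal-minimum entries of the Q criterion the
    lowest (row, column) index pair in the current matrix is joined.
    Negative branch lengths (possible under NJ) are kept as computed; on
    additive matrices the tree's patristic distances reproduce the input
    exactly. Incomparable (NaN) pairs are an error — supply an externally
    inferred tree for such data.
    """
    n = len(dm)
    if n < 3:
        raise ValueError(f"neighbor joining needs >=3 records, got {n}")
    iu, ju = np.triu_indices(n, k=1)
    if np.isnan(dm.d[iu, ju]).any():
        raise ValueError(
            "distance matrix has incomparable pairs; supply an external tree"
        )
    taxa = dendropy.TaxonNamespace(dm.ids)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes: list[dendropy.Node] = []
    for rid in dm.ids:
        node = dendropy.Node(taxon=taxa.get_taxon(rid))
        nodes.append(node)
    D = dm.d.copy().astype(float)

    active = list(range(n))
    while len(active) > 2:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # lowest flat index among minima = lowest (row, col) pair
        flat = int(np.argmin(Q, axis=None))
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        ai, aj = active[i], active[j]
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        parent = dendropy.Node()
        ci, cj = nodes[ai], nodes[aj]
        parent.add_child(ci)
        parent.add_child(cj)
        ci.edge.length = float(li)
        cj.edge.length = float(lj)
        # distances from the new node to every other active node
        new_row = np.full(D.shape[0] + 1, 0.0)
        for k in active:
            if k in (ai, aj):
                continue
            new_row[k] = 0.5 * (D[ai, k] + D[aj, k] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, : len(new_row) - 1] = new_row[:-1]
        D[: len(new_row) - 1, -1] = new_row[:-1]
        nodes.append(parent)
        active = [k for k in active if k not in (ai, aj)] + [len(nodes) - 1]

    a, b = active
    root = dendropy.Node()
    root.add_child(nodes[a])
    root.add_child(nodes[b])
    half = 0.5 * D[a, b]
    nodes[a].edge.length = float(half)
    nodes[b].edge.length = float(D[a, b] - half)
    tree.seed_node = root
    tree.is_rooted = True
    return tree


def read_taxa_list(path: str | Path) -> list[str]:
    """Single-column CSV of taxa to test (header optional, 'taxon' if present)."""
    df = pd.read_csv(path, header=None, dtype=str)
    values = df.iloc[:, 0].dropna().tolist()
    if values and values[0].lower() in {"taxon", "taxa", "species"}:
        values = values[1:]
    return values


def write_monophyly_report(
    results: Mapping[str, MonophylyResult], path: str | Path
) -> None:
    rows = [
        {
            "taxon": t,
            "n_tips": results[t].n_tips,
            "status": results[t].status,
            "intruders": ";".join(results[t].intruders),
        }
        for t in sorted(results)
    ]
    pd.DataFrame(rows, columns=["taxon", "n_tips", "status", "intruders"]).to_csv(
        path, sep="\t", index=False
    )
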