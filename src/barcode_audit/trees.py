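"""Distance trees (NJ, UPGMA), clock calibration and monophyly classification.

NJ follows Saitou–Nei agglomeration; negative branch lengths are clamped to
zero with the deficit moved to the sister branch so the pair's summed length
is preserved, and the unrooted result is midpoint-rooted.  UPGMA
(average-linkage agglomeration, heights = half the merge distance) yields the
ultrametric trees used for clock calibration and GMYC; under a strict clock
at pairwise rate r (default 1.5%/Myr) a node at per-lineage height h
substitutions/site has age 2h/r Myr.

A species is monophyletic iff the leaves under its MRCA are exactly its own
members; otherwise it is paraphyletic when the intruding heterospecific
leaves form a single clade, else polyphyletic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from barcode_audit.errors import DataError
from barcode_audit.distances import DistanceMatrix
from barcode_audit.haplotypes import sequences_identical

log = logging.getLogger(__name__)

ULTRAMETRIC_TOL = 1e-9

#: Strict-clock pairwise divergence rate, substitutions/site per Myr.
DEFAULT_PAIRWISE_RATE = 0.015


def _check_complete(matrix: DistanceMatrix) -> np.ndarray:
    d = np.asarray(matrix.d, dtype=float)
    if np.isnan(d).any():
        bad = [matrix.ids[i] for i in sorted(set(np.argwhere(np.isnan(d))[:, 0]))]
        raise DataError(
            f"distance matrix has missing entries involving {bad[:10]}; "
            "impute or drop those specimens before tree building"
        )
    return d


def _new_tree(taxa: Sequence[str]) -> tuple[dendropy.Tree, list[dendropy.Node]]:
    ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=ns)
    leaves = []
    for label in taxa:
        node = dendropy.Node(taxon=ns.new_taxon(label))
        leaves.append(node)
    return tree, leaves


def nj_tree(matrix: DistanceMatrix) -> dendropy.Tree:
    """Neighbor-Joining tree from a complete distance matrix, midpoint-rooted."""
    d = _check_complete(matrix).copy()
    n = matrix.n
    if n < 3:
        raise DataError("NJ requires at least 3 taxa")
    tree, nodes = _new_tree(matrix.ids)
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i_loc, j_loc = np.unravel_index(np.argmin(q), q.shape)
        if i_loc > j_loc:
            i_loc, j_loc = j_loc, i_loc
        i, j = active[i_loc], active[j_loc]
        dij = d[i, j]
        li = 0.5 * dij + (r[i_loc] - r[j_loc]) / (2.0 * (m - 2))
        lj = dij - li
        # clamp negative estimates; the deficit goes to the sister branch
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = float(li)
        nodes[j].edge.length = float(lj)
        # grow storage for the merged node
        new_row = 0.5 * (d[i, :] + d[j, :] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, : d.shape[1] - 1] = new_row
        d[: d.shape[0] - 1, -1] = new_row
        d[-1, -1] = 0.0
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [d.shape[0] - 1]
    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    root = dendropy.Node()
    for k, lk in ((a, la), (b, lb), (c, lc)):
        if lk < 0:
            log.warning("NJ final branch length %.3g clamped to 0", lk)
            lk = 0.0
        root.add_child(nodes[k])
        nodes[k].edge.length = float(lk)
    tree.seed_node = root
    tree.reroot_at_midpoint(update_bipartitions=True)
    return tree


def upgma_tree(matrix: DistanceMatrix) -> dendropy.Tree:
    """UPGMA (average-linkage) ultrametric tree; node heights = merge dist / 2."""
    d = _check_complete(matrix)
    n = matrix.n
    if n < 2:
        raise DataError("UPGMA requires at least 2 taxa")
    tree, nodes = _new_tree(matrix.ids)
    heights = [0.0] * n
    z = linkage(squareform(d, checks=False), method="average")
    for row in z:
        i, j, merge_dist = int(row[0]), int(row[1]), float(row[2])
        parent = dendropy.Node()
        h = merge_dist / 2.0
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = max(h - heights[i], 0.0)
        nodes[j].edge.length = max(h - heights[j], 0.0)
        nodes.append(parent)
        heights.append(h)
    tree.seed_node = nodes[-1]
    tree.is_rooted = True
    return tree


def leaf_depths(tree: dendropy.Tree) -> dict[str, float]:
    depths: dict[str, float] = {}
    for leaf in tree.leaf_node_iter():
        depth = 0.0
        node = leaf
        while node.parent_node is not None:
            depth += node.edge.length or 0.0
            node = node.parent_node
        depths[leaf.taxon.label] = depth
    return depths


def is_ultrametric(tree: dendropy.Tree, tol: float = ULTRAMETRIC_TOL) -> bool:
    depths = list(leaf_depths(tree).values())
    return (max(depths) - min(depths)) <= tol * max(1.0, max(depths))


def node_ages(tree: dendropy.Tree, tol: float = 1e-6) -> dict[dendropy.Node, float]:
    """Age (height above the tips) of every node of an ultrametric tree."""
    if not is_ultrametric(tree, tol):
        raise DataError("tree is not ultrametric; cannot assign node ages")
    ages: dict[dendropy.Node, float] = {}
    height = max(leaf_depths(tree).values())

    def _descend(node: dendropy.Node, depth: float) -> None:
        ages[node] = max(height - depth, 0.0)
        for child in node.child_nodes():
            _descend(child, depth + (child.edge.length or 0.0))

    _descend(tree.seed_node, 0.0)
    return ages


def calibrate_tree(
    tree: dendropy.Tree, pairwise_rate: float = DEFAULT_PAIRWISE_RATE
) -> dendropy.Tree:
    """Rescale an ultrametric tree from substitutions/site to ages in Myr.

    Pairwise divergence accumulates at ``pairwise_rate`` per Myr, so a node at
    per-lineage height h has age 2h/rate; equivalently every branch length is
    multiplied by 2/rate.
    """
    if pairwise_rate <= 0:
        raise DataError("pairwise_rate must be positive")
    if not is_ultrametric(tree, tol=1e-6):
        raise DataError("calibration requires an ultrametric tree")
    out = tree.clone(depth=1)
    factor = 2.0 / pairwise_rate
    for edge in out.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length * factor
    return out


@dataclass
class MonophylyCall:
    """Monophyly status of one species on a rooted tree."""

    species: str
    status: str  # monophyletic | paraphyletic | polyphyletic | undefined
    intruder_species: list[str] = field(default_factory=list)
    shares_barcode_with_intruder: bool | None = None


def classify_monophyly(
    tree: dendropy.Tree,
    species_labels: Mapping[str, str],
    sequences: Mapping[str, str] | None = None,
    min_overlap: int = 500,
) -> list[MonophylyCall]:
    """Classify every species on a rooted, fully labeled tree.

    Species with a single specimen are reported as ``undefined`` (monophyly
    is only meaningful for two or more specimens).  When ``sequences`` maps
    specimen ids to aligned sequences, ``shares_barcode_with_intruder`` marks
    whether any member is identical to any intruding specimen.
    """
    leaf_to_species: dict[str, str] = {}
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label
        if label not in species_labels:
            raise DataError(f"leaf {label!r} has no species label")
        leaf_to_species[label] = species_labels[label]

    # leaf set of every node (clade table), bottom-up
    clade_of: dict[dendropy.Node, frozenset[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            clade_of[node] = frozenset([node.taxon.label])
        else:
            s: set[str] = set()
            for child in node.child_nodes():
                s |= clade_of[child]
            clade_of[node] = frozenset(s)
    clades = set(clade_of.values())

    members_by_species: dict[str, set[str]] = {}
    for label, species in leaf_to_species.items():
        members_by_species.setdefault(species, set()).add(label)

    calls: list[MonophylyCall] = []
    for species in sorted(members_by_species):
        members = frozenset(members_by_species[species])
        if len(members) < 2:
            calls.append(MonophylyCall(species=species, status="undefined"))
            continue
        # MRCA = smallest clade containing all members
        mrca_set = min(
            (c for c in clades if members <= c), key=len
        )
        intruders = mrca_set - members
        if not intruders:
            calls.append(MonophylyCall(species=species, status="monophyletic"))
            continue
        status = "paraphyletic" if frozenset(intruders) in clades else "polyphyletic"
        intruder_species = sorted({leaf_to_species[x] for x in intruders})
        shares: bool | None = None
        if sequences is not None:
            shares = any(
                sequences_identical(sequences[m], sequences[i], min_overlap)
                for m in members
                for i in intruders
            )
        calls.append(
            MonophylyCall(
                species=species, status=status,
                intruder_species=intruder_species,
                shares_barcode_with_intruder=shares,
            )
        )
    return calls


def monophyly_counts(calls: Sequence[MonophylyCall]) -> dict[str, int]:
    counts = {"monophyletic": 0, "paraphyletic": 0, "polyphyletic": 0, "undefined": 0}
    for call in calls:
        counts[call.status] += 1
    return counts
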