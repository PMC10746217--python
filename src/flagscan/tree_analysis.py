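"""Species-tree / gene-tree concordance and inter-class transfer detection.

The flagellar-protein tree of flagellated species is expected to track
the species tree under vertical inheritance; topological distance is
quantified with the Robinson-Foulds metric, and individual leaves whose
gene-tree neighborhood belongs to a foreign taxonomic class — while
their species-tree neighborhood is class-consistent — are reported as
candidate inter-class transfers.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import dendropy

__all__ = [
    "PhyloTree",
    "TransferReport",
    "read_newick",
    "write_newick",
    "robinson_foulds",
    "detect_interclass_transfers",
]


@dataclass
class PhyloTree:
    """A leaf-labeled tree with optional per-leaf class annotations."""

    tree: dendropy.Tree
    classes: dict[str, str] = field(default_factory=dict)

    @property
    def leaf_labels(self) -> set[str]:
        return {lf.taxon.label for lf in self.tree.leaf_node_iter()}


@dataclass(frozen=True)
class TransferReport:
    leaf: str
    expected_class_context: str  # the leaf's own class
    observed_sister_class: str  # majority class of its gene-tree sisters
    ambiguous: bool = False


def read_newick(path: str, classes: dict[str, str] | None = None) -> PhyloTree:
    """Read a Newick tree; leaf labels must be unique."""
    try:
        tree = dendropy.Tree.get(
            path=path, schema="newick", preserve_underscores=True
        )
    except Exception as exc:
        raise ValueError(f"{path}: newick parse error: {exc}") from exc
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    dupes = sorted({x for x in labels if labels.count(x) > 1})
    if dupes:
        raise ValueError(f"duplicate leaf labels: {dupes}")
    return PhyloTree(tree=tree, classes=dict(classes or {}))


def write_newick(ptree: PhyloTree, path: str) -> None:
    ptree.tree.write(
        path=path,
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    )


# ---------------------------------------------------------------------------
# Robinson-Foulds
# ---------------------------------------------------------------------------


def _bipartitions(ptree: PhyloTree) -> set[frozenset[frozenset[str]]]:
    """Non-trivial bipartitions of the (implicitly unrooted) tree.

    Each internal edge splits the leaves in two; splits with a side of
    fewer than two leaves are trivial and dropped.  Representing a
    bipartition as the set of its two sides makes the encoding
    independent of rooting, so rooted inputs are effectively unrooted.
    """
    all_leaves = frozenset(lf.taxon.label for lf in ptree.tree.leaf_node_iter())
    bips: set[frozenset[frozenset[str]]] = set()
    for node in ptree.tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        other = all_leaves - side
        if len(side) >= 2 and len(other) >= 2:
            bips.add(frozenset((side, other)))
    return bips


def robinson_foulds(t1: PhyloTree, t2: PhyloTree) -> tuple[int, int, int]:
    """Robinson-Foulds distance between two trees on one leaf set.

    Returns ``(rf_distance, shared_bipartitions, max_possible)`` where
    the distance is the size of the symmetric difference of the
    non-trivial bipartition sets and ``max_possible`` is the sum of the
    two set sizes.  Zero iff the unrooted topologies are identical.
    """
    if t1.leaf_labels != t2.leaf_labels:
        only1 = sorted(t1.leaf_labels - t2.leaf_labels)
        only2 = sorted(t2.leaf_labels - t1.leaf_labels)
        raise ValueError(
            f"leaf sets differ: only in first {only1}, only in second {only2}"
        )
    b1, b2 = _bipartitions(t1), _bipartitions(t2)
    return len(b1 ^ b2), len(b1 & b2), len(b1) + len(b2)


# ---------------------------------------------------------------------------
# Inter-class transfer detection
# ---------------------------------------------------------------------------


def _sister_leaves(tree: dendropy.Tree, leaf_label: str) -> list[str]:
    """Leaves of the smallest clade of >= 2 leaves enclosing the leaf,
    excluding the leaf itself."""
    node = next(
        lf for lf in tree.leaf_node_iter() if lf.taxon.label == leaf_label
    )
    anc = node.parent_node
    while anc is not None:
        others = [
            lf.taxon.label
            for lf in anc.leaf_iter()
            if lf.taxon.label != leaf_label
        ]
        if others:
            return others
        anc = anc.parent_node
    return []


def detect_interclass_transfers(
    gene_tree: PhyloTree, species_tree: PhyloTree
) -> list[TransferReport]:
    """Report leaves whose gene-tree context belongs to a foreign class.

    A leaf is reported iff (a) the majority (plurality) class of its
    smallest enclosing gene-tree clade of >= 2 leaves differs from its
    own class, and (b) the corresponding species-tree clade is
    class-consistent — every sister leaf there shares the leaf's own
    class, so the discordance is specific to the gene tree.  Plurality
    ties that exclude the leaf's own class are reported with the tied
    classes joined by ``|`` and ``ambiguous=True``; ties that include
    the own class are not transfers.  Support values are carried on the
    trees but not used.
    """
    classes = gene_tree.classes or species_tree.classes
    leaves = sorted(gene_tree.leaf_labels)
    missing = [lf for lf in leaves if lf not in classes]
    if missing:
        raise ValueError(f"leaves without class annotation: {missing}")
    if gene_tree.leaf_labels != species_tree.leaf_labels:
        raise ValueError("gene and species tree must share their leaf set")

    reports: list[TransferReport] = []
    for leaf in leaves:
        own = classes[leaf]
        sisters = _sister_leaves(gene_tree.tree, leaf)
        if not sisters:
            continue
        counts = Counter(classes[s] for s in sisters)
        top = max(counts.values())
        winners = sorted(c for c, n in counts.items() if n == top)
        if own in winners:
            continue
        sp_sisters = _sister_leaves(species_tree.tree, leaf)
        if not sp_sisters or any(classes[s] != own for s in sp_sisters):
            continue
        if len(winners) == 1:
            reports.append(TransferReport(leaf, own, winners[0]))
        else:
            reports.append(
                TransferReport(leaf, own, "|".join(winners), ambiguous=True)
            )
    return reports
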