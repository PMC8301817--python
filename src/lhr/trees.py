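"""Tree-side bookkeeping: rooting, class concordance, iTOL export.

Trees are inferred externally (newick in, newick out); this module
roots a family tree on the edge separating two named leaf sets (the
published trees root between the Lhr-like and aLhr3 subtrees, or on the
Sfth outgroup), tests each family/class label for monophyly against the
tree, and quantifies discordance as the minimal number of leaves whose
removal would make the class monophyletic.

Monophyly is defined on the unrooted topology: a class is monophyletic
iff some edge's removal isolates exactly the class's leaves.
Multifurcations are accepted.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy


def read_newick(text_or_path: str, is_path: bool = False) -> dendropy.Tree:
    if is_path:
        return dendropy.Tree.get(path=text_or_path, schema="newick",
                                 preserve_underscores=True)
    return dendropy.Tree.get(data=text_or_path, schema="newick",
                             preserve_underscores=True)


@dataclass
class ClassConcordance:
    label: str
    n_leaves: int
    is_monophyletic: bool
    min_removals: int


@dataclass
class ConcordanceReport:
    per_class: dict[str, ClassConcordance]
    concordant_fraction: float


def _leaf_names(tree: dendropy.Tree) -> set[str]:
    return {leaf.taxon.label for leaf in tree.leaf_node_iter()}


def root_between(tree: dendropy.Tree, clade_a: set[str],
                 clade_b: set[str]) -> dendropy.Tree:
    """Root the tree on the single edge separating the two leaf sets.

    ``clade_a`` and ``clade_b`` must be disjoint and together cover all
    leaves; the root is placed at the midpoint of the separating edge
    when it carries a length.
    """
    overlap = clade_a & clade_b
    if overlap:
        raise ValueError(f"clades overlap on leaves {sorted(overlap)}")
    tree = tree.clone(depth=1)
    leaves = _leaf_names(tree)
    if clade_a | clade_b != leaves:
        missing = leaves - (clade_a | clade_b)
        extra = (clade_a | clade_b) - leaves
        raise ValueError(
            f"clades must cover all leaves (uncovered: {sorted(missing)}, "
            f"unknown: {sorted(extra)})")
    edge = _separating_edge(tree, clade_a)
    if edge is None:
        raise ValueError(
            f"no single edge separates {sorted(clade_a)} from "
            f"{sorted(clade_b)}")
    length = edge.length
    if length is not None:
        tree.reroot_at_edge(edge, length1=length / 2.0, length2=length / 2.0,
                            update_bipartitions=False)
    else:
        tree.reroot_at_edge(edge, update_bipartitions=False)
    return tree


def _below(node: dendropy.Node) -> set[str]:
    return {leaf.taxon.label for leaf in node.leaf_iter()}


def _separating_edge(tree: dendropy.Tree, side: set[str]):
    all_leaves = _leaf_names(tree)
    complement = all_leaves - side
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        under = _below(node)
        if under == side or under == complement:
            return node.edge
    return None


def class_concordance(tree: dendropy.Tree,
                      labels: dict[str, str]) -> ConcordanceReport:
    """Monophyly and minimal-removal discordance for every class label.

    For each class S, the removal count is the minimum over tree edges
    of |L(e) \\ S| + |S \\ L(e)| (intruders inside the best candidate
    clade plus class members stranded outside it), capped at |S| - 1;
    zero iff the class is monophyletic.  The concordant fraction is
    1 - (total removals) / (total leaves).
    """
    leaves = _leaf_names(tree)
    unlabeled = leaves - set(labels)
    if unlabeled:
        raise ValueError(f"unlabeled leaves: {sorted(unlabeled)}")
    class_members: dict[str, set[str]] = {}
    for leaf, lab in labels.items():
        if leaf in leaves:
            class_members.setdefault(lab, set()).add(leaf)

    # candidate leaf sets: each edge's two sides (unrooted bipartitions)
    sides: list[set[str]] = []
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        under = _below(node)
        sides.append(under)
        sides.append(leaves - under)

    per_class: dict[str, ClassConcordance] = {}
    total_removals = 0
    for lab, members in sorted(class_members.items()):
        best = len(members) - 1  # keeping one leaf is always monophyletic
        for side in sides:
            cost = len(side - members) + len(members - side)
            best = min(best, cost)
        best = max(best, 0)
        per_class[lab] = ClassConcordance(lab, len(members), best == 0, best)
        total_removals += best
    fraction = 1.0 - total_removals / len(leaves) if leaves else 1.0
    return ConcordanceReport(per_class, fraction)


# ---------------------------------------------------------------------------
# iTOL annotation export

_PALETTE = ["#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd",
            "#8c564b", "#e377c2", "#7f7f7f", "#bcbd22", "#17becf"]


def export_itol_colorstrip(labels: dict[str, str], path: str,
                           dataset_label: str = "classes") -> dict[str, str]:
    """iTOL DATASET_COLORSTRIP file; returns the label → color map."""
    classes = sorted(set(labels.values()))
    colors = {c: _PALETTE[i % len(_PALETTE)] for i, c in enumerate(classes)}
    with open(path, "w") as fh:
        fh.write("DATASET_COLORSTRIP\nSEPARATOR TAB\n"
                 f"DATASET_LABEL\t{dataset_label}\nCOLOR\t#000000\nDATA\n")
        for leaf in sorted(labels):
            fh.write(f"{leaf}\t{colors[labels[leaf]]}\t{labels[leaf]}\n")
    return colors


def read_itol_colorstrip(path: str) -> dict[str, str]:
    """Recover the leaf → label map from an exported color strip."""
    labels: dict[str, str] = {}
    in_data = False
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line == "DATA":
                in_data = True
                continue
            if in_data and line:
                leaf, _, label = line.split("\t")
                labels[leaf] = label
    return labels


def export_itol_annotations(labels: dict[str, str],
                            taxon_groups: dict[str, str],
                            out_prefix: str) -> list[str]:
    """Write class-ring and taxon-ring color strips; returns the paths."""
    orphans = set(labels) ^ set(taxon_groups)
    if orphans:
        import warnings
        warnings.warn(f"id mismatch between label maps: {sorted(orphans)}",
                      UserWarning)
    class_path = f"{out_prefix}.classes.txt"
    taxon_path = f"{out_prefix}.taxa.txt"
    export_itol_colorstrip(labels, class_path, "mcl_classes")
    export_itol_colorstrip(taxon_groups, taxon_path, "taxon_groups")
    return [class_path, taxon_path]
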