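"""Check an inferred tree against the MCL classes, then annotate it.

Builds a neighbor-joining tree from the pairwise alignment distances,
roots it between two family clades, tests each family for monophyly
and writes iTOL color-strip annotations.
"""

from skbio import DistanceMatrix
from skbio.tree import nj

from lhr import graph, pairwise
from lhr.reduce import dissimilarity_from_hits
from lhr.synthetic import SynthParams, generate_family_dataset
from lhr.trees import class_concordance, export_itol_annotations, \
    read_newick, root_between

dataset = generate_family_dataset(SynthParams())
proteins = graph.dedupe_strains(dataset.proteins)
hits = pairwise.all_vs_all(proteins)

ids = sorted(p.protein_id for p in proteins)
dissim = dissimilarity_from_hits(hits, ids)
tree = read_newick(str(nj(DistanceMatrix(dissim.loc[ids, ids].values,
                                         ids))))

labels = {pid: dataset.truth_labels[pid] for pid in ids}
report = class_concordance(tree, labels)
for c in report.per_class.values():
    print(f"{c.label:9s} {c.n_leaves:3d} leaves  "
          f"monophyletic={c.is_monophyletic}  removals={c.min_removals}")
print(f"concordant fraction: {report.concordant_fraction:.3f}")

# root between the Lhr-like clade and the rest, as the family tree is
# rooted between its most external subtrees
lhr_like = {pid for pid, lab in labels.items() if lab == "Lhr-like"}
rooted = root_between(tree, lhr_like, set(ids) - lhr_like)
print("rooted; children of root:",
      [len(list(k.leaf_iter())) for k in rooted.seed_node.child_nodes()])

taxon = {p.protein_id: p.taxon_group for p in proteins}
paths = export_itol_annotations(labels, taxon, "example_itol")
print("wrote", ", ".join(paths))
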