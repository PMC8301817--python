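"""Microsynteny: conserved genes within 4 kb of the focal Lhr genes.

The generator plants a conserved neighbor gene (a metallophosphoesterase
stand-in, profile TIGR0024) immediately upstream of focal genes at
frequency 0.6; the conservation table recovers that frequency, and an
XOR-planted dataset shows the mutually-exclusive pattern.
"""

from lhr.context import (conservation_profile, cooccurrence_summary,
                         neighborhood)
from lhr.synthetic import (NEIGHBOR_PROFILE, ArchitectureSpec, SynthParams,
                           generate_family_dataset)


def build_neighborhoods(dataset):
    by_genome = {}
    for f in dataset.features:
        by_genome.setdefault(f.genome_id, []).append(f)
    nbhs, genome_of = {}, {}
    for p in dataset.proteins:
        genome_of[p.protein_id] = p.genome_id
        feats = by_genome[p.genome_id]
        focal = next(f for f in feats if f.product_id == p.protein_id)
        nbhs[p.protein_id] = neighborhood(feats, focal)
    return nbhs, genome_of


dataset = generate_family_dataset(SynthParams())
nbhs, genome_of = build_neighborhoods(dataset)
table = conservation_profile(nbhs, dataset.truth_labels, genome_of).table
print(table[table.profile == NEIGHBOR_PROFILE].to_string(index=False))
# fraction ~ 0.6 per family: the planted conservation frequency.

xor_params = SynthParams(
    n_families=2, family_sizes=(20, 20),
    architectures=(ArchitectureSpec("aLhr2"),
                   ArchitectureSpec("aLhr1", cys_rich=True)),
    n_species=20, neighbor_xor_families=(0, 1), seed=3)
xor_ds = generate_family_dataset(xor_params)
nbhs, genome_of = build_neighborhoods(xor_ds)
summary = cooccurrence_summary(nbhs, xor_ds.truth_labels, genome_of,
                               "aLhr2", "aLhr1", NEIGHBOR_PROFILE)
print(f"\nneighbor near aLhr2 only: {summary.a_only} genomes, "
      f"near aLhr1 only: {summary.b_only}, both: {summary.both}, "
      f"neither: {summary.neither}")
print(f"mutually exclusive: {summary.mutually_exclusive}")
# both = 0 with non-empty exclusive cells reproduces the pattern where
# the neighbor sits near one lhr paralog or the other, never both.
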