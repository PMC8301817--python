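"""End-to-end convenience driver over the module surface.

Chains the stages in the order the classification study applies them:
strain dedup → all-vs-all alignment → BBH graph → MCL inflation scan →
identity-pruned medoid reduction → core-profile filtering → domain-
architecture family assignment → microsynteny profiling.  Intended for
synthetic datasets and desk-scale inputs; each stage remains directly
callable for anything bespoke.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

from . import architecture, context, graph, pairwise, reduce
from . import clustering
from .clustering import Partition, StabilityReport
from .records import ProteinRecord
from .reduce import ReductionParams, RepresentativeSet
from .synthetic import SynthDataset


@dataclass
class PipelineResult:
    proteins: list[ProteinRecord]
    hits: list[pairwise.PairwiseHit]
    bbh_graph: nx.Graph
    scan: StabilityReport
    stable_partition: Partition
    representatives: RepresentativeSet
    assignments: list
    paralog_table: pd.DataFrame
    conservation: context.ConservationTable


def run_pipeline(dataset: SynthDataset,
                 inflation_values: tuple[float, ...] = (2, 3, 4, 5, 6),
                 reduction: ReductionParams = ReductionParams(),
                 window_bp: int = 4000) -> PipelineResult:
    """Run the full classification pipeline on one dataset."""
    proteins = graph.dedupe_strains(dataset.proteins)
    ids = {p.protein_id for p in proteins}
    profile_hits = [h for h in dataset.profile_hits if h.protein_id in ids]

    candidates = graph.filter_candidates(profile_hits)
    proteins = [p for p in proteins if p.protein_id in candidates]

    hits = pairwise.all_vs_all(proteins)
    directed = graph.best_hits_per_species(hits, proteins)
    bbh = graph.build_bbh_graph(directed, proteins)

    scan = clustering.scan_inflation(bbh, list(inflation_values))
    stable_if = scan.min_stable_inflation
    key = stable_if if stable_if is not None else float(inflation_values[-1])
    stable = scan.partitions[key]

    pruned = reduce.prune_graph_by_identity(bbh, reduction.min_identity_pct)
    dissim = reduce.dissimilarity_from_hits(hits,
                                            [p.protein_id for p in proteins])
    lengths = {p.protein_id: p.length for p in proteins}
    reps = reduce.reduce_dataset(pruned, dissim, lengths, reduction)
    reps = reduce.discard_missing_core(reps, profile_hits,
                                       reduction.required_core_profiles)

    assignments = architecture.classify_dataset(
        proteins, profile_hits, cluster_of=stable.cluster_of)
    genome_of = {p.protein_id: p.genome_id for p in proteins}
    paralogs = architecture.tabulate_paralog_counts(assignments, genome_of)

    params = context.ContextParams(window_bp=window_bp)
    by_genome: dict[str, list] = {}
    for f in dataset.features:
        by_genome.setdefault(f.genome_id, []).append(f)
    focal_family = {a.protein_id: a.label for a in assignments}
    neighborhoods = {}
    for p in proteins:
        feats = by_genome.get(p.genome_id, [])
        focal = next((f for f in feats if f.product_id == p.protein_id), None)
        if focal is not None:
            neighborhoods[p.protein_id] = context.neighborhood(
                feats, focal, params)
    conservation = context.conservation_profile(
        {k: v for k, v in neighborhoods.items() if k in focal_family},
        {k: focal_family[k] for k in neighborhoods if k in focal_family},
        genome_of)

    return PipelineResult(proteins, hits, bbh, scan, stable, reps,
                          assignments, paralogs, conservation)
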