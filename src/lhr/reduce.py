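"""Sample reduction: identity pruning, MCL regrouping, medoid selection.

To shrink a redundant protein set while preserving sequence diversity,
edges below an identity threshold (default 70%) are removed from the
similarity graph, the pruned graph is re-clustered with MCL, and each
multi-member group is represented by its medoid — the member with
minimal average dissimilarity to the rest, constrained to lie near the
group's median length.  Singleton groups represent themselves.
Proteins on a keep-list are re-inserted after selection, and
representatives lacking the helicase-core profiles (PF00270 and
PF00271) are discarded.

Dissimilarity is ``100 - identity_pct`` from the pairwise hits; pairs
with no significant local alignment count as 100.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .clustering import MclParams, mcl
from .records import PF_RECA1, PF_RECA2, ProfileHit


@dataclass(frozen=True)
class ReductionParams:
    min_identity_pct: float = 70.0       # Sfth outgroup mode uses 55.0
    length_tolerance: float = 0.10       # fraction of the median length
    keep_list: tuple[str, ...] = ()
    required_core_profiles: tuple[str, ...] = (PF_RECA1, PF_RECA2)
    mcl_params: MclParams = field(default_factory=MclParams)

    def __post_init__(self) -> None:
        if not (0.0 < self.min_identity_pct <= 100.0):
            raise ValueError("min_identity_pct must be in (0, 100]")
        if self.length_tolerance < 0:
            raise ValueError("length_tolerance must be >= 0")


@dataclass
class RepresentativeSet:
    representatives: set[str]
    member_of: dict[str, str]
    n_singletons: int
    n_medoid_groups: int

    def validate(self) -> None:
        for member, rep in self.member_of.items():
            if rep not in self.representatives:
                raise ValueError(f"{member} maps to non-representative {rep}")
        for rep in self.representatives:
            if self.member_of.get(rep) != rep:
                raise ValueError(f"representative {rep} must map to itself")


def prune_graph_by_identity(graph: nx.Graph,
                            min_identity_pct: float) -> nx.Graph:
    """Subgraph on the same nodes keeping edges with identity >= threshold."""
    pruned = nx.Graph()
    pruned.add_nodes_from(graph.nodes(data=True))
    for a, b, d in graph.edges(data=True):
        if d["identity_pct"] >= min_identity_pct:
            pruned.add_edge(a, b, **d)
    return pruned


def compute_medoid(group: list[str], lengths: dict[str, int],
                   dissimilarity: pd.DataFrame,
                   length_tolerance: float = 0.10) -> str:
    """Medoid of a group under a median-length constraint.

    Candidates are members within ``length_tolerance x median`` of the
    median length (relaxed to the members closest in length if none
    qualify); among candidates the member with minimal mean
    dissimilarity to all *other* group members wins, ties broken by
    lexicographically smallest id.
    """
    if not group:
        raise ValueError("empty group")
    if len(group) == 1:
        return group[0]
    sub = dissimilarity.loc[group, group]
    if not np.allclose(sub.values, sub.values.T):
        raise ValueError("dissimilarity matrix is not symmetric")
    median_len = statistics.median(lengths[g] for g in group)
    tol = length_tolerance * median_len
    candidates = [g for g in group if abs(lengths[g] - median_len) <= tol]
    if not candidates:
        closest = min(abs(lengths[g] - median_len) for g in group)
        candidates = [g for g in group
                      if abs(lengths[g] - median_len) == closest]
    best_id, best_score = None, None
    for g in sorted(candidates):
        others = [h for h in group if h != g]
        score = float(sub.loc[g, others].mean())
        if best_score is None or score < best_score:
            best_id, best_score = g, score
    return best_id


def dissimilarity_from_hits(hits, protein_ids: list[str]) -> pd.DataFrame:
    """100 - identity_pct matrix; missing pairs = 100, diagonal = 0."""
    ids = sorted(protein_ids)
    mat = pd.DataFrame(100.0, index=ids, columns=ids)
    np.fill_diagonal(mat.values, 0.0)
    for h in hits:
        if h.query_id in mat.index and h.subject_id in mat.columns:
            d = 100.0 - h.identity_pct
            mat.loc[h.query_id, h.subject_id] = d
            mat.loc[h.subject_id, h.query_id] = d
    return mat


def reduce_dataset(pruned_graph: nx.Graph, dissimilarity: pd.DataFrame,
                   lengths: dict[str, int],
                   params: ReductionParams = ReductionParams()
                   ) -> RepresentativeSet:
    """Represent each >=identity-threshold group by a single sequence.

    Groups are the MCL clusters of the pruned graph; singletons
    represent themselves, multi-member groups contribute their medoid.
    Keep-list members absent from the representatives are then added
    back, mapping to themselves.
    """
    unknown = [k for k in params.keep_list if k not in pruned_graph]
    if unknown:
        raise ValueError(f"keep_list ids not in dataset: {unknown}")
    partition = mcl(pruned_graph, params.mcl_params)
    representatives: set[str] = set()
    member_of: dict[str, str] = {}
    n_singletons = n_medoid_groups = 0
    for cluster in partition.clusters():
        members = sorted(cluster)
        if len(members) == 1:
            rep = members[0]
            n_singletons += 1
        else:
            rep = compute_medoid(members, lengths, dissimilarity,
                                 params.length_tolerance)
            n_medoid_groups += 1
        representatives.add(rep)
        for m in members:
            member_of[m] = rep
    for kept in params.keep_list:
        if kept not in representatives:
            representatives.add(kept)
            member_of[kept] = kept
    result = RepresentativeSet(representatives, member_of,
                               n_singletons, n_medoid_groups)
    result.validate()
    return result


def discard_missing_core(representatives: RepresentativeSet,
                         profile_hits: list[ProfileHit],
                         required_core_profiles: tuple[str, ...] = (
                             PF_RECA1, PF_RECA2),
                         exempt: tuple[str, ...] = ()
                         ) -> RepresentativeSet:
    """Drop representatives lacking any required helicase-core profile.

    Members of a dropped representative are removed from the mapping as
    well.  ``exempt`` ids are never dropped (off by default even for
    keep-list members).
    """
    profiles_of: dict[str, set[str]] = {}
    for h in profile_hits:
        profiles_of.setdefault(h.protein_id, set()).add(h.profile_id)
    kept = {
        rep for rep in representatives.representatives
        if rep in exempt or
        all(p in profiles_of.get(rep, set()) for p in required_core_profiles)
    }
    member_of = {m: r for m, r in representatives.member_of.items()
                 if r in kept}
    singleton_reps = {r for r in kept
                      if sum(1 for v in member_of.values() if v == r) == 1}
    result = RepresentativeSet(
        kept, member_of,
        n_singletons=len(singleton_reps),
        n_medoid_groups=len(kept) - len(singleton_reps))
    result.validate()
    return result
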