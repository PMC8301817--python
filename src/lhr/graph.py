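"""Candidate filtering and best-bidirectional-hit (BBH) graph construction.

The relationship graph has proteins as vertices and BBH relations as
edges: ``a -- b`` exists iff ``b`` is ``a``'s best hit among proteins of
``b``'s species and vice versa.  Edges are weighted by the average
-log10 E-value of the two directed hits and carry the mean percent
identity; same-species pairs never form edges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx

from .pairwise import EVALUE_FLOOR, PairwiseHit
from .records import COG_LHR, ProfileHit, ProteinRecord


@dataclass(frozen=True)
class CandidateFilterParams:
    """Profile-hit thresholds for the initial candidate sweep."""

    max_evalue: float = 1e-4
    min_profile_coverage: float = 0.30
    required_profile_id: str = COG_LHR

    def __post_init__(self) -> None:
        if self.max_evalue <= 0:
            raise ValueError("max_evalue must be positive")
        if not (0.0 < self.min_profile_coverage <= 1.0):
            raise ValueError("min_profile_coverage must be in (0, 1]")


def filter_candidates(hits: list[ProfileHit],
                      params: CandidateFilterParams = CandidateFilterParams()
                      ) -> set[str]:
    """Protein ids with >=1 qualifying hit to the required profile.

    A hit qualifies when its E-value is at most ``max_evalue`` and it
    covers at least ``min_profile_coverage`` of the profile.
    """
    kept: set[str] = set()
    for h in hits:
        if h.profile_id != params.required_profile_id:
            continue
        if not (0.0 <= h.coverage <= 1.0):
            raise ValueError(f"coverage {h.coverage} outside [0, 1]")
        if h.e_value <= params.max_evalue and \
                h.coverage >= params.min_profile_coverage:
            kept.add(h.protein_id)
    return kept


def dedupe_strains(proteins: list[ProteinRecord]) -> list[ProteinRecord]:
    """Keep exactly one strain per species (lexicographically smallest).

    Removes every protein of the discarded strains; deterministic.
    """
    chosen: dict[str, str] = {}
    for p in proteins:
        cur = chosen.get(p.species_key)
        if cur is None or p.strain_key < cur:
            chosen[p.species_key] = p.strain_key
    return [p for p in proteins if p.strain_key == chosen[p.species_key]]


def best_hits_per_species(hits: list[PairwiseHit],
                          proteins: list[ProteinRecord]
                          ) -> dict[tuple[str, str], PairwiseHit]:
    """Best directed hit per (query protein, target species).

    Keeps the subject with minimal E-value (ties: higher bit score, then
    lexicographically smaller subject id); same-species pairs dropped.
    Returns a map (query_id, target_species) → winning hit.
    """
    species_of = {p.protein_id: p.species_key for p in proteins}
    best: dict[tuple[str, str], PairwiseHit] = {}
    for h in hits:
        if h.query_id == h.subject_id:
            continue
        qs = species_of.get(h.query_id)
        ss = species_of.get(h.subject_id)
        if qs is None or ss is None or qs == ss:
            continue
        key = (h.query_id, ss)
        cur = best.get(key)
        if cur is None or _beats(h, cur):
            best[key] = h
    return best


def _beats(new: PairwiseHit, cur: PairwiseHit) -> bool:
    return (new.e_value, -new.bit_score, new.subject_id) < \
           (cur.e_value, -cur.bit_score, cur.subject_id)


def build_bbh_graph(directed: dict[tuple[str, str], PairwiseHit],
                    proteins: list[ProteinRecord]) -> nx.Graph:
    """Reciprocal best-hit graph weighted by average -log10 E-value.

    Edge (a, b) exists iff a is b's best hit within a's species and b is
    a's best hit within b's species; the weight is the mean of
    -log10 E over the two directed hits (E floored at 1e-180) and
    ``identity_pct`` is the mean of the two directions.  All proteins
    appear as nodes, including BBH-less singletons.
    """
    species_of = {p.protein_id: p.species_key for p in proteins}
    graph = nx.Graph()
    graph.add_nodes_from(sorted(species_of))
    for (query_id, _), hit in sorted(directed.items()):
        a, b = hit.query_id, hit.subject_id
        if a >= b:
            continue  # handle each unordered pair once, from the smaller id
        back = directed.get((b, species_of[a]))
        if back is None or back.subject_id != a:
            continue
        w = 0.5 * (_neglog(hit.e_value) + _neglog(back.e_value))
        if w <= 0:
            continue  # E >= 1 in both directions: too weak for an edge
        ident = 0.5 * (hit.identity_pct + back.identity_pct)
        graph.add_edge(a, b, weight=w, identity_pct=ident)
    return graph


def _neglog(e_value: float) -> float:
    return -math.log10(max(e_value, EVALUE_FLOOR))
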