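"""Domain-architecture calls and the six-group Lhr family assignment.

Every Lhr protein carries the SF2 helicase core (Pfam PF00270 "DEAD" =
RecA1 and PF00271 "Helicase_C" = RecA2).  The groups differ in the
C-terminal accessories:

* ``aLhr1`` — archaeal, intact Domain 4 (PF08494) plus a cysteine-rich
  Zn-finger-like C-terminal motif;
* ``aLhr2`` — archaeal, intact Domain 4, no cys-rich motif (an HTH_42
  is tolerated, as in Methanomassiliicoccales);
* ``aLhr3`` — archaeal, highly deteriorated Domain 4;
* ``bLhr`` — bacterial, Lhr-core only;
* ``bLhr-HTH`` — bacterial, with an additional HTH_42 (PF06224);
* ``Lhr-like`` — Domain 4 absent, any taxon.

"Deteriorated" is quantified as a Domain 4 hit covering less than half
of the profile; the cys-rich motif as >= 4 cysteines within the 120
residues following the Domain 4 end.  Both thresholds are exposed in
:class:`ClassifierParams`.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .records import (FAMILY_LABELS, PF_DOMAIN4, PF_DUF1998, PF_HTH42,
                      PF_INTEIN, PF_RECA1, PF_RECA2, ProfileHit,
                      ProteinRecord)


@dataclass(frozen=True)
class ClassifierParams:
    domain4_intact_min_coverage: float = 0.50
    domain4_report_max_evalue: float = 1e-3
    cys_rich_window: int = 120
    cys_rich_min_count: int = 4

    def __post_init__(self) -> None:
        if self.domain4_intact_min_coverage <= 0 or \
                self.domain4_report_max_evalue <= 0 or \
                self.cys_rich_window <= 0 or self.cys_rich_min_count <= 0:
            raise ValueError("classifier thresholds must be positive")


@dataclass(frozen=True)
class ArchitectureCall:
    protein_id: str
    has_core: bool
    domain4_status: str          # intact | deteriorated | absent
    has_hth42: bool
    has_cys_rich_cterm: bool
    intein_inserted: bool


@dataclass(frozen=True)
class FamilyAssignment:
    protein_id: str
    label: str
    evidence: ArchitectureCall
    cluster_id: int | None = None

    def __post_init__(self) -> None:
        if self.label not in FAMILY_LABELS:
            raise ValueError(f"unknown family label {self.label!r}")


def _best_hit(hits: list[ProfileHit], profile_id: str) -> ProfileHit | None:
    """Best hit for a profile: min E-value, then max coverage, min start."""
    matching = [h for h in hits if h.profile_id == profile_id]
    if not matching:
        return None
    return min(matching, key=lambda h: (h.e_value, -h.coverage, h.q_start))


def call_architecture(protein: ProteinRecord, hits: list[ProfileHit],
                      params: ClassifierParams = ClassifierParams()
                      ) -> ArchitectureCall:
    """Derive the architecture flags for one protein from its hits."""
    foreign = [h.protein_id for h in hits if h.protein_id != protein.protein_id]
    if foreign:
        raise ValueError(
            f"hits reference other proteins: {sorted(set(foreign))}")
    reca1 = _best_hit(hits, PF_RECA1)
    reca2 = _best_hit(hits, PF_RECA2)
    has_core = reca1 is not None and reca2 is not None

    d4_hits = [h for h in hits if h.profile_id == PF_DOMAIN4
               and h.e_value <= params.domain4_report_max_evalue]
    if not d4_hits:
        domain4_status = "absent"
        d4_end = None
    elif any(h.coverage >= params.domain4_intact_min_coverage
             for h in d4_hits):
        domain4_status = "intact"
        d4_end = max(h.q_end for h in d4_hits)
    else:
        domain4_status = "deteriorated"
        d4_end = max(h.q_end for h in d4_hits)

    has_hth42 = any(h.profile_id == PF_HTH42 for h in hits)

    # cys-rich: count C in the window after Domain 4 (or after the last
    # core-domain end when Domain 4 is absent)
    if d4_end is None:
        core_ends = [h.q_end for h in (reca1, reca2) if h is not None]
        anchor = max(core_ends) if core_ends else 0
    else:
        anchor = d4_end
    window = protein.sequence[anchor:anchor + params.cys_rich_window]
    has_cys_rich = window.count("C") >= params.cys_rich_min_count

    core_intervals = [(h.q_start, h.q_end) for h in (reca1, reca2)
                      if h is not None]
    intein = any(
        h.profile_id == PF_INTEIN and
        any(s <= h.q_start and h.q_end <= e for s, e in core_intervals)
        for h in hits)

    return ArchitectureCall(protein.protein_id, has_core, domain4_status,
                            has_hth42, has_cys_rich, intein)


def classify_family(call: ArchitectureCall, taxon_group: str,
                    cluster_id: int | None = None) -> FamilyAssignment:
    """Map one architecture call to its Lhr group.

    Total over (domain4_status x taxon x flags): missing core means
    ``unclassified``; Domain 4 absent means ``Lhr-like`` in any taxon;
    bacterial proteins with Domain 4 present (intact or vestigial) split
    into bLhr-HTH / bLhr on the HTH_42 flag; archaeal/Asgard proteins
    split into aLhr3 (deteriorated) and, when intact, aLhr1 vs aLhr2 on
    the cys-rich flag.
    """
    if not call.has_core:
        label = "unclassified"
    elif call.domain4_status == "absent":
        label = "Lhr-like"
    elif taxon_group == "Bacteria":
        label = "bLhr-HTH" if call.has_hth42 else "bLhr"
    elif call.domain4_status == "deteriorated":
        label = "aLhr3"
    else:
        label = "aLhr1" if call.has_cys_rich_cterm else "aLhr2"
    return FamilyAssignment(call.protein_id, label, call, cluster_id)


def classify_dataset(proteins: list[ProteinRecord],
                     profile_hits: list[ProfileHit],
                     params: ClassifierParams = ClassifierParams(),
                     cluster_of: dict[str, int] | None = None
                     ) -> list[FamilyAssignment]:
    """Per-protein rule-mode classification of a whole dataset."""
    by_protein: dict[str, list[ProfileHit]] = {}
    for h in profile_hits:
        by_protein.setdefault(h.protein_id, []).append(h)
    out = []
    for p in sorted(proteins, key=lambda x: x.protein_id):
        call = call_architecture(p, by_protein.get(p.protein_id, []), params)
        cid = cluster_of.get(p.protein_id) if cluster_of else None
        out.append(classify_family(call, p.taxon_group, cid))
    return out


def classify_by_cluster_consensus(assignments: list[FamilyAssignment],
                                  cluster_of: dict[str, int]
                                  ) -> list[FamilyAssignment]:
    """Relabel each protein with its cluster's majority label.

    Mirrors naming whole subtrees/classes at once; ties broken by the
    lexicographically smallest label.
    """
    votes: dict[int, dict[str, int]] = {}
    for a in assignments:
        cid = cluster_of[a.protein_id]
        votes.setdefault(cid, {})[a.label] = \
            votes.setdefault(cid, {}).get(a.label, 0) + 1
    majority = {cid: min(sorted(v), key=lambda lab: (-v[lab], lab))
                for cid, v in votes.items()}
    return [FamilyAssignment(a.protein_id, majority[cluster_of[a.protein_id]],
                             a.evidence, cluster_of[a.protein_id])
            for a in assignments]


def extract_helicase_core(protein: ProteinRecord,
                          hits: list[ProfileHit]) -> str:
    """Merged RecA1+RecA2 subsequence (tree-building input).

    Takes the best PF00270 and PF00271 hits, merges overlapping
    intervals, and concatenates the covered subsequences in coordinate
    order; the output length equals the size of the interval union.
    """
    reca1 = _best_hit(hits, PF_RECA1)
    reca2 = _best_hit(hits, PF_RECA2)
    if reca1 is None or reca2 is None:
        raise ValueError(
            f"protein {protein.protein_id} lacks a core-domain hit")
    intervals = sorted([(reca1.q_start, reca1.q_end),
                        (reca2.q_start, reca2.q_end)])
    merged: list[tuple[int, int]] = []
    for start, end in intervals:
        if merged and start <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return "".join(protein.sequence[s - 1:e] for s, e in merged)


def filter_sfth(proteins: list[ProteinRecord], hits: list[ProfileHit],
                required: tuple[str, ...] = (PF_RECA1, PF_DUF1998, PF_RECA2),
                max_evalue: float = 1e-3) -> set[str]:
    """Sfth (outgroup) candidates: proteins with all three required domains."""
    profiles_of: dict[str, set[str]] = {}
    for h in hits:
        if h.e_value <= max_evalue:
            profiles_of.setdefault(h.protein_id, set()).add(h.profile_id)
    return {p.protein_id for p in proteins
            if all(r in profiles_of.get(p.protein_id, set())
                   for r in required)}


def tabulate_paralog_counts(assignments: list[FamilyAssignment],
                            genome_of: dict[str, str]) -> pd.DataFrame:
    """Per-genome x per-family paralog count table.

    Rows are genomes (all genomes in ``genome_of``, including those
    without classified proteins), columns the six family labels; the
    ``unclassified`` bucket is excluded so row sums equal each genome's
    classified Lhr proteins.
    """
    families = [lab for lab in FAMILY_LABELS if lab != "unclassified"]
    genomes = sorted(set(genome_of.values()))
    table = pd.DataFrame(0, index=genomes, columns=families)
    for a in assignments:
        if a.label == "unclassified":
            continue
        table.loc[genome_of[a.protein_id], a.label] += 1
    return table
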