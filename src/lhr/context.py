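"""Gene-neighborhood (microsynteny) analysis.

For each focal gene, the neighborhood is the set of genes on the same
contig within a boundary-to-boundary distance below the window (default
4000 bp).  Conservation tables report, per (focal family, neighbor
annotation profile), the fraction of genomes in which the profile is
found in-window, with side (upstream/downstream of the focal gene on
its own strand) and orientation (same/reverse strand) breakdowns.
Co-occurrence contingency over two focal families flags mutually
exclusive neighbors — the pattern the metallophosphoesterase (MPE) gene
shows around archaeal *lhr* genes.

Distances are measured between nearest interval boundaries (0 for
overlapping genes); contigs are linear.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .records import GeneFeature


@dataclass(frozen=True)
class ContextParams:
    window_bp: int = 4000

    def __post_init__(self) -> None:
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")


@dataclass(frozen=True)
class NeighborGene:
    feature: GeneFeature
    distance_bp: int
    side: str          # upstream | downstream | overlapping
    same_strand: bool


def gene_gap(a: GeneFeature, b: GeneFeature) -> int:
    """bp between nearest interval ends; 0 when the intervals overlap."""
    if a.start <= b.end and b.start <= a.end:
        return 0
    return b.start - a.end if a.end < b.start else a.start - b.end


def neighborhood(features: list[GeneFeature], focal: GeneFeature,
                 params: ContextParams = ContextParams()
                 ) -> list[NeighborGene]:
    """Genes within the window of the focal gene, same contig only.

    Side is defined on the focal gene's own strand: a gene 5' of the
    focal gene is upstream (for a ``+`` focal gene, smaller
    coordinates).
    """
    if focal not in features:
        raise ValueError("focal gene not among the supplied features")
    out: list[NeighborGene] = []
    for g in features:
        if g == focal or g.genome_id != focal.genome_id \
                or g.contig_id != focal.contig_id:
            continue
        gap = gene_gap(focal, g)
        if gap >= params.window_bp:
            continue
        if gap == 0:
            side = "overlapping"
        else:
            before = g.end < focal.start
            if focal.strand == "+":
                side = "upstream" if before else "downstream"
            else:
                side = "downstream" if before else "upstream"
        out.append(NeighborGene(g, gap, side, g.strand == focal.strand))
    out.sort(key=lambda n: (n.distance_bp, n.feature.start))
    return out


@dataclass
class ConservationTable:
    """Per (focal family, neighbor profile) cross-genome conservation."""

    table: pd.DataFrame   # columns: family, profile, n_genomes_with,
                          # n_genomes_total, fraction, n_upstream,
                          # n_downstream, n_same_strand, n_reverse_strand


def conservation_profile(neighborhoods: dict[str, list[NeighborGene]],
                         focal_family_of: dict[str, str],
                         genome_of: dict[str, str]) -> ConservationTable:
    """Tabulate neighbor-profile conservation across genomes.

    ``neighborhoods`` maps focal gene/protein id → its neighbor list;
    a genome counts as conserving a profile for a family when any of
    its focal genes of that family has the profile in-window.
    """
    genomes_of_family: dict[str, set[str]] = {}
    for focal_id, family in focal_family_of.items():
        genomes_of_family.setdefault(family, set()).add(genome_of[focal_id])

    rows: dict[tuple[str, str], dict] = {}
    seen: dict[tuple[str, str, str], bool] = {}
    for focal_id, neighbors in neighborhoods.items():
        family = focal_family_of[focal_id]
        genome = genome_of[focal_id]
        for nb in neighbors:
            for profile in nb.feature.product_profile_ids:
                key = (family, profile)
                row = rows.setdefault(key, {
                    "n_genomes_with": 0, "n_upstream": 0, "n_downstream": 0,
                    "n_same_strand": 0, "n_reverse_strand": 0})
                if not seen.get((family, profile, genome), False):
                    seen[(family, profile, genome)] = True
                    row["n_genomes_with"] += 1
                row["n_upstream" if nb.side == "upstream"
                    else "n_downstream"] += 1
                row["n_same_strand" if nb.same_strand
                    else "n_reverse_strand"] += 1
    records = []
    for (family, profile), row in rows.items():
        total = len(genomes_of_family[family])
        records.append({
            "family": family, "profile": profile,
            "n_genomes_with": row["n_genomes_with"],
            "n_genomes_total": total,
            "fraction": row["n_genomes_with"] / total,
            "n_upstream": row["n_upstream"],
            "n_downstream": row["n_downstream"],
            "n_same_strand": row["n_same_strand"],
            "n_reverse_strand": row["n_reverse_strand"]})
    df = pd.DataFrame(records, columns=[
        "family", "profile", "n_genomes_with", "n_genomes_total", "fraction",
        "n_upstream", "n_downstream", "n_same_strand", "n_reverse_strand"])
    if not df.empty:
        df = df.sort_values(["fraction", "family", "profile"],
                            ascending=[False, True, True],
                            ignore_index=True)
    return ConservationTable(df)


@dataclass
class CooccurrenceSummary:
    family_a: str
    family_b: str
    profile: str
    a_only: int
    b_only: int
    both: int
    neither: int
    mutually_exclusive: bool


def cooccurrence_summary(neighborhoods: dict[str, list[NeighborGene]],
                         focal_family_of: dict[str, str],
                         genome_of: dict[str, str],
                         family_a: str, family_b: str,
                         profile: str) -> CooccurrenceSummary:
    """2x2 genome contingency of a neighbor profile near two families.

    Genomes considered are those carrying a focal gene of either
    family; the mutual-exclusivity flag is set when the "both" cell is
    zero while both exclusive cells are non-zero.
    """
    near: dict[str, set[str]] = {family_a: set(), family_b: set()}
    genomes: set[str] = set()
    for focal_id, family in focal_family_of.items():
        if family not in (family_a, family_b):
            continue
        genome = genome_of[focal_id]
        genomes.add(genome)
        for nb in neighborhoods.get(focal_id, []):
            if profile in nb.feature.product_profile_ids:
                near[family].add(genome)
    both = len(near[family_a] & near[family_b])
    a_only = len(near[family_a] - near[family_b])
    b_only = len(near[family_b] - near[family_a])
    neither = len(genomes) - both - a_only - b_only
    return CooccurrenceSummary(
        family_a, family_b, profile, a_only, b_only, both, neither,
        mutually_exclusive=(both == 0 and a_only > 0 and b_only > 0))


def write_conservation_tsv(table: ConservationTable, path: str) -> None:
    table.table.to_csv(path, sep="\t", index=False)


def write_itol_domains(neighborhoods: dict[str, list[NeighborGene]],
                       genome_of: dict[str, str], path: str,
                       window_bp: int = 4000) -> None:
    """iTOL DATASET_DOMAINS-style annotation keyed by genome."""
    with open(path, "w") as fh:
        fh.write("DATASET_DOMAINS\nSEPARATOR TAB\n"
                 "DATASET_LABEL\tgene_neighborhoods\nCOLOR\t#888888\nDATA\n")
        for focal_id in sorted(neighborhoods):
            genome = genome_of[focal_id]
            shapes = [
                f"RE|{nb.feature.start}|{nb.feature.end}|#1f77b4|"
                f"{','.join(nb.feature.product_profile_ids) or 'unannotated'}"
                for nb in neighborhoods[focal_id]]
            fh.write("\t".join([genome, str(2 * window_bp)] + shapes) + "\n")
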