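"""Core record types shared across the pipeline.

Every stage of the Lhr classification pipeline exchanges one of three
plain records: a protein with its proteome-of-origin metadata, a
profile (Pfam/COG-style) hit on a protein, and a gene feature placing a
coding sequence on a contig.  They are deliberately thin frozen
dataclasses so that fixtures round-trip byte-identically through the
text formats in :mod:`lhr.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: The three taxon groups the classifier distinguishes.
TAXON_GROUPS = ("Archaea", "Bacteria", "Asgard")

# Pfam/COG profile identifiers used throughout (stand-ins for the real
# database entries carrying the same accession strings).
PF_RECA1 = "PF00270"       # DEAD — RecA1 ATPase lobe
PF_RECA2 = "PF00271"       # Helicase_C — RecA2 lobe
PF_DOMAIN4 = "PF08494"     # DEAD-associated domain, Lhr-specific Domain 4
PF_HTH42 = "PF06224"       # HTH_42 helix-turn-helix
PF_DUF1998 = "PF09369"     # DUF1998, required for the Sfth outgroup family
PF_INTEIN = "PF14890"      # intein splicing domain
PF_LAGLIDADG = "PF14528"   # LAGLIDADG homing endonuclease
COG_LHR = "COG1201"        # Lhr-like helicase profile (candidate search)
COG_SFTH = "COG1205"       # Sfth helicase profile (outgroup search)

#: Family labels assigned by the architecture classifier.
FAMILY_LABELS = ("aLhr1", "aLhr2", "aLhr3", "bLhr", "bLhr-HTH", "Lhr-like",
                 "unclassified")


@dataclass(frozen=True, order=True)
class ProteinRecord:
    """One protein with its proteome-of-origin metadata.

    ``(species_key, strain_key)`` identifies the proteome; ``taxon_group``
    is one of :data:`TAXON_GROUPS`.
    """

    protein_id: str
    species_key: str
    strain_key: str
    taxon_group: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.protein_id!r} has empty sequence")
        if self.taxon_group not in TAXON_GROUPS:
            raise ValueError(
                f"taxon_group {self.taxon_group!r} not in {TAXON_GROUPS}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def genome_id(self) -> str:
        return f"{self.species_key}{self.strain_key}"


@dataclass(frozen=True, order=True)
class ProfileHit:
    """A protein-vs-profile match (domtblout-style row).

    Coordinates are 1-based inclusive on the protein; ``coverage`` is the
    fraction of the profile matched, in [0, 1].
    """

    protein_id: str
    profile_id: str
    e_value: float
    bit_score: float
    q_start: int
    q_end: int
    profile_len: int
    coverage: float

    def __post_init__(self) -> None:
        if not (1 <= self.q_start <= self.q_end):
            raise ValueError(
                f"bad hit coordinates {self.q_start}..{self.q_end} "
                f"on {self.protein_id}")
        if not (0.0 <= self.coverage <= 1.0):
            raise ValueError(f"coverage {self.coverage} outside [0, 1]")
        if self.e_value < 0:
            raise ValueError("negative E-value")


@dataclass(frozen=True, order=True)
class GeneFeature:
    """A CDS placed on a contig of a genome.

    1-based inclusive coordinates, ``strand`` in {'+', '-'};
    ``product_profile_ids`` carries the functional annotation labels
    (TIGR/COG stand-ins) of the gene product.
    """

    genome_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    product_id: str
    product_profile_ids: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"bad feature interval {self.start}..{self.end} "
                f"({self.product_id})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)
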