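"""Synthetic Lhr-family datasets with planted ground truth.

The generator emulates the statistical structure the classification
pipeline assumes in real proteomes: several protein families descended
from distinct ancestors (controlled within- and between-family percent
identity), per-family Pfam-style domain architectures (helicase core
PF00270+PF00271, Domain 4 intact/deteriorated/absent, optional HTH_42,
optional cysteine-rich C-terminus), several species each with one or
more strains, and gene neighborhoods with a conserved neighbor gene
planted near focal genes at a controlled frequency.

Identity calibration
--------------------
``mutate_sequence`` substitutes each position independently with
probability ``1 - target_identity`` (uniform over the alternative
residues), so the *expected identity to the input* equals the target.
Two sequences independently mutated from a common ancestor with keep
probability ``q`` agree at a position with probability
``q^2 + (1-q)^2 / (A-1)`` (``A`` = alphabet size: both kept, or both
mutated to the same residue).  ``generate_family_dataset`` inverts this
so that the *pairwise* identity among family members matches
``within_identity`` and the identity between family ancestors matches
``between_identity``.

Substitutions are drawn over a cysteine-free alphabet and cys-rich
tails carry explicitly planted cysteine runs, keeping the truth
architecture deterministically on one side of the classifier's
cysteine-count threshold.
"""

from __future__ import annotations

import hashlib
import math
import os
from dataclasses import dataclass, field, replace

import numpy as np

from . import io as lhr_io
from .records import (COG_LHR, PF_DOMAIN4, PF_HTH42, PF_RECA1, PF_RECA2,
                      GeneFeature, ProfileHit, ProteinRecord)

#: 20 standard amino acids.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
#: Generator alphabet: cysteine excluded so cys-rich tails are planted,
#: never accidental.
AA_NO_CYS = AA_ALPHABET.replace("C", "")

#: Conserved-neighbor annotation label (metallophosphoesterase stand-in).
NEIGHBOR_PROFILE = "TIGR0024"
#: Uninformative background-gene annotation label.
BACKGROUND_PROFILE = "COG9999"

DOMAIN4_STATES = ("intact", "deteriorated", "absent")


@dataclass(frozen=True)
class ArchitectureSpec:
    """Per-family domain-architecture specification.

    ``domain4`` is one of ``intact`` / ``deteriorated`` / ``absent``;
    ``neighbor_prob``, if set, overrides the dataset-wide conserved
    neighbor probability for this family's focal genes.
    """

    name: str
    domain4: str = "intact"
    hth42: bool = False
    cys_rich: bool = False
    taxon: str = "Archaea"
    neighbor_prob: float | None = None

    def __post_init__(self) -> None:
        if self.domain4 not in DOMAIN4_STATES:
            raise ValueError(f"domain4 must be one of {DOMAIN4_STATES}")


def default_architectures() -> tuple[ArchitectureSpec, ...]:
    """The six Lhr groups, one family each, in canonical order."""
    return (
        ArchitectureSpec("aLhr1", "intact", hth42=False, cys_rich=True,
                         taxon="Archaea"),
        ArchitectureSpec("aLhr2", "intact", hth42=False, cys_rich=False,
                         taxon="Archaea"),
        ArchitectureSpec("aLhr3", "deteriorated", hth42=False, cys_rich=False,
                         taxon="Archaea"),
        ArchitectureSpec("bLhr", "intact", hth42=False, cys_rich=False,
                         taxon="Bacteria"),
        ArchitectureSpec("bLhr-HTH", "intact", hth42=True, cys_rich=False,
                         taxon="Bacteria"),
        ArchitectureSpec("Lhr-like", "absent", hth42=False, cys_rich=False,
                         taxon="Bacteria"),
    )


def expected_label(spec: ArchitectureSpec) -> str:
    """Truth family label implied by an architecture spec.

    Small, independent restatement of the published naming rules used to
    plant ground truth (the classifier under test re-derives labels from
    realized profile hits, not from this function).
    """
    if spec.domain4 == "absent":
        return "Lhr-like"
    if spec.taxon == "Bacteria":
        return "bLhr-HTH" if spec.hth42 else "bLhr"
    if spec.domain4 == "deteriorated":
        return "aLhr3"
    return "aLhr1" if spec.cys_rich else "aLhr2"


@dataclass(frozen=True)
class SynthParams:
    """Study conditions for one synthetic dataset.

    Defaults are the planted-recovery conditions exercised throughout:
    six families of sizes 20/12/8/4/3/2, pairwise within-family identity
    0.85 and between-family identity 0.25, twenty species with one
    strain each, and a conserved neighbor planted at frequency 0.6.

    Family members are placed in distinct species (member i goes to
    species ``i mod n_species``), mirroring the orthologous-group
    structure a best-bidirectional-hit graph assumes: one family member
    per genome.  Families larger than ``n_species`` wrap around and
    produce same-species paralogs, which BBH edges then cannot link.
    """

    n_families: int = 6
    family_sizes: tuple[int, ...] = (20, 12, 8, 4, 3, 2)
    within_identity: float = 0.85
    between_identity: float = 0.25
    core_length: int = 280
    architectures: tuple[ArchitectureSpec, ...] = field(
        default_factory=default_architectures)
    n_species: int = 20
    strains_per_species: int = 1
    neighbor_conservation_prob: float = 0.6
    window_gene_spacing: int = 200
    seed: int = 7
    #: Optional (family_index_a, family_index_b): per genome the neighbor
    #: is planted near one family's focal genes XOR the other's.
    neighbor_xor_families: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if len(self.family_sizes) != self.n_families:
            raise ValueError("len(family_sizes) must equal n_families")
        if len(self.architectures) != self.n_families:
            raise ValueError("need one ArchitectureSpec per family")
        if any(s <= 0 for s in self.family_sizes):
            raise ValueError("family sizes must be positive")
        if not (0.0 < self.within_identity <= 1.0):
            raise ValueError("within_identity must be in (0, 1]")
        if not (0.0 < self.between_identity < 1.0):
            raise ValueError("between_identity must be in (0, 1)")
        if self.within_identity <= self.between_identity:
            raise ValueError("within_identity must exceed between_identity")
        if not (0.0 <= self.neighbor_conservation_prob <= 1.0):
            raise ValueError("neighbor_conservation_prob must be in [0, 1]")
        if self.n_species < 1 or self.strains_per_species < 1:
            raise ValueError("need at least one species and one strain")


@dataclass
class SynthDataset:
    """A generated dataset plus its planted truth."""

    proteins: list[ProteinRecord]
    profile_hits: list[ProfileHit]
    features: list[GeneFeature]
    truth_labels: dict[str, str]
    truth_clusters: dict[str, int]

    def validate(self) -> None:
        lengths = {p.protein_id: p.length for p in self.proteins}
        for pid in lengths:
            if pid not in self.truth_labels:
                raise ValueError(f"protein {pid} lacks a truth label")
        for h in self.profile_hits:
            if h.q_end > lengths[h.protein_id]:
                raise ValueError(
                    f"hit {h.profile_id} exceeds length of {h.protein_id}")


# ---------------------------------------------------------------------------
# mutation machinery

def mutate_sequence(seq: str, target_identity: float, rng: np.random.Generator,
                    alphabet: str = AA_ALPHABET) -> str:
    """Substitute positions i.i.d. so expected identity equals the target.

    A substituted position never keeps its residue (uniform draw over the
    alternatives), so the expected fraction of identical positions is
    exactly ``target_identity``.
    """
    if not seq:
        raise ValueError("cannot mutate an empty sequence")
    if not (0.0 < target_identity <= 1.0):
        raise ValueError("target_identity must be in (0, 1]")
    mutate_mask = rng.random(len(seq)) >= target_identity
    if not mutate_mask.any():
        return seq
    chars = list(seq)
    idx = np.flatnonzero(mutate_mask)
    draws = rng.random(idx.size)
    for k, i in enumerate(idx):
        alts = [a for a in alphabet if a != chars[i]]
        chars[i] = alts[int(draws[k] * len(alts)) % len(alts)]
    return "".join(chars)


def keep_probability_for_pairwise_identity(pairwise_identity: float,
                                           alphabet_size: int) -> float:
    """Invert q^2 + (1-q)^2/(A-1) = t for the per-branch keep probability."""
    c = 1.0 / (alphabet_size - 1)
    disc = 4 * c * c - 4 * (1 + c) * (c - pairwise_identity)
    q = (2 * c + math.sqrt(disc)) / (2 * (1 + c))
    return min(1.0, q)


def _stream(master_seed: int, *keys: str) -> np.random.Generator:
    """Per-entity RNG derived from the master seed by stable id hashing."""
    digest = hashlib.blake2b("/".join(keys).encode(), digest_size=8).digest()
    return np.random.default_rng(
        np.random.SeedSequence([master_seed, int.from_bytes(digest, "big")]))


# ---------------------------------------------------------------------------
# architecture geometry

@dataclass(frozen=True)
class _Layout:
    """Planted domain coordinates (1-based inclusive) for one family."""

    reca1: tuple[int, int]
    reca2: tuple[int, int]
    domain4: tuple[int, int] | None   # realized hit interval
    hth42: tuple[int, int] | None
    cys_positions: tuple[int, ...]
    length: int


_LINKER = 20
_D4_PROFILE_LEN = 120
_D4_DETERIORATED_COVERAGE = 0.30
_HTH_LEN = 60
_CYS_WINDOW = 120
_N_PLANTED_CYS = 6


def _family_layout(spec: ArchitectureSpec, core_length: int) -> _Layout:
    reca1_len = core_length // 2
    reca2_len = core_length - reca1_len
    reca1 = (1, reca1_len)
    reca2 = (reca1_len + _LINKER + 1, reca1_len + _LINKER + reca2_len)
    cursor = reca2[1] + 10
    domain4 = None
    if spec.domain4 == "intact":
        domain4 = (cursor + 1, cursor + _D4_PROFILE_LEN)
    elif spec.domain4 == "deteriorated":
        span = int(round(_D4_PROFILE_LEN * _D4_DETERIORATED_COVERAGE))
        domain4 = (cursor + 1, cursor + span)
    tail_anchor = domain4[1] if domain4 else reca2[1]
    hth = None
    if spec.hth42:
        hth = (tail_anchor + 11, tail_anchor + 10 + _HTH_LEN)
    cys: tuple[int, ...] = ()
    if spec.cys_rich:
        # evenly spread planted cysteines inside the classifier's window
        step = _CYS_WINDOW // _N_PLANTED_CYS
        cys = tuple(tail_anchor + 5 + k * step for k in range(_N_PLANTED_CYS))
    end = max(reca2[1], domain4[1] if domain4 else 0,
              hth[1] if hth else 0, max(cys) if cys else 0)
    return _Layout(reca1, reca2, domain4, hth, cys, end + 20)


def _family_hits(pid: str, spec: ArchitectureSpec, layout: _Layout,
                 core_length: int) -> list[ProfileHit]:
    reca1_len = layout.reca1[1] - layout.reca1[0] + 1
    reca2_len = layout.reca2[1] - layout.reca2[0] + 1
    hits = [
        ProfileHit(pid, COG_LHR, 1e-60, 250.0, layout.reca1[0],
                   layout.reca2[1], core_length + _LINKER + _D4_PROFILE_LEN,
                   0.80),
        ProfileHit(pid, PF_RECA1, 1e-50, 200.0, *layout.reca1,
                   profile_len=reca1_len, coverage=1.0),
        ProfileHit(pid, PF_RECA2, 1e-48, 190.0, *layout.reca2,
                   profile_len=reca2_len, coverage=1.0),
    ]
    if layout.domain4 is not None:
        span = layout.domain4[1] - layout.domain4[0] + 1
        cov = span / _D4_PROFILE_LEN
        evalue = 1e-30 if spec.domain4 == "intact" else 1e-5
        bit = 120.0 if spec.domain4 == "intact" else 35.0
        hits.append(ProfileHit(pid, PF_DOMAIN4, evalue, bit, *layout.domain4,
                               profile_len=_D4_PROFILE_LEN, coverage=cov))
    if layout.hth42 is not None:
        hits.append(ProfileHit(pid, PF_HTH42, 1e-20, 80.0, *layout.hth42,
                               profile_len=_HTH_LEN, coverage=1.0))
    return hits


# ---------------------------------------------------------------------------
# dataset generation

def generate_family_dataset(params: SynthParams) -> SynthDataset:
    """Generate proteins, profile hits, gene features and planted truth.

    Each family descends from its own ancestor; ancestors descend from a
    single root.  Keep probabilities are calibrated so pairwise identity
    within families ≈ ``within_identity`` and between family ancestors
    ≈ ``between_identity``.  Fully reproducible under ``params.seed``.
    """
    A = len(AA_NO_CYS)
    q_within = keep_probability_for_pairwise_identity(params.within_identity, A)
    q_between = keep_probability_for_pairwise_identity(
        params.between_identity, A)

    layouts = [_family_layout(spec, params.core_length)
               for spec in params.architectures]
    max_len = max(layout.length for layout in layouts)

    root_rng = _stream(params.seed, "root")
    root = "".join(AA_NO_CYS[i] for i in
                   root_rng.integers(0, A, size=max_len))

    proteins: list[ProteinRecord] = []
    profile_hits: list[ProfileHit] = []
    truth_labels: dict[str, str] = {}
    truth_clusters: dict[str, int] = {}
    genome_members: dict[tuple[str, str],
                         list[tuple[ProteinRecord, ArchitectureSpec,
                                    int]]] = {}

    for fi, (size, spec) in enumerate(zip(params.family_sizes,
                                          params.architectures)):
        layout = layouts[fi]
        ancestor = mutate_sequence(root[:layout.length], q_between,
                                   _stream(params.seed, "fam", str(fi)),
                                   alphabet=AA_NO_CYS)
        label = expected_label(spec)
        for mi in range(size):
            si = mi % params.n_species
            member = mutate_sequence(
                ancestor, q_within,
                _stream(params.seed, "prot", str(fi), str(mi)),
                alphabet=AA_NO_CYS)
            if layout.cys_positions:
                chars = list(member)
                for pos in layout.cys_positions:
                    chars[pos - 1] = "C"
                member = "".join(chars)
            for st in range(params.strains_per_species):
                species_key = f"S{si:02d}"
                strain_key = f"A{st:02d}"
                pid = f"{species_key}{strain_key}.F{fi}M{mi:02d}"
                rec = ProteinRecord(pid, species_key, strain_key,
                                    spec.taxon, member)
                proteins.append(rec)
                profile_hits.extend(
                    _family_hits(pid, spec, layout, params.core_length))
                truth_labels[pid] = label
                truth_clusters[pid] = fi
                genome_members.setdefault((species_key, strain_key),
                                          []).append((rec, spec, fi))

    features = _tile_genomes(params, genome_members)
    dataset = SynthDataset(proteins, profile_hits, features,
                           truth_labels, truth_clusters)
    dataset.validate()
    return dataset


_BLOCK_GAP = 6000      # > context window: keeps neighborhoods independent
_NEIGHBOR_LEN = 900
_BACKGROUND_LEN = 600


def _tile_genomes(params: SynthParams, genome_members) -> list[GeneFeature]:
    """One contig per genome, + strand, focal-gene blocks far apart.

    Each block is [conserved neighbor?] → focal gene → background gene,
    with ``window_gene_spacing`` bp between genes; blocks are separated
    by a gap larger than the 4 kb context window so neighborhoods of
    different focal genes never overlap.
    """
    features: list[GeneFeature] = []
    for (species_key, strain_key), members in sorted(genome_members.items()):
        genome_id = f"{species_key}{strain_key}"
        rng = _stream(params.seed, "genome", genome_id)
        xor_side: int | None = None
        if params.neighbor_xor_families is not None:
            xor_side = int(rng.random() < 0.5)
        pos = 1
        for rec, spec, fi in members:
            if params.neighbor_xor_families is not None:
                fa, fb = params.neighbor_xor_families
                plant = (fi == (fa, fb)[xor_side]) if fi in (fa, fb) else False
                draw = 0.0  # deterministic in XOR mode
            else:
                prob = (spec.neighbor_prob
                        if spec.neighbor_prob is not None
                        else params.neighbor_conservation_prob)
                draw = rng.random()
                plant = draw < prob
            if plant:
                features.append(GeneFeature(
                    genome_id, "C1", pos, pos + _NEIGHBOR_LEN - 1, "+",
                    f"{rec.protein_id}.nbr", (NEIGHBOR_PROFILE,)))
                pos += _NEIGHBOR_LEN + params.window_gene_spacing
            gene_len = 3 * rec.length + 3
            features.append(GeneFeature(
                genome_id, "C1", pos, pos + gene_len - 1, "+",
                rec.protein_id, ()))
            pos += gene_len + params.window_gene_spacing
            features.append(GeneFeature(
                genome_id, "C1", pos, pos + _BACKGROUND_LEN - 1, "+",
                f"{rec.protein_id}.bg", (BACKGROUND_PROFILE,)))
            pos += _BACKGROUND_LEN + _BLOCK_GAP
    return features


# ---------------------------------------------------------------------------
# fixture bundle round trip

BUNDLE_FILES = ("proteins.fasta", "profile_hits.tsv", "features.gff3",
                "truth.tsv")


def write_fixture_bundle(dataset: SynthDataset, destination: str
                         ) -> dict[str, str]:
    """Write the four fixture files; returns a manifest name → path."""
    lhr_io.ensure_dir(destination)
    paths = {name: os.path.join(destination, name) for name in BUNDLE_FILES}
    lhr_io.write_proteins_fasta(dataset.proteins, paths["proteins.fasta"])
    lhr_io.write_profile_hits(dataset.profile_hits, paths["profile_hits.tsv"])
    lhr_io.write_gff3(dataset.features, paths["features.gff3"])
    lhr_io.write_truth(dataset.truth_labels, dataset.truth_clusters,
                       paths["truth.tsv"])
    return paths


def read_fixture_bundle(directory: str) -> SynthDataset:
    """Inverse of :func:`write_fixture_bundle`."""
    proteins = lhr_io.read_proteins_fasta(
        os.path.join(directory, "proteins.fasta"))
    hits = lhr_io.read_profile_hits(
        os.path.join(directory, "profile_hits.tsv"))
    features = lhr_io.read_gff3(os.path.join(directory, "features.gff3"))
    labels, clusters = lhr_io.read_truth(os.path.join(directory, "truth.tsv"))
    return SynthDataset(proteins, hits, features, labels, clusters)
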