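"""Exact local pairwise alignment with Karlin–Altschul E-values.

Stand-in for the all-against-all blastp step: full affine-gap
Smith–Waterman (no seeding or banding heuristics) producing the score,
percent identity and E-value fields the homology-graph builder
consumes.  The dynamic programme itself runs through
Bio.Align.PairwiseAligner in local mode, which computes the optimal
affine-gap local alignment exactly; identity bookkeeping, the E-value
model and the tabular interface live here.

Conventions
-----------
* Gap of length k costs ``gap_open + (k-1) * gap_extend`` (both
  negative), defaults -11/-1 on BLOSUM62.
* ``identity_pct`` = 100 x identical columns / alignment length, gap
  columns included (blastp ``pident`` convention).
* ``E = K * m * n * exp(-lambda * S)``; reported E-values are floored at
  1e-180 so that -log10 E stays finite for edge weighting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .records import ProteinRecord

#: Reporting floor: E-values below this are clamped (keeps -log10 E finite).
EVALUE_FLOOR = 1e-180

_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix plus affine gap penalties (both negative)."""

    matrix_name: str = "BLOSUM62"
    gap_open: int = -11
    gap_extend: int = -1

    def __post_init__(self) -> None:
        if self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("gap penalties must be negative")


@dataclass(frozen=True)
class KarlinAltschulParams:
    """Parameters of the extreme-value score statistics.

    Defaults are the classical ungapped BLOSUM62 values (lambda = 0.267,
    K = 0.041); the search space is the product of the two sequence
    lengths unless set explicitly.
    """

    lam: float = 0.267
    K: float = 0.041
    search_space_m: int | None = None
    search_space_n: int | None = None

    def __post_init__(self) -> None:
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("lambda and K must be positive")


@dataclass(frozen=True)
class PairwiseHit:
    """One local alignment in blastp-like terms (1-based coordinates)."""

    query_id: str
    subject_id: str
    raw_score: int
    bit_score: float
    e_value: float
    identity_pct: float
    aln_len: int
    q_start: int = 0
    q_end: int = 0
    s_start: int = 0
    s_end: int = 0


@lru_cache(maxsize=None)
def _aligner(scheme: ScoringScheme) -> Align.PairwiseAligner:
    matrix = substitution_matrices.load(scheme.matrix_name)
    if "X" in matrix.alphabet:
        # unknown residue scores 0 against everything
        xi = matrix.alphabet.index("X")
        matrix[xi, :] = 0.0
        matrix[:, xi] = 0.0
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = float(scheme.gap_open)
    aligner.extend_gap_score = float(scheme.gap_extend)
    return aligner


def _sanitize(seq: str) -> str:
    seq = seq.upper()
    if all(c in _STANDARD_AA for c in seq):
        return seq
    return "".join(c if c in _STANDARD_AA else "X" for c in seq)


def align_local(a: str, b: str, scheme: ScoringScheme = ScoringScheme(),
                ka: KarlinAltschulParams = KarlinAltschulParams(),
                query_id: str = "query", subject_id: str = "subject"
                ) -> PairwiseHit:
    """Optimal affine-gap local alignment of two amino-acid sequences.

    Returns an empty hit (raw_score 0, aln_len 0) when no positive-scoring
    local alignment exists, as the local-alignment definition forces.
    """
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    a_s, b_s = _sanitize(a), _sanitize(b)
    aligner = _aligner(scheme)
    m = ka.search_space_m if ka.search_space_m is not None else len(a)
    n = ka.search_space_n if ka.search_space_n is not None else len(b)
    score = aligner.score(a_s, b_s)
    if score <= 0:
        return PairwiseHit(query_id, subject_id, 0,
                           bit_score=_bit_score(0, ka),
                           e_value=_evalue(0, ka, m, n),
                           identity_pct=0.0, aln_len=0)
    # canonicalize the pair so co-optimal alignment choice (and hence
    # identity/length bookkeeping) is invariant under argument swap
    swapped = a_s > b_s
    first, second = (b_s, a_s) if swapped else (a_s, b_s)
    aln = aligner.align(first, second)[0]
    counts = aln.counts()
    aln_len = aln.length
    identity_pct = 100.0 * counts.identities / aln_len if aln_len else 0.0
    raw = int(round(score))
    f0, f1 = int(aln.coordinates[0][0]), int(aln.coordinates[0][-1])
    g0, g1 = int(aln.coordinates[1][0]), int(aln.coordinates[1][-1])
    (q0, q1, s0, s1) = (g0, g1, f0, f1) if swapped else (f0, f1, g0, g1)
    return PairwiseHit(
        query_id, subject_id, raw,
        bit_score=_bit_score(raw, ka),
        e_value=_evalue(raw, ka, m, n),
        identity_pct=identity_pct, aln_len=aln_len,
        q_start=q0 + 1, q_end=q1, s_start=s0 + 1, s_end=s1)


def _evalue(raw_score: int, ka: KarlinAltschulParams, m: int, n: int) -> float:
    e = ka.K * m * n * math.exp(-ka.lam * raw_score)
    return max(e, EVALUE_FLOOR)


def _bit_score(raw_score: int, ka: KarlinAltschulParams) -> float:
    return (ka.lam * raw_score - math.log(ka.K)) / math.log(2.0)


def evalue_from_score(raw_score: int, ka: KarlinAltschulParams) -> float:
    """E = K * m * n * exp(-lambda * S); strictly decreasing in S."""
    if ka.search_space_m is None or ka.search_space_n is None:
        raise ValueError("search space m and n must be set")
    return ka.K * ka.search_space_m * ka.search_space_n * math.exp(
        -ka.lam * raw_score)


def all_vs_all(proteins: list[ProteinRecord],
               scheme: ScoringScheme = ScoringScheme(),
               ka: KarlinAltschulParams = KarlinAltschulParams()
               ) -> list[PairwiseHit]:
    """All-against-all local alignments, one hit per ordered pair.

    Self-pairs are excluded; pairs without a positive-scoring alignment
    are dropped.  The aligner is symmetric, so each unordered pair is
    aligned once and reported in both directions.  Output is sorted by
    (query_id, e_value, subject_id).
    """
    ids = [p.protein_id for p in proteins]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate protein ids in all_vs_all input")
    hits: list[PairwiseHit] = []
    ordered = sorted(proteins, key=lambda p: p.protein_id)
    for i, p in enumerate(ordered):
        for q in ordered[i + 1:]:
            fwd = align_local(p.sequence, q.sequence, scheme, ka,
                              query_id=p.protein_id, subject_id=q.protein_id)
            if fwd.raw_score <= 0:
                continue
            rev = PairwiseHit(
                q.protein_id, p.protein_id, fwd.raw_score, fwd.bit_score,
                fwd.e_value, fwd.identity_pct, fwd.aln_len,
                q_start=fwd.s_start, q_end=fwd.s_end,
                s_start=fwd.q_start, s_end=fwd.q_end)
            hits.extend((fwd, rev))
    hits.sort(key=lambda h: (h.query_id, h.e_value, h.subject_id))
    return hits


def mean_identity(hits: list[PairwiseHit],
                  group_of: dict[str, int]) -> tuple[float, float]:
    """Mean identity_pct of within-group vs between-group hits."""
    within = [h.identity_pct for h in hits
              if group_of[h.query_id] == group_of[h.subject_id]]
    between = [h.identity_pct for h in hits
               if group_of[h.query_id] != group_of[h.subject_id]]
    w = float(np.mean(within)) if within else float("nan")
    b = float(np.mean(between)) if between else float("nan")
    return w, b
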