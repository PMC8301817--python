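"""Readers and writers for the plain-text formats the pipeline exchanges.

Formats
-------
* proteins FASTA — one record per protein; the description carries
  ``species= strain= taxon=`` key-value metadata so a fixture round-trips.
* profile_hits.tsv — domtblout-like dialect with columns
  (protein_id, profile_id, e_value, bit_score, q_start, q_end,
  profile_len, coverage); tab-separated, 1-based inclusive coordinates.
* features.gff3 — ``##gff-version 3``, CDS features with ``ID=``,
  ``genome_id=`` and ``product_profile=`` (comma-separated) attributes.
* truth.tsv — (protein_id, family_label, cluster_id) planted ground truth.
* pairwise hits TSV — the 12 standard outfmt-6 columns.
* graph edge list TSV — (node_a, node_b, weight, identity_pct) — and ABC
  (node node weight) for interoperability with external MCL tooling.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import GeneFeature, ProfileHit, ProteinRecord

PROFILE_HIT_COLUMNS = ["protein_id", "profile_id", "e_value", "bit_score",
                       "q_start", "q_end", "profile_len", "coverage"]
TRUTH_COLUMNS = ["protein_id", "family_label", "cluster_id"]
OUTFMT6_COLUMNS = ["qseqid", "sseqid", "pident", "length", "mismatch",
                   "gapopen", "qstart", "qend", "sstart", "send",
                   "evalue", "bitscore"]
EDGE_COLUMNS = ["node_a", "node_b", "weight", "identity_pct"]


# ---------------------------------------------------------------------------
# proteins FASTA

def write_proteins_fasta(proteins: Iterable[ProteinRecord], path: str) -> None:
    records = [
        SeqRecord(
            Seq(p.sequence), id=p.protein_id,
            description=(f"species={p.species_key} strain={p.strain_key} "
                         f"taxon={p.taxon_group}"))
        for p in proteins
    ]
    SeqIO.write(records, path, "fasta")


def read_proteins_fasta(path: str) -> list[ProteinRecord]:
    proteins = []
    for rec in SeqIO.parse(path, "fasta"):
        meta = {}
        for token in rec.description.split()[1:]:
            if "=" in token:
                key, _, val = token.partition("=")
                meta[key] = val
        proteins.append(ProteinRecord(
            protein_id=rec.id,
            species_key=meta.get("species", "unknown"),
            strain_key=meta.get("strain", "unknown"),
            taxon_group=meta.get("taxon", "Bacteria"),
            sequence=str(rec.seq),
        ))
    return proteins


# ---------------------------------------------------------------------------
# profile hits TSV (domtblout-like dialect)

def write_profile_hits(hits: Iterable[ProfileHit], path: str) -> None:
    df = pd.DataFrame(
        [(h.protein_id, h.profile_id, h.e_value, h.bit_score, h.q_start,
          h.q_end, h.profile_len, h.coverage) for h in hits],
        columns=PROFILE_HIT_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_profile_hits(path: str) -> list[ProfileHit]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip",
                     dtype={"protein_id": str, "profile_id": str})
    return [
        ProfileHit(protein_id=row.protein_id, profile_id=row.profile_id,
                   e_value=float(row.e_value), bit_score=float(row.bit_score),
                   q_start=int(row.q_start), q_end=int(row.q_end),
                   profile_len=int(row.profile_len),
                   coverage=float(row.coverage))
        for row in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# GFF3

def write_gff3(features: Iterable[GeneFeature], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            profiles = ",".join(f.product_profile_ids)
            attrs = f"ID={f.product_id};genome_id={f.genome_id}"
            if profiles:
                attrs += f";product_profile={profiles}"
            fh.write("\t".join([
                f.contig_id, "lhr_synth", "CDS", str(f.start), str(f.end),
                ".", f.strand, "0", attrs]) + "\n")


def read_gff3(path: str) -> list[GeneFeature]:
    features = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            attrs = dict(kv.partition("=")[::2]
                         for kv in cols[8].split(";") if kv)
            profiles = tuple(p for p in
                             attrs.get("product_profile", "").split(",") if p)
            features.append(GeneFeature(
                genome_id=attrs.get("genome_id", cols[0]),
                contig_id=cols[0], start=int(cols[3]), end=int(cols[4]),
                strand=cols[6], product_id=attrs["ID"],
                product_profile_ids=profiles))
    return features


# ---------------------------------------------------------------------------
# truth table

def write_truth(truth_labels: dict[str, str], truth_clusters: dict[str, int],
                path: str) -> None:
    df = pd.DataFrame(
        [(pid, truth_labels[pid], truth_clusters[pid])
         for pid in sorted(truth_labels)],
        columns=TRUTH_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_truth(path: str) -> tuple[dict[str, str], dict[str, int]]:
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    labels = dict(zip(df.protein_id, df.family_label))
    clusters = dict(zip(df.protein_id, df.cluster_id.astype(int)))
    return labels, clusters


# ---------------------------------------------------------------------------
# outfmt-6-like pairwise-hit table

def write_outfmt6(hits: Sequence, path: str) -> None:
    """Write PairwiseHit rows as the 12 standard outfmt-6 columns."""
    rows = []
    for h in hits:
        identical = round(h.identity_pct * h.aln_len / 100.0)
        rows.append((h.query_id, h.subject_id, h.identity_pct, h.aln_len,
                     int(h.aln_len - identical), 0, h.q_start, h.q_end,
                     h.s_start, h.s_end, h.e_value, h.bit_score))
    pd.DataFrame(rows, columns=OUTFMT6_COLUMNS).to_csv(
        path, sep="\t", index=False, header=False)


def read_outfmt6(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", names=OUTFMT6_COLUMNS,
                       float_precision="round_trip",
                       dtype={"qseqid": str, "sseqid": str})


# ---------------------------------------------------------------------------
# similarity-graph edge lists

def write_edge_list(graph: nx.Graph, path: str) -> None:
    rows = [(a, b, d["weight"], d.get("identity_pct", float("nan")))
            for a, b, d in sorted(graph.edges(data=True))]
    pd.DataFrame(rows, columns=EDGE_COLUMNS).to_csv(path, sep="\t",
                                                    index=False)


def write_abc(graph: nx.Graph, path: str) -> None:
    with open(path, "w") as fh:
        for a, b, d in sorted(graph.edges(data=True)):
            fh.write(f"{a}\t{b}\t{d['weight']:.6g}\n")


def read_edge_list(path: str) -> nx.Graph:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip",
                     dtype={"node_a": str, "node_b": str})
    g = nx.Graph()
    for row in df.itertuples(index=False):
        g.add_edge(row.node_a, row.node_b, weight=float(row.weight),
                   identity_pct=float(row.identity_pct))
    return g


def ensure_dir(path: str) -> None:
    os.makedirs(path, exist_ok=True)
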