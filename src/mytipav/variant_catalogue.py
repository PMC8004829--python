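"""Variant deduplication, identity clustering, consensuses and PAV tables.

Clustering is complete-linkage agglomeration on global nucleotide
percent identity, cut so that every retained cluster satisfies the
all-pairs property "minimum within-cluster pairwise identity above the
threshold" (default 95%) — single linkage cannot guarantee that.
Cluster labels are assigned A, B, C, ... in decreasing cluster size
(ties by the lexicographically smallest member CDS).  Pseudogenes take
part in clustering; partial variants never do.

Presence/absence variation (PAV) is summarized as boolean variant x
genome and cluster x genome tables.  Variants that fall outside every
retained cluster (and pseudogenes) are assigned to the cluster whose
consensus they match best — the operational form of a maximum-parsimony
assignment of all variants to clusters, recorded as such in the output
metadata.
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from Bio.Seq import Seq

from .align import global_identity
from .msa import mafft_align
from .synthetic_data import IUPAC_NT

_NT = set("ACGTUN")


@dataclass(frozen=True)
class VariantRecord:
    """One distinct recovered coding variant and its carrier genomes."""

    variant_id: str
    cds: str
    protein: str
    pseudogene: bool
    carriers: tuple[str, ...] = ()
    partial: bool = False


@dataclass
class Cluster:
    """A group of variants satisfying the within-cluster identity floor."""

    label: str
    members: tuple[str, ...]  # variant ids
    nt_consensus: str
    protein_consensus: str
    min_identity: float


def pairwise_identity(a: str, b: str) -> float:
    """Percent identity under global alignment (end gaps penalized)."""
    if not a or not b:
        raise ValueError("empty sequence")
    a_nt, b_nt = set(a.upper()) <= _NT, set(b.upper()) <= _NT
    if a_nt != b_nt:
        raise ValueError("sequences must share one alphabet (both nt or both protein)")
    return global_identity(a, b, nucleotide=a_nt)


def flag_pseudogenes(variants: list[VariantRecord]) -> tuple[list[VariantRecord], dict]:
    """Re-derive pseudogene/partial flags from each CDS.

    A CDS whose length is not divisible by 3 is flagged partial and
    excluded from the counts; an internal stop codon (before the final
    codon) marks a pseudogene.  A terminal stop alone does not.
    """
    out = []
    counts = {"functional": 0, "pseudogene": 0, "partial": 0}
    for v in variants:
        cds = v.cds.upper()
        if len(cds) % 3 != 0:
            out.append(replace(v, partial=True))
            counts["partial"] += 1
            continue
        protein = str(Seq(cds).translate())
        if protein.endswith("*"):
            protein = protein[:-1]
        pseudo = "*" in protein
        out.append(replace(v, protein=protein, pseudogene=pseudo, partial=False))
        counts["pseudogene" if pseudo else "functional"] += 1
    return out, counts


def _labels():
    letters = string.ascii_uppercase
    for r in range(1, 3):
        for combo in itertools.product(letters, repeat=r):
            yield "".join(combo)


def consensus(cds_list: list[str]) -> tuple[str, str]:
    """Nucleotide + protein consensus of aligned cluster members.

    Members are multiple-aligned (mafft); a nucleotide column collapses
    to the minimal IUPAC code covering its observed bases, a protein
    column with two or more distinct residues becomes 'X', and columns
    that are gaps in the majority of members are dropped.
    """
    if not cds_list:
        raise ValueError("empty cluster")
    aligned = mafft_align([(f"m{i}", s) for i, s in enumerate(cds_list)], protein=False)
    rows = [row for _, row in aligned]
    nt_cons = []
    for col in zip(*rows):
        bases = [c for c in col if c != "-"]
        if len(bases) * 2 <= len(col):  # gap-majority column
            continue
        covered = frozenset(c for b in bases for c in IUPAC_NT.get(b, b))
        code = min(
            (sym for sym, chars in IUPAC_NT.items() if covered <= frozenset(chars)),
            key=lambda sym: (len(IUPAC_NT[sym]), sym),
        )
        nt_cons.append(code)

    proteins = []
    for s in cds_list:
        p = str(Seq(s[: len(s) - len(s) % 3]).translate())
        proteins.append(p[:-1] if p.endswith("*") else p)
    aligned_p = mafft_align([(f"m{i}", p) for i, p in enumerate(proteins)], protein=True)
    prot_cons = []
    for col in zip(*(row for _, row in aligned_p)):
        residues = [c for c in col if c != "-"]
        if len(residues) * 2 <= len(col):
            continue
        distinct = set(residues)
        prot_cons.append(residues[0] if len(distinct) == 1 else "X")
    return "".join(nt_cons), "".join(prot_cons)


def cluster_variants(variants: list[VariantRecord],
                     threshold: float = 95.0) -> list[Cluster]:
    """Complete-linkage clustering of non-partial variants on CDS identity.

    The dendrogram is cut so that every cluster's minimum within-cluster
    pairwise identity is strictly above ``threshold``.
    """
    usable = [v for v in variants if not v.partial]
    if not usable:
        raise ValueError("no non-partial variants to cluster")
    n = len(usable)
    ident = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            ident[i, j] = ident[j, i] = pairwise_identity(usable[i].cds, usable[j].cds)
    if n == 1:
        assignments = np.array([1])
    else:
        dist = 100.0 - ident
        Z = linkage(squareform(dist, checks=False), method="complete")
        assignments = fcluster(Z, t=(100.0 - threshold) - 1e-9, criterion="distance")

    groups: dict[int, list[int]] = {}
    for idx, grp in enumerate(assignments):
        groups.setdefault(int(grp), []).append(idx)
    ordered = sorted(
        groups.values(),
        key=lambda idxs: (-len(idxs), min(usable[i].cds for i in idxs)),
    )
    clusters = []
    for label, idxs in zip(_labels(), ordered):
        min_ident = min(
            (ident[i, j] for i, j in itertools.combinations(idxs, 2)), default=100.0
        )
        nt_cons, prot_cons = consensus([usable[i].cds for i in idxs])
        clusters.append(
            Cluster(
                label=label,
                members=tuple(usable[i].variant_id for i in idxs),
                nt_consensus=nt_cons,
                protein_consensus=prot_cons,
                min_identity=float(min_ident),
            )
        )
    return clusters


@dataclass
class PAVMatrix:
    """Presence/absence tables and their summary statistics."""

    variant_matrix: pd.DataFrame  # variants x genomes, bool
    cluster_matrix: pd.DataFrame  # clusters x genomes, bool
    assignment: dict[str, str]  # variant id -> cluster label
    cluster_frequency: pd.Series
    mean_variants_per_genome: float
    mean_unique_variants_per_genome: float


def assign_to_clusters(variants: list[VariantRecord],
                       clusters: list[Cluster]) -> dict[str, str]:
    """Nearest-consensus assignment of every variant to a cluster.

    Ties break by highest identity, then largest cluster, then
    alphabetical label.
    """
    members = {vid: c.label for c in clusters for vid in c.members}
    out = {}
    for v in variants:
        if v.variant_id in members:
            out[v.variant_id] = members[v.variant_id]
            continue
        best = min(
            clusters,
            key=lambda c: (
                -pairwise_identity(v.cds, c.nt_consensus.replace("U", "T")),
                -len(c.members),
                c.label,
            ),
        )
        out[v.variant_id] = best.label
    return out


def build_pav(variants: list[VariantRecord], genomes: list[str],
              clusters: list[Cluster]) -> PAVMatrix:
    """Boolean variant x genome and cluster x genome occurrence tables.

    A variant is present in a genome iff that genome carries its exact
    CDS; a cluster is present iff any assigned member is.  Also reports
    per-cluster occurrence frequencies and the mean number of variants
    (and of genome-unique variants) per genome.
    """
    genomes = list(genomes)
    vids = [v.variant_id for v in variants]
    vmat = pd.DataFrame(False, index=vids, columns=genomes)
    for v in variants:
        for g in v.carriers:
            if g in vmat.columns:
                vmat.loc[v.variant_id, g] = True

    assignment = assign_to_clusters(variants, clusters)
    labels = [c.label for c in clusters]
    cmat = pd.DataFrame(False, index=labels, columns=genomes)
    for vid, label in assignment.items():
        cmat.loc[label] |= vmat.loc[vid]

    freq = cmat.sum(axis=1) / len(genomes)
    mean_variants = float(vmat.sum(axis=0).mean())
    unique = vmat.loc[vmat.sum(axis=1) == 1]
    mean_unique = float(unique.sum(axis=0).mean()) if len(unique) else 0.0
    return PAVMatrix(
        variant_matrix=vmat,
        cluster_matrix=cmat,
        assignment=assignment,
        cluster_frequency=freq,
        mean_variants_per_genome=mean_variants,
        mean_unique_variants_per_genome=mean_unique,
    )
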