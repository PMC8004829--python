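"""Cluster the recovered variants at the 95% identity floor, build
cluster consensuses, and quantify presence/absence variation.

Reads the variant set from step 02; writes cluster membership, consensus
FASTA and the variant x genome / cluster x genome PAV matrices.
"""

from pathlib import Path

import pandas as pd

from mytipav.io import read_fasta, read_tsv, write_fasta, write_tsv
from mytipav.variant_catalogue import (
    VariantRecord,
    build_pav,
    cluster_variants,
    flag_pseudogenes,
)

OUT = Path("results/analysis")
SEED = 0


def load_variants():
    nt = {r.id: str(r.seq) for r in read_fasta(OUT / "variants_nt.fa")}
    table = read_tsv(OUT / "variants.tsv")
    return [
        VariantRecord(
            row.variant_id, nt[row.variant_id], "", bool(row.pseudogene),
            carriers=tuple(str(row.carriers).split(",")),
        )
        for row in table.itertuples()
    ]


def main():
    variants, counts = flag_pseudogenes(load_variants())
    clusters = cluster_variants(variants, threshold=95.0)
    genomes = sorted({g for v in variants for g in v.carriers})
    pav = build_pav(variants, genomes, clusters)

    write_tsv(
        pd.DataFrame(
            [
                {
                    "cluster": c.label,
                    "n_members": len(c.members),
                    "members": ",".join(c.members),
                    "min_within_identity": round(c.min_identity, 2),
                    "frequency": round(float(pav.cluster_frequency[c.label]), 3),
                }
                for c in clusters
            ]
        ),
        OUT / "clusters.tsv", seed=SEED,
    )
    write_fasta(
        [(f"{c.label}_nt", c.nt_consensus) for c in clusters]
        + [(f"{c.label}_protein", c.protein_consensus) for c in clusters],
        OUT / "consensus.fa",
    )
    write_tsv(pav.variant_matrix.astype(int), OUT / "pav_variants.tsv",
              seed=SEED, index=True)
    write_tsv(pav.cluster_matrix.astype(int), OUT / "pav_clusters.tsv",
              seed=SEED, index=True)

    print(f"variants: {counts['functional']} functional, "
          f"{counts['pseudogene']} pseudogenes, {counts['partial']} partial")
    print(f"clusters at >95% identity: {len(clusters)} "
          f"({', '.join(c.label for c in clusters)})")
    print("cluster occurrence frequencies:")
    for c in clusters:
        print(f"  {c.label}: {pav.cluster_frequency[c.label]:.2f} "
              f"({len(c.members)} members, min identity "
              f"{c.min_identity:.1f}%)")
    print(f"mean variants per genome: {pav.mean_variants_per_genome:.1f}")
    print(f"mean genome-unique variants: {pav.mean_unique_variants_per_genome:.1f}")
    print(f"wrote {OUT}/clusters.tsv, consensus.fa, pav_*.tsv")


if __name__ == "__main__":
    main()
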