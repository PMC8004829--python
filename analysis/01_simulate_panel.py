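"""Generate the study panel: 16 individual genomes carrying a planted
13-cluster AMP gene family with presence/absence variation, plus matched
transcriptomes and the ground-truth manifest.

Writes per-individual genome and transcriptome FASTAs and the manifest
TSV under results/analysis/.
"""

from pathlib import Path

from mytipav.io import write_fasta, write_tsv
from mytipav.synthetic_data import SimConfig, generate_cohort

OUT = Path("results/analysis")
CONFIG = SimConfig(rng_seed=0)  # study conditions: 16 x 13 x 8, PAV 0.7


def main():
    cohort = generate_cohort(CONFIG)
    for ind in cohort.individuals:
        write_fasta(ind.contigs, OUT / "genomes" / f"{ind.individual_id}.fa")
    for t in cohort.transcriptomes:
        write_fasta(t.transcripts, OUT / "transcriptomes" / f"{t.individual_id}.fa")
    manifest = cohort.manifest.to_frame()
    write_tsv(manifest, OUT / "manifest.tsv", seed=CONFIG.rng_seed, config=CONFIG)

    n_copies = len(cohort.manifest.copies)
    n_distinct = len(cohort.manifest.distinct_cds())
    n_pseudo = sum(c.pseudogene for c in cohort.manifest.copies)
    per_genome = manifest.groupby("individual").size()
    print(f"panel: {CONFIG.n_individuals} individuals, {CONFIG.n_clusters} clusters, "
          f"{CONFIG.alleles_per_cluster} alleles/cluster, seed {CONFIG.rng_seed}")
    print(f"planted copies: {n_copies} ({n_pseudo} pseudogenized), "
          f"{n_distinct} distinct CDS")
    print(f"copies per genome: mean {per_genome.mean():.1f} "
          f"(range {per_genome.min()}-{per_genome.max()})")
    print(f"wrote {OUT}/genomes, {OUT}/transcriptomes, {OUT}/manifest.tsv")


if __name__ == "__main__":
    main()
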