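"""Extract 1 kb upstream promoter regions of one representative locus
per cluster and discover shared ungapped motifs (width 6-30) with the
ZOOPS EM model.

Reads genomes (01), loci (02) and cluster membership (03); writes the
motifs in minimal MEME text plus a motif x promoter presence matrix.
"""

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from mytipav import promoter_motifs as pm
from mytipav.io import read_fasta, read_tsv, write_tsv
from mytipav.pipeline import _write_meme

OUT = Path("results/analysis")
SEED = 0


@dataclass
class _Locus:
    contig: str
    strand: str
    exon_starts: tuple
    exon_ends: tuple


def main():
    loci = read_tsv(OUT / "loci.tsv")
    contigs = {}
    for p in sorted((OUT / "genomes").glob("*.fa")):
        for r in read_fasta(p):
            contigs[r.id] = str(r.seq)

    # one representative locus per cluster: the contig naming of the
    # simulated panel carries the planted cluster index
    reps, seen = [], set()
    for row in loci.sort_values(["contig"]).itertuples():
        cluster_key = row.contig.split("_")[-1]
        if cluster_key in seen or row.partial:
            continue
        seen.add(cluster_key)
        reps.append(
            _Locus(
                row.contig, row.strand,
                tuple(int(x) for x in str(row.exon_starts).split(",")),
                tuple(int(x) for x in str(row.exon_ends).split(",")),
            )
        )
    promoters = pm.extract_promoters(reps, contigs, window=1000)
    print(f"promoters: {len(promoters.records)} representative loci, "
          f"{sum(r.truncated for r in promoters.records)} truncated")

    motifs = pm.discover_motifs(
        promoters, widths=range(6, 31), n_motifs=10, rng=SEED
    )
    _write_meme(motifs, OUT / "motifs.meme")
    presence = pd.DataFrame(
        False,
        index=[f"motif_{i + 1}" for i in range(len(motifs))],
        columns=[r.label for r in promoters.records],
    )
    for i, m in enumerate(motifs):
        for label, *_ in m.occurrences:
            presence.loc[f"motif_{i + 1}", label] = True
    write_tsv(presence.astype(int), OUT / "motif_presence.tsv", seed=SEED,
              index=True)

    print(f"discovered {len(motifs)} motif(s):")
    for i, m in enumerate(motifs):
        print(f"  motif_{i + 1}: {m.consensus} (w={m.width}, "
              f"IC {m.ic_per_column:.2f} bits/col, "
              f"{len(m.occurrences)}/{len(promoters.records)} promoters)")
    print(f"wrote {OUT}/motifs.meme, motif_presence.tsv")


if __name__ == "__main__":
    main()
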