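"""Characterize the mature peptides: isoelectric point, net charge at
cytoplasmic pH 7.4, molecular weight, and 15-residue sliding-window pI
profiles of the cluster consensus precursors.

Reads variants (02) and cluster consensuses (03).
"""

from pathlib import Path

import pandas as pd

from mytipav import peptide_chemistry as pc
from mytipav.io import read_fasta, read_tsv, write_tsv
from mytipav.synthetic_data import default_seed

OUT = Path("results/analysis")
SEED = 0


def main():
    seed = default_seed()
    proteins = {r.id: str(r.seq) for r in read_fasta(OUT / "variants_protein.fa")}
    table = read_tsv(OUT / "variants.tsv")
    pseudo = dict(zip(table.variant_id, table.pseudogene))

    rows = []
    for vid, protein in proteins.items():
        if pseudo.get(vid, False) or "*" in protein:
            continue
        ann = pc.segment_precursor(protein, seed.protein, seed.annotation)
        mature = protein[ann.mature[0]:ann.mature[1]]
        pi, _ = pc.isoelectric_point(mature)
        rows.append(
            {
                "variant": vid,
                "mature_start": ann.mature[0],
                "mature_end": ann.mature[1],
                "pI": round(pi, 3),
                "charge_pH7.4": round(pc.net_charge(mature, 7.4), 3),
                "mw_da": round(pc.molecular_weight(mature), 1),
            }
        )
    peptides = pd.DataFrame(rows).sort_values("variant")
    write_tsv(peptides, OUT / "peptides.tsv", seed=SEED)

    profiles = []
    for rec in read_fasta(OUT / "consensus.fa"):
        if not rec.id.endswith("_protein"):
            continue
        label = rec.id[: -len("_protein")]
        centers, values, _ = pc.sliding_window_pi(str(rec.seq), window=15)
        profiles.append(pd.DataFrame({"cluster": label, "center": centers,
                                      "pI": [round(v, 3) for v in values]}))
    write_tsv(pd.concat(profiles, ignore_index=True), OUT / "pi_profiles.tsv",
              seed=SEED)

    print(f"mature peptides characterized: {len(peptides)}")
    print(f"pI range: {peptides['pI'].min():.2f} - {peptides['pI'].max():.2f}")
    print(f"charge at pH 7.4: {peptides['charge_pH7.4'].min():.1f} "
          f"to {peptides['charge_pH7.4'].max():.1f} (cationic mature region)")
    print(f"wrote {OUT}/peptides.tsv, pi_profiles.tsv")


if __name__ == "__main__":
    main()
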