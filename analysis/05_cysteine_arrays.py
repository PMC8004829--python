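"""Classify the cysteine disulfide arrays of the recovered mature
peptides, and tabulate the five canonical array types with their slot
occupancy and optional bonds.

Reads variants (02) and cluster assignment (03).
"""

from pathlib import Path

import pandas as pd

from mytipav import cysteine_arrays as ca
from mytipav import peptide_chemistry as pc
from mytipav.io import read_fasta, read_tsv, write_tsv
from mytipav.synthetic_data import default_seed

OUT = Path("results/analysis")
SEED = 0


def main():
    seed = default_seed()
    proteins = {r.id: str(r.seq) for r in read_fasta(OUT / "variants_protein.fa")}
    clusters = read_tsv(OUT / "clusters.tsv")
    label_of = {
        m: row.cluster
        for row in clusters.itertuples()
        for m in str(row.members).split(",")
    }

    rows, calls = [], []
    for vid, protein in sorted(proteins.items()):
        if "*" in protein:
            continue
        ann = pc.segment_precursor(protein, seed.protein, seed.annotation)
        mature = protein[ann.mature[0]:ann.mature[1]]
        fp = ca.fingerprint(mature)
        call = ca.classify_type(ca.assign_slots(fp))
        label = label_of.get(vid, "?")
        calls.append((label, call))
        rows.append(
            {
                "variant": vid,
                "cluster": label,
                "array": fp.to_string(),
                "type": call.array_type,
                "bonds": ",".join(map(str, call.bonds)),
                "n_cys": call.n_cys,
            }
        )
    write_tsv(pd.DataFrame(rows), OUT / "cys_types.tsv", seed=SEED)
    occurrence = ca.summarize_taxa(calls)
    write_tsv(occurrence.astype(int), OUT / "cys_occurrence.tsv", seed=SEED,
              index=True)

    # the five canonical reference arrays, for context
    ref_rows = []
    for t, pattern in ca.CANONICAL_PATTERNS.items():
        call = ca.classify_type(ca.assign_slots(ca.parse_pattern(pattern)))
        ref_rows.append({"type": t, "array": pattern, "n_cys": call.n_cys,
                         "bonds": ",".join(map(str, call.bonds))})
    write_tsv(pd.DataFrame(ref_rows), OUT / "cys_reference_types.tsv", seed=SEED)

    by_type = ca.type_membership(calls)
    print("array types among recovered mature peptides:")
    for t, labels in by_type.items():
        print(f"  type {t}: clusters {', '.join(labels)}")
    print(f"wrote {OUT}/cys_types.tsv, cys_occurrence.tsv, cys_reference_types.tsv")


if __name__ == "__main__":
    main()
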