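# mytipav

Cataloguing the intra-species diversity of a cysteine-rich antimicrobial
peptide (AMP) gene family across individual genome assemblies.

Mussels and other bivalves carry families of dispensable immune genes:
different individuals of one species carry different subsets of the
family — presence/absence variation (PAV). The antifungal mytimycin-type
peptides are a striking case: a precursor with a signal peptide, a
cationic mature peptide stabilized by a conserved disulfide array (10
invariant "backbone" cysteines plus up to 6 accessory ones forming as
many as 3 optional bonds, giving array types I–V), and an anionic
C-terminal extension with an EF-hand-like motif. `mytipav` implements the
full desk workflow for such a family and a synthetic genome panel
generator so every stage is testable end to end without external data:

1. **synthetic_data** — seeded panels of individual genomes carrying a
   planted multi-cluster family (allelic pools >95% nucleotide identity,
   clusters <95%, per-cluster retention probabilities, two-exon genes
   with GT..AG introns, planted degenerate promoter motifs, optional
   pseudogenization), matched transcriptomes, and a ground-truth manifest.
2. **translated_search** — six-frame translated Smith–Waterman against a
   seed precursor (BLOSUM62, affine gaps), splice-aware exon chaining
   with GT..AG boundary refinement, CDS extraction; the report threshold
   is calibrated on shuffled contigs.
3. **variant_catalogue** — exact-CDS deduplication, complete-linkage
   clustering at the 95% identity floor (the cut guarantees the all-pairs
   property), IUPAC/X consensuses, pseudogene flagging, and PAV matrices.
4. **peptide_chemistry** — precursor segmentation by alignment projection
   with dibasic-site snapping, Henderson–Hasselbalch net charge
   `Z(pH) = Σ_b 1/(1+10^(pH−pKa_b)) − Σ_a 1/(1+10^(pKa_a−pH))`,
   pI by bisection, and 15-residue sliding-window pI profiles.
5. **cysteine_arrays** — run-length cysteine fingerprints, deterministic
   assignment onto the 10-backbone + 6-accessory slot model, array types
   I–V, optional bonds 1–3, cross-taxon occurrence tables.
6. **molecular_evolution** — protein-guided codon alignment, p-distances,
   neighbor joining, and a SLAC-style per-site selection test (Fitch
   ancestral codons, Nei–Gojobori pathway counting, one-sided binomial
   tests in each direction).
7. **promoter_motifs** — 1 kb upstream extraction and ZOOPS EM motif
   discovery (widths 6–30, both strands, IUPAC consensus, occurrence
   masking).
8. **expression_screen** — translated screening of cluster consensuses
   against transcriptomes (>95% identity + mature-region coverage) and a
   perfect-match genome-vs-transcript concordance check for RNA editing.

The package is aimed at comparative genomicists studying dispensable
gene families — and at anyone needing a fully self-contained, seeded
test bed for this kind of pipeline.

## Worked example

The analysis scripts run the whole study on the default synthetic panel
(16 individuals × 13 clusters × 8 alleles, retention 0.7, 17%
pseudogenization, seed 0):

```bash
python analysis/01_simulate_panel.py
python analysis/02_recover_variants.py
python analysis/03_catalogue_pav.py
```

prints

```
planted copies: 146 (27 pseudogenized), 97 distinct CDS
copies per genome: mean 9.1 (range 6-11)
calibrated score threshold (99.9th pct of 1000 shuffled contigs): 51
recovered 97 distinct variants (27 pseudogenes) across 16 genomes
variants: 70 functional, 27 pseudogenes, 0 partial
clusters at >95% identity: 13 (A, B, C, D, E, F, G, H, I, J, K, L, M)
mean variants per genome: 9.1
mean genome-unique variants: 3.8
```

i.e. the search recovers every planted variant exactly (97/97), the
complete-linkage cut reconstitutes the 13 planted clusters, and each
simulated individual carries a personal repertoire of ~9 variants, ~4 of
them found in no other genome — the PAV signature the pipeline is built
to quantify. Steps `04`–`08` add peptide chemistry (pI 6.3–8.4, mature
charge up to +6.9 at pH 7.4), disulfide-array typing (all planted
variants type III, `CC-C-C-CC-C-CC-C-C-C`, 12 cysteines, bond 2),
the NJ tree and per-site selection table, promoter motif discovery
(recovers the planted degenerate 30-mer `TGCTTGTTTAYTTWTAACAAYAATTTTAAG`
in 13/13 promoters and correctly reports nothing else), and the
expression/concordance screen (evidence matrix equal to the simulated
expression truth; 78/78 transcripts perfectly concordant with their
genomic CDS, i.e. no spurious RNA-editing signal).

`mytipav.pipeline.run_pipeline(PipelineConfig(...))` drives the same
stages programmatically and writes every table with a version/seed/config
header.

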