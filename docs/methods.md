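# Methods

This note documents the models, parameter choices and numerical
behaviour of `mytipav`, in the package's own terms. Nothing here states
an empirical result that the test suite or the analysis scripts do not
themselves compute.

## Synthetic panel generator

The generator is first-class code, not a fixture: it defines the study
conditions every downstream stage is validated against.

**Family structure.** A seed precursor (23-residue signal, 54-residue
mature peptide with a 12-cysteine `CC-C-C-CC-C-CC-C-C-C` array ending
just before a KR dibasic site, 75-residue acidic C-terminal extension
with an EF-hand-like loop) is reverse-translated with one fixed codon
per residue. Cluster founders are drawn by mutating the seed CDS at
`between_cluster_divergence` (default 0.10 substitutions/site) and
allele pools by mutating each founder at `within_cluster_divergence`
(default 0.01). The identity separation — all within-pool pairs above
the 95% floor, all cross-pool pairs below — is verified exhaustively
(Hamming identity is exact here because mutation is substitution-only)
and re-drawn up to `max_retries` (100) times; failure raises, never
passes silently.

**Mutation model.** Substitution-only and codon-respecting: a codon that
would become a stop reverts, as does one that would *gain* a cysteine.
The second rule reflects the family biology this simulator emulates —
the disulfide array is the conserved, family-defining trait, and random
cysteine gain would corrupt the array typing of planted copies. Start
codon, mature-region cysteine codons, the dibasic cleavage codons and
the terminal stop are never mutated. Consequences worth knowing: all
alleles share one length (no indels), conserved sites are *invariant*
rather than purifying-selected, and mature peptides drift freely at
non-protected sites.

**Genes and genomes.** Default conditions: 16 individuals, 13 clusters,
8 alleles per cluster, per-cluster retention probability 0.7,
pseudogenization probability 0.17 (one mature-region sense codon → TAA),
expression probability 0.6, contigs of 6000 bp (one gene per contig plus
2 background contigs), intron of 287 bp, promoter window 1000 bp.
Each retained copy is planted as a two-exon gene — the single phase-0
intron sits at a fixed codon boundary 23 codons into the C-terminal
extension coding region, mirroring the extension living on its own exon
— with `GT..AG` ends, on a random strand, behind a planted instance of
the degenerate 30-bp promoter element `TGCTTGTTTAYTTWTAACAAYAATTTTAAG`
(degenerate positions sampled per IUPAC) at a uniform offset within the
upstream window. Background sequence is i.i.d. uniform A/C/G/T: the
simplest null that cannot spuriously encode the seed peptide at these
lengths. Introns are re-drawn until they offer no competing phase-0 `GT`
near the donor nor `AG` near the acceptor, keeping splice recovery
well-posed. Everything flows from one seeded `numpy` generator, so a
configuration is byte-reproducible.

**What it does not emulate:** diploidy/heterozygosity (one haplotype per
individual; within-genome allelic pairs are out of scope), indels,
repeats, assembly fragmentation or base-calling error, realistic base
composition, and selection acting through substitution bias. Tests that
pass on these panels therefore demonstrate correctness of the machinery
under clean conditions, not robustness to assembly artefacts.

## Translated search

Six-frame translation (N → X) with exact coordinate maps between
peptide and forward-strand nucleotide intervals. Each frame is locally
aligned to the seed precursor under BLOSUM62 with BLAST-style affine
gaps (open 11, extend 1; a length-k gap costs 11 + k). Alignments
bridging an intron as a ≥10-residue target-side gap are split into
segments; segments scoring below 60 are discarded (empirical null peaks
near 40–55 for this seed). Chaining maximizes summed segment score
subject to query collinearity (≤60 residues overlap allowed — local
alignments overshoot splice sites into translated intron — and ≥10
residues of query advance, which excludes nested spurious segments).

Splice boundaries are then refined: donor candidates are phase-0 `GT`
positions in a window spanning the alignment break and the query-anchored
donor estimate (the next exon's first aligned query residue projected
through the spliced length); acceptor candidates are nearby `AG` ends.
Among GT/AG pairs, the one whose spliced translation aligns best to the
seed wins, ties by proximity to the break, then leftmost. No consistent
pair → best single hit, flagged partial. The CDS runs from the projected
query start (anchored at the ATG) to the first in-frame stop of the last
exon.

**Report threshold.** In place of e-value statistics, the default
threshold is the 99.9th percentile of the best six-frame local score of
the seed against 1000 seeded random contigs of 1 kb. Manual curation is
replaced by a deterministic rule: a model must cover ≥60% of the seed's
mature region. Distinct spliced CDSs (exact nucleotide identity) become
variants listing their carrier genomes; partial models are reported but
never become variants and never enter clustering.

## Catalogue, clustering and PAV

Percent identity is matches / alignment-length × 100 under global
alignment with end gaps penalized. Clustering is complete-linkage
agglomeration on 100 − identity, cut at the 95% floor (minus an epsilon
so exactly-95% pairs do not merge): complete linkage is the only linkage
that *guarantees* the all-pairs within-cluster property the catalogue
asserts. Labels are A, B, C, … by decreasing size, ties by smallest
member CDS. Pseudogenes (internal stop before the final codon) cluster
normally but are excluded from peptide chemistry and selection analyses.

Consensuses align members with mafft (protein and nucleotide runs; the
aligned rows are restored to the original symbols, so degapping returns
the inputs exactly): a nucleotide column becomes the minimal IUPAC code
covering its bases, a protein column with ≥2 distinct residues becomes
`X`, gap-majority columns are dropped.

PAV: a variant is present in a genome iff that genome carries its exact
CDS. Every variant — including pseudogenes — is assigned to the cluster
whose nucleotide consensus it matches best (ties: higher identity,
larger cluster, alphabetical label); this nearest-consensus rule is the
package's operationalization of a maximum-parsimony assignment, and the
outputs record it as such. Cluster presence is the OR of assigned
members; the summary reports per-cluster occurrence frequencies and the
mean number of variants and genome-unique variants per genome.

## Peptide chemistry

Net charge is the Henderson–Hasselbalch sum over titratable groups,
termini included; `X` contributes nothing; charge is therefore a pure
function of composition. pI is the unique root of the (strictly
decreasing) charge on pH ∈ [0, 14] by bisection to 1e-4; when the charge
does not change sign the nearer boundary is returned with a flag.
Three pKa tables ship: `ipc_protein` (default), `emboss`, `lehninger`.
Cysteines count as titratable regardless of disulfide status — this
matches what any sequence-only calculator does, and with the IPC table
(Cys pKa 7.555, essentially cytoplasmic pH) a 12-cysteine mature peptide
carries roughly −0.4 charge per cysteine at pH 7.4; comparisons across
tables should keep that in mind. Sliding-window profiles (default 15
residues) treat each window as an isolated peptide with free termini (a
flag disables the termini); a protein shorter than the window yields a
single flagged whole-sequence value. Molecular weights use average
residue masses.

Precursor segmentation projects the seed's signal/mature/extension
boundaries through a global alignment and snaps the mature C-terminus to
the residue preceding the first dibasic motif (KK/KR/RK/RR — a
furin-like cleavage site) at or after the projected position.

## Cysteine arrays

The mature peptide's cysteines are reduced to maximal-run lengths
(`CC-C-C-…` dialect; `-` and whitespace are equivalent separators). Slot
assignment tries every accessory complement that is a union of complete
bond pairs — {a1,a2}, {a3,a4}, {a5,a6} — against the induced run-length
template (a1/a2 free-standing between backbone Cys2 and Cys3, a3/a4 in
tandem with Cys5/Cys7 forming `CC` doublets, a5/a6 free-standing after
Cys10). Lone accessory slots are never consumed: an unpaired accessory
cysteine would have no bond partner, and arrays such as 11 or 13
cysteines are reported UNKNOWN, never coerced. When several complements
fit (the type II pattern matches both {a1,a2} and {a5,a6}), the fewest
accessory slots win, then the most *C-terminal* usage — under which the
five canonical patterns parse uniquely and type II's extra pair is the
C-terminal bond-3 pair, as the family's array table has it. Types follow
the accessory complement (IV none; II bond 3; III bond 2; I bonds 2+3;
V bonds 1+2). The five canonical patterns are carried as reference data
and round-trip exactly through parse → assign → serialize.

## Distances, trees and site selection

Codon alignment aligns translations (mafft) and back-threads gaps as
triplets; pseudogenes are rejected by id. p-distance is the proportion
of differing columns among ungapped columns. Neighbor joining (scikit-bio)
with negative branch lengths clamped to zero is the deterministic
stand-in for full phylogenetic inference — outputs note this — and on
additive distances it reproduces the generating tree exactly, which the
tests assert.

The per-site test is counting-based, in the SLAC tradition: per codon
column, (i) Fitch parsimony on codon states reconstructs ancestral sets
(gap codons are unconstrained and free); (ii) a consistent minimal
labeling is built top-down — a node inherits its parent's state when
that state is in its Fitch set, else takes the lexicographically
smallest member — and root-state ties are averaged over up to 4 tied
states (beyond that, lexicographic pick); (iii) per branch, synonymous
and nonsynonymous differences are averaged over all minimal mutational
pathways between the two codons, excluding pathways through stop codons
(if all pathways hit stops, all are used); (iv) the expected synonymous
proportion is the mean synonymous site fraction of the codons observed
at the column (per position, the synonymous share of non-stop
single-nucleotide changes); (v) one-sided binomial tests in each
direction use the regularized incomplete beta function — the continuous
extension of the binomial tail — because pathway averaging yields
fractional counts. A site is negative if p_neg < α (and ≤ p_pos),
positive if p_pos < α; default α = 0.1, a deliberately permissive level
at which positive calls in this family carry only marginal support. The
counting test is conservative by construction (under neutral simulation
its type-I error sits far below α) and has *no power at invariant
sites*: perfectly conserved positions — e.g. the simulator's protected
cysteines — produce zero observed changes and a "none" call, which is
why heavily conserved synthetic panels yield few negative calls.

## Promoter motifs

Upstream windows (default 1000 bp on the coding strand, truncated and
flagged at contig edges) feed a ZOOPS (zero-or-one occurrence per
sequence) EM mixture: position probability matrix θ (pseudocount 0.1),
0-order background from the promoter set, per-sequence occurrence prior
γ, both strands scanned, windows containing N excluded. The objective
reported in `ll_trace` is the observed-data log-likelihood plus the
Dirichlet log-prior on θ; by EM construction it never decreases, and the
tests assert that on every iteration of every run.

Discovery is MEME-like, per width 6–30: start models from observed
w-mers (a seeded subsample of up to 200), screened in one batched
objective evaluation; the top 3 run to convergence (tolerance 1e-6, ≤200
iterations); a phase-shift hill climb (±1..3 columns, repeated while the
objective improves) corrects the frequent off-by-a-few-columns local
optima; if most occurrences sit on the minus strand the matrix is
reverse-complemented so the reported orientation is canonical. Widths
compete by information content × expected site count. A candidate is
accepted only if its log-likelihood gain over the background-only model
exceeds 1.5× its parameter count (3w+1): EM on random sequence overfits
by roughly one unit per parameter, real shared motifs gain several times
that, so this AIC-style rule stops discovery at noise — the sole
information-content floor (0.5 bits/column) cannot, since overfit null
motifs reach ~1 bit/column at desk scale. Accepted occurrences
(posterior presence > 0.5) are masked with N before the next motif, so
motifs never share an occurrence interval. The IUPAC consensus takes,
per column, the minimal code covering bases with frequency ≥ 0.25.
Scanning reports both-strand log-odds matches above 80% of the
consensus score.

## Expression and concordance

A cluster counts as expressed in a sample when the best translated local
alignment of its consensus protein against six-frame transcript
translations exceeds 95% identity with ≥60% mature-region coverage.
Identity is computed over *informative* query columns: an `X` in a
consensus marks a within-cluster polymorphic position and can neither
match nor mismatch (at study-scale cluster sizes ~10% of columns are
polymorphic, and counting them as mismatches would mechanically defeat
the 95% threshold); gap columns still count against identity. Hits are
ranked coverage-floor-first so a tiny 100%-identity fragment cannot
shadow a full-length near-identical match. Raising the threshold can
only remove evidence (asserted as a property).

Concordance realizes a stringent read-mapping contract at sequence
level: a locus is concordant iff the global alignment of genomic spliced
CDS and transcript has zero mismatching and zero gap columns. Mismatches
are listed in transcript coordinates; unaligned segments are reported
per side ("genomic"/"transcript") so a deletion appears as one interval
of its true length. Length differences beyond 20% short-circuit to a
structural-discordance flag.

## Problem sizes and determinism

The default analysis runs 16 genomes × 15 contigs × 6 kb, 1000-contig
threshold calibration, 13 representative promoters, and a 70-taxon
selection analysis — about two minutes end to end. The test suite uses
3–4-individual panels, 2–13-cluster partitions, 200-replicate neutral
simulations at 6 × 12 codons, and brute-force oracles on ≤6-symbol
alignment instances and ≤6-leaf trees; these sizes were chosen so each
check is exhaustive or statistically decisive at desk scale. Every
stochastic component takes an explicit seed or `numpy` Generator, and
rerunning any configuration is byte-identical.

## Known limitations

* The searcher assumes substitution-level divergence from the seed;
  frameshifts and assembly gaps inside a gene yield partial models, not
  repaired ones.
* Splice refinement considers phase-0 GT..AG introns only, matching the
  simulator; other phases would need the donor-phase constraint relaxed.
* The slot model is family-specific by design; arrays outside the five
  canonical types are surfaced as UNKNOWN rather than interpreted.
* pKa models are sequence-only; disulfide-bonded cysteines are treated
  as titratable, a documented convention, not a chemical claim.
* NJ on p-distances replaces model-based phylogenetics; branch supports
  are not computed.
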