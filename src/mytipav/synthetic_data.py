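"""Synthetic genome panels carrying a planted AMP gene family.

The generator emulates the situation the pipeline is built for: a panel
of individual genome assemblies from one species, each carrying a
personal subset of a multi-cluster antimicrobial-peptide gene family.
Per cluster there is a pool of alleles (pairwise nucleotide identity
above the clustering floor), pools are mutually divergent (identity below
the floor), and each individual retains each cluster independently with a
per-cluster retention probability — the presence/absence variation (PAV)
phenomenon.  Planted copies are two-exon genes with a canonical GT..AG
intron, a degenerate promoter motif within the upstream window, random
strand, and optional pseudogenization (one mature-region codon mutated to
TAA).  Matched transcriptomes contain the spliced CDS of a random subset
of the carried functional clusters.

Every random draw flows from one seeded generator, so identical
configurations give byte-identical FASTA output.  Background sequence is
i.i.d. uniform A/C/G/T — the simplest null that cannot spuriously encode
the seed peptide at these lengths.  Mutations are substitution-only
(codon-respecting, never creating a stop), so planted alleles of one
family all share one length; real assemblies would add indels,
heterozygosity and repeats, which are out of scope here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .peptide_chemistry import PrecursorAnnotation
from .translated_search import STOP_CODONS, reverse_complement

IUPAC_NT = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

#: Degenerate promoter element planted upstream of every copy (30 bp,
#: the most conserved motif of the family's promoters).
DEFAULT_PROMOTER_MOTIF = "TGCTTGTTTAYTTWTAACAAYAATTTTAAG"


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Panel-generation parameters (defaults mirror the study conditions:
    16 individuals, 13 clusters, ~8 alleles per cluster, a 95% identity
    floor separating alleles from clusters, ~17% pseudogenization)."""

    n_individuals: int = 16
    n_clusters: int = 13
    alleles_per_cluster: int = 8
    within_cluster_divergence: float = 0.01
    between_cluster_divergence: float = 0.10
    retention_prob_per_cluster: float | tuple[float, ...] = 0.7
    pseudogene_prob: float = 0.17
    contig_length: int = 6000
    intron_length: int = 287
    promoter_motif: str = DEFAULT_PROMOTER_MOTIF
    promoter_window: int = 1000
    expression_prob: float = 0.6
    rng_seed: int = 0
    identity_threshold: float = 95.0
    background_contigs: int = 2
    max_retries: int = 100

    def __post_init__(self):
        counts = {
            "n_individuals": self.n_individuals,
            "n_clusters": self.n_clusters,
            "alleles_per_cluster": self.alleles_per_cluster,
            "contig_length": self.contig_length,
            "intron_length": self.intron_length,
            "promoter_window": self.promoter_window,
        }
        for name, v in counts.items():
            if v < 1:
                raise ValueError(f"{name} must be >= 1, got {v}")
        probs = {
            "pseudogene_prob": self.pseudogene_prob,
            "expression_prob": self.expression_prob,
            "within_cluster_divergence": self.within_cluster_divergence,
            "between_cluster_divergence": self.between_cluster_divergence,
        }
        for p in self.retention_probs:
            probs[f"retention({p})"] = p
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        if not 6 <= len(self.promoter_motif) <= 30:
            raise ValueError("promoter_motif length must be in [6, 30]")
        bad = set(self.promoter_motif.upper()) - set(IUPAC_NT)
        if bad:
            raise ValueError(f"promoter_motif has non-IUPAC symbols {sorted(bad)}")
        if self.within_cluster_divergence >= self.between_cluster_divergence:
            raise ValueError(
                "within_cluster_divergence must be < between_cluster_divergence"
            )

    @property
    def retention_probs(self) -> tuple[float, ...]:
        p = self.retention_prob_per_cluster
        if isinstance(p, (int, float)):
            return tuple([float(p)] * self.n_clusters)
        if len(p) != self.n_clusters:
            raise ValueError("retention_prob_per_cluster length != n_clusters")
        return tuple(float(x) for x in p)


# ---------------------------------------------------------------------------
# Seed precursor

# 23-residue signal, 54-residue mature peptide with a 12-cysteine
# (CC-C-C-CC-C-CC-C-C-C) array ending just before a KR dibasic site, and a
# 75-residue acidic C-terminal extension with an EF-hand-like loop.  This
# is a synthetic stand-in for the family's reference precursor, built to
# the reference architecture, not a natural sequence.
_SIGNAL = "MKLFVSLVALLLVASVALAQSEA"
_MATURE = (
    "G" + "CC" + "GWKVK" + "C" + "HRAYV" + "C" + "NKGH" + "CC" + "SKPWR"
    + "C" + "VGKGH" + "CC" + "SNRVT" + "C" + "IGYKG" + "C" + "AVSHK" + "C" + "GS"
)
_CTERM = (
    "KR" + "SLDEANELIGSEWQ" + "DKDGDGTIDFEE" + "FASLVGEMANDPE"
    + "AVDTNEDGFIEESELQ" + "SWIDANEGDESTGEDLNE"
)
assert len(_SIGNAL) == 23 and len(_MATURE) == 54 and len(_CTERM) == 75

#: One fixed sense codon per amino acid, for reverse translation.
_CODON_OF = {
    "A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGT",
    "Q": "CAA", "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT",
    "L": "CTG", "K": "AAA", "M": "ATG", "F": "TTT", "P": "CCT",
    "S": "TCT", "T": "ACT", "W": "TGG", "Y": "TAT", "V": "GTT",
}


@dataclass(frozen=True)
class SeedPrecursor:
    """The annotated seed peptide used as the search query."""

    protein: str
    cds: str  # includes the terminal stop codon
    annotation: PrecursorAnnotation

    @property
    def mature(self) -> str:
        s, e = self.annotation.mature
        return self.protein[s:e]


def default_seed() -> SeedPrecursor:
    protein = _SIGNAL + _MATURE + _CTERM
    cds = "".join(_CODON_OF[aa] for aa in protein) + "TAA"
    ann = PrecursorAnnotation((0, 23), (23, 77), (77, 152))
    return SeedPrecursor(protein, cds, ann)


def _protected_positions(seed: SeedPrecursor) -> frozenset:
    """Nucleotide positions that mutation must leave untouched: the start
    codon, the mature-region cysteine codons, the dibasic cleavage codons
    and the terminal stop."""
    protected = set(range(0, 3))
    m0, m1 = seed.annotation.mature
    for i, aa in enumerate(seed.protein):
        if (m0 <= i < m1 and aa == "C") or i in (m1, m1 + 1):
            protected.update(range(3 * i, 3 * i + 3))
    protected.update(range(len(seed.cds) - 3, len(seed.cds)))
    return frozenset(protected)


_BASES = "ACGT"


def mutate_cds(cds: str, rate: float, rng: np.random.Generator,
               protected: frozenset = frozenset()) -> str:
    """Substitution-only mutation at the given per-site rate.

    Codons that would become stops revert to the original codon, and
    protected positions never change, so the reading frame and the
    terminal stop survive any rate.
    """
    out = list(cds)
    for codon_start in range(0, len(cds) - len(cds) % 3, 3):
        original = cds[codon_start:codon_start + 3]
        codon = list(original)
        changed = False
        for k in range(3):
            pos = codon_start + k
            if pos in protected or rng.random() >= rate:
                continue
            codon[k] = _BASES[(_BASES.index(codon[k]) + rng.integers(1, 4)) % 4]
            changed = True
        new = "".join(codon)
        if changed and new in STOP_CODONS and original not in STOP_CODONS:
            codon = list(original)
        # never *gain* a cysteine: the disulfide array is the conserved,
        # family-defining trait the downstream typing relies on
        if changed and new in ("TGT", "TGC") and original not in ("TGT", "TGC"):
            codon = list(original)
        out[codon_start:codon_start + 3] = codon
    return "".join(out)


def _hamming_identity(a: str, b: str) -> float:
    assert len(a) == len(b)
    return 100.0 * sum(x == y for x, y in zip(a, b)) / len(a)


@dataclass
class FamilyPanel:
    """Allele pools per cluster plus the seed architecture."""

    seed: SeedPrecursor
    alleles: list[list[str]]  # alleles[cluster][allele] -> CDS (with stop)
    config: SimConfig

    @property
    def n_clusters(self) -> int:
        return len(self.alleles)


def generate_panel(config: SimConfig,
                   rng: np.random.Generator | None = None) -> FamilyPanel:
    """Draw cluster founder CDSs and allele pools satisfying the identity
    separation (within-pool identity above the floor, cross-pool below),
    with bounded rejection sampling; failure is loud."""
    rng = np.random.default_rng(config.rng_seed) if rng is None else rng
    seed = default_seed()
    protected = _protected_positions(seed)
    thr = config.identity_threshold
    for _ in range(config.max_retries):
        founders = [
            mutate_cds(seed.cds, config.between_cluster_divergence, rng, protected)
            for _ in range(config.n_clusters)
        ]
        pools = []
        for founder in founders:
            pool = [founder]
            for _ in range(config.alleles_per_cluster - 1):
                pool.append(
                    mutate_cds(founder, config.within_cluster_divergence, rng, protected)
                )
            pools.append(pool)
        ok = all(
            _hamming_identity(a, b) > thr
            for pool in pools
            for i, a in enumerate(pool)
            for b in pool[i + 1:]
        ) and all(
            _hamming_identity(a, b) < thr
            for ci, pa in enumerate(pools)
            for pb in pools[ci + 1:]
            for a in pa
            for b in pb
        )
        if ok:
            return FamilyPanel(seed, pools, config)
    raise SimulationError(
        "could not satisfy the identity separation after "
        f"{config.max_retries} retries; adjust the divergence settings"
    )


# ---------------------------------------------------------------------------
# Individuals

#: Codon-boundary CDS split point for the single phase-0 intron: 23 codons
#: into the C-terminal-extension coding region (the extension sits on its
#: own exon in the reference architecture).
_INTRON_SPLIT_CODON = 100


@dataclass(frozen=True)
class PlantedCopy:
    """Manifest row for one planted gene copy."""

    individual: str
    cluster: int
    allele: int
    contig: str
    strand: str
    exon_starts: tuple[int, ...]  # forward-strand, ascending
    exon_ends: tuple[int, ...]
    pseudogene: bool
    motif_offset: int  # bp from motif start to gene 5' start, coding strand
    motif_seq: str
    cds: str  # realized CDS (after any pseudogenization)


@dataclass
class Individual:
    individual_id: str
    contigs: list[tuple[str, str]]
    copies: list[PlantedCopy]


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list(_BASES))[rng.integers(0, 4, size=n)])


def _sample_motif(motif: str, rng: np.random.Generator) -> str:
    return "".join(
        IUPAC_NT[c][rng.integers(0, len(IUPAC_NT[c]))] for c in motif.upper()
    )


def _make_intron(config: SimConfig, exon1_tail: str, exon2_head: str,
                 rng: np.random.Generator) -> str:
    """Random GT..AG intron, re-drawn until the intron itself offers no
    competing phase-0 GT near the donor nor a competing AG near the
    acceptor (keeps splice-boundary recovery unambiguous)."""
    n = config.intron_length
    if n < 24:
        raise SimulationError("intron_length must be >= 24")
    d = len(exon1_tail)  # donor offset within the probe string
    for _ in range(config.max_retries):
        intron = "GT" + _random_dna(rng, n - 4) + "AG"
        probe = exon1_tail + intron + exon2_head
        a = d + n
        bad = any(
            probe[x:x + 2] == "GT" and x != d and (x - d) % 3 == 0
            for x in range(d, min(len(probe) - 1, d + 13))
        ) or any(
            probe[y - 2:y] == "AG" and y != a
            for y in range(max(2, a - 12), a + 1)
        )
        if not bad:
            return intron
    raise SimulationError("could not draw an unambiguous intron")


def pseudogenize(cds: str, seed: SeedPrecursor, rng: np.random.Generator) -> str:
    """Mutate one non-cysteine sense codon of the mature region to TAA."""
    m0, m1 = seed.annotation.mature
    candidates = [
        i for i in range(m0, m1)
        if seed.protein[i] != "C" and cds[3 * i:3 * i + 3] not in STOP_CODONS
    ]
    i = candidates[rng.integers(0, len(candidates))]
    return cds[:3 * i] + "TAA" + cds[3 * i + 3:]


def generate_individual(panel: FamilyPanel, config: SimConfig, index: int,
                        rng: np.random.Generator) -> Individual:
    """One genome: per cluster an independent retention draw; retained
    copies embedded as two-exon genes with a planted promoter motif."""
    ind_id = f"ind{index:02d}"
    contigs: list[tuple[str, str]] = []
    copies: list[PlantedCopy] = []
    motif_len = len(config.promoter_motif)
    retention = config.retention_probs
    for cluster in range(panel.n_clusters):
        if rng.random() >= retention[cluster]:
            continue
        allele = int(rng.integers(0, config.alleles_per_cluster))
        cds = panel.alleles[cluster][allele]
        pseudo = rng.random() < config.pseudogene_prob
        if pseudo:
            cds = pseudogenize(cds, panel.seed, rng)
        split = 3 * _INTRON_SPLIT_CODON
        exon1, exon2 = cds[:split], cds[split:]
        intron = _make_intron(config, exon1[-12:], exon2[:12], rng)
        gene = exon1 + intron + exon2

        min_start = config.promoter_window
        max_start = config.contig_length - len(gene) - 50
        if max_start <= min_start:
            raise SimulationError(
                "contig_length too small to host promoter window + gene"
            )
        gene_start = int(rng.integers(min_start, max_start + 1))
        background = _random_dna(rng, config.contig_length)
        motif_seq = _sample_motif(config.promoter_motif, rng)
        motif_offset = int(rng.integers(motif_len, config.promoter_window + 1))
        motif_start = gene_start - motif_offset
        contig = (
            background[:motif_start]
            + motif_seq
            + background[motif_start + motif_len:gene_start]
            + gene
            + background[gene_start + len(gene):]
        )
        exon_iv = [
            (gene_start, gene_start + len(exon1)),
            (gene_start + len(exon1) + len(intron), gene_start + len(gene)),
        ]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            L = len(contig)
            contig = reverse_complement(contig)
            exon_iv = sorted((L - e, L - s) for s, e in exon_iv)
        contig_id = f"{ind_id}_c{cluster:02d}"
        contigs.append((contig_id, contig))
        copies.append(
            PlantedCopy(
                individual=ind_id,
                cluster=cluster,
                allele=allele,
                contig=contig_id,
                strand=strand,
                exon_starts=tuple(s for s, _ in exon_iv),
                exon_ends=tuple(e for _, e in exon_iv),
                pseudogene=pseudo,
                motif_offset=motif_offset,
                motif_seq=motif_seq,
                cds=cds,
            )
        )
    for j in range(config.background_contigs):
        contigs.append((f"{ind_id}_bg{j}", _random_dna(rng, config.contig_length)))
    _check_manifest(copies, dict(contigs))
    return Individual(ind_id, contigs, copies)


def _check_manifest(copies: list[PlantedCopy], contigs: dict[str, str]) -> None:
    for c in copies:
        iv = list(zip(c.exon_starts, c.exon_ends))
        assert iv == sorted(iv) and all(s < e for s, e in iv)
        assert all(e1 <= s2 for (_, e1), (s2, _) in zip(iv, iv[1:]))
        seq = contigs[c.contig]
        assert iv[-1][1] <= len(seq)
        coding = seq if c.strand == "+" else reverse_complement(seq)
        L = len(seq)
        civ = iv if c.strand == "+" else sorted((L - e, L - s) for s, e in iv)
        for (_, e1), (s2, _) in zip(civ, civ[1:]):
            assert coding[e1:e1 + 2] == "GT" and coding[s2 - 2:s2] == "AG"
        spliced = "".join(coding[s:e] for s, e in civ)
        assert spliced == c.cds


# ---------------------------------------------------------------------------
# Transcriptomes

@dataclass
class Transcriptome:
    individual_id: str
    transcripts: list[tuple[str, str]]
    expressed: set  # cluster indices
    edits: list[tuple[int, int, str, str]]  # (cluster, pos, genomic, transcript)


def generate_transcriptome(individual: Individual, config: SimConfig,
                           rng: np.random.Generator,
                           plant_edit: bool = False) -> Transcriptome:
    """Spliced transcripts of a random subset of carried functional
    clusters; optionally plant one single-nucleotide edit (RNA-editing
    test fixture) in the first emitted transcript."""
    transcripts = []
    expressed = set()
    edits = []
    for copy in individual.copies:
        if copy.pseudogene or rng.random() >= config.expression_prob:
            continue
        seq = copy.cds
        if plant_edit and not edits:
            pos = int(rng.integers(3, len(seq) - 3))
            old = seq[pos]
            new = _BASES[(_BASES.index(old) + 1 + rng.integers(0, 3)) % 4]
            seq = seq[:pos] + new + seq[pos + 1:]
            edits.append((copy.cluster, pos, old, new))
        transcripts.append((f"{individual.individual_id}_t{copy.cluster:02d}", seq))
        expressed.add(copy.cluster)
    return Transcriptome(individual.individual_id, transcripts, expressed, edits)


# ---------------------------------------------------------------------------
# Cohort + manifest

@dataclass
class GroundTruthManifest:
    """The simulator's complete record of what was planted where."""

    config: SimConfig
    alleles: list[list[str]]
    copies: list[PlantedCopy] = field(default_factory=list)
    expressed: dict[str, set] = field(default_factory=dict)
    edits: dict[str, list] = field(default_factory=dict)

    def copies_of(self, individual_id: str) -> list[PlantedCopy]:
        return [c for c in self.copies if c.individual == individual_id]

    def distinct_cds(self, include_pseudogenes: bool = True) -> set:
        return {
            c.cds for c in self.copies if include_pseudogenes or not c.pseudogene
        }

    def cluster_of_cds(self) -> dict[str, int]:
        return {c.cds: c.cluster for c in self.copies}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "individual": c.individual,
                "cluster": c.cluster,
                "allele": c.allele,
                "contig": c.contig,
                "strand": c.strand,
                "exon_starts": ",".join(map(str, c.exon_starts)),
                "exon_ends": ",".join(map(str, c.exon_ends)),
                "pseudogene": c.pseudogene,
                "motif_offset": c.motif_offset,
            }
            for c in self.copies
        ]
        return pd.DataFrame(rows)


@dataclass
class Cohort:
    panel: FamilyPanel
    individuals: list[Individual]
    transcriptomes: list[Transcriptome]
    manifest: GroundTruthManifest

    @property
    def genomes(self) -> dict[str, list[tuple[str, str]]]:
        return {ind.individual_id: ind.contigs for ind in self.individuals}

    @property
    def transcript_sets(self) -> dict[str, list[tuple[str, str]]]:
        return {t.individual_id: t.transcripts for t in self.transcriptomes}


def generate_cohort(config: SimConfig, plant_edit: bool = False) -> Cohort:
    """Full panel + individuals + transcriptomes from one seeded RNG."""
    rng = np.random.default_rng(config.rng_seed)
    panel = generate_panel(config, rng)
    individuals = [
        generate_individual(panel, config, i, rng)
        for i in range(config.n_individuals)
    ]
    transcriptomes = [
        generate_transcriptome(ind, config, rng, plant_edit=plant_edit and i == 0)
        for i, ind in enumerate(individuals)
    ]
    manifest = GroundTruthManifest(config, panel.alleles)
    for ind in individuals:
        manifest.copies.extend(ind.copies)
    for t in transcriptomes:
        manifest.expressed[t.individual_id] = t.expressed
        manifest.edits[t.individual_id] = t.edits
    return Cohort(panel, individuals, transcriptomes, manifest)
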