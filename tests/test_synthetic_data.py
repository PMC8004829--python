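"""Synthetic panel generator: identity separation, determinism, manifest truth."""

import numpy as np
import pytest

from mytipav.io import write_fasta
from mytipav.synthetic_data import (
    SimConfig,
    SimulationError,
    default_seed,
    generate_cohort,
    generate_panel,
    mutate_cds,
)
from mytipav.translated_search import STOP_CODONS, reverse_complement


def _hamming_identity(a, b):
    return 100.0 * sum(x == y for x, y in zip(a, b)) / len(a)


def test_config_validation():
    with pytest.raises(ValueError, match="within_cluster_divergence"):
        SimConfig(within_cluster_divergence=0.3, between_cluster_divergence=0.1)
    with pytest.raises(ValueError, match=r"\[0, 1\]"):
        SimConfig(pseudogene_prob=1.5)
    with pytest.raises(ValueError, match="promoter_motif"):
        SimConfig(promoter_motif="ACGT")  # too short
    with pytest.raises(ValueError, match=">= 1"):
        SimConfig(n_clusters=0)


def test_seed_precursor_architecture():
    """The planted precursor follows the reference architecture: a
    23-residue signal, 54-residue mature peptide and 75-residue
    C-terminal extension."""
    seed = default_seed()
    assert seed.annotation.signal == (0, 23)
    assert seed.annotation.mature == (23, 77)
    assert seed.annotation.c_terminal == (77, 152)
    assert len(seed.protein) == 23 + 54 + 75
    assert len(seed.cds) == 3 * len(seed.protein) + 3


def test_degenerate_single_allele_panel():
    cfg = SimConfig(n_individuals=1, n_clusters=1, alleles_per_cluster=1, rng_seed=0)
    panel = generate_panel(cfg)
    assert len(panel.alleles) == 1 and len(panel.alleles[0]) == 1


def test_identity_separation_verified_by_alignment_oracle():
    """Within-pool identities all above 95%, cross-pool all below, for
    every pair — checked against exhaustive pairwise global alignment."""
    from mytipav.variant_catalogue import pairwise_identity

    cfg = SimConfig(
        n_individuals=1, n_clusters=3, alleles_per_cluster=2,
        within_cluster_divergence=0.01, between_cluster_divergence=0.30,
        rng_seed=7,
    )
    panel = generate_panel(cfg)
    pools = panel.alleles
    for pool in pools:
        for i, a in enumerate(pool):
            for b in pool[i + 1:]:
                assert pairwise_identity(a, b) > 95.0
    for ci, pa in enumerate(pools):
        for pb in pools[ci + 1:]:
            for a in pa:
                for b in pb:
                    assert pairwise_identity(a, b) < 95.0


def test_impossible_separation_fails_loudly():
    cfg = SimConfig(
        within_cluster_divergence=0.049, between_cluster_divergence=0.05,
        n_clusters=3, alleles_per_cluster=3, max_retries=3, rng_seed=0,
    )
    with pytest.raises(SimulationError, match="identity separation"):
        generate_panel(cfg)


def test_mutation_preserves_frame_and_protected_sites():
    rng = np.random.default_rng(0)
    seed = default_seed()
    mutated = mutate_cds(seed.cds, 0.5, rng, frozenset(range(3)))
    assert len(mutated) == len(seed.cds)
    assert mutated[:3] == "ATG"
    for i in range(0, len(mutated) - 3, 3):
        assert mutated[i:i + 3] not in STOP_CODONS


def test_retention_limits():
    base = dict(n_individuals=3, n_clusters=2, alleles_per_cluster=1,
                contig_length=3000, rng_seed=5)
    all_in = generate_cohort(SimConfig(retention_prob_per_cluster=1.0, **base))
    assert all(len(ind.copies) == 2 for ind in all_in.individuals)
    none_in = generate_cohort(SimConfig(retention_prob_per_cluster=0.0, **base))
    assert all(ind.copies == [] for ind in none_in.individuals)
    # background-only contigs remain
    assert all(len(ind.contigs) == 2 for ind in none_in.individuals)


def test_no_pseudogenes_when_probability_zero(small_cohort):
    from Bio.Seq import Seq

    for copy in small_cohort.manifest.copies:
        protein = str(Seq(copy.cds).translate())
        assert protein.count("*") == 1 and protein.endswith("*")


def test_contig_too_small_fails():
    cfg = SimConfig(n_individuals=1, n_clusters=1, alleles_per_cluster=1,
                    retention_prob_per_cluster=1.0, contig_length=1200, rng_seed=0)
    with pytest.raises(SimulationError, match="contig_length too small"):
        generate_cohort(cfg)


def test_manifest_geometry_and_splice_sites(small_cohort):
    """Exons are disjoint, ordered, within the contig; introns start GT
    and end AG on the coding strand; the spliced exons equal the CDS."""
    contigs = {cid: s for ind in small_cohort.individuals for cid, s in ind.contigs}
    for c in small_cohort.manifest.copies:
        iv = list(zip(c.exon_starts, c.exon_ends))
        assert iv == sorted(iv)
        seq = contigs[c.contig]
        coding = seq if c.strand == "+" else reverse_complement(seq)
        L = len(seq)
        civ = iv if c.strand == "+" else sorted((L - e, L - s) for s, e in iv)
        for (_, e1), (s2, _) in zip(civ, civ[1:]):
            assert coding[e1:e1 + 2] == "GT"
            assert coding[s2 - 2:s2] == "AG"
        assert "".join(coding[s:e] for s, e in civ) == c.cds


def test_promoter_motif_planted_at_manifest_offset(small_cohort):
    """The sampled motif instance sits motif_offset bp upstream of the
    gene start on the coding strand."""
    contigs = {cid: s for ind in small_cohort.individuals for cid, s in ind.contigs}
    for c in small_cohort.manifest.copies:
        seq = contigs[c.contig]
        coding = seq if c.strand == "+" else reverse_complement(seq)
        L = len(seq)
        if c.strand == "+":
            gene_start = c.exon_starts[0]
        else:
            gene_start = L - c.exon_ends[-1]
        mstart = gene_start - c.motif_offset
        assert coding[mstart:mstart + len(c.motif_seq)] == c.motif_seq


def test_seeded_determinism_byte_identical(tmp_path):
    cfg = SimConfig(n_individuals=2, n_clusters=2, alleles_per_cluster=2,
                    contig_length=3000, rng_seed=42)
    paths = []
    for run in range(2):
        cohort = generate_cohort(cfg)
        p = tmp_path / f"run{run}.fa"
        write_fasta(
            [(cid, s) for ind in cohort.individuals for cid, s in ind.contigs], p
        )
        paths.append(p.read_bytes())
    assert paths[0] == paths[1]


class TestTranscriptomes:
    def test_expression_limits(self):
        base = dict(n_individuals=2, n_clusters=2, alleles_per_cluster=1,
                    retention_prob_per_cluster=1.0, pseudogene_prob=0.0,
                    contig_length=3000, rng_seed=13)
        full = generate_cohort(SimConfig(expression_prob=1.0, **base))
        for t in full.transcriptomes:
            assert len(t.transcripts) == 2
        empty = generate_cohort(SimConfig(expression_prob=0.0, **base))
        assert all(t.transcripts == [] for t in empty.transcriptomes)

    def test_transcript_translation_equals_genomic(self):
        from Bio.Seq import Seq

        cohort = generate_cohort(
            SimConfig(n_individuals=2, n_clusters=2, alleles_per_cluster=1,
                      retention_prob_per_cluster=1.0, pseudogene_prob=0.0,
                      expression_prob=1.0, contig_length=3000, rng_seed=13)
        )
        cds_by = {(c.individual, c.cluster): c.cds for c in cohort.manifest.copies}
        for t in cohort.transcriptomes:
            for tx_id, seq in t.transcripts:
                cluster = int(tx_id.rsplit("_t", 1)[1])
                genomic = cds_by[(t.individual_id, cluster)]
                assert str(Seq(seq).translate()) == str(Seq(genomic).translate())

    def test_planted_edit_recorded(self):
        cohort = generate_cohort(
            SimConfig(n_individuals=1, n_clusters=2, alleles_per_cluster=1,
                      retention_prob_per_cluster=1.0, pseudogene_prob=0.0,
                      expression_prob=1.0, contig_length=3000, rng_seed=19),
            plant_edit=True,
        )
        edits = cohort.manifest.edits["ind00"]
        assert len(edits) == 1
        cluster, pos, old, new = edits[0]
        genomic = {c.cluster: c.cds for c in cohort.manifest.copies}[cluster]
        tx = dict(cohort.transcriptomes[0].transcripts)[f"ind00_t{cluster:02d}"]
        assert genomic[pos] == old and tx[pos] == new
        assert old != new
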