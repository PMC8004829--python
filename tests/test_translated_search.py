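"""Six-frame translation, local alignment and variant recovery."""

import numpy as np
import pytest

from mytipav import translated_search as ts
from mytipav.align import DEFAULT_SCHEME, ScoringScheme, local_align

from helpers import (
    brute_force_local_score,
    revcomp,
    translate_codon_lookup,
)

from conftest import FIXTURE_MIN_SCORE


class TestSixFrameTranslate:
    def test_simple_codons(self):
        frames = {(f.strand, f.frame): f for f in ts.six_frame_translate("ATGGCC")}
        assert frames[("+", 0)].peptide == "MA"

    def test_strand_symmetry(self):
        """Searching the reverse complement on minus frames yields the
        same peptide as the plus frame of the original."""
        rng = np.random.default_rng(1)
        dna = "".join(np.random.default_rng(1).choice(list("ACGT"), size=99))
        fwd = {f.frame: f.peptide for f in ts.six_frame_translate(dna) if f.strand == "+"}
        rc_minus = {
            f.frame: f.peptide
            for f in ts.six_frame_translate(revcomp(dna))
            if f.strand == "-"
        }
        assert fwd == rc_minus

    def test_matches_per_codon_lookup_oracle(self):
        rng = np.random.default_rng(2)
        dna = "".join(rng.choice(list("ACGT"), size=300))
        for frame in ts.six_frame_translate(dna):
            coding = dna if frame.strand == "+" else revcomp(dna)
            sub = coding[frame.frame:]
            expected = translate_codon_lookup(sub)
            assert frame.peptide == expected

    def test_coordinate_maps_invert(self):
        dna = "".join(np.random.default_rng(3).choice(list("ACGT"), size=60))
        for frame in ts.six_frame_translate(dna):
            s, e = frame.forward_interval(2, 5)
            assert e - s == 9
            region = dna[s:e]
            if frame.strand == "-":
                region = revcomp(region)
            assert translate_codon_lookup(region) == frame.peptide[2:5]

    def test_empty_and_invalid(self):
        assert all(f.peptide == "" for f in ts.six_frame_translate(""))
        with pytest.raises(ValueError, match="non-ACGTN"):
            ts.six_frame_translate("ATGQ")

    def test_n_translates_to_x(self):
        assert ts.six_frame_translate("ATGNNN")[0].peptide == "MX"


class TestLocalAlign:
    def test_self_alignment_is_diagonal_score(self):
        pep = "MKTAYIAKQRQISFVKSHFS"
        aln = local_align(pep, pep)
        matrix = DEFAULT_SCHEME.matrix
        assert aln.identity == 100.0
        assert aln.score == sum(matrix[c, c] for c in pep)

    def test_reversal_scores_strictly_less(self):
        pep = "MKTAYIAKQRQISFVKSHFS"
        self_score = local_align(pep, pep).score
        rev = local_align(pep, pep[::-1])
        assert rev is None or rev.score < self_score

    def test_score_symmetry(self):
        rng = np.random.default_rng(7)
        alphabet = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(20):
            a = "".join(rng.choice(alphabet, size=rng.integers(5, 30)))
            b = "".join(rng.choice(alphabet, size=rng.integers(5, 30)))
            ra, rb = local_align(a, b), local_align(b, a)
            sa = ra.score if ra else 0.0
            sb = rb.score if rb else 0.0
            assert sa == pytest.approx(sb)

    def test_matches_exhaustive_enumeration(self):
        """Optimal local score equals a brute-force enumeration of every
        alignment of every substring pair on short peptides."""
        rng = np.random.default_rng(13)
        alphabet = list("ARNDCQEGHK")
        matrix = DEFAULT_SCHEME.matrix
        for _ in range(8):
            a = "".join(rng.choice(alphabet, size=5))
            b = "".join(rng.choice(alphabet, size=5))
            expected = brute_force_local_score(
                a, b, matrix, DEFAULT_SCHEME.gap_open, DEFAULT_SCHEME.gap_extend
            )
            aln = local_align(a, b)
            got = aln.score if aln else 0.0
            assert got == pytest.approx(expected)

    def test_rejects_unknown_residue_by_name(self):
        with pytest.raises(ValueError, match="J"):
            local_align("MKJ", "MKT")
        with pytest.raises(ValueError, match="empty"):
            local_align("", "MKT")


class TestChainExons:
    def test_recovers_manifest_exons_exactly(self, small_cohort, seed_precursor):
        contigs = {
            cid: seq for ind in small_cohort.individuals for cid, seq in ind.contigs
        }
        for copy in small_cohort.manifest.copies:
            hits = ts.scan_contig(copy.contig, contigs[copy.contig], seed_precursor.protein)
            strand_hits = [h for h in hits if h.strand == copy.strand]
            model = ts.chain_exons(strand_hits, contigs[copy.contig],
                                   query=seed_precursor.protein)
            assert model.strand == copy.strand
            assert tuple(sorted(model.exons)) == tuple(
                sorted(zip(copy.exon_starts, copy.exon_ends))
            )
            assert model.cds == copy.cds
            assert not model.partial

    def test_single_uninterrupted_cds_is_one_exon(self, seed_precursor):
        rng = np.random.default_rng(4)
        background = "".join(rng.choice(list("ACGT"), size=2000))
        cds = seed_precursor.cds
        contig = background[:700] + cds + background[700 + len(cds):]
        hits = ts.scan_contig("c", contig, seed_precursor.protein)
        model = ts.chain_exons(
            [h for h in hits if h.strand == "+"], contig, query=seed_precursor.protein
        )
        assert len(model.exons) == 1
        assert model.cds == cds
        assert not model.partial

    def test_opposite_query_order_not_chained(self, seed_precursor):
        """Hits whose query order contradicts their genomic order cannot
        be one gene; the best single hit is returned flagged partial."""
        rng = np.random.default_rng(9)
        background = "".join(rng.choice(list("ACGT"), size=3000))
        cds = seed_precursor.cds
        # plant the C-terminal half upstream of the N-terminal half, in a
        # different frame so both surface as separate hits
        first, second = cds[:228], cds[228:]
        contig = (
            background[:301] + second + background[301 + len(second):1500]
            + first + background[1500 + len(first):]
        )
        hits = [h for h in ts.scan_contig("c", contig, seed_precursor.protein)
                if h.strand == "+"]
        assert len(hits) >= 2
        model = ts.chain_exons(hits, contig, query=seed_precursor.protein)
        assert model.partial


class TestRecoverVariants:
    def test_full_retention_every_variant_everywhere(self, small_cohort, small_search):
        """Retention 1.0: every distinct planted allele that was actually
        drawn appears as a variant carried by its planting genomes."""
        manifest_cds = small_cohort.manifest.distinct_cds()
        assert {v.cds for v in small_search.variants} == manifest_cds

    def test_shared_allele_deduplicates_to_one_record(self):
        from mytipav.synthetic_data import SimConfig, generate_cohort

        cfg = SimConfig(
            n_individuals=2, n_clusters=1, alleles_per_cluster=1,
            retention_prob_per_cluster=1.0, pseudogene_prob=0.0,
            contig_length=4000, rng_seed=21,
        )
        cohort = generate_cohort(cfg)
        seed = cohort.panel.seed
        res = ts.recover_variants(
            cohort.genomes, seed.protein, seed.annotation.mature,
            min_score=FIXTURE_MIN_SCORE,
        )
        assert len(res.variants) == 1
        assert res.variants[0].carriers == ("ind00", "ind01")

    def test_strand_invariance(self, small_cohort, small_search, seed_precursor):
        flipped = {
            g: [(cid, ts.reverse_complement(seq)) for cid, seq in contigs]
            for g, contigs in small_cohort.genomes.items()
        }
        res = ts.recover_variants(
            flipped, seed_precursor.protein, seed_precursor.annotation.mature,
            min_score=FIXTURE_MIN_SCORE,
        )
        assert {v.cds for v in res.variants} == {v.cds for v in small_search.variants}

    def test_no_hits_in_pure_background(self, seed_precursor):
        """Motif-free random contigs yield zero variants above the
        calibrated threshold (10 replicate genomes)."""
        rng = np.random.default_rng(77)
        genomes = {
            f"bg{i:02d}": [
                ("c0", "".join(rng.choice(list("ACGT"), size=3000)))
            ]
            for i in range(10)
        }
        res = ts.recover_variants(
            genomes, seed_precursor.protein, seed_precursor.annotation.mature,
            calibration_rng=1, calibration_shuffles=200,
        )
        assert res.variants == []

    def test_full_recall_at_moderate_divergence(self, seed_precursor):
        """All planted functional copies are recovered when the family
        diverges up to 0.15 substitutions/site from the seed."""
        from mytipav.synthetic_data import SimConfig, generate_cohort

        cfg = SimConfig(
            n_individuals=2, n_clusters=3, alleles_per_cluster=2,
            between_cluster_divergence=0.15,
            retention_prob_per_cluster=1.0, pseudogene_prob=0.0,
            contig_length=4000, rng_seed=31,
        )
        cohort = generate_cohort(cfg)
        res = ts.recover_variants(
            cohort.genomes, seed_precursor.protein,
            seed_precursor.annotation.mature, min_score=FIXTURE_MIN_SCORE,
        )
        assert {v.cds for v in res.variants} >= cohort.manifest.distinct_cds()


def test_calibrated_threshold_above_null_below_signal(seed_precursor):
    thr = ts.calibrate_score_threshold(
        seed_precursor.protein, rng=0, n_shuffles=100, contig_length=1000
    )
    assert 40.0 < thr < 120.0
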