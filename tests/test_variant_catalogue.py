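"""Identity, clustering, consensus, pseudogene flagging and PAV tables."""

import numpy as np
import pytest

from mytipav import variant_catalogue as vc
from mytipav.align import DEFAULT_SCHEME
from mytipav.synthetic_data import SimConfig, generate_cohort, generate_panel

from helpers import brute_force_global_identity


def _variants_from_pools(pools):
    out = []
    k = 0
    for pool in pools:
        for cds in pool:
            out.append(
                vc.VariantRecord(f"v{k:03d}", cds, "", False, carriers=("g0",))
            )
            k += 1
    return out


class TestPairwiseIdentity:
    def test_trivial_values(self):
        assert vc.pairwise_identity("ACGTACGT", "ACGTACGT") == 100.0
        assert vc.pairwise_identity("AAAA", "AAAT") == 75.0

    def test_errors(self):
        with pytest.raises(ValueError, match="empty"):
            vc.pairwise_identity("", "AAA")
        with pytest.raises(ValueError, match="alphabet"):
            vc.pairwise_identity("ACGT", "MKWF")

    def test_matches_exhaustive_global_enumeration(self):
        """Identity of the optimal global alignment agrees with brute
        force over all alignments on short peptide pairs."""
        rng = np.random.default_rng(19)
        alphabet = list("ARNDCQEG")
        matrix = DEFAULT_SCHEME.matrix
        for _ in range(6):
            # leading W keeps the autodetector in protein mode
            a = "W" + "".join(rng.choice(alphabet, size=4))
            b = "W" + "".join(rng.choice(alphabet, size=rng.integers(3, 6)))
            expected = brute_force_global_identity(
                a, b, matrix, DEFAULT_SCHEME.gap_open, DEFAULT_SCHEME.gap_extend
            )
            assert vc.pairwise_identity(a, b) == pytest.approx(expected)


class TestClustering:
    def test_threshold_splits_and_merges(self):
        base = "ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTAC"  # 50 nt
        near = "T" + base[1:49] + "G"  # 2 mismatches -> 96%
        far = "TTTTT" + base[5:]  # 5 mismatches -> 90%
        v = [
            vc.VariantRecord("a", base, "", False),
            vc.VariantRecord("b", near, "", False),
        ]
        assert len(vc.cluster_variants(v)) == 1
        v2 = [
            vc.VariantRecord("a", base, "", False),
            vc.VariantRecord("c", far, "", False),
        ]
        assert len(vc.cluster_variants(v2)) == 2

    @pytest.mark.parametrize("k,seed", [(2, 1), (5, 2), (13, 3)])
    def test_recovers_planted_pools(self, k, seed):
        """Clustering a planted k-pool panel returns exactly k clusters
        whose membership equals the manifest pools."""
        cfg = SimConfig(
            n_individuals=1, n_clusters=k, alleles_per_cluster=3,
            rng_seed=seed,
        )
        panel = generate_panel(cfg)
        variants = _variants_from_pools(panel.alleles)
        clusters = vc.cluster_variants(variants)
        assert len(clusters) == k
        cds_of = {v.variant_id: v.cds for v in variants}
        got = {frozenset(cds_of[m] for m in c.members) for c in clusters}
        expected = {frozenset(pool) for pool in panel.alleles}
        assert got == expected

    def test_complete_linkage_guarantee(self):
        """Every reported cluster satisfies the all-pairs identity floor."""
        cfg = SimConfig(n_individuals=1, n_clusters=4, alleles_per_cluster=4,
                        rng_seed=9)
        panel = generate_panel(cfg)
        clusters = vc.cluster_variants(_variants_from_pools(panel.alleles))
        for c in clusters:
            assert c.min_identity > 95.0

    def test_partition_invariant_to_input_order(self):
        cfg = SimConfig(n_individuals=1, n_clusters=3, alleles_per_cluster=3,
                        rng_seed=5)
        panel = generate_panel(cfg)
        variants = _variants_from_pools(panel.alleles)
        shuffled = [variants[i] for i in np.random.default_rng(0).permutation(len(variants))]
        part = lambda cl, vs: {
            frozenset(
                next(v.cds for v in vs if v.variant_id == m) for m in c.members
            )
            for c in cl
        }
        assert part(vc.cluster_variants(variants), variants) == part(
            vc.cluster_variants(shuffled), shuffled
        )

    def test_labels_by_decreasing_size(self):
        cfg = SimConfig(n_individuals=1, n_clusters=2, alleles_per_cluster=4,
                        rng_seed=2)
        panel = generate_panel(cfg)
        pools = [panel.alleles[0], panel.alleles[1][:2]]  # sizes 4 and 2
        clusters = vc.cluster_variants(_variants_from_pools(pools))
        assert [c.label for c in clusters] == ["A", "B"]
        assert len(clusters[0].members) == 4


class TestConsensus:
    def test_single_member_is_identity(self):
        nt, prot = vc.consensus(["ATGAAATTTTAA"])
        assert nt == "ATGAAATTTTAA"
        assert prot == "MKF"

    def test_polymorphic_residue_becomes_x_and_iupac(self):
        # AAA (K) vs AGA (R): protein column -> X, nucleotide A/G -> R
        nt, prot = vc.consensus(["ATGAAATTT", "ATGAGATTT"])
        assert prot == "MXF"
        assert nt == "ATGARATTT"

    def test_iupac_codes_minimal(self):
        nt, _ = vc.consensus(["ATGA", "ATGC", "ATGT"])
        assert nt == "ATGH"  # A/C/T


class TestPseudogeneFlagging:
    def test_internal_stop_flags_terminal_does_not(self):
        v = [
            vc.VariantRecord("p", "ATGTAATTTTAA", "", False),
            vc.VariantRecord("f", "ATGAAATTTTGA", "", False),
            vc.VariantRecord("part", "ATGAAAT", "", False),
        ]
        flagged, counts = vc.flag_pseudogenes(v)
        assert flagged[0].pseudogene and not flagged[1].pseudogene
        assert flagged[2].partial
        assert counts == {"functional": 1, "pseudogene": 1, "partial": 1}

    def test_simulated_pseudogene_set_matches_manifest(self):
        """Flags derived from the CDS alone reproduce the simulator's
        pseudogenization record over ~100 planted copies."""
        cfg = SimConfig(
            n_individuals=8, n_clusters=13, alleles_per_cluster=4,
            retention_prob_per_cluster=1.0, pseudogene_prob=0.2,
            rng_seed=11,
        )
        cohort = generate_cohort(cfg)
        copies = cohort.manifest.copies
        assert len(copies) == 8 * 13
        variants = [
            vc.VariantRecord(f"v{i}", c.cds, "", False) for i, c in enumerate(copies)
        ]
        flagged, _ = vc.flag_pseudogenes(variants)
        for rec, copy in zip(flagged, copies):
            assert rec.pseudogene == copy.pseudogene


class TestPAV:
    def test_all_retained_frequencies_one(self, small_cohort, small_search):
        variants, _ = vc.flag_pseudogenes(small_search.variants)
        clusters = vc.cluster_variants(variants)
        pav = vc.build_pav(variants, sorted(small_cohort.genomes), clusters)
        assert (pav.cluster_frequency == 1.0).all()

    def test_matrix_matches_manifest(self, small_cohort, small_search):
        variants, _ = vc.flag_pseudogenes(small_search.variants)
        clusters = vc.cluster_variants(variants)
        pav = vc.build_pav(variants, sorted(small_cohort.genomes), clusters)
        by_cds = {v.cds: v.variant_id for v in variants}
        for copy in small_cohort.manifest.copies:
            assert pav.variant_matrix.loc[by_cds[copy.cds], copy.individual]
        # column sums equal per-genome variant counts
        for g in pav.variant_matrix.columns:
            expected = len(
                {c.cds for c in small_cohort.manifest.copies if c.individual == g}
            )
            assert pav.variant_matrix[g].sum() == expected

    def test_unique_variant_counting(self):
        v = [
            vc.VariantRecord("a", "ATGAAATTTTAA", "MKF", False, carriers=("g0",)),
            vc.VariantRecord("b", "ATGAAAGGGTAA", "MKG", False, carriers=("g0", "g1")),
        ]
        clusters = vc.cluster_variants(v)
        pav = vc.build_pav(v, ["g0", "g1"], clusters)
        assert pav.mean_variants_per_genome == pytest.approx(1.5)
        assert pav.mean_unique_variants_per_genome == pytest.approx(0.5)

    def test_observed_retention_matches_binomial_oracle(self):
        """Across 200 seeded panels with retention 0.5 and 16 individuals,
        the mean cluster occurrence frequency stays within three standard
        errors of 0.5 (binomial sampling)."""
        draws = []
        for seed in range(200):
            cfg = SimConfig(
                n_individuals=16, n_clusters=2, alleles_per_cluster=1,
                retention_prob_per_cluster=0.5, pseudogene_prob=0.0,
                contig_length=2000, rng_seed=1000 + seed,
            )
            cohort = generate_cohort(cfg)
            carried = np.zeros((2, 16))
            for c in cohort.manifest.copies:
                carried[c.cluster, int(c.individual[3:])] = 1
            draws.append(carried.mean())
        n = 200 * 16 * 2
        se = np.sqrt(0.25 / n)
        assert abs(np.mean(draws) - 0.5) < 3 * se
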