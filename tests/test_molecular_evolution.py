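"""Codon alignment, distances, NJ trees, Fitch parsimony and site selection."""

import itertools

import numpy as np
import pytest
from skbio import DistanceMatrix, TreeNode

from mytipav import molecular_evolution as me

from helpers import brute_force_fitch_cost


class TestCodonAlign:
    def test_identical_pair_no_gaps(self):
        aln = me.codon_align({"a": "ATGAAATTT", "b": "ATGAAATTT"})
        assert aln.rows == ("ATGAAATTT", "ATGAAATTT")

    def test_inframe_insertion_gives_one_codon_gap(self):
        aln = me.codon_align({"a": "ATGAAAGGCTGGTTT", "b": "ATGAAATGGTTT"})
        short = dict(zip(aln.ids, aln.rows))["b"]
        assert len(short) == 15
        assert short.count("-") == 3
        assert "---" in short

    def test_rejects_internal_stop_with_id(self):
        with pytest.raises(ValueError, match="bad_variant"):
            me.codon_align({"bad_variant": "ATGTAATTT"})

    def test_degap_round_trip_on_simulated_families(self):
        from mytipav.synthetic_data import SimConfig, generate_panel

        for seed in range(5):
            cfg = SimConfig(n_individuals=1, n_clusters=2, alleles_per_cluster=3,
                            rng_seed=seed)
            panel = generate_panel(cfg)
            cds_by_id = {
                f"c{ci}a{ai}": cds
                for ci, pool in enumerate(panel.alleles)
                for ai, cds in enumerate(pool)
            }
            aln = me.codon_align(cds_by_id)
            for vid, row in zip(aln.ids, aln.rows):
                expected = cds_by_id[vid]
                if expected[-3:] in {"TAA", "TAG", "TGA"}:
                    expected = expected[:-3]
                assert row.replace("-", "") == expected


class TestPDistance:
    def test_trivial_values(self):
        aln = me.CodonAlignment(("a", "b"), ("ATGAAATTT", "ATGAAATTT"))
        assert me.p_distance(aln)["a", "b"] == 0.0

    def test_counts_only_comparable_columns(self):
        ids = ("a", "b")
        rows = ("ACGTACGTAC--", "ACGAACGAAC--")  # 2 diffs in 10 ungapped
        assert me.p_distance((ids, rows))["a", "b"] == pytest.approx(0.2)

    def test_matches_hand_enumerated_toy(self):
        ids = ("s1", "s2", "s3", "s4")
        rows = (
            "ATGAAATTTGGG",
            "ATGAAATTTGGC",  # 1/12 vs s1
            "ATGAACTTAGGG",  # 2/12 vs s1
            "ATG---TTTGGG",  # 0/9 vs s1
        )
        dm = me.p_distance((ids, rows))
        assert dm["s1", "s2"] == pytest.approx(1 / 12)
        assert dm["s1", "s3"] == pytest.approx(2 / 12)
        assert dm["s1", "s4"] == pytest.approx(0.0)
        assert dm["s2", "s4"] == pytest.approx(1 / 9)

    def test_no_comparable_columns_fails(self):
        with pytest.raises(ValueError, match="a.*b"):
            me.p_distance((("a", "b"), ("AAA---", "---AAA")))


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        """NJ on three taxa returns the closed-form star solution:
        l_a = (d_ab + d_ac - d_bc)/2, etc."""
        d_ab, d_ac, d_bc = 0.3, 0.5, 0.6
        dm = DistanceMatrix(
            [[0, d_ab, d_ac], [d_ab, 0, d_bc], [d_ac, d_bc, 0]], ["a", "b", "c"]
        )
        tree = me.nj_tree(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["a"] == pytest.approx((d_ab + d_ac - d_bc) / 2)
        assert lengths["b"] == pytest.approx((d_ab + d_bc - d_ac) / 2)
        assert lengths["c"] == pytest.approx((d_ac + d_bc - d_ab) / 2)

    def test_additive_distances_recovered_exactly(self):
        """On additive (tree-realizable) distances NJ recovers the
        generating tree: all leaf-to-leaf path lengths match the input."""
        true_paths = {
            ("A", "B"): 5, ("A", "C"): 7, ("A", "D"): 9, ("A", "E"): 8,
            ("B", "C"): 8, ("B", "D"): 10, ("B", "E"): 9,
            ("C", "D"): 6, ("C", "E"): 9, ("D", "E"): 11,
        }
        ids = list("ABCDE")
        mat = np.zeros((5, 5))
        for (x, y), d in true_paths.items():
            i, j = ids.index(x), ids.index(y)
            mat[i, j] = mat[j, i] = d
        tree = me.nj_tree(DistanceMatrix(mat, ids))
        dm_out = tree.tip_tip_distances()
        for (x, y), d in true_paths.items():
            assert dm_out[x, y] == pytest.approx(d)

    def test_ultrametric_pairs_are_siblings(self):
        mat = np.array(
            [
                [0.0, 0.2, 1.0, 1.0],
                [0.2, 0.0, 1.0, 1.0],
                [1.0, 1.0, 0.0, 0.2],
                [1.0, 1.0, 0.2, 0.0],
            ]
        )
        tree = me.nj_tree(DistanceMatrix(mat, ["a", "b", "c", "d"]))
        # unrooted tree: the ab|cd bipartition must be present
        splits = {
            frozenset(t.name for t in n.tips())
            for n in tree.non_tips(include_self=False)
        }
        assert frozenset({"a", "b"}) in splits or frozenset({"c", "d"}) in splits


class TestFitch:
    @pytest.mark.parametrize("seed", range(5))
    def test_cost_equals_brute_force_minimum(self, seed):
        """Fitch parsimony cost matches exhaustive minimization over all
        ancestral labelings on small random trees."""
        rng = np.random.default_rng(seed)
        states = ["AAA", "AAG", "AAT"]
        n_leaves = int(rng.integers(4, 7))
        newick = None
        # random binary tree over the leaves
        nodes = [f"L{i}" for i in range(n_leaves)]
        counter = 0
        while len(nodes) > 1:
            i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
            merged = f"({nodes[i]},{nodes[j]})I{counter}"
            counter += 1
            nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
        newick = nodes[0] + ";"
        tree = TreeNode.read([newick])
        leaf_states = {
            f"L{i}": states[rng.integers(len(states))] for i in range(n_leaves)
        }
        _, cost = me.fitch_sets(tree, leaf_states)

        children_of = {}
        leaf_map = {}
        for node in tree.postorder():
            nid = id(node)
            children_of[nid] = [id(c) for c in node.children]
            if node.is_tip():
                leaf_map[nid] = leaf_states[node.name]
        expected = brute_force_fitch_cost(children_of, leaf_map, states)
        assert cost == expected


class TestSlac:
    def _aln_tree(self, seqs):
        aln = me.CodonAlignment(tuple(seqs), tuple(seqs.values()))
        tree = me.nj_tree(me.p_distance(aln))
        return aln, tree

    def test_identical_sequences_all_none(self):
        seqs = {f"s{i}": "ATGGGAAAA" for i in range(4)}
        aln, tree = self._aln_tree(seqs)
        assert all(r.call == "none" for r in me.slac_sites(aln, tree))

    def test_fourfold_synonymous_site_counts(self):
        """A site carrying GGA/GGG/GGT/GGC accumulates >= 3 purely
        synonymous changes; the negative-direction p-value must undercut
        the positive one ((1/3)^3 by hand)."""
        seqs = {"s1": "ATGGGAAAA", "s2": "ATGGGGAAA",
                "s3": "ATGGGTAAA", "s4": "ATGGGCAAA"}
        aln, tree = self._aln_tree(seqs)
        site2 = me.slac_sites(aln, tree, alpha=0.1)[1]
        assert site2.s_obs >= 3 and site2.n_obs == 0
        assert site2.expected_syn_proportion == pytest.approx(1 / 3)
        assert site2.p_negative == pytest.approx((1 / 3) ** site2.s_obs)
        assert site2.p_negative < site2.p_positive
        assert site2.call == "negative"

    def test_purifying_regime_calls_mostly_negative(self):
        """Synonymous-only evolution (12 sequences, 60 codons) yields more
        negative than positive calls at alpha = 0.1."""
        rng = np.random.default_rng(5)
        fourfold = ["GG", "GC", "CC", "CG", "AC", "GT", "CT", "TC"]
        n_sites = 60
        stems = [fourfold[rng.integers(len(fourfold))] for _ in range(n_sites)]
        seqs = {}
        for i in range(12):
            codons = [stem + "ACGT"[rng.integers(4)] for stem in stems]
            seqs[f"s{i:02d}"] = "".join(codons)
        aln, tree = self._aln_tree(seqs)
        res = me.slac_sites(aln, tree, alpha=0.1)
        n_neg = sum(r.call == "negative" for r in res)
        n_pos = sum(r.call == "positive" for r in res)
        assert n_neg > n_pos
        assert n_neg > 0

    def test_mismatched_tree_rejected(self):
        seqs = {"s1": "ATGGGA", "s2": "ATGGGG", "s3": "ATGGGT"}
        aln = me.CodonAlignment(tuple(seqs), tuple(seqs.values()))
        wrong = me.nj_tree(
            me.p_distance((("x", "y", "z"), ("AAA", "AAC", "AAG")))
        )
        with pytest.raises(ValueError, match="leaves"):
            me.slac_sites(aln, wrong)


class TestPathwayCounting:
    def test_single_synonymous_step(self):
        assert me.count_pathways("GGA", "GGG") == (1.0, 0.0)

    def test_single_nonsynonymous_step(self):
        assert me.count_pathways("AAA", "GAA") == (0.0, 1.0)

    def test_two_step_average(self):
        # TTT (F) -> TTA (L) -> CTA (L): pathway order changes the split;
        # TTT->CTT (L) -> CTA(L): path1: F->L (non), L->L (syn); path2: F->L(non), L->L(syn)
        s, n = me.count_pathways("TTT", "CTA")
        assert s + n == pytest.approx(2.0)
        assert n >= 1.0

    def test_stop_pathways_excluded(self):
        # TAT (Y) -> TAA would pass through a stop on one ordering
        s, n = me.count_pathways("TAT", "TGA")
        assert s + n == pytest.approx(2.0)


def test_cluster_monophyly_on_planted_panel():
    """Members of each planted cluster form a clade of the NJ tree."""
    from mytipav.synthetic_data import SimConfig, generate_panel

    cfg = SimConfig(n_individuals=1, n_clusters=4, alleles_per_cluster=3,
                    rng_seed=23)
    panel = generate_panel(cfg)
    cds_by_id = {}
    groups = {}
    for ci, pool in enumerate(panel.alleles):
        distinct = sorted(set(pool))
        for ai, cds in enumerate(distinct):
            cds_by_id[f"c{ci}a{ai}"] = cds
        groups[f"c{ci}"] = {f"c{ci}a{ai}" for ai in range(len(distinct))}
    aln = me.codon_align(cds_by_id)
    tree = me.nj_tree(me.p_distance(aln))
    assert all(me.cluster_monophyly(tree, groups).values())
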