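"""Codon alignment, distance trees and a counting-based site selection test.

The phylogeny here is deliberately lightweight and deterministic:
p-distances (proportion of differing ungapped columns) feed a standard
neighbor-joining agglomeration.  NJ on additive distances recovers the
generating tree exactly, which the tests exploit; it stands in for the
Bayesian inference a full study would run, and outputs record it as such.

The per-site selection test follows the SLAC (single-likelihood ancestor
counting) counting recipe: ancestral codons are reconstructed by Fitch
parsimony on codon states, synonymous/nonsynonymous differences along
each branch are counted by averaging over the minimal mutational
pathways between codons (Nei-Gojobori pathway weighting; pathways
through stop codons are excluded), the expected synonymous proportion at
a site comes from the synonymous/nonsynonymous site fractions of the
codons observed in that column, and one-sided binomial tests (continuous
beta-function extension, since pathway averaging yields fractional
counts) give a p-value in each direction.  A site is called negative
(purifying) when synonymous changes are in significant excess, positive
when nonsynonymous changes are, at ``alpha`` (default 0.1 — positive
calls in this family typically carry only marginal support).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.special import betainc
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from Bio.Seq import Seq

from .msa import mafft_align
from .translated_search import STOP_CODONS

_BASES = "ACGT"
CODON_TABLE = {
    "".join(c): str(Seq("".join(c)).translate())
    for c in itertools.product(_BASES, repeat=3)
}


@dataclass
class CodonAlignment:
    """Gap-padded CDS alignment whose gaps come in codon triplets."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self):
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1 or next(iter(lengths)) % 3 != 0:
            raise ValueError("codon alignment columns must be equal and divisible by 3")

    @property
    def n_sites(self) -> int:
        return len(self.rows[0]) // 3

    def codon(self, row: int, site: int) -> str:
        return self.rows[row][3 * site:3 * site + 3]


def codon_align(cds_by_id: dict[str, str]) -> CodonAlignment:
    """Protein-guided codon alignment: align translations, back-thread gaps.

    CDSs must be in frame and free of internal stops (pseudogenes are the
    caller's job to exclude); a terminal stop codon is trimmed before
    alignment.
    """
    ids, trimmed, proteins = [], [], []
    for vid in cds_by_id:
        cds = cds_by_id[vid].upper()
        if len(cds) % 3:
            raise ValueError(f"{vid}: CDS length not divisible by 3")
        if cds[-3:] in STOP_CODONS:
            cds = cds[:-3]
        protein = str(Seq(cds).translate())
        if "*" in protein:
            raise ValueError(f"{vid}: internal stop codon; exclude pseudogenes")
        ids.append(vid)
        trimmed.append(cds)
        proteins.append(protein)
    aligned = mafft_align(list(zip(ids, proteins)), protein=True)
    rows = []
    for (vid, row), cds in zip(aligned, trimmed):
        out = []
        j = 0
        for aa in row:
            if aa == "-":
                out.append("---")
            else:
                out.append(cds[3 * j:3 * j + 3])
                j += 1
        rows.append("".join(out))
    return CodonAlignment(tuple(ids), tuple(rows))


def p_distance(alignment: CodonAlignment | tuple[tuple[str, ...], tuple[str, ...]]) -> DistanceMatrix:
    """Pairwise proportion of differing columns among ungapped columns."""
    if isinstance(alignment, CodonAlignment):
        ids, rows = alignment.ids, alignment.rows
    else:
        ids, rows = alignment
    n = len(ids)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comparable = diffs = 0
            for a, b in zip(rows[i], rows[j]):
                if a == "-" or b == "-":
                    continue
                comparable += 1
                diffs += a != b
            if comparable == 0:
                raise ValueError(f"no comparable columns between {ids[i]} and {ids[j]}")
            mat[i, j] = mat[j, i] = diffs / comparable
    return DistanceMatrix(mat, ids)


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Neighbor joining; negative branch lengths are clamped to zero."""
    if dm.shape[0] < 3:
        tree = TreeNode(name=None)
        for vid in dm.ids:
            tree.append(TreeNode(name=vid, length=float(dm[dm.ids[0], vid]) / 2 or 0.0))
        return tree
    return nj(dm, neg_as_zero=True)


# ---------------------------------------------------------------------------
# Nei-Gojobori style counting

def _syn_fraction(codon: str) -> float:
    """Synonymous site count of a codon (0..3): per position, the fraction
    of non-stop single-nucleotide changes that preserve the amino acid."""
    aa = CODON_TABLE[codon]
    total = 0.0
    for k in range(3):
        syn = valid = 0
        for b in _BASES:
            if b == codon[k]:
                continue
            alt = codon[:k] + b + codon[k + 1:]
            if alt in STOP_CODONS:
                continue
            valid += 1
            syn += CODON_TABLE[alt] == aa
        if valid:
            total += syn / valid
    return total


def count_pathways(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) changes between two codons, averaged
    over all minimal mutational pathways not passing through a stop.

    If every pathway hits a stop codon, all pathways are used (standard
    fallback).  Identical codons give (0, 0).
    """
    diff = [k for k in range(3) if c1[k] != c2[k]]
    if not diff:
        return 0.0, 0.0
    results = []
    for order in itertools.permutations(diff):
        cur = c1
        syn = non = 0
        ok = True
        for k in order:
            nxt = cur[:k] + c2[k] + cur[k + 1:]
            if nxt in STOP_CODONS:
                ok = False
                break
            if CODON_TABLE[nxt] == CODON_TABLE[cur]:
                syn += 1
            else:
                non += 1
            cur = nxt
        if ok:
            results.append((syn, non))
    if not results:
        for order in itertools.permutations(diff):
            cur = c1
            syn = non = 0
            for k in order:
                nxt = cur[:k] + c2[k] + cur[k + 1:]
                if CODON_TABLE[nxt] == CODON_TABLE[cur] and nxt not in STOP_CODONS:
                    syn += 1
                else:
                    non += 1
                cur = nxt
            results.append((syn, non))
    s = sum(r[0] for r in results) / len(results)
    n = sum(r[1] for r in results) / len(results)
    return s, n


# ---------------------------------------------------------------------------
# Fitch parsimony on codon states

def fitch_sets(tree: TreeNode, leaf_states: dict[str, str]) -> tuple[dict, int]:
    """Bottom-up Fitch: per node the candidate state set; returns (sets, cost).

    Leaves with missing states (gap codons) are unconstrained and do not
    contribute to the cost.
    """
    sets: dict[int, frozenset] = {}
    cost = 0
    for node in tree.postorder():
        if node.is_tip():
            state = leaf_states.get(node.name)
            sets[id(node)] = frozenset([state]) if state else frozenset()
            continue
        child_sets = [sets[id(c)] for c in node.children if sets[id(c)]]
        if not child_sets:
            sets[id(node)] = frozenset()
            continue
        inter = frozenset.intersection(*child_sets)
        if inter:
            sets[id(node)] = inter
        else:
            # pairwise fold, counting one union event per empty intersection
            acc = child_sets[0]
            for cs in child_sets[1:]:
                both = acc & cs
                if both:
                    acc = both
                else:
                    acc = acc | cs
                    cost += 1
            sets[id(node)] = acc
    return sets, cost


def _site_counts(tree: TreeNode, sets: dict, max_root_ties: int = 4) -> tuple[float, float]:
    """Total (syn, nonsyn) changes over the tree under minimal labelings.

    A consistent ancestral labeling is built top-down: each node takes its
    parent's state when that state is in its Fitch set, otherwise the
    lexicographically smallest member of its own set.  Root-state ties are
    averaged when at most ``max_root_ties`` states are tied; beyond that
    the lexicographic pick is used.
    """
    root_set = sets[id(tree)]
    if not root_set:
        return 0.0, 0.0
    root_choices = sorted(root_set)
    if len(root_choices) > max_root_ties:
        root_choices = root_choices[:1]
    s_tot = n_tot = 0.0
    for root_state in root_choices:
        state: dict[int, str | None] = {}
        s_obs = n_obs = 0.0
        for node in tree.preorder():
            node_set = sets[id(node)]
            if node.parent is None:
                state[id(node)] = root_state
                continue
            parent_state = state[id(node.parent)]
            if not node_set:
                state[id(node)] = parent_state
                continue
            if parent_state in node_set:
                state[id(node)] = parent_state
                continue
            own = min(node_set)
            state[id(node)] = own
            if parent_state is not None:
                s, n = count_pathways(parent_state, own)
                s_obs += s
                n_obs += n
        s_tot += s_obs
        n_tot += n_obs
    k = len(root_choices)
    return s_tot / k, n_tot / k


@dataclass(frozen=True)
class SiteSelectionResult:
    site: int  # 1-based codon site
    n_obs: float
    s_obs: float
    expected_syn_proportion: float
    p_negative: float
    p_positive: float
    call: str  # negative | positive | none


def _binom_sf(k: float, n: float, p: float) -> float:
    """P(X >= k) for Binomial(n, p), continuous extension via the
    regularized incomplete beta function (handles fractional counts)."""
    if k <= 0:
        return 1.0
    if k > n:
        return 0.0
    if p <= 0:
        return 0.0
    if p >= 1:
        return 1.0
    return float(betainc(k, n - k + 1.0, p))


def slac_sites(alignment: CodonAlignment, tree: TreeNode,
               alpha: float = 0.1) -> list[SiteSelectionResult]:
    """Per-site synonymous/nonsynonymous counting test on a fixed tree."""
    leaves = {t.name for t in tree.tips()}
    if set(alignment.ids) != leaves:
        raise ValueError("tree leaves must match alignment ids")
    if len(alignment.ids) < 3:
        raise ValueError("need at least 3 sequences")
    row_of = {vid: i for i, vid in enumerate(alignment.ids)}
    results = []
    for site in range(alignment.n_sites):
        leaf_states = {}
        observed = []
        for vid in alignment.ids:
            codon = alignment.codon(row_of[vid], site)
            if "-" in codon or codon in STOP_CODONS:
                continue
            leaf_states[vid] = codon
            observed.append(codon)
        if len(set(observed)) <= 1:
            results.append(
                SiteSelectionResult(site + 1, 0.0, 0.0, _site_exp(observed), 1.0, 1.0, "none")
            )
            continue
        sets, _ = fitch_sets(tree, leaf_states)
        s_obs, n_obs = _site_counts(tree, sets)
        p_syn = _site_exp(observed)
        total = s_obs + n_obs
        p_neg = _binom_sf(s_obs, total, p_syn)
        p_pos = _binom_sf(n_obs, total, 1.0 - p_syn)
        if p_neg < alpha and p_neg <= p_pos:
            call = "negative"
        elif p_pos < alpha:
            call = "positive"
        else:
            call = "none"
        results.append(
            SiteSelectionResult(site + 1, n_obs, s_obs, p_syn, p_neg, p_pos, call)
        )
    return results


def _site_exp(observed_codons: list[str]) -> float:
    """Expected synonymous proportion of a random single-nucleotide change,
    from the synonymous site fractions of the codons seen at the column."""
    if not observed_codons:
        return 0.5
    fracs = [_syn_fraction(c) / 3.0 for c in observed_codons]
    return float(np.mean(fracs))


def cluster_monophyly(tree: TreeNode, groups: dict[str, set]) -> dict[str, bool]:
    """Whether each group of leaf names forms a clade of the (unrooted)
    tree — i.e. its leaves are separated from the rest by one edge."""
    all_tips = {t.name for t in tree.tips()}
    out = {}
    for label, members in groups.items():
        members = set(members)
        if len(members) <= 1 or members == all_tips:
            out[label] = True
            continue
        lca = tree.lca([tree.find(m) for m in members])
        under = {t.name for t in lca.tips()}
        # unrooted: a group is also a clade if its complement is one
        comp = all_tips - members
        lca_c = tree.lca([tree.find(m) for m in comp])
        under_c = {t.name for t in lca_c.tips()}
        out[label] = under == members or under_c == comp
    return out
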