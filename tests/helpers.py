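"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from first principles (explicit
recursion, hard-coded tables) so it shares no code path with the package
implementation it checks.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

#: Standard genetic code, written out independently of Biopython.
_CODON_STRING = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
_BASE_ORDER = "TCAG"
CODON_TABLE = {
    a + b + c: _CODON_STRING[16 * i + 4 * j + k]
    for i, a in enumerate(_BASE_ORDER)
    for j, b in enumerate(_BASE_ORDER)
    for k, c in enumerate(_BASE_ORDER)
}

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(seq))


def translate_codon_lookup(dna: str) -> str:
    """Per-codon table translation; codons with N give X."""
    out = []
    for i in range(0, len(dna) - len(dna) % 3, 3):
        codon = dna[i:i + 3]
        out.append(CODON_TABLE.get(codon, "X"))
    return "".join(out)


def enumerate_global_alignments(a: str, b: str):
    """Yield every global alignment of a and b as (a_row, b_row) pairs."""
    if not a and not b:
        yield ("", "")
        return
    if a:
        for ra, rb in enumerate_global_alignments(a[1:], b):
            yield (a[0] + ra, "-" + rb)
    if b:
        for ra, rb in enumerate_global_alignments(a, b[1:]):
            yield ("-" + ra, b[0] + rb)
    if a and b:
        for ra, rb in enumerate_global_alignments(a[1:], b[1:]):
            yield (a[0] + ra, b[0] + rb)


def score_alignment_affine(row_a: str, row_b: str, matrix,
                           gap_open: float, gap_extend: float) -> float:
    """Score an alignment with BLAST-style affine gaps: a gap of length k
    costs gap_open + k * gap_extend."""
    score = 0.0
    in_gap_a = in_gap_b = False
    for ca, cb in zip(row_a, row_b):
        if ca == "-":
            score -= gap_extend + (0.0 if in_gap_a else gap_open)
            in_gap_a, in_gap_b = True, False
        elif cb == "-":
            score -= gap_extend + (0.0 if in_gap_b else gap_open)
            in_gap_b, in_gap_a = True, False
        else:
            score += matrix[ca, cb]
            in_gap_a = in_gap_b = False
    return score


def brute_force_local_score(query: str, target: str, matrix,
                            gap_open: float, gap_extend: float) -> float:
    """Optimal local score by enumerating all alignments of all substring
    pairs.  Exponential; only for short sequences."""
    best = 0.0
    for qs in range(len(query) + 1):
        for qe in range(qs, len(query) + 1):
            for ts in range(len(target) + 1):
                for te in range(ts, len(target) + 1):
                    sub_q, sub_t = query[qs:qe], target[ts:te]
                    if not sub_q or not sub_t:
                        continue
                    for ra, rb in enumerate_global_alignments(sub_q, sub_t):
                        s = score_alignment_affine(ra, rb, matrix, gap_open, gap_extend)
                        best = max(best, s)
    return best


def brute_force_global_identity(a: str, b: str, matrix,
                                gap_open: float, gap_extend: float) -> float:
    """Identity of the best-scoring global alignment (end gaps penalized):
    matches / alignment length * 100."""
    best = None
    for ra, rb in enumerate_global_alignments(a, b):
        s = score_alignment_affine(ra, rb, matrix, gap_open, gap_extend)
        if best is None or s > best[0]:
            matches = sum(x == y and x != "-" for x, y in zip(ra, rb))
            best = (s, 100.0 * matches / len(ra))
    return best[1]


def brute_force_fitch_cost(children_of, leaf_state, states) -> int:
    """Minimum number of state changes over all labelings of a rooted tree.

    ``children_of`` maps node id -> child ids (empty for leaves),
    ``leaf_state`` maps leaf id -> state.
    """
    internal = [n for n, ch in children_of.items() if ch]
    best = None
    for labels in itertools.product(states, repeat=len(internal)):
        assign = dict(zip(internal, labels))
        assign.update(leaf_state)
        cost = sum(
            assign[parent] != assign[child]
            for parent, children in children_of.items()
            for child in children
        )
        if best is None or cost < best:
            best = cost
    return best
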