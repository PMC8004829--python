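"""Shared pairwise-alignment primitives (Biopython PairwiseAligner backed).

Affine gap convention: a gap of length *k* costs ``gap_open + k *
gap_extend`` (BLAST-style), so the aligner's per-position scores are
``-(gap_open + gap_extend)`` for the first gap column and ``-gap_extend``
for each further column.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices


@dataclass(frozen=True)
class ScoringScheme:
    """Protein local-alignment scoring: substitution matrix + affine gaps.

    ``min_score`` is the raw-score report threshold used by the variant
    search; ``None`` means "calibrate against a shuffled-sequence null".
    """

    matrix_name: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    min_score: float | None = None

    def __post_init__(self):
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        matrix = substitution_matrices.load(self.matrix_name)
        for aa in "ACDEFGHIKLMNPQRSTVWYX*":
            if aa not in matrix.alphabet:
                raise ValueError(f"matrix {self.matrix_name} lacks residue {aa!r}")

    @property
    def matrix(self):
        return substitution_matrices.load(self.matrix_name)


DEFAULT_SCHEME = ScoringScheme()


def local_protein_aligner(scheme: ScoringScheme = DEFAULT_SCHEME) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = scheme.matrix
    aligner.open_gap_score = -(scheme.gap_open + scheme.gap_extend)
    aligner.extend_gap_score = -scheme.gap_extend
    return aligner


def global_aligner(nucleotide: bool = False,
                   scheme: ScoringScheme = DEFAULT_SCHEME) -> Align.PairwiseAligner:
    """Global aligner with end gaps penalized (for percent identity)."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if nucleotide:
        aligner.match_score = 2.0
        aligner.mismatch_score = -1.0
        aligner.open_gap_score = -6.0
        aligner.extend_gap_score = -1.0
    else:
        aligner.substitution_matrix = scheme.matrix
        aligner.open_gap_score = -(scheme.gap_open + scheme.gap_extend)
        aligner.extend_gap_score = -scheme.gap_extend
    return aligner


@dataclass(frozen=True)
class LocalAlignment:
    score: float
    query_span: tuple[int, int]
    target_span: tuple[int, int]
    identity: float  # percent over aligned columns (gaps included)
    blocks: tuple[tuple[tuple[int, int], tuple[int, int]], ...]  # (q, t) aligned runs


def _check_alphabet(seq: str, alphabet: str, role: str) -> None:
    bad = set(seq) - set(alphabet)
    if bad:
        raise ValueError(f"{role} contains residue(s) outside matrix alphabet: {sorted(bad)}")


def local_align(query: str, target: str,
                scheme: ScoringScheme = DEFAULT_SCHEME) -> LocalAlignment | None:
    """Best local alignment of two peptides; None when nothing scores > 0."""
    if not query or not target:
        raise ValueError("empty sequence")
    alphabet = str(scheme.matrix.alphabet)
    _check_alphabet(query, alphabet, "query")
    _check_alphabet(target, alphabet, "target")
    aligner = local_protein_aligner(scheme)
    alignments = aligner.align(query, target)
    if len(alignments) == 0 or alignments.score <= 0:
        return None
    aln = alignments[0]
    q_blocks, t_blocks = aln.aligned
    blocks = tuple(
        ((int(qs), int(qe)), (int(ts), int(te)))
        for (qs, qe), (ts, te) in zip(q_blocks, t_blocks)
    )
    qs, qe = blocks[0][0][0], blocks[-1][0][1]
    ts, te = blocks[0][1][0], blocks[-1][1][1]
    matches = sum(
        1
        for (q0, q1), (t0, t1) in blocks
        for k in range(q1 - q0)
        if query[q0 + k] == target[t0 + k]
    )
    # alignment length = aligned columns + internal gap columns
    length = (qe - qs) + (te - ts) - sum(q1 - q0 for (q0, q1), _ in blocks)
    identity = 100.0 * matches / length if length else 0.0
    return LocalAlignment(float(aln.score), (qs, qe), (ts, te), identity, blocks)


def global_identity(a: str, b: str, nucleotide: bool | None = None,
                    scheme: ScoringScheme = DEFAULT_SCHEME) -> float:
    """Percent identity under global alignment, end gaps penalized.

    Identity = matching columns / alignment length (gap columns count in
    the length).  ``nucleotide=None`` autodetects from the alphabet.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    a, b = a.upper(), b.upper()
    if nucleotide is None:
        nucleotide = set(a) | set(b) <= set("ACGTUN")
    aligner = global_aligner(nucleotide=nucleotide, scheme=scheme)
    aln = aligner.align(a, b)[0]
    q_blocks, t_blocks = aln.aligned
    matches = 0
    aligned_cols = 0
    for (qs, qe), (ts, te) in zip(q_blocks, t_blocks):
        aligned_cols += qe - qs
        matches += sum(1 for k in range(qe - qs) if a[qs + k] == b[ts + k])
    length = len(a) + len(b) - aligned_cols
    return 100.0 * matches / length
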