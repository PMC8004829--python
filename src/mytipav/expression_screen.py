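"""Transcriptome screening for expression evidence and genome/transcript
concordance (RNA-editing check).

A cluster counts as expressed in a transcriptome sample when the
translated local alignment of its consensus protein against the
six-frame translation of some transcript exceeds the identity threshold
(default >95%, the level at which a transcript is attributable to a
cluster rather than a related one) and covers at least 60% of the mature
region.  The identity is protein-level, matching a translated
(tBLASTn-style) screen; the coverage floor keeps short spurious matches
from counting as evidence.

The editing check compares the genomic spliced CDS of a locus with the
transcript from the same individual under a stringent global alignment:
concordant means zero mismatches and zero uncovered positions, the
sequence-level equivalent of read mapping that only accepts perfect
matches.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .align import DEFAULT_SCHEME, ScoringScheme, global_aligner, local_align
from .translated_search import six_frame_translate


@dataclass
class ExpressionEvidence:
    """Cluster x sample boolean evidence matrix plus per-hit detail."""

    matrix: pd.DataFrame
    hits: pd.DataFrame  # cluster, sample, transcript, identity, coverage


def screen_expression(
    consensus_proteins: dict[str, str],
    transcript_sets: dict[str, list[tuple[str, str]]],
    mature_region: tuple[int, int],
    identity_threshold: float = 95.0,
    coverage_floor: float = 0.6,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> ExpressionEvidence:
    """Translated screen of cluster consensuses against transcriptomes.

    ``consensus_proteins`` maps cluster label -> consensus protein;
    ``transcript_sets`` maps sample id -> transcript ``(id, seq)`` pairs.
    Evidence requires best-hit identity strictly above the threshold AND
    mature-region query coverage at or above the floor.  An empty
    transcriptome yields an all-absent column.
    """
    m0, m1 = mature_region
    mature_len = max(1, m1 - m0)
    clusters = sorted(consensus_proteins)
    samples = sorted(transcript_sets)
    matrix = pd.DataFrame(False, index=clusters, columns=samples)
    rows = []
    for sample in samples:
        frames_by_tx = [
            (tx_id, [f.peptide for f in six_frame_translate(seq) if f.peptide])
            for tx_id, seq in transcript_sets[sample]
        ]
        for label in clusters:
            query = consensus_proteins[label].replace("*", "X")
            best = None
            for tx_id, peptides in frames_by_tx:
                for pep in peptides:
                    aln = local_align(query, pep, scheme)
                    if aln is None:
                        continue
                    covered = len(
                        range(max(m0, aln.query_span[0]), min(m1, aln.query_span[1]))
                    )
                    identity = _informative_identity(query, pep, aln)
                    cand = (identity, covered / mature_len, tx_id)
                    # rank usable hits (coverage floor met) above fragments,
                    # then by identity: a tiny 100%-identity fragment must
                    # not shadow a full-length near-identical hit
                    key = (cand[1] >= coverage_floor, cand[0], cand[1])
                    if best is None or key > best[1]:
                        best = (cand, key)
            if best is None:
                continue
            best = best[0]
            identity, coverage, tx_id = best
            expressed = identity > identity_threshold and coverage >= coverage_floor
            matrix.loc[label, sample] = expressed
            rows.append(
                {
                    "cluster": label,
                    "sample": sample,
                    "transcript": tx_id,
                    "identity": identity,
                    "coverage": coverage,
                    "expressed": expressed,
                }
            )
    return ExpressionEvidence(matrix=matrix, hits=pd.DataFrame(rows))


def _informative_identity(query: str, target: str, aln) -> float:
    """Percent identity over aligned columns whose query residue is
    informative: an 'X' in a consensus marks a within-cluster polymorphic
    position, so it can neither match nor mismatch."""
    matches = cols = 0
    gap_cols = 0
    prev = None
    for (q0, q1), (t0, t1) in aln.blocks:
        if prev is not None:
            gap_cols += max(q0 - prev[0], t0 - prev[1])
        for k in range(q1 - q0):
            if query[q0 + k] == "X":
                continue
            cols += 1
            matches += query[q0 + k] == target[t0 + k]
        prev = (q1, t1)
    total = cols + gap_cols
    return 100.0 * matches / total if total else 0.0


@dataclass
class ConcordanceReport:
    """Genome vs transcript comparison for one locus.

    ``mismatches`` lists (transcript position, genomic base, transcript
    base); ``uncovered`` lists alignment gaps as (sequence, start, end)
    with sequence "genomic" or "transcript" — the coordinates of the
    bases that have no counterpart on the other side.
    """

    mismatches: list[tuple[int, str, str]]
    uncovered: list[tuple[str, int, int]]
    structurally_discordant: bool = False

    @property
    def concordant(self) -> bool:
        return (
            not self.mismatches
            and not self.uncovered
            and not self.structurally_discordant
        )


def concordance(genomic_cds: str, transcript_cds: str,
                max_length_difference: float = 0.2) -> ConcordanceReport:
    """Perfect-match contract between a genomic spliced CDS and the
    transcript of the same locus.

    Concordant means the global alignment has zero mismatching columns
    and zero gap columns; a length difference above
    ``max_length_difference`` is reported as structural discordance
    without a per-base list.
    """
    g, t = genomic_cds.upper(), transcript_cds.upper()
    if not g or not t:
        raise ValueError("empty sequence")
    if abs(len(g) - len(t)) > max_length_difference * max(len(g), len(t)):
        return ConcordanceReport([], [], structurally_discordant=True)
    aligner = global_aligner(nucleotide=True)
    aln = aligner.align(g, t)[0]
    g_blocks, t_blocks = aln.aligned
    mismatches = []
    uncovered: list[tuple[str, int, int]] = []
    prev_g_end = prev_t_end = 0
    for (gs, ge), (ts, te) in zip(g_blocks, t_blocks):
        if gs > prev_g_end:
            uncovered.append(("genomic", prev_g_end, gs))
        if ts > prev_t_end:
            uncovered.append(("transcript", prev_t_end, ts))
        for k in range(ge - gs):
            if g[gs + k] != t[ts + k]:
                mismatches.append((ts + k, g[gs + k], t[ts + k]))
        prev_g_end, prev_t_end = ge, te
    if prev_g_end < len(g):
        uncovered.append(("genomic", prev_g_end, len(g)))
    if prev_t_end < len(t):
        uncovered.append(("transcript", prev_t_end, len(t)))
    return ConcordanceReport(mismatches, uncovered)
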