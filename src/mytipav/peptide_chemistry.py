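"""Peptide charge, isoelectric point and precursor segmentation.

The net charge model is the standard Henderson–Hasselbalch sum over
titratable groups: at a given pH, each basic group (N-terminal amine,
Lys, Arg, His) contributes ``1/(1+10^(pH-pKa))`` and each acidic group
(C-terminal carboxyl, Asp, Glu, Cys, Tyr) contributes
``-1/(1+10^(pKa-pH))``.  The isoelectric point is the unique root of the
net charge on [0, 14], found by bisection.  Charge therefore depends on
residue composition only, never on residue order.

Three published side-chain pKa tables are provided; the IPC_protein set
is the default.  Cysteines are treated as titratable regardless of
disulfide status — this mirrors what any sequence-only calculator does
and slightly underestimates the pI of heavily disulfide-bonded peptides.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align import global_aligner

ACIDIC = "DECY"
BASIC = "KRH"


@dataclass(frozen=True)
class PkaSet:
    """Named table of pKa values for titratable groups."""

    name: str
    n_term: float
    c_term: float
    side_chain: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for label, v in [("n_term", self.n_term), ("c_term", self.c_term)] + list(
            self.side_chain.items()
        ):
            if not 0.0 < v < 14.0:
                raise ValueError(f"pKa {label}={v} outside (0, 14)")


#: pKa sets published with the Isoelectric Point Calculator (IPC_protein),
#: the EMBOSS suite, and Lehninger's textbook.
PKA_TABLES: dict[str, PkaSet] = {
    "ipc_protein": PkaSet(
        "ipc_protein",
        n_term=9.094,
        c_term=2.869,
        side_chain={
            "D": 3.872, "E": 4.412, "C": 7.555, "Y": 10.85,
            "H": 5.637, "K": 9.052, "R": 11.84,
        },
    ),
    "emboss": PkaSet(
        "emboss",
        n_term=8.6,
        c_term=3.6,
        side_chain={
            "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1,
            "H": 6.5, "K": 10.8, "R": 12.5,
        },
    ),
    "lehninger": PkaSet(
        "lehninger",
        n_term=9.69,
        c_term=2.34,
        side_chain={
            "D": 3.65, "E": 4.25, "C": 8.3, "Y": 10.07,
            "H": 6.0, "K": 10.53, "R": 12.48,
        },
    ),
}

DEFAULT_PKA = PKA_TABLES["ipc_protein"]

#: Average residue masses (Da) for molecular weight; water added per chain.
_AVG_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
    "X": 110.0,
}
_WATER = 18.01528


@dataclass(frozen=True)
class PrecursorAnnotation:
    """Signal / mature / C-terminal-extension residue intervals (0-based, half-open)."""

    signal: tuple[int, int]
    mature: tuple[int, int]
    c_terminal: tuple[int, int]

    def __post_init__(self):
        s, m, c = self.signal, self.mature, self.c_terminal
        if not (s[0] == 0 and s[1] == m[0] and m[1] == c[0] and s[0] < s[1] <= m[1] <= c[1]):
            raise ValueError("segments must be contiguous, ordered and cover the precursor")

    @property
    def length(self) -> int:
        return self.c_terminal[1]


def _validate(peptide: str) -> str:
    peptide = peptide.upper()
    if not peptide:
        raise ValueError("empty peptide")
    bad = set(peptide) - set(_AVG_MASS) - {"X"}
    if bad:
        raise ValueError(f"unknown residue symbol(s): {sorted(bad)}")
    return peptide


def net_charge(peptide: str, pH: float, pkaset: PkaSet = DEFAULT_PKA,
               termini: bool = True) -> float:
    """Net charge of a peptide at a given pH (X residues contribute nothing)."""
    peptide = _validate(peptide)
    charge = 0.0
    if termini:
        charge += 1.0 / (1.0 + 10.0 ** (pH - pkaset.n_term))
        charge -= 1.0 / (1.0 + 10.0 ** (pkaset.c_term - pH))
    for aa, pka in pkaset.side_chain.items():
        n = peptide.count(aa)
        if not n:
            continue
        if aa in BASIC:
            charge += n / (1.0 + 10.0 ** (pH - pka))
        else:
            charge -= n / (1.0 + 10.0 ** (pka - pH))
    return charge


def isoelectric_point(peptide: str, pkaset: PkaSet = DEFAULT_PKA,
                      termini: bool = True, tol: float = 1e-4) -> tuple[float, bool]:
    """pH at which the net charge is zero, by bisection on [0, 14].

    Returns ``(pI, at_boundary)``: when the charge does not change sign on
    the interval (e.g. side chains only, no termini modelled) the nearer
    boundary is returned with ``at_boundary=True``.
    """
    lo, hi = 0.0, 14.0
    c_lo, c_hi = net_charge(peptide, lo, pkaset, termini), net_charge(peptide, hi, pkaset, termini)
    if c_lo <= 0.0:
        return lo, True
    if c_hi >= 0.0:
        return hi, True
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(peptide, mid, pkaset, termini) > 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi), False


def molecular_weight(peptide: str) -> float:
    """Average molecular mass in Da (X counted at 110 Da)."""
    peptide = _validate(peptide)
    return sum(_AVG_MASS[aa] for aa in peptide) + _WATER


def sliding_window_pi(protein: str, window: int = 15, pkaset: PkaSet = DEFAULT_PKA,
                      termini: bool = True) -> tuple[np.ndarray, np.ndarray, bool]:
    """pI profile over all windows of the given width.

    Each window substring is treated as an isolated peptide (free termini
    included unless ``termini=False``).  Returns ``(centers, values,
    whole_sequence_flag)``; a protein shorter than the window yields the
    single whole-sequence pI with the flag set.
    """
    protein = _validate(protein)
    if len(protein) < window:
        pi, _ = isoelectric_point(protein, pkaset, termini)
        return np.array([len(protein) / 2.0]), np.array([pi]), True
    centers, values = [], []
    for start in range(len(protein) - window + 1):
        sub = protein[start:start + window]
        pi, _ = isoelectric_point(sub, pkaset, termini)
        centers.append(start + window / 2.0)
        values.append(pi)
    return np.asarray(centers), np.asarray(values), False


_DIBASIC = ("KK", "KR", "RK", "RR")


def segment_precursor(protein: str, seed_protein: str,
                      seed_annotation: PrecursorAnnotation) -> PrecursorAnnotation:
    """Project seed signal/mature/extension boundaries onto a homologous protein.

    The seed boundaries are carried through a global alignment; the mature
    C-terminus is then snapped to the residue preceding the first dibasic
    motif (KK/KR/RK/RR, a furin-like cleavage site) at or after the
    projected position.
    """
    protein = _validate(protein)
    aligner = global_aligner()
    try:
        aln = aligner.align(seed_protein.replace("*", "X"), protein.replace("*", "X"))[0]
    except Exception as exc:  # pragma: no cover - aligner failure is diagnostic
        raise ValueError(f"cannot align precursor to seed: {exc}") from exc

    # seed index -> target index map (next aligned target position).
    seed_to_target = {}
    for (qs, qe), (ts, te) in zip(*aln.aligned):
        for k in range(qe - qs):
            seed_to_target[qs + k] = ts + k

    def project(seed_idx: int) -> int:
        if seed_idx >= len(seed_protein):
            return len(protein)
        for i in range(seed_idx, len(seed_protein)):
            if i in seed_to_target:
                return seed_to_target[i]
        return len(protein)

    sig_end = project(seed_annotation.signal[1])
    mat_end = project(seed_annotation.mature[1])
    if sig_end >= len(protein):
        raise ValueError("no alignable mature region: signal boundary beyond target")

    # Snap: first dibasic at/after the projected mature end marks the
    # cleavage, mature peptide ends just before it.
    snapped = None
    for i in range(mat_end, len(protein) - 1):
        if protein[i:i + 2] in _DIBASIC:
            snapped = i
            break
    if snapped is not None:
        mat_end = snapped
    mat_end = max(mat_end, sig_end)
    return PrecursorAnnotation((0, sig_end), (sig_end, mat_end), (mat_end, len(protein)))
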