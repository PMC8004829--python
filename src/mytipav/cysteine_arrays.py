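"""Cysteine disulfide-array fingerprinting and classification.

Mature peptides of this AMP family carry a conserved scaffold of 10
"backbone" cysteines that are present in every variant, plus up to 6
"accessory" cysteines that are present only in some variants and pair up
into as many as three optional disulfide bonds.  The accessory cysteines
occupy fixed positions relative to the backbone:

* ``a1``/``a2`` — two free-standing cysteines between backbone Cys2 and
  Cys3 (their pairing is optional bond 1),
* ``a3``/``a4`` — cysteines in tandem with backbone Cys5 and Cys7,
  producing ``CC`` doublets (optional bond 2),
* ``a5``/``a6`` — two free-standing cysteines C-terminal of backbone
  Cys10 (optional bond 3).

The observed accessory complement determines the array type:

========  =========================  =====  ==============
type      accessory slots occupied   bonds  total cysteines
========  =========================  =====  ==============
I         a3 a4 a5 a6                2, 3   14
II        a5 a6                      3      12
III       a3 a4                      2      12
IV        (none)                     —      10
V         a1 a2 a3 a4                1, 2   14
========  =========================  =====  ==============

Any other accessory complement (e.g. 11 or 13 cysteines) is reported as
``UNKNOWN`` rather than coerced.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

import pandas as pd

BACKBONE_SLOTS = tuple(f"b{i}" for i in range(1, 11))
ACCESSORY_SLOTS = tuple(f"a{i}" for i in range(1, 7))

#: Accessory complement -> array type.
TYPE_BY_ACCESSORY: dict[frozenset, str] = {
    frozenset(): "IV",
    frozenset({"a5", "a6"}): "II",
    frozenset({"a3", "a4"}): "III",
    frozenset({"a3", "a4", "a5", "a6"}): "I",
    frozenset({"a1", "a2", "a3", "a4"}): "V",
}

#: Optional bond number -> the accessory pair that forms it.
BOND_PAIRS: dict[int, frozenset] = {
    1: frozenset({"a1", "a2"}),
    2: frozenset({"a3", "a4"}),
    3: frozenset({"a5", "a6"}),
}

#: The five canonical array patterns (run-length dialect: '-' separates
#: maximal runs of cysteines; spacing is not significant).
CANONICAL_PATTERNS: dict[str, str] = {
    "I": "CC- C-C-CC-C-CC-C-C-C-C-C",
    "II": "CC- C-C- C-C- C-C-C-C-C-C",
    "III": "CC- C-C-CC-C-CC-C-C-C",
    "IV": "CC- C-C- C-C- C-C-C-C",
    "V": "CC-C-C-C-C-CC-C-CC-C-C-C",
}


@dataclass(frozen=True)
class CysFingerprint:
    """Run-length structure of the cysteines of one mature peptide."""

    groups: tuple[int, ...]
    positions: tuple[int, ...] = ()

    @property
    def n_cys(self) -> int:
        return sum(self.groups)

    def to_string(self) -> str:
        """Serialize in the run-length dialect (``CC-C-C-...``)."""
        return "-".join("C" * g for g in self.groups)


@dataclass(frozen=True)
class SlotAssignment:
    """Mapping of observed cysteines onto the canonical slot sequence."""

    fingerprint: CysFingerprint
    occupied: frozenset = field(default_factory=frozenset)
    valid: bool = False

    @property
    def accessory(self) -> frozenset:
        return self.occupied & frozenset(ACCESSORY_SLOTS)


@dataclass(frozen=True)
class ArrayTypeCall:
    array_type: str  # I..V or UNKNOWN
    occupied: frozenset
    bonds: tuple[int, ...]
    n_cys: int


def fingerprint(mature_peptide: str) -> CysFingerprint:
    """Run-length fingerprint of the cysteines in a mature peptide.

    Zero cysteines yield an empty fingerprint, which downstream classifies
    as UNKNOWN.
    """
    if not mature_peptide:
        raise ValueError("empty peptide")
    seq = mature_peptide.upper()
    groups: list[int] = []
    positions: list[int] = []
    for m in re.finditer(r"C+", seq):
        groups.append(m.end() - m.start())
        positions.extend(range(m.start(), m.end()))
    return CysFingerprint(tuple(groups), tuple(positions))


def parse_pattern(pattern: str) -> CysFingerprint:
    """Parse a printed array string; '-' and whitespace are both separators."""
    tokens = [t for t in re.split(r"[-\s]+", pattern.strip()) if t]
    groups = []
    for tok in tokens:
        if set(tok.upper()) != {"C"}:
            raise ValueError(f"unexpected token {tok!r} in array pattern")
        groups.append(len(tok))
    return CysFingerprint(tuple(groups))


def _template_groups(accessory: frozenset) -> tuple[tuple[int, ...], tuple[tuple[str, ...], ...]]:
    """Expected run-length groups (and their slot content) for an accessory set."""
    groups: list[tuple[str, ...]] = [("b1", "b2")]
    if "a1" in accessory:
        groups.append(("a1",))
    if "a2" in accessory:
        groups.append(("a2",))
    groups.append(("b3",))
    groups.append(("b4",))
    groups.append(("a3", "b5") if "a3" in accessory else ("b5",))
    groups.append(("b6",))
    groups.append(("a4", "b7") if "a4" in accessory else ("b7",))
    groups.append(("b8",))
    groups.append(("b9",))
    groups.append(("b10",))
    if "a5" in accessory:
        groups.append(("a5",))
    if "a6" in accessory:
        groups.append(("a6",))
    sizes = tuple(len(g) for g in groups)
    return sizes, tuple(groups)


def assign_slots(fp: CysFingerprint) -> SlotAssignment:
    """Deterministic parse of a fingerprint onto the canonical slot sequence.

    All 64 accessory complements are tried; the fingerprint must match the
    induced run-length template exactly (every cysteine consumed).  When
    more than one complement fits, the parse using the fewest accessory
    slots wins, ties broken by the most C-terminal accessory usage (extra
    free-standing cysteines at the tail are the optional bond-3 pair, not
    the bond-1 pair — this is what makes the five canonical patterns parse
    uniquely).  A fingerprint with no consistent parse gets an invalid
    (UNKNOWN-bound) assignment — that is a value, not an error.
    """
    # accessory cysteines only occur as complete bond pairs: a lone
    # accessory cysteine would have no partner to pair with
    candidates: list[frozenset] = []
    for r in range(len(BOND_PAIRS) + 1):
        for pair_combo in itertools.combinations(BOND_PAIRS.values(), r):
            acc = frozenset().union(*pair_combo) if pair_combo else frozenset()
            sizes, _ = _template_groups(acc)
            if sizes == fp.groups:
                candidates.append(acc)
    if not candidates:
        return SlotAssignment(fp, frozenset(), valid=False)
    candidates.sort(
        key=lambda a: (len(a), sorted(-int(s[1:]) for s in a))
    )
    acc = candidates[0]
    return SlotAssignment(fp, frozenset(BACKBONE_SLOTS) | acc, valid=True)


def serialize_assignment(assignment: SlotAssignment) -> str:
    """Regenerate the printed run-length pattern from a slot assignment."""
    if not assignment.valid:
        return assignment.fingerprint.to_string()
    sizes, _ = _template_groups(assignment.accessory)
    return "-".join("C" * s for s in sizes)


def classify_type(assignment: SlotAssignment) -> ArrayTypeCall:
    """Array type (I-V or UNKNOWN) and optional bonds of an assignment."""
    if not assignment.valid:
        return ArrayTypeCall(
            "UNKNOWN", assignment.occupied, (), assignment.fingerprint.n_cys
        )
    acc = assignment.accessory
    array_type = TYPE_BY_ACCESSORY.get(acc, "UNKNOWN")
    bonds = tuple(sorted(b for b, pair in BOND_PAIRS.items() if pair <= acc))
    return ArrayTypeCall(array_type, assignment.occupied, bonds, assignment.fingerprint.n_cys)


def classify_peptide(mature_peptide: str) -> ArrayTypeCall:
    """Convenience: fingerprint -> slot assignment -> type call."""
    return classify_type(assign_slots(fingerprint(mature_peptide)))


def summarize_taxa(calls: list[tuple[str, ArrayTypeCall]]) -> pd.DataFrame:
    """Presence/absence matrix of array types (rows) across taxa (columns).

    ``calls`` holds ``(taxon_or_cluster_label, call)`` pairs.  Cells are
    booleans; the per-type label lists (the "(B, D, E, F, G, L, M)" style
    annotation) are available via :func:`type_membership`.
    """
    if not calls:
        return pd.DataFrame()
    types = sorted({c.array_type for _, c in calls})
    taxa = sorted({label for label, _ in calls})
    mat = pd.DataFrame(False, index=types, columns=taxa)
    for label, call in calls:
        mat.loc[call.array_type, label] = True
    return mat


def type_membership(calls: list[tuple[str, ArrayTypeCall]]) -> dict[str, list[str]]:
    """Sorted distinct labels observed for each array type."""
    out: dict[str, set] = {}
    for label, call in calls:
        out.setdefault(call.array_type, set()).add(label)
    return {t: sorted(v) for t, v in sorted(out.items())}
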