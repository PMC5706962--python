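"""Kinase consensus-motif rules and sequence-window matching.

A phosphosite is summarised by a 15-mer sequence window centred on the
phosphorylated residue (index 7, 0-based), with ``X`` padding where the
protein terminus truncates the window.  A :class:`MotifRule` is a small
position-offset pattern over that window: a residue class for the centre
plus a list of offset constraints.  The four built-in rules cover the
minimal Cdk1 consensus (pS/pT-P), the optimal Cdk1 consensus (adds a basic
residue at +2 or +3), and the minimal Aurora B (R/K at -2) and Plk1
(D/E at -2) consensus motifs.  ``X`` padding never satisfies any residue
class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

WINDOW_LENGTH = 15
CENTER_INDEX = 7

__all__ = [
    "WINDOW_LENGTH",
    "CENTER_INDEX",
    "MotifRule",
    "BUILTIN_MOTIFS",
    "match_motif",
    "annotate_motifs",
]


@dataclass(frozen=True)
class MotifRule:
    """A position-offset residue-class pattern defining a kinase consensus.

    Parameters
    ----------
    name
        Identifier used in column names (``motif_<name>``) and reports.
    center_residues
        Residues accepted at the phosphosite itself (offset 0).
    constraints
        Tuples ``(offsets, residues, mode)``.  With mode ``"all_of"`` every
        listed offset must carry an allowed residue; with ``"any_of"`` at
        least one must.  Offsets are relative to the centre and must lie
        within ±7.
    """

    name: str
    center_residues: frozenset[str]
    constraints: tuple[tuple[tuple[int, ...], frozenset[str], str], ...] = field(
        default_factory=tuple
    )

    def __post_init__(self) -> None:
        for offsets, residues, mode in self.constraints:
            if mode not in ("all_of", "any_of"):
                raise ValueError(f"unknown constraint mode {mode!r}")
            for off in offsets:
                if not -7 <= off <= 7:
                    raise ValueError(f"offset {off} outside the ±7 window")
                if off == 0:
                    raise ValueError("offset 0 is reserved for center_residues")


def _rule(name, center, constraints):
    return MotifRule(
        name=name,
        center_residues=frozenset(center),
        constraints=tuple(
            (tuple(offs), frozenset(res), mode) for offs, res, mode in constraints
        ),
    )


#: Built-in consensus rules, keyed by name.  All four are written for
#: phospho-S/T; phosphotyrosine sites never match.
BUILTIN_MOTIFS: dict[str, MotifRule] = {
    "cdk1_minimal": _rule("cdk1_minimal", "ST", [((1,), "P", "all_of")]),
    "cdk1_optimal": _rule(
        "cdk1_optimal",
        "ST",
        [((1,), "P", "all_of"), ((2, 3), "KR", "any_of")],
    ),
    "aurora": _rule("aurora", "ST", [((-2,), "RK", "all_of")]),
    "plk1": _rule("plk1", "ST", [((-2,), "DE", "all_of")]),
}


def match_motif(window: str, rule: MotifRule) -> bool:
    """Return True iff ``window`` satisfies ``rule``.

    The window must be exactly 15 characters; the phosphosite sits at
    index 7.  Padding characters (``X``) match no residue class, so motifs
    reaching past a protein terminus fail rather than match vacuously.
    """
    if len(window) != WINDOW_LENGTH:
        raise ValueError(
            f"window must be {WINDOW_LENGTH} characters, got {len(window)}"
        )
    window = window.upper()
    if window[CENTER_INDEX] not in rule.center_residues:
        return False
    for offsets, residues, mode in rule.constraints:
        hits = [window[CENTER_INDEX + off] in residues for off in offsets]
        if mode == "all_of" and not all(hits):
            return False
        if mode == "any_of" and not any(hits):
            return False
    return True


def annotate_motifs(sites, rules=None):
    """Add one boolean ``motif_<name>`` column per rule to a site table.

    Purely sequence-based: flags depend only on the ``window`` column and
    are therefore invariant under any ratio normalization.  Returns a new
    DataFrame; the input is not mutated.
    """
    if rules is None:
        rules = list(BUILTIN_MOTIFS.values())
    import numpy as np

    out = sites.copy()
    for rule in rules:
        flags = np.fromiter(
            (match_motif(w, rule) for w in out["window"].astype(str)),
            dtype=bool,
            count=len(out),
        )
        out[f"motif_{rule.name}"] = flags
    return out
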