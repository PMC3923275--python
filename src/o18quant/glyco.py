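"""N-glycosylation sequon detection and peptide class assignment.

N-linked glycans attach to Asn inside the consensus motif Asn-X-Ser/Thr with
X ≠ Pro.  After PNGase-F deglycosylation the site carries a deamidation
footprint, so a peptide is treated as a glycopeptide when at least one
deamidation sits on a motif Asn.  Deamidation on a non-motif Asn is most
likely spontaneous chemical deamidation, not evidence of glycosylation: such
peptides are flagged ``inconsistent`` and excluded from glycopeptide
quantitation by default (they are still reported).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from .masscalc import RESIDUE_FORMULAS, PeptideIon, UnknownResidueError

__all__ = ["SequonMatch", "find_sequons", "classify_peptide", "PeptideClass"]

PeptideClass = Literal["glyco", "non-glyco", "inconsistent"]

#: Modifications whose presence marks a formerly glycosylated Asn.
_DEAMIDATION_NAMES = frozenset({"Deamidation", "Deamidation18O"})


@dataclass(frozen=True)
class SequonMatch:
    """One N-X-S/T (X ≠ P) motif occurrence.

    ``position`` is the 1-based index of the Asn; ``following`` the two
    downstream residues.  ``valid`` is always True for matches returned by
    :func:`find_sequons`; the field exists so callers can build and report
    near-misses too.
    """

    position: int
    following: str
    valid: bool = True


def find_sequons(sequence: str) -> list[SequonMatch]:
    """All valid N-X-S/T (X ≠ P) motif positions, in sequence order.

    An Asn in the last two positions can never match — there is no +2
    residue to complete the motif.
    """
    if not sequence:
        raise ValueError("empty sequence")
    bad = set(sequence) - set(RESIDUE_FORMULAS)
    if bad:
        raise UnknownResidueError(f"unknown residue letters: {sorted(bad)}")
    matches = []
    for i in range(len(sequence) - 2):
        if (
            sequence[i] == "N"
            and sequence[i + 1] != "P"
            and sequence[i + 2] in ("S", "T")
        ):
            matches.append(SequonMatch(i + 1, sequence[i + 1 : i + 3]))
    return matches


def classify_peptide(ion: PeptideIon) -> tuple[PeptideClass, tuple[int, ...]]:
    """Assign glycopeptide / non-glycopeptide / inconsistent, with site list.

    Returns the class and the tuple of deamidated positions that fall on
    valid sequon Asn residues.  ``inconsistent`` means at least one
    deamidation sits on an Asn outside any sequon; those peptides carry an
    ambiguous label count and are excluded from glycopeptide ratios.
    """
    sequon_positions = {m.position for m in find_sequons(ion.sequence)}
    deamidated = [
        pos
        for pos, spec in ion.modifications
        if isinstance(pos, int) and spec.name in _DEAMIDATION_NAMES
    ]
    on_sequon = tuple(sorted(p for p in deamidated if p in sequon_positions))
    off_sequon = [p for p in deamidated if p not in sequon_positions]
    if off_sequon:
        return "inconsistent", on_sequon
    if on_sequon:
        return "glyco", on_sequon
    return "non-glyco", ()
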