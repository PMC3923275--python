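"""Exact peptide masses, isotope envelopes and labeling mass arithmetic.

All mass bookkeeping for the tandem-labeling workflow lives here: elemental
compositions of modified peptides (with ``O18`` tracked as a separate,
isotopically pure element), monoisotopic masses from an embedded IUPAC table,
precursor and b/y fragment m/z, nominal-mass-binned theoretical isotope
envelopes, and the 4/6-Da heavy-light pair shifts that the labeling chemistry
produces (two carboxyl oxygens at the tryptic C-terminus plus one oxygen per
deglycosylated Asn).

The envelope is aggregated by integer nominal offset above the monoisotopic
peak: ``M0, M1, M2, ...``.  Only the even offsets enter the downstream ratio
algebra; the odd ones are kept for diagnostics.  Reagent purity (the fraction
of nominal ¹⁸O positions actually occupied by ¹⁸O) is *not* applied here — it
is a property of the labeling reaction, handled by :mod:`o18quant.quant`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterator, Literal, Mapping

import numpy as np

__all__ = [
    "ATOMIC_MASSES",
    "ISOTOPE_ABUNDANCES",
    "PROTON_MASS",
    "O18_DELTA",
    "C13_DELTA",
    "WATER",
    "RESIDUE_FORMULAS",
    "ElementalComposition",
    "ModificationSpec",
    "MODIFICATIONS",
    "PeptideIon",
    "IsotopeDistribution",
    "parse_modifications",
    "format_modifications",
    "peptide_composition",
    "monoisotopic_mass",
    "ion_mz",
    "isotope_distribution",
    "label_mass_shift",
    "fragment_mz",
]

# ---------------------------------------------------------------------------
# Embedded atomic data (IUPAC 2013 monoisotopic masses / representative
# abundances).  Fixed constants so every result is bit-reproducible; no
# runtime lookups.  "O18" is the enriched label oxygen, treated as pure —
# reagent impurity is modeled downstream as binomial label mixing.
# ---------------------------------------------------------------------------

ATOMIC_MASSES: Mapping[str, float] = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
    "O18": 17.9991604,
}

# Per-element abundance vectors indexed by nominal mass offset from the
# lightest isotope.  O18 is a delta at offset 0 (pure by construction).
ISOTOPE_ABUNDANCES: Mapping[str, tuple[float, ...]] = {
    "H": (0.999885, 0.000115),
    "C": (0.9893, 0.0107),
    "N": (0.99636, 0.00364),
    "O": (0.99757, 0.00038, 0.00205),
    "S": (0.9499, 0.0075, 0.0425, 0.0, 0.0001),
    "O18": (1.0,),
}

PROTON_MASS = 1.00727646688
#: Mass increment of one ¹⁶O → ¹⁸O exchange (Da).
O18_DELTA = ATOMIC_MASSES["O18"] - ATOMIC_MASSES["O"]
#: Spacing of the natural isotopologue ladder (¹³C − ¹²C), Da.
C13_DELTA = 1.0033548378
WATER = 2 * ATOMIC_MASSES["H"] + ATOMIC_MASSES["O"]

# Residue (i.e. amino acid minus water) formulas for the 20 canonical letters.
RESIDUE_FORMULAS: Mapping[str, Mapping[str, int]] = {
    "G": {"C": 2, "H": 3, "N": 1, "O": 1},
    "A": {"C": 3, "H": 5, "N": 1, "O": 1},
    "S": {"C": 3, "H": 5, "N": 1, "O": 2},
    "P": {"C": 5, "H": 7, "N": 1, "O": 1},
    "V": {"C": 5, "H": 9, "N": 1, "O": 1},
    "T": {"C": 4, "H": 7, "N": 1, "O": 2},
    "C": {"C": 3, "H": 5, "N": 1, "O": 1, "S": 1},
    "L": {"C": 6, "H": 11, "N": 1, "O": 1},
    "I": {"C": 6, "H": 11, "N": 1, "O": 1},
    "N": {"C": 4, "H": 6, "N": 2, "O": 2},
    "D": {"C": 4, "H": 5, "N": 1, "O": 3},
    "Q": {"C": 5, "H": 8, "N": 2, "O": 2},
    "K": {"C": 6, "H": 12, "N": 2, "O": 1},
    "E": {"C": 5, "H": 7, "N": 1, "O": 3},
    "M": {"C": 5, "H": 9, "N": 1, "O": 1, "S": 1},
    "H": {"C": 6, "H": 7, "N": 3, "O": 1},
    "F": {"C": 9, "H": 9, "N": 1, "O": 1},
    "R": {"C": 6, "H": 12, "N": 4, "O": 1},
    "Y": {"C": 9, "H": 9, "N": 1, "O": 2},
    "W": {"C": 11, "H": 10, "N": 2, "O": 1},
}


class UnknownResidueError(ValueError):
    """Sequence contains a letter outside the 20 canonical residues."""


class UnknownElementError(KeyError):
    """Composition references an element absent from the embedded table."""


@dataclass(frozen=True)
class ElementalComposition:
    """Integer element counts, with ¹⁸O tracked separately from natural O.

    Supports element-wise ``+`` and ``-``; subtraction below zero raises,
    because a physical composition can never go negative.
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {}
        for el, n in self.counts.items():
            if not float(n).is_integer():
                raise ValueError(f"non-integer count for {el}: {n}")
            n = int(n)
            if n < 0:
                raise ValueError(f"negative count for {el}: {n}")
            if n:
                clean[el] = n
        object.__setattr__(self, "counts", clean)

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    def __iter__(self) -> Iterator[str]:
        return iter(self.counts)

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) + n
        return ElementalComposition(merged)

    def __sub__(self, other: "ElementalComposition") -> "ElementalComposition":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) - n
            if merged[el] < 0:
                raise ValueError(f"subtraction yields negative {el} count")
        return ElementalComposition(merged)

    @property
    def n_atoms(self) -> int:
        return sum(self.counts.values())

    @property
    def n_o18(self) -> int:
        return self["O18"]

    def hill_formula(self) -> str:
        order = sorted(self.counts, key=lambda e: (e != "C", e != "H", e))
        return "".join(f"{el}{n}" if n > 1 else el for el in order for n in [self.counts[el]])


@dataclass(frozen=True)
class ModificationSpec:
    """A named residue or terminal modification with its mass delta.

    ``composition_delta`` is a signed element-count mapping (may remove
    atoms, e.g. deamidation swaps NH for O); when given, its monoisotopic
    mass must agree with ``mass_delta`` to 1e-4 Da.  ``n_o18`` counts the
    enzymatically introduced ¹⁸O atoms, which is what the pair-shift and
    purity logic care about.
    """

    name: str
    target: str  # residue letter, "cterm" or "nterm"
    mass_delta: float
    composition_delta: Mapping[str, int] | None = None
    n_o18: int = 0

    def __post_init__(self) -> None:
        if not math.isfinite(self.mass_delta):
            raise ValueError("mass delta must be finite")
        if self.composition_delta is not None:
            m = sum(
                n * ATOMIC_MASSES[el] for el, n in self.composition_delta.items()
            )
            if abs(m - self.mass_delta) > 1e-4:
                raise ValueError(
                    f"{self.name}: composition delta mass {m:.6f} does not "
                    f"match declared delta {self.mass_delta:.6f}"
                )

    @property
    def is_label(self) -> bool:
        return self.n_o18 > 0


# The modification vocabulary of the workflow.  Deamidation is the PNGase-F
# footprint at a formerly glycosylated Asn (+0.98 Da in H2-16O, +2.99 Da in
# H2-18O); "2x18O"/"1x18O" are the trypsin-catalyzed C-terminal carboxyl
# exchanges (+4.01 / +2.00 Da); carbamidomethyl-Cys and Met oxidation are the
# usual search modifications.
MODIFICATIONS: Mapping[str, ModificationSpec] = {
    m.name: m
    for m in [
        ModificationSpec(
            "Deamidation", "N", 0.9840155850,
            {"H": -1, "N": -1, "O": 1}, n_o18=0,
        ),
        ModificationSpec(
            "Deamidation18O", "N", 2.9882613629,
            {"H": -1, "N": -1, "O18": 1}, n_o18=1,
        ),
        ModificationSpec(
            "2x18O", "cterm", 2 * O18_DELTA,
            {"O": -2, "O18": 2}, n_o18=2,
        ),
        ModificationSpec(
            "1x18O", "cterm", O18_DELTA,
            {"O": -1, "O18": 1}, n_o18=1,
        ),
        ModificationSpec(
            "Carbamidomethyl", "C", 57.0214637236,
            {"C": 2, "H": 3, "N": 1, "O": 1},
        ),
        ModificationSpec(
            "Oxidation", "M", 15.9949146221,
            {"O": 1},
        ),
    ]
}

ModPosition = int | Literal["cterm", "nterm"]


def parse_modifications(text: str) -> tuple[tuple[ModPosition, ModificationSpec], ...]:
    """Parse the ``position:name`` grammar used in identification tables.

    Entries are semicolon-separated; positions are 1-based residue indices or
    the keyword ``cterm``/``nterm``.  Example: ``"4:Deamidation18O;cterm:2x18O"``.
    An empty or ``-`` string means no modifications.
    """
    text = (text or "").strip()
    if text in ("", "-"):
        return ()
    mods: list[tuple[ModPosition, ModificationSpec]] = []
    for entry in text.split(";"):
        entry = entry.strip()
        if not entry:
            continue
        try:
            pos_s, name = entry.split(":", 1)
        except ValueError:
            raise ValueError(f"malformed modification entry {entry!r}") from None
        name = name.strip()
        if name not in MODIFICATIONS:
            raise ValueError(f"unknown modification {name!r}")
        pos: ModPosition
        pos_s = pos_s.strip().lower()
        if pos_s in ("cterm", "nterm"):
            pos = pos_s  # type: ignore[assignment]
        else:
            pos = int(pos_s)
        mods.append((pos, MODIFICATIONS[name]))
    return tuple(mods)


def format_modifications(
    mods: tuple[tuple[ModPosition, ModificationSpec], ...],
) -> str:
    return ";".join(f"{pos}:{spec.name}" for pos, spec in mods) or "-"


@dataclass(frozen=True)
class PeptideIon:
    """An identified peptide species: sequence, modifications, charge.

    ``glycosites`` are the 1-based Asn positions that carried an N-glycan
    before PNGase-F removal; ``label_state`` records which arm of the paired
    labeling the species belongs to (``light`` = all ¹⁶O, ``heavy`` = ¹⁸O
    processed, ``unknown`` when the table does not say).
    """

    sequence: str
    modifications: tuple[tuple[ModPosition, ModificationSpec], ...] = ()
    charge: int = 2
    glycosites: tuple[int, ...] = ()
    label_state: Literal["light", "heavy", "unknown"] = "unknown"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty sequence")
        bad = set(self.sequence) - set(RESIDUE_FORMULAS)
        if bad:
            raise UnknownResidueError(f"unknown residue letters: {sorted(bad)}")
        if self.charge < 1:
            raise ValueError("charge must be >= 1")
        n = len(self.sequence)
        for pos, spec in self.modifications:
            if isinstance(pos, int):
                if not 1 <= pos <= n:
                    raise ValueError(f"modification position {pos} outside 1..{n}")
                if spec.target not in ("cterm", "nterm") and self.sequence[pos - 1] != spec.target:
                    raise ValueError(
                        f"{spec.name} targets {spec.target}, but position {pos} "
                        f"is {self.sequence[pos - 1]}"
                    )
        for site in self.glycosites:
            if not 1 <= site <= n or self.sequence[site - 1] != "N":
                raise ValueError(f"glycosite {site} does not index an Asn")

    @property
    def n_o18(self) -> int:
        return sum(spec.n_o18 for _, spec in self.modifications)

    def mods_at(self, position: ModPosition) -> list[ModificationSpec]:
        return [spec for pos, spec in self.modifications if pos == position]

    def mz(self) -> float:
        return ion_mz(self)


def peptide_composition(ion: PeptideIon) -> ElementalComposition:
    """Elemental composition of the (neutral) modified peptide.

    Residue formulas + one water + every modification's composition delta;
    ¹⁸O labels show up as ``O18`` counts.  Raises if a modification lacks a
    composition delta.
    """
    counts: dict[str, int] = {"H": 2, "O": 1}  # the terminal water
    for letter in ion.sequence:
        for el, n in RESIDUE_FORMULAS[letter].items():
            counts[el] = counts.get(el, 0) + n
    for _, spec in ion.modifications:
        if spec.composition_delta is None:
            raise ValueError(
                f"modification {spec.name} has no composition delta"
            )
        for el, n in spec.composition_delta.items():
            counts[el] = counts.get(el, 0) + n
            if counts[el] < 0:
                raise ValueError(
                    f"modification {spec.name} drives {el} count negative"
                )
    return ElementalComposition(counts)


def monoisotopic_mass(comp: ElementalComposition) -> float:
    """Neutral monoisotopic mass in Da from the embedded atomic table."""
    try:
        return sum(n * ATOMIC_MASSES[el] for el, n in comp.counts.items())
    except KeyError as exc:
        raise UnknownElementError(f"element {exc} not in embedded mass table") from None


def ion_mz(ion: PeptideIon) -> float:
    """Monoisotopic m/z of the protonated peptide, (M + z·H⁺)/z."""
    if ion.charge < 1:
        raise ValueError("charge must be >= 1")
    neutral = monoisotopic_mass(peptide_composition(ion))
    return (neutral + ion.charge * PROTON_MASS) / ion.charge


def label_mass_shift(n_glycosites: int) -> float:
    """Mass difference between the heavy and light members of a pair, Da.

    Two C-terminal exchanges plus one per deglycosylated site:
    (2 + g) · Δ(¹⁸O−¹⁶O).  g = 0 gives the 4-Da non-glycopeptide shift,
    g = 1 the 6-Da glycopeptide shift.
    """
    if n_glycosites < 0:
        raise ValueError("glycosite count must be >= 0")
    return (2 + n_glycosites) * O18_DELTA


@dataclass(frozen=True)
class IsotopeDistribution:
    """Relative envelope intensities at integer offsets 0..K above M0.

    Normalized to sum to one; ratios Mk/M0 are what the overlap-correction
    algebra consumes and are invariant to the normalization choice.
    """

    intensities: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        if arr.ndim != 1 or arr.size < 1:
            raise ValueError("intensities must be a 1-D vector")
        if np.any(arr < 0):
            raise ValueError("negative envelope intensity")
        if arr[0] <= 0:
            raise ValueError("M0 must be positive")
        s = arr.sum()
        if abs(s - 1.0) > 1e-9:
            arr = arr / s
        object.__setattr__(self, "intensities", arr)

    def __getitem__(self, k: int) -> float:
        return float(self.intensities[k]) if k < self.intensities.size else 0.0

    @property
    def K(self) -> int:
        return self.intensities.size - 1

    def ratio(self, k: int) -> float:
        """Mk/M0 — the natural-overlap coefficient at offset k."""
        return self[k] / self[0]


def isotope_distribution(comp: ElementalComposition, K: int = 10) -> IsotopeDistribution:
    """Nominal-mass-binned theoretical envelope of a composition.

    Convolves per-element abundance vectors (each raised to the element
    count) and truncates at offset K, renormalizing to sum one.  ``O18``
    atoms are treated as isotopically pure, so a labeled composition has the
    same envelope *shape* as its light counterpart — the +2-per-label
    displacement is offset arithmetic handled by the extraction, and reagent
    impurity is corrected in the quantitation stage.  Warns if the truncated
    mass fraction exceeds 1e-6.
    """
    if K < 6:
        raise ValueError("K must be >= 6 (the ratio algebra needs M0..M6)")
    dist = np.array([1.0])
    for el, count in comp.counts.items():
        if el not in ISOTOPE_ABUNDANCES:
            raise UnknownElementError(f"no abundance data for element {el!r}")
        vec = np.asarray(ISOTOPE_ABUNDANCES[el], dtype=float)
        if vec.size == 1:
            continue  # pure isotope contributes nothing to the shape
        for _ in range(count):
            dist = np.convolve(dist, vec)
            if dist.size > K + 1 + 8:  # keep a guard band, trim the tail
                tail = dist[K + 1 + 8:].sum()
                dist = dist[: K + 1 + 8]
                dist[-1] += tail
    full = np.zeros(K + 1)
    upto = min(dist.size, K + 1)
    full[:upto] = dist[:upto]
    truncated = dist[K + 1:].sum() if dist.size > K + 1 else 0.0
    if truncated > 1e-6:
        warnings.warn(
            f"isotope envelope truncated at +{K} Da; {truncated:.2e} of the "
            "distribution discarded",
            stacklevel=2,
        )
    return IsotopeDistribution(full / full.sum())


_Y_SERIES_EXTRA = WATER  # y fragments keep the C-terminal water


def fragment_mz(
    ion: PeptideIon,
    series: Literal["b", "y"],
    index: int,
    charge: int = 1,
) -> float:
    """Monoisotopic m/z of a b- or y-series fragment (singly charged default).

    Modifications are included when their residue falls inside the fragment;
    C-terminal labels travel with y ions only, so a doubly ¹⁸O-labeled
    C-terminus lifts every y ion by ~4 Da while b ions shift only where the
    labeled site is included — the fragment-level signature that localizes
    the labels.
    """
    n = len(ion.sequence)
    if not 1 <= index < n:
        raise ValueError(f"fragment index {index} outside 1..{n - 1}")
    if series not in ("b", "y"):
        raise ValueError("series must be 'b' or 'y'")
    if series == "b":
        residues = range(1, index + 1)
    else:
        residues = range(n - index + 1, n + 1)
    mass = sum(
        sum(
            cnt * ATOMIC_MASSES[el]
            for el, cnt in RESIDUE_FORMULAS[ion.sequence[pos - 1]].items()
        )
        for pos in residues
    )
    included = set(residues)
    for pos, spec in ion.modifications:
        if pos == "cterm":
            if series == "y":
                mass += spec.mass_delta
        elif pos == "nterm":
            if series == "b":
                mass += spec.mass_delta
        elif pos in included:
            mass += spec.mass_delta
    if series == "y":
        mass += _Y_SERIES_EXTRA
    return (mass + charge * PROTON_MASS) / charge
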