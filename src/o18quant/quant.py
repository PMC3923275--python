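"""Overlap-corrected heavy/light ratios from merged ¹⁸O/¹⁶O MS1 envelopes.

A tandem-labeled pair produces one merged isotope cluster: the light (all
¹⁶O) species at the monoisotopic position and the heavy species displaced by
+2 Da per ¹⁸O label (two C-terminal labels, plus one per deglycosylated Asn).
Because peptide natural envelopes extend several Da, the +2/+4/+6 channels
mix natural isotopologues of lighter species with monoisotopic peaks of
heavier ones.  This module separates them.

Let I0, I2, I4, I6 be the summed intensities at nominal offsets 0/+2/+4/+6
from the light monoisotopic peak, and r_k = M_k/M_0 the theoretical envelope
ratios of the peptide.  Sequential stripping peels the natural contribution
of each lighter species off the next channel:

    S0 = I0
    S2 = I2 − r2·S0
    S4 = I4 − r4·S0 − r2·S2
    S6 = I6 − r6·S0 − r4·S2 − r2·S4

S_k is then the monoisotopic-equivalent abundance of the k/2-label species.
Expanding the recursion gives the closed forms used for manual calculation:

    ratio(¹⁶O/¹⁸O), glycopeptide (3 labels):
        I0 / [I2 + I4 + I6 − r2·I4 − (r2 + r4 − r2²)·I2
              − (r2 + r4 + r6 − r2² − 2·r2·r4 + r2³)·I0]
    ratio(¹⁶O/¹⁸O), non-glycopeptide (2 labels):
        I0 / [I2 + I4 − r2·I2 − (r2 + r4 − r2²)·I0]

and the grouped ratio reported for the paired comparison is

    ratio(¹⁸O/¹⁶O) = (S6 + S4) / S0

i.e. (fully site-labeled species with two or one C-terminal label) over the
unlabeled species — a grouping deliberately insensitive to C-terminal
back-exchange and incomplete C-terminal labeling, which only move abundance
between S6 and S4.  Reagent impurity (nominally 97% ¹⁸O water) is inverted
as a binomial mixing over label counts before grouping.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from math import comb
from typing import Iterable, Literal

import numpy as np

from .masscalc import (
    C13_DELTA,
    O18_DELTA,
    IsotopeDistribution,
    PeptideIon,
    ion_mz,
    isotope_distribution,
    peptide_composition,
)

__all__ = [
    "EnvelopeMeasurement",
    "CorrectionRatios",
    "SpeciesAbundances",
    "RatioResult",
    "correction_ratios",
    "extract_envelope",
    "strip_species",
    "ratio_formula1",
    "ratio_formula2",
    "ratio_formula3",
    "purity_correct",
    "MultisiteError",
]

#: Labeled total below this fraction of I0 is flagged "denominator-small".
DENOMINATOR_FLOOR = 0.01


class MultisiteError(ValueError):
    """Peptide has ≥2 glycosites; the 4-channel algebra does not apply.

    The pair shift exceeds 6 Da and the envelope needs channels beyond +6.
    Pass ``max_labels`` explicitly to use the generalized stripping.
    """


@dataclass(frozen=True)
class CorrectionRatios:
    """Natural-envelope overlap coefficients r_k = M_k/M_0 at even offsets."""

    r2: float
    r4: float
    r6: float
    higher: tuple[float, ...] = ()  # r8, r10, ... for multi-site peptides

    def __post_init__(self) -> None:
        for r in (self.r2, self.r4, self.r6, *self.higher):
            if r < 0:
                raise ValueError("correction ratios must be >= 0")

    def as_vector(self, n_channels: int) -> np.ndarray:
        """[1, r2, r4, ...] padded with zeros out to n_channels entries."""
        vec = np.zeros(n_channels)
        known = (1.0, self.r2, self.r4, self.r6, *self.higher)
        vec[: min(n_channels, len(known))] = known[:n_channels]
        return vec


def correction_ratios(dist: IsotopeDistribution, n_extra: int = 0) -> CorrectionRatios:
    """Build overlap coefficients from a theoretical envelope."""
    higher = tuple(dist.ratio(8 + 2 * i) for i in range(n_extra))
    return CorrectionRatios(dist.ratio(2), dist.ratio(4), dist.ratio(6), higher)


@dataclass(frozen=True)
class EnvelopeMeasurement:
    """Observed intensities of a merged pair cluster at even nominal offsets.

    ``even`` holds I0, I2, I4, I6 (and further channels for multi-site
    peptides); ``odd`` holds the diagnostic I1/I3/I5 channels that never
    enter the ratio algebra.  Intensities are arbitrary units summed over
    the scans in the extraction window.
    """

    even: tuple[float, ...]
    odd: tuple[float, ...] = ()
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.even) < 4:
            raise ValueError("need at least channels I0, I2, I4, I6")
        if any(v < 0 for v in (*self.even, *self.odd)):
            raise ValueError("negative intensity")

    @property
    def i0(self) -> float:
        return self.even[0]

    @property
    def i2(self) -> float:
        return self.even[1]

    @property
    def i4(self) -> float:
        return self.even[2]

    @property
    def i6(self) -> float:
        return self.even[3]

    @property
    def quantifiable(self) -> bool:
        return self.i0 > 0


@dataclass(frozen=True)
class SpeciesAbundances:
    """Monoisotopic-equivalent abundances of the 0/1/2/3-label species.

    ``s[k]`` is the abundance of the species carrying k ¹⁸O labels
    (S0 = unlabeled, S4 = one C-terminal pair member short, S6 = fully
    labeled glycopeptide).  Components clamped to zero during stripping are
    flagged in ``clamped``.
    """

    s: tuple[float, ...]
    clamped: tuple[bool, ...] = ()

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.s):
            raise ValueError("species abundances must be >= 0 after clamping")
        if not self.clamped:
            object.__setattr__(self, "clamped", (False,) * len(self.s))
        if len(self.clamped) != len(self.s):
            raise ValueError("clamp flags must match component count")

    @property
    def s0(self) -> float:
        return self.s[0]

    @property
    def s2(self) -> float:
        return self.s[1]

    @property
    def s4(self) -> float:
        return self.s[2]

    @property
    def s6(self) -> float:
        return self.s[3]

    @property
    def any_clamped(self) -> bool:
        return any(self.clamped)


Orientation = Literal["heavy/light", "light/heavy"]


@dataclass(frozen=True)
class RatioResult:
    """An oriented abundance ratio with provenance and quality flags.

    ``value`` is None when the measurement is not quantifiable (zero or
    near-zero denominator); ``reason`` then says why.  ``invert()`` returns
    the reciprocal with the opposite orientation — exactly.
    """

    value: float | None
    orientation: Orientation
    formula: Literal["F1", "F2", "F3-groups"]
    species: SpeciesAbundances | None = None
    flags: tuple[str, ...] = ()
    reason: str | None = None

    @property
    def quantifiable(self) -> bool:
        return self.value is not None

    def invert(self) -> "RatioResult":
        flipped: Orientation = (
            "light/heavy" if self.orientation == "heavy/light" else "heavy/light"
        )
        return replace(
            self,
            value=None if self.value is None else 1.0 / self.value,
            orientation=flipped,
        )

    def oriented(self, orientation: Orientation) -> "RatioResult":
        return self if orientation == self.orientation else self.invert()


# ---------------------------------------------------------------------------
# Envelope extraction
# ---------------------------------------------------------------------------

def extract_envelope(
    spectra: Iterable,
    light_ion: PeptideIon,
    rt_s: float | None = None,
    rt_window_s: float = 30.0,
    tol_ppm: float = 10.0,
    max_offset: int = 6,
) -> EnvelopeMeasurement:
    """Sum centroid intensities at the pair's nominal offset channels.

    For each offset k (0..max_offset) two candidate positions exist within
    the merged cluster: the natural isotopologue ladder of a lighter species
    at ``mz + k·1.00335/z`` and, at even k, the monoisotopic peak of the
    k/2-label species at ``mz + (k/2)·2.00425/z``.  At 100k resolving power
    these partially split, so intensity is summed over every centroid within
    ``tol_ppm`` of *either* candidate (each centroid counted once), across
    all scans whose retention time falls in ``rt_s ± rt_window_s``.  With
    ``rt_s=None`` every scan is used.

    ``spectra`` yields objects with ``rt_s``, ``mz`` and ``intensity``
    attributes (see :mod:`o18quant.spectra`).  An empty window or an empty
    I0 channel is reported through the measurement's ``quantifiable`` flag,
    not raised.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be > 0")
    z = light_ion.charge
    mz0 = ion_mz(light_ion)
    even = np.zeros(max_offset // 2 + 1)
    odd = np.zeros((max_offset + 1) // 2)
    scan_ids: list = []
    n_scans = 0
    for spec in spectra:
        rt = getattr(spec, "rt_s")
        if rt_s is not None and abs(rt - rt_s) > rt_window_s:
            continue
        n_scans += 1
        scan_ids.append(getattr(spec, "scan_id", None))
        mz = np.asarray(spec.mz)
        inten = np.asarray(spec.intensity)
        for k in range(max_offset + 1):
            candidates = [mz0 + k * C13_DELTA / z]
            if k % 2 == 0 and k > 0:
                candidates.append(mz0 + (k // 2) * O18_DELTA / z)
            hit = np.zeros(mz.size, dtype=bool)
            for c in candidates:
                hit |= np.abs(mz - c) <= c * tol_ppm * 1e-6
            total = float(inten[hit].sum())
            if k % 2 == 0:
                even[k // 2] += total
            else:
                odd[k // 2] += total
    meta = {
        "tol_ppm": tol_ppm,
        "rt_center_s": rt_s,
        "rt_window_s": rt_window_s,
        "n_scans": n_scans,
        "scan_ids": scan_ids,
        "mz_light": mz0,
        "charge": z,
    }
    return EnvelopeMeasurement(tuple(even), tuple(odd), meta)


# ---------------------------------------------------------------------------
# Natural-envelope stripping and the ratio formulas
# ---------------------------------------------------------------------------

def strip_species(
    env: EnvelopeMeasurement, r: CorrectionRatios
) -> SpeciesAbundances:
    """Peel natural isotopologue overlap off each even channel in turn.

    S_k = I_k − Σ_{j<k} r_{k−j}·S_j over even offsets; negative intermediate
    values are clamped to zero *before* propagating to the next channel, and
    flagged.  Requires I0 > 0.
    """
    if env.i0 <= 0:
        raise ValueError("I0 must be > 0 for species stripping")
    n = len(env.even)
    rv = r.as_vector(n)
    s = np.zeros(n)
    clamped = [False] * n
    for k in range(n):
        val = env.even[k] - sum(rv[k - j] * s[j] for j in range(k))
        if val < 0:
            val, clamped[k] = 0.0, True
        s[k] = val
    return SpeciesAbundances(tuple(s), tuple(clamped))


def _labeled_total_result(
    env: EnvelopeMeasurement,
    r: CorrectionRatios,
    denominator: float,
    formula: Literal["F1", "F2"],
    denominator_floor: float,
) -> RatioResult:
    """Package a closed-form light/(labeled total) ratio with flag logic."""
    species = strip_species(env, r)
    flags: list[str] = []
    if species.any_clamped:
        flags.append("clamped")
    if denominator <= 0:
        return RatioResult(
            None, "light/heavy", formula, species, tuple(flags),
            reason="non-positive labeled total",
        )
    if denominator < denominator_floor * env.i0:
        flags.append("denominator-small")
        return RatioResult(
            None, "light/heavy", formula, species, tuple(flags),
            reason=f"labeled total < {denominator_floor:.0%} of I0",
        )
    return RatioResult(env.i0 / denominator, "light/heavy", formula, species, tuple(flags))


def ratio_formula1(
    env: EnvelopeMeasurement,
    r: CorrectionRatios,
    denominator_floor: float = DENOMINATOR_FLOOR,
) -> RatioResult:
    """Closed-form ¹⁶O/¹⁸O ratio for a mono-glycosylated peptide.

    The labeled total is I2+I4+I6 with the natural overlap of every lighter
    species subtracted; algebraically identical to S2+S4+S6 from
    :func:`strip_species` (without clamping).  Returned oriented
    light/heavy; use ``.invert()`` for the canonical heavy/light value.
    """
    if env.i0 <= 0:
        return RatioResult(None, "light/heavy", "F1", reason="I0 is zero")
    r2, r4, r6 = r.r2, r.r4, r.r6
    denom = (
        env.i2 + env.i4 + env.i6
        - r2 * env.i4
        - (r2 + r4 - r2**2) * env.i2
        - (r2 + r4 + r6 - r2**2 - 2 * r2 * r4 + r2**3) * env.i0
    )
    return _labeled_total_result(env, r, denom, "F1", denominator_floor)


def ratio_formula2(
    env: EnvelopeMeasurement,
    r: CorrectionRatios,
    denominator_floor: float = DENOMINATOR_FLOOR,
) -> RatioResult:
    """Closed-form ¹⁶O/¹⁸O ratio for a non-glycopeptide (C-term labels only).

    The heavy species sits at +4 Da, so I6 never enters: the labeled total
    is I2+I4 − r2·I2 − (r2+r4−r2²)·I0 = S2+S4.
    """
    if env.i0 <= 0:
        return RatioResult(None, "light/heavy", "F2", reason="I0 is zero")
    r2, r4 = r.r2, r.r4
    denom = env.i2 + env.i4 - r2 * env.i2 - (r2 + r4 - r2**2) * env.i0
    return _labeled_total_result(env, r, denom, "F2", denominator_floor)


def ratio_formula3(
    species: SpeciesAbundances,
    include_single_label: bool = False,
    n_glycosites: int = 1,
) -> RatioResult:
    """Grouped ¹⁸O/¹⁶O ratio, (fully site-labeled species)/(unlabeled).

    For the mono-glycosylated case: (S6 + S4)/S0, where S6 is the fully
    labeled species (two C-terminal + site), S4 the back-exchanged /
    incompletely C-terminally labeled species (one C-terminal + site), and
    S0 the light species.  The single-label species S2 (site only, both
    C-terminal labels lost) is excluded by default; pass
    ``include_single_label=True`` to count it with the heavy total, which
    reconciles the grouped ratio with the reciprocal of the closed-form
    glycopeptide ratio.

    Peptides with g ≥ 2 sites need the extended channels: the groups then
    sit at 2g+4 and 2g+2 labels-equivalent offsets.  Raises
    :class:`MultisiteError` if the species vector is too short for g.
    """
    if species.s0 <= 0:
        return RatioResult(
            None, "heavy/light", "F3-groups", species, reason="S0 is zero"
        )
    hi = 2 + n_glycosites  # label count of the fully labeled (Group A) species
    if hi >= len(species.s):
        raise MultisiteError(
            f"{n_glycosites} glycosites need {hi + 1} species channels, "
            f"got {len(species.s)}"
        )
    numerator = species.s[hi] + species.s[hi - 1]
    flags: list[str] = []
    if species.any_clamped:
        flags.append("clamped")
    if include_single_label:
        numerator += sum(species.s[1 : hi - 1])
        flags.append("single-label-included")
    return RatioResult(
        numerator / species.s0, "heavy/light", "F3-groups", species, tuple(flags)
    )


# ---------------------------------------------------------------------------
# Reagent purity correction
# ---------------------------------------------------------------------------

def purity_mixing_matrix(purity: float, n_species: int) -> np.ndarray:
    """M[k, n] = P(observe k labels | nominal n labels) under purity p.

    Each nominal ¹⁸O position independently carries ¹⁸O with probability p
    (the enrichment of the labeling water), so observed counts are
    binomially thinned nominal counts.  Lower-triangular in n ≥ k, unit
    diagonal scaled by p^n.
    """
    if not 0 < purity <= 1:
        raise ValueError("purity must be in (0, 1]")
    m = np.zeros((n_species, n_species))
    for n in range(n_species):
        for k in range(n + 1):
            m[k, n] = comb(n, k) * purity**k * (1 - purity) ** (n - k)
    return m


def purity_correct(species: SpeciesAbundances, purity: float) -> SpeciesAbundances:
    """Invert the binomial label-purity mixing on observed species abundances.

    With 97% ¹⁸O water a nominal triple-label molecule is observed with
    0/1/2/3 labels in binomial proportions; solving the (triangular) mixing
    system recovers the nominal-label abundances.  purity = 1 is the
    identity.  Small negative solutions (noise) are clamped and flagged.
    """
    if purity == 1.0:
        return species
    m = purity_mixing_matrix(purity, len(species.s))
    true = np.linalg.solve(m, np.asarray(species.s))
    clamped = list(species.clamped)
    for i, v in enumerate(true):
        if v < 0:
            true[i] = 0.0
            clamped[i] = True
    return SpeciesAbundances(tuple(true), tuple(clamped))


def envelope_ratios_for(ion: PeptideIon, n_extra: int = 0) -> CorrectionRatios:
    """Theoretical overlap coefficients for a peptide's light composition."""
    comp = peptide_composition(ion)
    k_needed = 6 + 2 * n_extra
    dist = isotope_distribution(comp, K=max(12, k_needed))
    return correction_ratios(dist, n_extra=n_extra)
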