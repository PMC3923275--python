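"""Ground-truthed synthetic paired-label MS1 spectra.

The forward model mirrors the labeling chemistry: a light sample processed
entirely in H₂¹⁶O and a heavy sample processed in H₂¹⁸O are mixed at a known
heavy/light ratio R.  Heavy-sample molecules acquire 0/1/2 C-terminal ¹⁸O
with probabilities (p0, p1, p2) — incomplete trypsin-catalyzed exchange and
back-exchange move mass from p2 toward p0 — and each glycosite is labeled
with efficiency q; every nominal ¹⁸O position actually carries ¹⁸O with
probability equal to the reagent purity.  Species populations are expected
values (not sampled), each convolved with the peptide's natural envelope and
emitted as centroid sticks; stochasticity enters only as per-centroid
multiplicative log-normal intensity noise, so noise-free runs are exactly
invertible by the quantitation stage.

Defaults represent the bench conditions of the workflow this emulates:
97% ¹⁸O water, complete C-terminal double labeling, complete site labeling,
and LC peaks sampled by a handful of MS1 scans.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb
from typing import Mapping, Sequence

import numpy as np

from .glyco import find_sequons
from .masscalc import (
    C13_DELTA,
    MODIFICATIONS,
    O18_DELTA,
    PeptideIon,
    format_modifications,
    ion_mz,
    isotope_distribution,
    parse_modifications,
    peptide_composition,
)
from .spectra import Spectrum

__all__ = [
    "LabelingModel",
    "TruthManifest",
    "light_ion",
    "heavy_ion",
    "simulate_pair",
    "simulate_cohort",
]

#: Base total ion intensity planted per peptide (arbitrary counts).
BASE_INTENSITY = 1.0e6


@dataclass(frozen=True)
class LabelingModel:
    """Labeling-state distribution of the heavy sample and mixing ratio.

    ratio            heavy/light mixing ratio R (> 0)
    p_cterm          (p0, p1, p2): probabilities of 0/1/2 C-terminal ¹⁸O
    site_efficiency  q, probability a glycosite carries its ¹⁸O
    purity           ¹⁸O enrichment of the labeling water (0.97 nominal)
    """

    ratio: float = 1.0
    p_cterm: tuple[float, float, float] = (0.0, 0.0, 1.0)
    site_efficiency: float = 1.0
    purity: float = 0.97

    def __post_init__(self) -> None:
        if self.ratio <= 0:
            raise ValueError("mixing ratio must be > 0")
        if any(p < 0 for p in self.p_cterm) or abs(sum(self.p_cterm) - 1) > 1e-12:
            raise ValueError("p_cterm must be a probability vector summing to 1")
        if not 0 <= self.site_efficiency <= 1:
            raise ValueError("site efficiency must be in [0, 1]")
        if not 0 < self.purity <= 1:
            raise ValueError("purity must be in (0, 1]")

    def with_back_exchange(self, extent: float) -> "LabelingModel":
        """Binomially thin the C-terminal labels: each survives w.p. 1−extent.

        Models protease-catalyzed back-exchange after mixing; extent 0 is
        identity, extent 1 strips the C-terminus entirely.
        """
        if not 0 <= extent <= 1:
            raise ValueError("extent must be in [0, 1]")
        keep = 1 - extent
        p0, p1, p2 = self.p_cterm
        q0 = p0 + p1 * extent + p2 * extent**2
        q1 = p1 * keep + p2 * 2 * keep * extent
        q2 = p2 * keep**2
        return LabelingModel(self.ratio, (q0, q1, q2), self.site_efficiency, self.purity)

    def label_count_distribution(self, n_glycosites: int) -> np.ndarray:
        """P(k actual ¹⁸O labels) for a heavy-sample molecule.

        Convolves the C-terminal distribution with the per-site Bernoulli(q)
        labels, then thins every nominal label by the reagent purity.
        """
        nominal = np.array(self.p_cterm)
        site = np.array([1 - self.site_efficiency, self.site_efficiency])
        for _ in range(n_glycosites):
            nominal = np.convolve(nominal, site)
        n_max = nominal.size - 1
        actual = np.zeros(n_max + 1)
        p = self.purity
        for n, w in enumerate(nominal):
            for k in range(n + 1):
                actual[k] += w * comb(n, k) * p**k * (1 - p) ** (n - k)
        return actual


@dataclass(frozen=True)
class TruthManifest:
    """Everything needed to verify recovery: per-peptide ground truth.

    ``records`` maps peptide sequence → dict with the true heavy/light
    ratio, the species abundances by label count, the planted noise-free
    even-channel intensities, RT center and charge.  Regenerating with the
    same seed reproduces the spectra bit-identically.
    """

    seed: int
    noise_cv: float
    n_scans: int
    records: Mapping[str, dict] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "noise_cv": self.noise_cv,
            "n_scans": self.n_scans,
            "records": {k: dict(v) for k, v in self.records.items()},
        }


def light_ion(
    sequence: str,
    charge: int = 2,
    extra_mods: str = "",
) -> PeptideIon:
    """Build the all-¹⁶O member of a pair: ¹⁶O-deamidation at every sequon."""
    sites = tuple(m.position for m in find_sequons(sequence))
    mods = [(p, MODIFICATIONS["Deamidation"]) for p in sites]
    mods += list(parse_modifications(extra_mods))
    return PeptideIon(sequence, tuple(mods), charge, sites, "light")


def heavy_ion(light: PeptideIon) -> PeptideIon:
    """The fully labeled counterpart: ¹⁸O-deamidation + double C-term label."""
    mods = []
    for pos, spec in light.modifications:
        if spec.name == "Deamidation" and isinstance(pos, int) and pos in light.glycosites:
            mods.append((pos, MODIFICATIONS["Deamidation18O"]))
        else:
            mods.append((pos, spec))
    mods.append(("cterm", MODIFICATIONS["2x18O"]))
    return PeptideIon(light.sequence, tuple(mods), light.charge, light.glycosites, "heavy")


def _species_abundances(
    light: PeptideIon, model: LabelingModel
) -> np.ndarray:
    """Expected abundance per actual-label-count species (index = k labels)."""
    g = len(light.glycosites)
    heavy_dist = model.label_count_distribution(g)
    abundances = np.zeros(max(heavy_dist.size, 1))
    abundances[0] += 1.0  # the light sample, amount 1
    abundances += model.ratio * heavy_dist
    return abundances


def _stick_spectrum(
    light: PeptideIon,
    abundances: np.ndarray,
    envelope: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free merged cluster: m/z and intensity sticks.

    Species with k labels places its natural ladder at
    (k·Δ¹⁸O + j·Δ¹³C)/z above the light monoisotopic m/z.
    """
    z = light.charge
    mz0 = ion_mz(light)
    mzs, ints = [], []
    for k, a in enumerate(abundances):
        if a <= 0:
            continue
        for j, m in enumerate(envelope):
            if m <= 0:
                continue
            mzs.append(mz0 + (k * O18_DELTA + j * C13_DELTA) / z)
            ints.append(a * m * BASE_INTENSITY)
    order = np.argsort(mzs)
    return np.asarray(mzs)[order], np.asarray(ints)[order]


def _planted_channels(abundances: np.ndarray, envelope: np.ndarray, n_even: int) -> list[float]:
    """Noise-free even-channel intensities I0, I2, ... of the merged cluster."""
    out = []
    for e in range(n_even):
        total = 0.0
        for k, a in enumerate(abundances):
            j = 2 * e - 2 * k
            if 0 <= j < envelope.size:
                total += a * envelope[j] * BASE_INTENSITY
        out.append(total)
    return out


def simulate_pair(
    light: PeptideIon,
    model: LabelingModel,
    noise_cv: float = 0.0,
    n_scans: int = 5,
    seed: int = 0,
    rt_center_s: float = 600.0,
) -> tuple[list[Spectrum], TruthManifest]:
    """Simulate the merged MS1 cluster of one labeled pair.

    Returns ``n_scans`` centroid spectra spaced 1 s around ``rt_center_s``
    (total planted intensity split evenly across scans) and a manifest with
    the exact species abundances and noise-free channel intensities.  With
    ``noise_cv = 0`` extraction + stripping + purity inversion recovers the
    mixing ratio exactly.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    abund = _species_abundances(light, model)
    K = 12
    envelope = isotope_distribution(peptide_composition(light), K=K).intensities
    mz, inten = _stick_spectrum(light, abund, envelope)
    rng = np.random.default_rng(seed)
    spectra = []
    rts = rt_center_s + (np.arange(n_scans) - (n_scans - 1) / 2)
    for i, rt in enumerate(rts):
        scan_int = inten / n_scans
        if noise_cv > 0:
            sigma = np.sqrt(np.log(1 + noise_cv**2))
            noise = rng.lognormal(-sigma**2 / 2, sigma, size=scan_int.size)
            scan_int = scan_int * noise
        spectra.append(Spectrum(f"scan={i + 1}", float(rt), mz.copy(), scan_int))
    g = len(light.glycosites)
    record = {
        "sequence": light.sequence,
        "charge": light.charge,
        "n_glycosites": g,
        "true_ratio_heavy_light": model.ratio,
        "species_abundances": abund.tolist(),
        "planted_even_channels": _planted_channels(abund, envelope, 2 + g + 2),
        "rt_center_s": rt_center_s,
    }
    manifest = TruthManifest(seed, noise_cv, n_scans, {light.sequence: record})
    return spectra, manifest


def simulate_cohort(
    panel: Sequence[dict],
    per_peptide_ratios: Sequence[float],
    model: LabelingModel = LabelingModel(),
    noise_cv: float = 0.0,
    n_scans: int = 5,
    seed: int = 0,
) -> tuple[list[Spectrum], "pandas.DataFrame", TruthManifest]:
    """Simulate a multiplexed comparison: many pairs, one spectrum stream.

    ``panel`` entries are dicts with keys ``sequence`` (required) and
    optional ``charge``, ``protein``, ``subgroup``, ``probability``;
    ``per_peptide_ratios`` gives each pair's true heavy/light ratio (per
    lectin subgroup assignments are made by listing the same protein under
    different subgroups).  Peptides are placed at RT centers 120 s apart so
    their extraction windows never overlap.  Returns the merged scan list,
    an identification table (light-form identifications, modification-string
    grammar of :mod:`o18quant.masscalc`), and the combined truth manifest.
    """
    import pandas as pd

    if not panel:
        raise ValueError("panel must be non-empty")
    if len(panel) != len(per_peptide_ratios):
        raise ValueError("one ratio per panel peptide required")
    all_spectra: list[Spectrum] = []
    rows = []
    records = {}
    for idx, (entry, ratio) in enumerate(zip(panel, per_peptide_ratios)):
        seq = entry["sequence"]
        charge = int(entry.get("charge", 2))
        ion = light_ion(seq, charge=charge)
        rt = 300.0 + 120.0 * idx
        pep_model = LabelingModel(
            ratio, model.p_cterm, model.site_efficiency, model.purity
        )
        spectra, manifest = simulate_pair(
            ion, pep_model, noise_cv, n_scans,
            seed=seed + idx + 1, rt_center_s=rt,
        )
        all_spectra.extend(spectra)
        records.update(manifest.records)
        rows.append(
            {
                "peptide": seq,
                "mods": format_modifications(ion.modifications),
                "charge": charge,
                "rt_s": rt,
                "protein": entry.get("protein", f"PROT{idx + 1}"),
                "subgroup": entry.get("subgroup", "none"),
                "probability": float(entry.get("probability", 0.99)),
            }
        )
    # one merged chronologically ordered stream with unique scan ids
    all_spectra.sort(key=lambda s: s.rt_s)
    all_spectra = [
        Spectrum(f"scan={i + 1}", s.rt_s, s.mz, s.intensity)
        for i, s in enumerate(all_spectra)
    ]
    id_table = pd.DataFrame(rows)
    manifest = TruthManifest(seed, noise_cv, n_scans, records)
    return all_spectra, id_table, manifest
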