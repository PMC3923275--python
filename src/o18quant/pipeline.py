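"""End-to-end quantitation: spectra + identifications → ratio tables.

For every identified peptide the pipeline anchors on the light (all-¹⁶O)
form, extracts the merged pair envelope from the MS1 scans around the
identification's retention time, strips natural-isotope overlap, inverts the
reagent-purity mixing, and reports both the closed-form light/heavy ratio
(glycopeptide or non-glycopeptide form, as the sequon classification
dictates) and the canonical grouped heavy/light ratio, with a three-sigma
significance call.  Protein ratios are medians of their glycopeptide ratios
per lectin subgroup.  Everything is deterministic given inputs and config.
"""

from __future__ import annotations

import logging
from typing import Sequence

import pandas as pd

from .glyco import classify_peptide
from .io import DEFAULT_CONFIG, IdentificationRecord, load_config, read_ids, write_results
from .masscalc import MODIFICATIONS, PeptideIon
from .quant import (
    MultisiteError,
    envelope_ratios_for,
    extract_envelope,
    purity_correct,
    ratio_formula1,
    ratio_formula2,
    ratio_formula3,
    strip_species,
)
from .spectra import Spectrum, read_ms1
from .stats import classify_change, protein_ratio, thresholds_from_sd

__all__ = ["to_light", "quantify_peptides", "rollup_proteins", "discordant_proteins", "run_quantify"]

log = logging.getLogger("o18quant")


def to_light(ion: PeptideIon) -> PeptideIon:
    """The all-¹⁶O anchor form: ¹⁸O mods replaced by their ¹⁶O counterparts."""
    mods = []
    for pos, spec in ion.modifications:
        if spec.name == "Deamidation18O":
            mods.append((pos, MODIFICATIONS["Deamidation"]))
        elif spec.name in ("2x18O", "1x18O"):
            continue  # unlabeled C-terminus carries no modification
        else:
            mods.append((pos, spec))
    return PeptideIon(ion.sequence, tuple(mods), ion.charge, ion.glycosites, "light")


def _empty_row(rec: IdentificationRecord, pclass: str, reason: str) -> dict:
    return {
        "peptide": rec.peptide,
        "mods": rec.mods,
        "charge": rec.charge,
        "rt_s": rec.rt_s,
        "protein": rec.protein,
        "subgroup": rec.subgroup,
        "class": pclass,
        "n_glycosites": 0,
        "quantifiable": False,
        "reason": reason,
    }


def quantify_peptides(
    spectra: Sequence[Spectrum],
    records: Sequence[IdentificationRecord],
    config: dict | None = None,
) -> pd.DataFrame:
    """One quantitation row per identification.

    Columns: identification fields, peptide class, even-channel intensities
    I0..I6(+), species abundances S0..S6(+), the closed-form light/heavy
    ratio (F1 for glycopeptides, F2 otherwise), the grouped heavy/light
    ratio, flags, significance classification, and extraction traceability
    (scan ids, window).  Not-quantifiable rows carry a reason and no ratio.
    """
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    thresholds = thresholds_from_sd(cfg["sd_peptide"], "peptide")
    rows = []
    for rec in records:
        ion = rec.to_ion()
        pclass, sites = classify_peptide(ion)
        if pclass == "inconsistent":
            rows.append(_empty_row(rec, pclass, "deamidation outside any sequon"))
            continue
        g = len(sites)
        if g >= 2 and not cfg["allow_multisite"]:
            raise MultisiteError(
                f"{rec.peptide} has {g} labeled glycosites; the 4-channel "
                "formulas cover one site — set allow_multisite to use the "
                "generalized stripping"
            )
        ion = rec.to_ion(glycosites=sites)
        light = to_light(ion)
        n_extra = max(0, g - 1)
        r = envelope_ratios_for(light, n_extra=n_extra)
        env = extract_envelope(
            spectra,
            light,
            rt_s=rec.rt_s,
            rt_window_s=cfg["rt_window_s"],
            tol_ppm=cfg["tol_ppm"],
            max_offset=6 + 2 * n_extra,
        )
        row = {
            **_empty_row(rec, pclass, ""),
            "n_glycosites": g,
            "mz_light": env.metadata["mz_light"],
            "n_scans": env.metadata["n_scans"],
            "scan_ids": ";".join(str(s) for s in env.metadata["scan_ids"]),
        }
        for k, v in enumerate(env.even):
            row[f"I{2 * k}"] = v
        if not env.quantifiable:
            row["reason"] = "no signal at the light monoisotopic position"
            rows.append(row)
            continue
        species = strip_species(env, r)
        species = purity_correct(species, cfg["purity"])
        for k, v in enumerate(species.s):
            row[f"S{2 * k}"] = v
        closed = (
            ratio_formula1(env, r, cfg["denominator_floor"])
            if pclass == "glyco"
            else ratio_formula2(env, r, cfg["denominator_floor"])
        )
        grouped = ratio_formula3(
            species,
            include_single_label=cfg["include_single_label"],
            n_glycosites=g,
        )
        flags = sorted(set(closed.flags) | set(grouped.flags))
        row["formula"] = closed.formula
        row["ratio_light_heavy"] = closed.value
        row["ratio_heavy_light"] = grouped.value
        row["flags"] = ";".join(flags)
        if grouped.quantifiable:
            row["quantifiable"] = True
            row["significance"] = classify_change(grouped.value, thresholds).classification
        else:
            row["reason"] = grouped.reason or closed.reason or "not quantifiable"
        rows.append(row)
    return pd.DataFrame(rows)


def rollup_proteins(peptide_df: pd.DataFrame, config: dict | None = None) -> pd.DataFrame:
    """Protein × subgroup medians of quantifiable glycopeptide ratios."""
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    thresholds = thresholds_from_sd(cfg["sd_protein"], "protein")
    rows = []
    if peptide_df.empty:
        return pd.DataFrame(rows)
    quant = peptide_df[
        (peptide_df.get("quantifiable", False))
        & (peptide_df["class"] == "glyco")
    ]
    for (protein, subgroup), grp in quant.groupby(["protein", "subgroup"], sort=True):
        ratios = grp["ratio_heavy_light"].tolist()
        med, low_support = protein_ratio(ratios)
        rows.append(
            {
                "protein": protein,
                "subgroup": subgroup,
                "n_peptides": len(ratios),
                "ratio_heavy_light": med,
                "low_support": low_support,
                "significance": classify_change(med, thresholds).classification,
            }
        )
    return pd.DataFrame(rows)


def discordant_proteins(protein_df: pd.DataFrame) -> list[str]:
    """Proteins whose lectin subgroups disagree in change direction.

    A protein is discordant when one subgroup calls it up (minor or
    significant) and another calls it down — the signature of a glycoform
    shift rather than an abundance change.
    """
    out = []
    if protein_df.empty:
        return out
    for protein, grp in protein_df.groupby("protein"):
        calls = set(grp["significance"])
        ups = {"minor-up", "significant-up"} & calls
        downs = {"minor-down", "significant-down"} & calls
        if ups and downs:
            out.append(protein)
    return sorted(out)


def run_quantify(config: dict | str | None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """File-level entry: read mzML + IDs per config, write both ratio TSVs."""
    cfg = load_config(config) if isinstance(config, (str, type(None))) else {**DEFAULT_CONFIG, **config}
    if not cfg.get("mzml") or not cfg.get("ids"):
        raise ValueError("config must point to 'mzml' and 'ids' inputs")
    log.info("config: %s", {k: cfg[k] for k in sorted(cfg)})
    spectra = read_ms1(cfg["mzml"])
    records = read_ids(cfg["ids"], min_probability=cfg["min_probability"])
    peptide_df = quantify_peptides(spectra, records, cfg)
    protein_df = rollup_proteins(peptide_df, cfg)
    if len(records) == 0:
        log.warning("identification table is empty; writing empty results")
    write_results(peptide_df, cfg["out_peptides"])
    write_results(protein_df, cfg["out_proteins"])
    return peptide_df, protein_df
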