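"""Identification and results tables (TSV), configuration loading.

Conventions, printed in every file header comment: retention times in
seconds, m/z in Th, residue positions 1-based, modification strings in the
``position:name`` grammar of :mod:`o18quant.masscalc`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from .masscalc import PeptideIon, parse_modifications

__all__ = [
    "IdentificationRecord",
    "read_ids",
    "write_results",
    "load_config",
    "DEFAULT_CONFIG",
]

log = logging.getLogger("o18quant")

REQUIRED_ID_COLUMNS = ("peptide", "mods", "charge", "rt_s", "protein")

HEADER_COMMENT = (
    "# o18quant table: rt in seconds, m/z in Th, 1-based residue positions, "
    "mods as position:name;...\n"
)


@dataclass(frozen=True)
class IdentificationRecord:
    """One identified peptide from the search-engine export.

    ``subgroup`` tags the lectin fraction the peptide was enriched in
    (ConA / LCH / WGA / none) — an annotation, not a computation.
    ``probability`` is the identification probability used for filtering.
    """

    peptide: str
    mods: str
    charge: int
    rt_s: float
    protein: str
    subgroup: str = "none"
    probability: float | None = None

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError("charge must be >= 1")
        if self.probability is not None and not 0 <= self.probability <= 1:
            raise ValueError("probability must lie in [0, 1]")
        parse_modifications(self.mods)  # grammar check; raises on bad input

    def to_ion(self, glycosites: tuple[int, ...] = ()) -> PeptideIon:
        return PeptideIon(
            self.peptide,
            parse_modifications(self.mods),
            self.charge,
            glycosites,
        )


def read_ids(path: str | Path, min_probability: float = 0.9) -> list[IdentificationRecord]:
    """Read the identification TSV, dropping low-probability rows.

    Required columns: peptide, mods, charge, rt_s, protein; optional:
    subgroup, probability.  Rows whose probability falls below
    ``min_probability`` are dropped (count logged); a missing probability
    column keeps every row.  Malformed modification strings raise with the
    offending line number.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in REQUIRED_ID_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"identification table missing columns: {missing}")
    records: list[IdentificationRecord] = []
    dropped = 0
    for i, row in df.iterrows():
        prob = float(row["probability"]) if "probability" in df.columns else None
        if prob is not None and prob < min_probability:
            dropped += 1
            continue
        try:
            records.append(
                IdentificationRecord(
                    peptide=str(row["peptide"]),
                    mods="" if pd.isna(row["mods"]) else str(row["mods"]),
                    charge=int(row["charge"]),
                    rt_s=float(row["rt_s"]),
                    protein=str(row["protein"]),
                    subgroup=str(row.get("subgroup", "none")),
                    probability=prob,
                )
            )
        except (ValueError, KeyError) as exc:
            raise ValueError(f"row {i + 2} of {path}: {exc}") from exc
    if dropped:
        log.info("dropped %d identifications below probability %.2f", dropped, min_probability)
    return records


def write_ids(records: pd.DataFrame, path: str | Path) -> None:
    """Write an identification table with the convention header."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(HEADER_COMMENT)
        records.to_csv(fh, sep="\t", index=False)


def write_results(df: pd.DataFrame, path: str | Path) -> None:
    """Write a results table (peptide- or protein-level) with header."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(HEADER_COMMENT)
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


DEFAULT_CONFIG: dict = {
    "mzml": None,
    "ids": None,
    "out_peptides": "peptide_ratios.tsv",
    "out_proteins": "protein_ratios.tsv",
    "min_probability": 0.9,
    "tol_ppm": 10.0,
    "rt_window_s": 30.0,
    "purity": 0.97,
    "include_single_label": False,
    "denominator_floor": 0.01,
    "sd_peptide": 0.186,
    "sd_protein": 0.216,
    "allow_multisite": False,
}


def load_config(path: str | Path | None) -> dict:
    """Merge a YAML config file over the documented defaults."""
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        unknown = set(user) - set(cfg)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(user)
    return cfg
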