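"""Published calibration measurements for the tandem-labeling workflow.

These constants are the printed validation data of the original study the
method was developed in: dilution-series ratios of glycopeptides and
non-glycopeptides from ConA-enriched invertase and fetuin standards,
replicate SDs of a 1:1 mixture measured seven times, the significance bounds
derived from them, and the clusterin glycopeptide pair whose spectrum
anchors the mass arithmetic.  They are inputs for validation and worked
examples — nothing in the package computes *from* them except comparisons.
"""

from __future__ import annotations

#: Heavy/light mixing points of the standard dilution design.
DILUTION_EXPECTED = (1.0, 2.0, 5.0, 0.5, 0.2, 0.1, 10.0)

#: Measured ratio series per peptide: (manual calculation, automated method).
#: Glycopeptides are marked by a "*" after the glycosylated Asn.  A None
#: entry is a point the automated method could not quantify.
DILUTION_SERIES: dict[str, dict] = {
    "FATN*TTLTK": {
        "protein": "invertase",
        "glyco": True,
        "manual": (0.961, 1.997, 4.880, 0.563, 0.236, 0.129, 9.989),
        "automated": (0.897, 1.982, 4.856, 0.491, 0.188, 0.104, 9.456),
    },
    "LMTN*ETSDRPLVHFTPNK": {
        "protein": "invertase",
        "glyco": True,
        "manual": (0.992, 2.169, 4.980, 0.567, 0.216, 0.103, 10.110),
        "automated": (0.953, 1.939, 5.033, 0.517, 0.192, 0.089, 10.050),
    },
    "ENPYFTNR": {
        "protein": "invertase",
        "glyco": False,
        "manual": (0.937, 2.040, 5.217, 0.474, 0.177, 0.085, 10.558),
        "automated": (0.997, 2.144, 5.462, 0.539, 0.208, 0.111, 11.160),
    },
    "GLEDPEEYLR": {
        "protein": "invertase",
        "glyco": False,
        "manual": (0.769, 1.714, 5.014, 0.472, 0.184, 0.084, 9.636),
        "automated": (0.837, 1.788, 4.437, 0.458, 0.183, 0.086, 11.110),
    },
    "AESN*GSYLQLVEISR": {
        "protein": "fetuin",
        "glyco": True,
        "manual": (1.138, 1.735, 4.664, 0.562, 0.219, 0.075, 9.849),
        "automated": (0.886, 1.588, 5.070, 0.424, 0.143, 0.036, 12.330),
    },
    "LAPLN*DSR": {
        "protein": "fetuin",
        "glyco": True,
        "manual": (0.980, 1.797, 4.627, 0.397, 0.158, 0.096, 11.289),
        "automated": (0.965, 1.824, 4.174, 0.415, 0.184, 0.103, None),
    },
    "ALGGEDVR": {
        "protein": "fetuin",
        "glyco": False,
        "manual": (0.904, 2.116, 5.748, 0.469, 0.175, 0.088, 12.237),
        "automated": (0.969, 1.913, 4.589, 0.471, 0.170, 0.080, 11.540),
    },
    "TPIVGQPSIPGGPVR": {
        "protein": "fetuin",
        "glyco": False,
        "manual": (1.067, 2.102, 5.823, 0.460, 0.183, 0.063, 10.414),
        "automated": (1.042, 1.986, 5.559, 0.479, 0.163, 0.100, 10.120),
    },
}

#: Replicate SDs of the 1:1 standard mixture (seven repeated analyses).
REPLICATE_SD: dict[str, float] = {
    "invertase glycoprotein": 0.216,
    "FATN*TTLTK": 0.186,
    "NPVLAAN*STQFR": 0.156,
    "fetuin glycoprotein": 0.075,
    "LAPLN*DSR": 0.054,
    "AESN*GSYLQLVEISR": 0.023,
}

#: The level-wide maximum SDs that set the global significance bounds.
MAX_SD_PEPTIDE = 0.186
MAX_SD_PROTEIN = 0.216

#: Published significance bounds (lower-significant, lower-minor-high,
#: upper-minor-low, upper-significant) as printed.
PUBLISHED_BOUNDS = {
    "peptide": (0.63, 0.84, 1.19, 1.57),
    "protein": (0.60, 0.82, 1.22, 1.65),
}

#: The clusterin (CLUS) glycopeptide pair used as the worked spectrum.
CLUSTERIN_PAIR = {
    "sequence": "LANLTQGEDQYYLR",
    "glycosite": 3,
    "charge": 2,
    "mz_light": 842.91333,
    "mz_heavy": 845.91943,
    "observed_ratio_heavy_light": 1.812,
}


def strip_site_marks(peptide: str) -> str:
    """Remove the glycosite asterisks from an annotated sequence."""
    return peptide.replace("*", "")
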