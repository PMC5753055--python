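"""Experimental NMR descriptor tables for the eight pentapeptide systems.

Systems are labelled 1-4 by central residue (1 = Ser, 2 = Thr,
3 = (2S,3R)-CF3-Thr, 4 = (2S,3S)-CF3-Thr) with suffix 'a' for the
Boc-protected and 'b' for the free-amine form.  Positions are Ala1, Val2,
X3 (the variable central residue), Val4, Leu5.

The tables hold the published measurements in CD3OH: Halpha and Calpha
chemical shift deviations (ppm, 298 K), 3J(HN-HA) couplings (Hz),
3J(HA-HB) couplings (Hz; slash-separated when two couplings were resolved),
amide temperature coefficients (ppb/K), and the MD-derived beta-basin
probabilities (%) of the three central residues together with the global
extension probability P.  ``None`` marks a value that was not measured or
has no defined reference; ``"broad"`` marks an unresolvably broad peak.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "SYSTEMS",
    "POSITIONS",
    "position_codes",
    "halpha_csd_table",
    "calpha_csd_table",
    "j_hn_ha_table",
    "j_ha_hb_table",
    "temp_coefficient_table",
    "beta_probability_table",
]

SYSTEMS = ("1a", "2a", "3a", "4a", "1b", "2b", "3b", "4b")
POSITIONS = ("Ala1", "Val2", "X3", "Val4", "Leu5")

_CENTRAL = {"1": "SER", "2": "THR", "3": "TFR", "4": "TFS"}


def position_codes(system: str) -> dict[str, str]:
    """Map table column -> residue type code for one system label."""
    return {
        "Ala1": "ALA",
        "Val2": "VAL",
        "X3": _CENTRAL[system[0]],
        "Val4": "VAL",
        "Leu5": "LEU",
    }


# Halpha chemical shift deviations, ppm (298 K).  X3 has no coil reference
# for the fluorinated systems 3/4.
_HA_CSD = {
    "1a": (-0.23, 0.09, 0.01, 0.15, 0.09),
    "2a": (-0.20, 0.13, 0.04, 0.13, 0.11),
    "3a": (-0.22, 0.09, None, 0.17, 0.07),
    "4a": (-0.19, 0.13, None, 0.15, 0.09),
    "1b": (-0.35, 0.14, 0.04, 0.15, 0.08),
    "2b": (-0.41, 0.14, 0.05, 0.12, 0.07),
    "3b": (-0.33, 0.14, None, 0.18, 0.07),
    "4b": (-0.35, 0.22, None, 0.17, 0.08),
}

# Calpha chemical shift deviations, ppm (298 K).
_CA_CSD = {
    "1a": (-0.6, -2.0, -1.6, -2.1, -2.8),
    "2a": (-0.9, -2.0, -1.8, -2.2, -2.9),
    "3a": (-0.8, -2.5, None, -2.4, -2.7),
    "4a": (-0.8, -1.6, None, -1.9, -2.9),
    "1b": (-2.1, -1.7, -1.8, -2.2, -2.8),
    "2b": (-2.1, -1.6, -1.9, -2.3, -2.9),
    "3b": (-2.2, -2.0, None, -2.4, -2.7),
    "4b": (-2.1, -2.0, None, -2.4, -2.8),
}

# 3J(HN-HA) couplings, Hz.  Free-amine Ala1 amides were not observable;
# the Val2 peak of 2b was too broad to resolve.
_J_HN_HA = {
    "1a": (6.8, 8.2, 7.5, 8.9, 7.8),
    "2a": (6.9, 8.3, 8.4, 8.8, 7.8),
    "3a": (7.1, 8.9, 9.1, 9.2, 7.6),
    "4a": (6.8, 7.7, 8.6, 9.0, 7.7),
    "1b": (None, 8.3, 7.6, 8.6, 7.6),
    "2b": (None, "broad", 8.4, 8.7, 7.7),
    "3b": (None, 8.7, 9.0, 8.2, 7.4),
    "4b": (None, 8.9, 9.0, 8.9, 7.6),
}

# 3J(HA-HB) couplings, Hz; "x/y" when both beta protons were resolved.
_J_HA_HB = {
    "1a": (7.1, 6.7, "6/6", 6.6, "5.1/10.6"),
    "2a": (7.2, 7.3, 4.9, 6.9, "5.0/10.6"),
    "3a": (7.3, 7.1, 6.4, 6.5, "6/10"),
    "4a": (7.0, 7.0, 2.5, 7.1, "5.0/10.5"),
    "1b": (7.2, 6.6, "7.5/7.5", 6.6, "5.3/10.3"),
    "2b": (7.2, 7.1, 4.6, 7.1, "5.6/10.0"),
    "3b": (7.3, 7.3, 6.7, 7.0, "5.3/10.3"),
    "4b": (7.2, 8.2, 2.0, 7.5, "5.4/10.5"),
}

# Amide temperature coefficients, ppb/K.
_TEMP_COEFF = {
    "1a": (-7.8, -6.4, -7.7, -8.0, -7.4),
    "2a": (-7.4, -5.8, -7.5, -7.6, -7.9),
    "3a": (-6.5, -5.3, -7.4, -7.4, -5.0),
    "4a": (-7.4, -5.9, -8.9, -4.5, -9.0),
    "1b": (None, -6.1, -7.8, -7.8, -7.0),
    "2b": (None, -5.5, -8.1, -8.0, -7.7),
    "3b": (None, -6.6, -8.5, -9.0, -6.0),
    "4b": (None, -5.5, -8.3, -4.6, -7.9),
}

# Beta-basin probabilities (%) of the three central residues from the MD
# ensembles, and the global extension probability P (%).
_BETA_PROB = {
    "1a": (59.9, 51.4, 55.8, 17.2),
    "2a": (53.5, 91.1, 61.0, 29.7),
    "3a": (59.7, 31.7, 69.9, 13.2),
    "4a": (67.1, 82.7, 75.6, 42.0),
    "1b": (76.5, 50.3, 64.9, 25.0),
    "2b": (64.8, 73.5, 59.1, 28.2),
    "3b": (63.3, 59.4, 74.7, 28.1),
    "4b": (77.9, 85.6, 74.8, 49.9),
}


def _to_frame(data: dict, columns) -> pd.DataFrame:
    df = pd.DataFrame.from_dict(data, orient="index", columns=list(columns))
    df.index.name = "peptide"
    return df


def halpha_csd_table() -> pd.DataFrame:
    """Halpha CSDs (ppm) per system and position."""
    return _to_frame(_HA_CSD, POSITIONS)


def calpha_csd_table() -> pd.DataFrame:
    """Calpha CSDs (ppm) per system and position."""
    return _to_frame(_CA_CSD, POSITIONS)


def j_hn_ha_table() -> pd.DataFrame:
    """3J(HN-HA) couplings (Hz) with None / 'broad' markers."""
    return _to_frame(_J_HN_HA, POSITIONS)


def j_ha_hb_table() -> pd.DataFrame:
    """3J(HA-HB) couplings (Hz), slash-separated where two were resolved."""
    return _to_frame(_J_HA_HB, POSITIONS)


def temp_coefficient_table() -> pd.DataFrame:
    """Amide temperature coefficients (ppb/K)."""
    return _to_frame(_TEMP_COEFF, POSITIONS)


def beta_probability_table() -> pd.DataFrame:
    """Central-residue beta probabilities and global P, percent."""
    return _to_frame(_BETA_PROB, ("Val2", "X3", "Val4", "P"))
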