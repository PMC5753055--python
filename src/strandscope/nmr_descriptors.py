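"""Experimental-NMR interpretation rules for backbone conformation.

Four descriptor families are implemented:

* **Chemical shift deviations (CSD)** — observed shift minus the residue's
  random-coil reference.  Positive Halpha / negative Calpha CSDs mark
  extended (beta) propensity.  Terminal residues are excluded (no flanking
  residue on one side biases their shifts) and so are residues without a
  tabulated random-coil value, e.g. the CF3-threonines.

* **Amide temperature coefficients** — least-squares slope of the HN shift
  versus temperature, in ppb/K.  Slopes above -4.5 ppb/K suggest an
  intramolecularly hydrogen-bonded (protected) amide, slopes below -6 ppb/K
  a solvent-exposed one; the band between is ambiguous.  Exact boundary
  values classify as intermediate.

* **chi1 rotamer calls** — 3J(HA-HB) below 5 Hz indicates a dominant gauche
  HA/HB relationship, above 10 Hz a dominant anti arrangement; mid-range
  values reflect rotamer averaging.

* **i/i+2 periodicity scan** — flags residues whose temperature coefficient
  is markedly less negative than both sequence neighbours', the pattern
  expected from transient intermolecular beta-strand contacts alternating
  along the chain.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RandomCoilReference",
    "DEFAULT_RANDOM_COIL",
    "coil_reference_from_yaml",
    "TempCoefficient",
    "compute_csd",
    "summarize_csd",
    "temp_coefficient",
    "classify_hbond",
    "classify_chi1",
    "periodicity_scan",
]

EXCLUDED_TERMINAL = "terminal"
EXCLUDED_NO_REFERENCE = "no-reference"


@dataclass(frozen=True)
class RandomCoilReference:
    """Random-coil chemical shifts: (residue code, nucleus) -> ppm."""

    values: Mapping[tuple[str, str], float]
    name: str = "standard-coil-table"

    def get(self, code: str, nucleus: str):
        return self.values.get((code, nucleus))


#: Standard random-coil shifts (ppm) for the natural residues occurring in
#: the pentapeptides.  The CF3-threonine stereoisomers (TFR/TFS) have no
#: published coil values and are deliberately absent.
DEFAULT_RANDOM_COIL = RandomCoilReference(
    {
        ("ALA", "HA"): 4.32,
        ("VAL", "HA"): 4.12,
        ("LEU", "HA"): 4.34,
        ("SER", "HA"): 4.47,
        ("THR", "HA"): 4.35,
        ("ALA", "CA"): 52.5,
        ("VAL", "CA"): 62.2,
        ("LEU", "CA"): 55.1,
        ("SER", "CA"): 58.3,
        ("THR", "CA"): 61.8,
    },
    name="wishart-style-coil-shifts",
)


def coil_reference_from_yaml(path=None) -> RandomCoilReference:
    """Load a random-coil reference set from YAML (default: packaged config)."""
    import yaml

    if path is None:
        from importlib.resources import files

        text = (files("strandscope") / "config" / "random_coil.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    data = yaml.safe_load(text)
    values = {
        (code, nucleus): float(ppm)
        for code, by_nucleus in data["shifts"].items()
        for nucleus, ppm in by_nucleus.items()
    }
    return RandomCoilReference(values, name=data.get("name", "custom"))


def compute_csd(
    shifts: pd.DataFrame,
    coil: RandomCoilReference = DEFAULT_RANDOM_COIL,
    temperature_K: float = 298.0,
) -> pd.DataFrame:
    """Chemical shift deviations with explicit exclusion bookkeeping.

    ``shifts`` is long-format with columns peptide, residue_index,
    residue_code, nucleus, temperature_K, shift_ppm.  Only rows at the
    reporting temperature are used.  Output columns: peptide, residue_index,
    residue_code, nucleus, shift_ppm, coil_ppm, csd_ppm, excluded
    (empty / ``terminal`` / ``no-reference``); excluded rows keep NaN CSD.
    """
    required = {"peptide", "residue_index", "residue_code", "nucleus", "temperature_K", "shift_ppm"}
    missing = required - set(shifts.columns)
    if missing:
        raise ValueError(f"shift table missing columns: {sorted(missing)}")
    at_t = shifts[np.isclose(shifts["temperature_K"], temperature_K)].copy()
    if at_t.empty:
        raise ValueError(f"no shifts at the reporting temperature {temperature_K} K")
    rows = []
    for peptide, grp in at_t.groupby("peptide", sort=False):
        first = grp["residue_index"].min()
        last = grp["residue_index"].max()
        for _, r in grp.iterrows():
            coil_val = coil.get(r["residue_code"], r["nucleus"])
            excluded = ""
            if r["residue_index"] in (first, last):
                excluded = EXCLUDED_TERMINAL
            elif coil_val is None:
                excluded = EXCLUDED_NO_REFERENCE
            csd = np.nan if excluded or coil_val is None else r["shift_ppm"] - coil_val
            rows.append(
                {
                    "peptide": peptide,
                    "residue_index": r["residue_index"],
                    "residue_code": r["residue_code"],
                    "nucleus": r["nucleus"],
                    "shift_ppm": r["shift_ppm"],
                    "coil_ppm": np.nan if coil_val is None else coil_val,
                    "csd_ppm": csd,
                    "excluded": excluded,
                }
            )
    return pd.DataFrame(rows)


def summarize_csd(csd_values: Sequence[float]) -> tuple[float, float, bool]:
    """(min, max, sign-consistency) over a set of included CSD values.

    NaNs (excluded entries) are dropped first; an empty remainder is an
    error.  The flag is True when every value shares one strict sign.
    """
    arr = np.asarray([v for v in csd_values if np.isfinite(v)], dtype=float)
    if arr.size == 0:
        raise ValueError("no included CSD values to summarise")
    consistent = bool(np.all(arr > 0) or np.all(arr < 0))
    return float(arr.min()), float(arr.max()), consistent


@dataclass(frozen=True)
class TempCoefficient:
    """Slope of the amide-proton shift with temperature, ppb/K."""

    slope_ppb_per_K: float
    n_points: int
    residual_ppm: float  # RMS residual of the linear fit


def temp_coefficient(temperatures_K, shifts_ppm) -> TempCoefficient:
    """Ordinary least-squares slope of shift (ppm) vs temperature (K), x1000.

    Requires at least two distinct temperatures.
    """
    t = np.asarray(temperatures_K, dtype=float)
    d = np.asarray(shifts_ppm, dtype=float)
    if t.shape != d.shape or t.ndim != 1:
        raise ValueError("temperatures and shifts must be 1-D arrays of equal length")
    if np.unique(t).size < 2:
        raise ValueError("need at least 2 distinct temperatures for a slope")
    slope, intercept = np.polyfit(t, d, 1)
    resid = d - (slope * t + intercept)
    return TempCoefficient(
        slope_ppb_per_K=float(slope * 1000.0),
        n_points=t.size,
        residual_ppm=float(np.sqrt(np.mean(resid**2))),
    )


def classify_hbond(coefficient: TempCoefficient | float) -> str:
    """Hydrogen-bond class from the temperature coefficient.

    Slopes above -4.5 ppb/K -> ``hbonded-candidate``; below -6 ppb/K ->
    ``exposed``; anything else (including exactly -4.5 or -6.0, since the
    thresholds are strict inequalities) -> ``intermediate``.
    """
    slope = (
        coefficient.slope_ppb_per_K
        if isinstance(coefficient, TempCoefficient)
        else float(coefficient)
    )
    if not np.isfinite(slope):
        raise ValueError("slope must be finite")
    if slope > -4.5:
        return "hbonded-candidate"
    if slope < -6.0:
        return "exposed"
    return "intermediate"


def classify_chi1(j_hz: float, gauche_max: float = 5.0, anti_min: float = 10.0) -> str:
    """chi1 rotamer class from 3J(HA-HB): gauche-dominated / mixed / anti-dominated."""
    if j_hz <= 0:
        raise ValueError("coupling constant must be positive")
    if j_hz < gauche_max:
        return "gauche-dominated"
    if j_hz > anti_min:
        return "anti-dominated"
    return "mixed"


def periodicity_scan(
    coefficients: Mapping[int, float], margin: float = 1.0
) -> list[int]:
    """Residues whose temperature coefficient stands out above both neighbours.

    ``coefficients`` maps residue index -> slope (ppb/K); a residue is
    flagged when its slope exceeds (is less negative than) both sequence
    neighbours' slopes by more than ``margin``.  Residues lacking a finite
    neighbour on either side are never flagged.  An alternating i/i+2
    pattern of flags is the signature of transient intermolecular
    beta-strand contacts.
    """
    if len(coefficients) < 3:
        raise ValueError("need coefficients for at least 3 residues")
    flagged = []
    for i, v in coefficients.items():
        left = coefficients.get(i - 1)
        right = coefficients.get(i + 1)
        if left is None or right is None:
            continue
        if not (np.isfinite(v) and np.isfinite(left) and np.isfinite(right)):
            continue
        if v > left + margin and v > right + margin:
            flagged.append(i)
    return sorted(flagged)
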