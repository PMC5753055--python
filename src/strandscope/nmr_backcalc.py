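"""Karplus back-calculation of 3J(HN-HA) couplings and coil-library comparison.

The three-bond amide-to-alpha proton coupling reports on the backbone phi
angle through a Karplus curve J(phi) = A cos^2(theta) + B cos(theta) + C with
theta = phi + phase.  For an ensemble the observable is the arithmetic mean
of J over frames (couplings average linearly under fast conformational
exchange), never J evaluated at the mean phi.

Observed couplings are judged against mean coil-library values; couplings
above the coil mean lean extended, since extended phi (around -120 deg) sits
near the Karplus maximum.  Coil means are only published for a subset of
residue types; residues without a coil value are reported "not comparable"
rather than silently compared.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .synthetic_ensemble import DihedralEnsemble

__all__ = [
    "KarplusParameters",
    "DEFAULT_KARPLUS",
    "karplus_from_yaml",
    "CoilLibrary",
    "DEFAULT_COIL",
    "JTable",
    "karplus_j",
    "ensemble_mean_j",
    "compare_to_coil",
]


@dataclass(frozen=True)
class KarplusParameters:
    """Coefficients (Hz) and phase (degrees) of one Karplus parameterisation."""

    A: float = 6.51
    B: float = -1.76
    C: float = 1.60
    phase: float = -60.0
    name: str = "vuister-bax-1993"

    def __post_init__(self) -> None:
        for v in (self.A, self.B, self.C, self.phase):
            if not np.isfinite(v):
                raise ValueError("Karplus parameters must be finite")


#: Standard HN-HA parameterisation (A=6.51, B=-1.76, C=1.60, theta=phi-60).
DEFAULT_KARPLUS = KarplusParameters()


def karplus_from_yaml(path=None, name: str | None = None) -> KarplusParameters:
    """Load a Karplus parameter set from a YAML config.

    Without ``path`` the packaged ``config/karplus.yaml`` is used; ``name``
    selects among its sets (default: the file's ``default`` entry).
    """
    import yaml

    if path is None:
        from importlib.resources import files

        text = (files("strandscope") / "config" / "karplus.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    data = yaml.safe_load(text)
    name = name or data["default"]
    if name not in data["sets"]:
        raise KeyError(f"no Karplus set named {name!r}; have {sorted(data['sets'])}")
    return KarplusParameters(name=name, **data["sets"][name])


@dataclass(frozen=True)
class CoilLibrary:
    """Mean coil-library 3J(HN-HA) per residue code, Hz."""

    values: Mapping[str, float]
    name: str = "coil-library-means"

    def __contains__(self, code: str) -> bool:
        return code in self.values

    def __getitem__(self, code: str) -> float:
        return self.values[code]


#: Published mean coil couplings for the residue types present in the
#: pentapeptides: Ala 6.1, Leu 7.0, Val 7.5 Hz.  Ser, Thr and the CF3-Thr
#: stereoisomers have no tabulated coil mean and are never compared.
DEFAULT_COIL = CoilLibrary({"ALA": 6.1, "LEU": 7.0, "VAL": 7.5})

#: Markers used in coupling tables: missing (not measured) and broad
#: (peak too broad to resolve).  Both are excluded from comparisons.
MISSING = ""
BROAD = "broad"


def karplus_j(phi, params: KarplusParameters = DEFAULT_KARPLUS):
    """Evaluate J(phi) = A cos^2(theta) + B cos(theta) + C, theta = phi + phase.

    ``phi`` in degrees, scalar or array; returns Hz with the same shape.
    """
    theta = np.radians(np.asarray(phi, dtype=float) + params.phase)
    c = np.cos(theta)
    out = params.A * c * c + params.B * c + params.C
    return float(out) if out.ndim == 0 else out


def ensemble_mean_j(
    ensemble: DihedralEnsemble,
    residue_index: int,
    params: KarplusParameters = DEFAULT_KARPLUS,
) -> float:
    """Ensemble-averaged 3J(HN-HA) of one residue: mean over frames of J(phi)."""
    if ensemble.n_frames == 0:
        raise ValueError("ensemble has no frames")
    if not 1 <= residue_index <= ensemble.n_residues:
        raise IndexError(
            f"residue_index {residue_index} outside 1..{ensemble.n_residues}"
        )
    phi = ensemble.phi[:, residue_index - 1]
    return float(np.mean(karplus_j(phi, params)))


class JTable:
    """Observed couplings: peptide label x residue position, Hz or markers.

    Backed by a DataFrame with index = peptide labels and one column per
    residue position; cells hold floats, ``""`` (not measured) or
    ``"broad"`` (unresolvable multiplet).
    """

    def __init__(self, data: pd.DataFrame, residue_codes: Mapping[str, str]):
        #: residue_codes maps column name -> residue type code (e.g. "Val2" -> "VAL")
        self.data = data
        self.residue_codes = dict(residue_codes)
        missing_cols = set(self.residue_codes) - set(data.columns)
        if missing_cols:
            raise ValueError(f"residue_codes name absent columns: {sorted(missing_cols)}")

    @classmethod
    def from_csv(cls, path, residue_codes: Mapping[str, str]) -> "JTable":
        df = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
        return cls(df, residue_codes)

    def value(self, peptide: str, column: str):
        """Float coupling, or the marker string for missing/broad entries."""
        raw = self.data.loc[peptide, column]
        if isinstance(raw, str):
            raw = raw.strip()
            if raw in (MISSING, "-", "–"):
                return MISSING
            if raw.lower().startswith("broad"):
                return BROAD
            return float(raw)
        if raw is None or (isinstance(raw, float) and np.isnan(raw)):
            return MISSING
        return float(raw)


def compare_to_coil(
    jtable: JTable, coil: CoilLibrary = DEFAULT_COIL
) -> pd.DataFrame:
    """Delta to the coil mean for every entry with a comparable residue type.

    Returns a long-format DataFrame with columns peptide, column,
    residue_code, j_obs, j_coil, delta, extended_flag, status.  Status is
    one of ``compared`` / ``no-coil-reference`` / ``missing`` / ``broad``;
    only ``compared`` rows carry delta = j_obs - j_coil and the
    extended-leaning flag (delta > 0).
    """
    rows = []
    for peptide in jtable.data.index:
        for column, code in jtable.residue_codes.items():
            v = jtable.value(peptide, column)
            row = {
                "peptide": peptide,
                "column": column,
                "residue_code": code,
                "j_obs": np.nan,
                "j_coil": np.nan,
                "delta": np.nan,
                "extended_flag": False,
                "status": "",
            }
            if v == MISSING:
                row["status"] = "missing"
            elif v == BROAD:
                row["status"] = "broad"
            elif code not in coil:
                row["j_obs"] = v
                row["status"] = "no-coil-reference"
            else:
                row.update(
                    j_obs=v,
                    j_coil=coil[code],
                    delta=v - coil[code],
                    extended_flag=v - coil[code] > 0,
                    status="compared",
                )
            rows.append(row)
    return pd.DataFrame(rows)
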