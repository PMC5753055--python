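"""Beta-strand propensity statistics from dihedral and coordinate ensembles.

A residue is counted in the alpha basin when psi falls in [-70, +40] degrees
and in the beta (extended) basin when psi falls in [90, 180]; both windows
are closed, so a psi exactly on a boundary counts inward.  The global
extension probability P of a pentapeptide is the product of the
beta-basin probabilities of its three central residues; the peptide's overall
reach is summarised by the end-to-end distance from the backbone nitrogen of
residue 1 to the C-terminal ester carbonyl carbon.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .synthetic_ensemble import DihedralEnsemble, Ensemble3D

__all__ = [
    "BasinWindow",
    "ALPHA_WINDOW",
    "BETA_WINDOW",
    "PsiHistogram",
    "EndToEndResult",
    "psi_histogram",
    "basin_probability",
    "global_extension_probability",
    "end_to_end_distances",
    "propensity_report",
]


@dataclass(frozen=True)
class BasinWindow:
    """Closed psi window [lo, hi] in degrees labelling one Ramachandran basin."""

    label: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if self.lo >= self.hi:
            raise ValueError(f"window requires lo < hi, got [{self.lo}, {self.hi}]")

    def contains(self, psi: np.ndarray) -> np.ndarray:
        psi = np.asarray(psi)
        return (psi >= self.lo) & (psi <= self.hi)


ALPHA_WINDOW = BasinWindow("alpha", -70.0, 40.0)
BETA_WINDOW = BasinWindow("beta", 90.0, 180.0)


@dataclass
class PsiHistogram:
    residue_index: int
    bin_edges: np.ndarray  # degrees, spanning (-180, 180]
    counts: np.ndarray
    n_total: int

    def __post_init__(self) -> None:
        if self.counts.sum() != self.n_total:
            raise ValueError("histogram counts do not sum to n_total")

    @property
    def density(self) -> np.ndarray:
        """Probability density per degree (integrates to 1 over the circle)."""
        widths = np.diff(self.bin_edges)
        return self.counts / (self.n_total * widths)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_lo": self.bin_edges[:-1],
                "bin_hi": self.bin_edges[1:],
                "count": self.counts,
                "density": self.density,
            }
        )


def _psi_column(ensemble: DihedralEnsemble, residue_index: int) -> np.ndarray:
    if not 1 <= residue_index <= ensemble.n_residues:
        raise IndexError(
            f"residue_index {residue_index} outside 1..{ensemble.n_residues}"
        )
    return ensemble.psi[:, residue_index - 1]


def psi_histogram(
    ensemble: DihedralEnsemble, residue_index: int, bin_width: float = 5.0
) -> PsiHistogram:
    """Histogram of psi for one residue on a grid partitioning (-180, 180].

    ``bin_width`` must divide 360 exactly so that the bins tile the circle.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    n_bins = round(360.0 / bin_width)
    if not math.isclose(n_bins * bin_width, 360.0, rel_tol=1e-12):
        raise ValueError(f"bin_width {bin_width} does not divide 360 degrees")
    psi = _psi_column(ensemble, residue_index)
    edges = np.linspace(-180.0, 180.0, n_bins + 1)
    # psi lies in (-180, 180]; np.histogram's closed last edge matches.
    counts, _ = np.histogram(psi, bins=edges)
    return PsiHistogram(
        residue_index=residue_index,
        bin_edges=edges,
        counts=counts,
        n_total=psi.size,
    )


def basin_probability(
    ensemble: DihedralEnsemble, residue_index: int, window: BasinWindow = BETA_WINDOW
) -> float:
    """Fraction of frames whose psi lies inside the (closed) basin window."""
    psi = _psi_column(ensemble, residue_index)
    return float(window.contains(psi).mean())


def global_extension_probability(p_list: Iterable[float]) -> float:
    """Product of per-residue beta probabilities: P(all residues extended).

    Treats the residues as independent, which is exact when the ensemble
    factorises over residues (as the basin-mixture generator does).
    """
    p_list = list(p_list)
    if not p_list:
        raise ValueError("need at least one probability")
    for p in p_list:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"probability {p} outside [0, 1]")
    return float(np.prod(p_list))


@dataclass
class EndToEndResult:
    """Per-model N(1)..C(ester) distances plus a unit-mass histogram."""

    distances: np.ndarray  # Angstrom
    bin_edges: np.ndarray
    probability: np.ndarray  # sums to 1
    atom_pair: tuple[str, str] = ("N of residue 1", "C-terminal carbonyl C")

    @property
    def mean(self) -> float:
        return float(self.distances.mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_lo": self.bin_edges[:-1],
                "bin_hi": self.bin_edges[1:],
                "probability": self.probability,
            }
        )


def end_to_end_distances(ensemble: Ensemble3D, bin_width: float = 0.5) -> EndToEndResult:
    """End-to-end distance: N-terminal backbone N to C-terminal carbonyl C.

    The C-terminal carbonyl is the ester carbonyl carbon (atom C of the last
    residue).  Distances are Euclidean per model, in Angstrom.
    """
    last = int(np.max(ensemble.res_ids))
    try:
        i_n = ensemble.atom_index("N", 1)
    except KeyError as exc:
        raise KeyError("backbone N of residue 1 missing from ensemble") from exc
    try:
        i_c = ensemble.atom_index("C", last)
    except KeyError as exc:
        raise KeyError(f"carbonyl C of residue {last} missing from ensemble") from exc
    d = np.linalg.norm(ensemble.coords[:, i_c] - ensemble.coords[:, i_n], axis=1)
    lo = np.floor(d.min() / bin_width) * bin_width
    hi = np.ceil(d.max() / bin_width) * bin_width
    hi = max(hi, lo + bin_width)
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    counts, _ = np.histogram(d, bins=edges)
    return EndToEndResult(
        distances=d,
        bin_edges=edges,
        probability=counts / counts.sum(),
    )


def propensity_report(
    ensembles: Mapping[str, DihedralEnsemble],
    residues: Sequence[int] = (2, 3, 4),
    window: BasinWindow = BETA_WINDOW,
) -> pd.DataFrame:
    """Per-peptide beta probabilities of the selected residues and their product.

    Returns one row per peptide label with columns ``p_res<i>`` (fractions),
    ``P`` (the product) and percentage renderings rounded to one decimal,
    mirroring how such tables are conventionally reported.
    """
    rows = []
    for label, ens in ensembles.items():
        p = [basin_probability(ens, r, window) for r in residues]
        P = global_extension_probability(p)
        row: dict[str, object] = {"peptide": label}
        for r, pr in zip(residues, p):
            row[f"p_res{r}"] = pr
        row["P"] = P
        for r, pr in zip(residues, p):
            row[f"pct_res{r}"] = round(100.0 * pr, 1)
        row["pct_P"] = round(100.0 * P, 1)
        rows.append(row)
    return pd.DataFrame(rows)
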