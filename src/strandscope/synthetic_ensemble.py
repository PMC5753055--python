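"""Synthetic backbone ensembles with controlled alpha/beta basin statistics.

The systems of interest are pentapeptides R-Ala-Val-X-Val-Leu-OMe where X is
Ser, Thr, (2S,3R)-CF3-Thr or (2S,3S)-CF3-Thr, studied both Boc-protected and
as free amines.  Instead of running molecular dynamics, each residue's psi
dihedral is drawn from a two-component wrapped-Gaussian mixture over the
alpha-helical basin (centre -30 deg) and the beta/extended basin (centre
+140 deg), with a per-residue mixing weight ``beta_weight`` that directly
controls the beta-strand propensity.  phi is drawn from a single Gaussian in
the extended range, omega is trans, and chi1 defaults to the gauche+ rotamer
(+60 deg).

3D coordinates are built from the dihedrals by sequential chain extension
with idealised bond lengths and angles, including the atoms needed for all
backbone torsions: a two-atom N-terminal reference cap (the carbamate O-C=O
carbon for Boc peptides; a virtual reference frame for free amines, so that
phi/omega of residue 1 stay well defined) and the C-terminal methyl ester
(ester oxygen OS and methyl carbon CM), which supplies the "following
carbonyl" that defines psi of the last residue.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._geometry import dihedral, nerf_place, wrap_angle

__all__ = [
    "RESIDUE_ALPHABET",
    "PeptideSpec",
    "ResidueBasin",
    "BasinModel",
    "DihedralEnsemble",
    "BackboneGeometry",
    "Ensemble3D",
    "PDBFormatError",
    "sample_dihedrals",
    "mixture_window_mass",
    "build_coordinates",
    "measure_dihedrals",
    "write_ensemble",
    "read_ensemble",
]

#: Residue codes understood by the package.  TFR = (2S,3R)-CF3-threonine,
#: TFS = (2S,3S)-CF3-threonine (the stereoisomer mimicking natural Thr).
RESIDUE_ALPHABET = frozenset({"ALA", "VAL", "LEU", "SER", "THR", "TFR", "TFS"})

_CENTRAL_CODES = {"1": "SER", "2": "THR", "3": "TFR", "4": "TFS"}


@dataclass(frozen=True)
class PeptideSpec:
    """Sequence plus terminal chemistry of one peptide system."""

    sequence: tuple[str, ...]
    n_terminus: str = "boc"
    c_terminus: str = "methyl-ester"
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", tuple(self.sequence))
        if len(self.sequence) < 2:
            raise ValueError("sequence must contain at least 2 residues")
        unknown = [r for r in self.sequence if r not in RESIDUE_ALPHABET]
        if unknown:
            raise ValueError(f"unknown residue code(s): {unknown}")
        if self.n_terminus not in ("boc", "free-amine"):
            raise ValueError(f"n_terminus must be 'boc' or 'free-amine', got {self.n_terminus!r}")
        if self.c_terminus != "methyl-ester":
            raise ValueError(f"unsupported c_terminus {self.c_terminus!r}")

    def __len__(self) -> int:
        return len(self.sequence)

    @classmethod
    def pentapeptide(cls, system: str) -> "PeptideSpec":
        """Build one of the eight study systems from its label, e.g. '4a'.

        '1'..'4' select the central residue Ser / Thr / (2S,3R)-CF3-Thr /
        (2S,3S)-CF3-Thr; suffix 'a' means Boc-protected, 'b' free amine.
        """
        if len(system) != 2 or system[0] not in _CENTRAL_CODES or system[1] not in "ab":
            raise ValueError(f"unknown system label {system!r} (expected e.g. '1a', '4b')")
        central = _CENTRAL_CODES[system[0]]
        nterm = "boc" if system[1] == "a" else "free-amine"
        return cls(("ALA", "VAL", central, "VAL", "LEU"), n_terminus=nterm, label=system)


@dataclass(frozen=True)
class ResidueBasin:
    """Two-basin psi model plus phi/chi1 Gaussians for a single residue.

    ``beta_weight`` is the mixing proportion of the beta component; the psi
    density is ``w * N_wrap(beta_center, beta_sd) + (1-w) * N_wrap(alpha_center,
    alpha_sd)``.  Default centres are -30 deg (alpha) and +140 deg (beta);
    phi defaults to a Gaussian centred in the extended range (-160 to -110).
    """

    beta_weight: float = 0.5
    alpha_center: float = -30.0
    beta_center: float = 140.0
    alpha_sd: float = 15.0
    beta_sd: float = 15.0
    phi_center: float = -135.0
    phi_sd: float = 15.0
    chi1_center: float = 60.0
    chi1_sd: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.beta_weight <= 1.0:
            raise ValueError(f"beta_weight must lie in [0, 1], got {self.beta_weight}")
        if self.alpha_sd <= 0 or self.beta_sd <= 0 or self.phi_sd <= 0:
            raise ValueError("basin standard deviations must be positive")
        if self.chi1_sd < 0:
            raise ValueError("chi1_sd must be non-negative")


@dataclass(frozen=True)
class BasinModel:
    """Per-residue basin specification for a whole peptide."""

    residues: tuple[ResidueBasin, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", tuple(self.residues))

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, i: int) -> ResidueBasin:
        return self.residues[i]

    @classmethod
    def uniform(cls, n_residues: int, **kwargs) -> "BasinModel":
        """Same basin parameters at every residue."""
        return cls(tuple(ResidueBasin(**kwargs) for _ in range(n_residues)))

    @classmethod
    def from_beta_weights(cls, weights, **kwargs) -> "BasinModel":
        """One residue per weight; remaining parameters shared."""
        return cls(tuple(ResidueBasin(beta_weight=float(w), **kwargs) for w in weights))

    def validate_for(self, spec: PeptideSpec) -> None:
        if len(self) != len(spec):
            raise ValueError(
                f"basin model has {len(self)} residues but peptide has {len(spec)}"
            )
        for i, r in enumerate(self.residues):
            if not 0.0 <= r.beta_weight <= 1.0:  # re-check: dataclass may be replaced
                raise ValueError(
                    f"invalid beta_weight {r.beta_weight} at residue {i + 1} "
                    f"({spec.sequence[i]})"
                )


@dataclass
class DihedralEnsemble:
    """Per-frame backbone dihedrals, degrees wrapped to (-180, +180].

    Angle arrays have shape ``(n_frames, n_residues)``.  ``chi1`` may contain
    NaN where the side-chain torsion is not represented (e.g. ensembles
    re-measured from backbone-only coordinates).
    """

    spec: PeptideSpec
    phi: np.ndarray
    psi: np.ndarray
    omega: np.ndarray
    chi1: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        shapes = {a.shape for a in (self.phi, self.psi, self.omega, self.chi1)}
        if len(shapes) != 1:
            raise ValueError("phi/psi/omega/chi1 must share one shape")
        (shape,) = shapes
        if len(shape) != 2 or shape[1] != len(self.spec):
            raise ValueError(
                f"angle arrays must be (n_frames, {len(self.spec)}), got {shape}"
            )
        for name in ("phi", "psi", "omega"):
            arr = getattr(self, name)
            if not np.all((arr > -180.0) & (arr <= 180.0)):
                raise ValueError(f"{name} contains values outside (-180, +180]")

    @property
    def n_frames(self) -> int:
        return self.phi.shape[0]

    @property
    def n_residues(self) -> int:
        return self.phi.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: frame, residue_index, residue_code, phi..chi1."""
        n, m = self.phi.shape
        frames = np.repeat(np.arange(n), m)
        res_idx = np.tile(np.arange(1, m + 1), n)
        codes = np.tile(np.asarray(self.spec.sequence), n)
        return pd.DataFrame(
            {
                "frame": frames,
                "residue_index": res_idx,
                "residue_code": codes,
                "phi": self.phi.ravel(),
                "psi": self.psi.ravel(),
                "omega": self.omega.ravel(),
                "chi1": self.chi1.ravel(),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, spec: PeptideSpec | None = None) -> "DihedralEnsemble":
        df = pd.read_csv(path)
        required = {"frame", "residue_index", "residue_code", "phi", "psi", "omega", "chi1"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"dihedral CSV missing columns: {sorted(missing)}")
        df = df.sort_values(["frame", "residue_index"])
        m = df["residue_index"].max()
        codes = tuple(df[df["frame"] == df["frame"].iloc[0]]["residue_code"])
        if spec is None:
            spec = PeptideSpec(codes, n_terminus="free-amine")
        angles = {
            name: df[name].to_numpy(dtype=float).reshape(-1, m)
            for name in ("phi", "psi", "omega", "chi1")
        }
        return cls(spec=spec, **angles)


def sample_dihedrals(
    spec: PeptideSpec, model: BasinModel, n_frames: int, seed: int
) -> DihedralEnsemble:
    """Draw a dihedral ensemble from the basin-mixture model.

    Per residue: a Bernoulli(beta_weight) draw selects the basin, psi is a
    wrapped-Gaussian draw from that basin, phi a wrapped-Gaussian from the phi
    component, chi1 likewise (a point mass when chi1_sd == 0); omega is fixed
    trans (180 deg).  Draws are independent across frames and residues.
    Identical (spec, model, n_frames, seed) give bit-identical arrays; the
    random stream is consumed residue by residue (component indicators, then
    both basin draws, then phi, then chi1).
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    model.validate_for(spec)
    rng = np.random.default_rng(seed)
    m = len(spec)
    phi = np.empty((n_frames, m))
    psi = np.empty((n_frames, m))
    chi1 = np.empty((n_frames, m))
    for j, basin in enumerate(model.residues):
        in_beta = rng.random(n_frames) < basin.beta_weight
        psi_beta = rng.normal(basin.beta_center, basin.beta_sd, n_frames)
        psi_alpha = rng.normal(basin.alpha_center, basin.alpha_sd, n_frames)
        psi[:, j] = np.where(in_beta, psi_beta, psi_alpha)
        phi[:, j] = rng.normal(basin.phi_center, basin.phi_sd, n_frames)
        if basin.chi1_sd > 0:
            chi1[:, j] = rng.normal(basin.chi1_center, basin.chi1_sd, n_frames)
        else:
            chi1[:, j] = basin.chi1_center
    omega = np.full((n_frames, m), 180.0)
    return DihedralEnsemble(
        spec=spec,
        phi=wrap_angle(phi),
        psi=wrap_angle(psi),
        omega=omega,
        chi1=wrap_angle(chi1),
        seed=seed,
    )


def mixture_window_mass(
    basin: ResidueBasin, lo: float, hi: float, n_wraps: int = 5
) -> float:
    """Analytic probability mass of the wrapped psi mixture inside [lo, hi].

    Sums the unwrapped Gaussian mass over all 360-degree images of the window
    (|k| <= n_wraps covers any sd below ~300 deg to double precision).  This
    is the ground truth against which empirically recovered basin
    probabilities are compared.
    """
    if hi <= lo:
        raise ValueError("window must satisfy lo < hi")
    mass = 0.0
    for k in range(-n_wraps, n_wraps + 1):
        shift = 360.0 * k
        mass += basin.beta_weight * (
            norm.cdf(hi + shift, basin.beta_center, basin.beta_sd)
            - norm.cdf(lo + shift, basin.beta_center, basin.beta_sd)
        )
        mass += (1.0 - basin.beta_weight) * (
            norm.cdf(hi + shift, basin.alpha_center, basin.alpha_sd)
            - norm.cdf(lo + shift, basin.alpha_center, basin.alpha_sd)
        )
    return float(mass)


# --------------------------------------------------------------------------
# Coordinate building
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class BackboneGeometry:
    """Idealised bond lengths (Angstrom) and angles (degrees)."""

    n_ca: float = 1.46
    ca_c: float = 1.52
    c_n: float = 1.33
    c_o: float = 1.23
    n_h: float = 1.01
    ca_ha: float = 1.09
    ca_cb: float = 1.53
    c_os: float = 1.34  # ester C-O
    os_cm: float = 1.44  # ester O-CH3
    cap_bond: float = 1.35  # cap O..C(=O) of the carbamate
    ang_c_n_ca: float = 121.7
    ang_n_ca_c: float = 110.5
    ang_ca_c_n: float = 116.2
    ang_ca_c_o: float = 120.8
    ang_ca_n_h: float = 119.0
    ang_n_ca_ha: float = 108.5
    ang_n_ca_cb: float = 110.5
    ang_ca_c_os: float = 111.5
    ang_c_os_cm: float = 116.0
    ang_cap: float = 123.0

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if name.startswith("ang_"):
                if not 0.0 < value < 180.0:
                    raise ValueError(f"{name} must lie in (0, 180), got {value}")
            elif value <= 0:
                raise ValueError(f"bond length {name} must be positive, got {value}")


@dataclass
class Ensemble3D:
    """Multi-model Cartesian coordinates with a fixed atom table.

    ``coords`` is ``(n_models, n_atoms, 3)`` in Angstrom; atom names,
    1-based residue indices (0 = N-terminal cap) and residue names are
    shared by all models.
    """

    atom_names: tuple[str, ...]
    res_ids: np.ndarray
    res_names: tuple[str, ...]
    coords: np.ndarray
    provenance: DihedralEnsemble | None = None

    def __post_init__(self) -> None:
        n_atoms = len(self.atom_names)
        if self.coords.ndim != 3 or self.coords.shape[1:] != (n_atoms, 3):
            raise ValueError(
                f"coords must be (n_models, {n_atoms}, 3), got {self.coords.shape}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates contain non-finite values")
        if len(self.res_names) != n_atoms or len(self.res_ids) != n_atoms:
            raise ValueError("atom_names, res_ids and res_names must have equal length")

    @property
    def n_models(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def atom_index(self, name: str, res_id: int) -> int:
        """Index of the (unique) atom with this name in this residue."""
        hits = [
            i
            for i, (an, ri) in enumerate(zip(self.atom_names, self.res_ids))
            if an == name and ri == res_id
        ]
        if not hits:
            raise KeyError(f"no atom {name!r} in residue {res_id}")
        return hits[0]

    def select(self, atom_names=None, res_ids=None) -> np.ndarray:
        """Boolean mask over atoms by name set and/or residue-id set."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if atom_names is not None:
            names = set(atom_names)
            mask &= np.asarray([a in names for a in self.atom_names])
        if res_ids is not None:
            ids = set(res_ids)
            mask &= np.asarray([r in ids for r in self.res_ids])
        return mask


def _chain_plan(spec: PeptideSpec) -> list[tuple[str, int, str]]:
    """Atom layout: (atom_name, residue_id, residue_name) in build order."""
    cap_name = "BOC" if spec.n_terminus == "boc" else "REF"
    plan = [("OP", 0, cap_name), ("CP", 0, cap_name)]
    for i, code in enumerate(spec.sequence, start=1):
        plan += [
            ("N", i, code),
            ("H", i, code),
            ("CA", i, code),
            ("HA", i, code),
            ("CB", i, code),
            ("C", i, code),
            ("O", i, code),
        ]
    last = len(spec.sequence)
    code = spec.sequence[-1]
    plan += [("OS", last, code), ("CM", last, code)]
    return plan


def build_coordinates(
    dihedrals: DihedralEnsemble, geometry: BackboneGeometry | None = None
) -> Ensemble3D:
    """Build Cartesian models from dihedrals by sequential chain extension.

    Every placement is a NeRF step, vectorised over frames, so re-measuring
    any (phi, psi, omega) from the result recovers the input angle exactly
    (to floating point) and every bond length matches the geometry table.
    chi1 is not realised in 3D (side chains stop at C-beta).
    """
    g = geometry or BackboneGeometry()
    ens = dihedrals
    n = ens.n_frames
    plan = _chain_plan(ens.spec)
    names = [p[0] for p in plan]
    idx = {(name, rid): k for k, (name, rid, _) in enumerate(plan)}
    coords = np.empty((n, len(plan), 3))

    # seed atoms: cap OP at origin, CP on x-axis, N1 in the xy-plane
    coords[:, idx[("OP", 0)]] = [0.0, 0.0, 0.0]
    coords[:, idx[("CP", 0)]] = [g.cap_bond, 0.0, 0.0]
    ang = np.radians(g.ang_cap)
    coords[:, idx[("N", 1)]] = [
        g.cap_bond - g.c_n * np.cos(ang),
        g.c_n * np.sin(ang),
        0.0,
    ]

    def place(name, rid, frame_keys, bond, angle, torsion):
        a, b, c = (coords[:, idx[k]] for k in frame_keys)
        coords[:, idx[(name, rid)]] = nerf_place(a, b, c, bond, angle, torsion)

    n_res = ens.n_residues
    for i in range(1, n_res + 1):
        j = i - 1  # column in the angle arrays
        prev_c = ("CP", 0) if i == 1 else ("C", i - 1)
        prev_ca = ("OP", 0) if i == 1 else ("CA", i - 1)
        place("CA", i, (prev_ca, prev_c, ("N", i)), g.n_ca, g.ang_c_n_ca, ens.omega[:, j])
        place("H", i, (prev_ca, prev_c, ("N", i)), g.n_h, g.ang_ca_n_h,
              wrap_angle(ens.omega[:, j] + 180.0))
        place("C", i, (prev_c, ("N", i), ("CA", i)), g.ca_c, g.ang_n_ca_c, ens.phi[:, j])
        place("HA", i, (prev_c, ("N", i), ("CA", i)), g.ca_ha, g.ang_n_ca_ha,
              wrap_angle(ens.phi[:, j] + 122.0))
        place("CB", i, (prev_c, ("N", i), ("CA", i)), g.ca_cb, g.ang_n_ca_cb,
              wrap_angle(ens.phi[:, j] - 118.0))
        if i < n_res:
            place("N", i + 1, (("N", i), ("CA", i), ("C", i)), g.c_n, g.ang_ca_c_n,
                  ens.psi[:, j])
        else:
            place("OS", i, (("N", i), ("CA", i), ("C", i)), g.c_os, g.ang_ca_c_os,
                  ens.psi[:, j])
            place("CM", i, (("CA", i), ("C", i), ("OS", i)), g.os_cm, g.ang_c_os_cm, 180.0)
        place("O", i, (("N", i), ("CA", i), ("C", i)), g.c_o, g.ang_ca_c_o,
              wrap_angle(ens.psi[:, j] + 180.0))

    res_ids = np.asarray([p[1] for p in plan])
    res_names = tuple(p[2] for p in plan)
    return Ensemble3D(
        atom_names=tuple(names),
        res_ids=res_ids,
        res_names=res_names,
        coords=coords,
        provenance=dihedrals,
    )


def measure_dihedrals(ensemble: Ensemble3D, spec: PeptideSpec | None = None) -> DihedralEnsemble:
    """Re-measure (phi, psi, omega) from coordinates.

    psi of the final residue uses the ester oxygen OS as the following
    carbonyl substituent, so all residues have a defined psi.  chi1 is NaN
    (side chains are not built beyond C-beta).
    """
    if spec is None:
        seq = []
        seen = set()
        for rid, rname in zip(ensemble.res_ids, ensemble.res_names):
            if rid >= 1 and rid not in seen:
                seen.add(rid)
                seq.append(rname)
        nterm = "boc" if "BOC" in ensemble.res_names else "free-amine"
        spec = PeptideSpec(tuple(seq), n_terminus=nterm)
    n_res = len(spec)
    X = ensemble.coords

    def at(name, rid):
        return X[:, ensemble.atom_index(name, rid)]

    n = ensemble.n_models
    phi = np.empty((n, n_res))
    psi = np.empty((n, n_res))
    omega = np.empty((n, n_res))
    for i in range(1, n_res + 1):
        prev_c = at("CP", 0) if i == 1 else at("C", i - 1)
        prev_ca = at("OP", 0) if i == 1 else at("CA", i - 1)
        omega[:, i - 1] = dihedral(prev_ca, prev_c, at("N", i), at("CA", i))
        phi[:, i - 1] = dihedral(prev_c, at("N", i), at("CA", i), at("C", i))
        nxt = at("N", i + 1) if i < n_res else at("OS", n_res)
        psi[:, i - 1] = dihedral(at("N", i), at("CA", i), at("C", i), nxt)
    chi1 = np.full((n, n_res), np.nan)
    return DihedralEnsemble(spec=spec, phi=phi, psi=psi, omega=omega, chi1=chi1)


# --------------------------------------------------------------------------
# Multi-model PDB I/O
# --------------------------------------------------------------------------


class PDBFormatError(ValueError):
    """Raised when a multi-model PDB file violates the expected layout."""


def write_ensemble(ensemble: Ensemble3D, path) -> None:
    """Write a multi-model PDB (MODEL/ENDMDL, chain A, 3-decimal coords)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    if ensemble.n_models == 0:
        raise ValueError("refusing to write an empty ensemble")
    stack = struc.AtomArrayStack(ensemble.n_models, ensemble.n_atoms)
    # round to the format's 3 decimals first so the float32 cast cannot
    # push a value across a rounding boundary
    stack.coord = np.round(ensemble.coords, 3).astype(np.float32)
    stack.atom_name = np.asarray(ensemble.atom_names)
    stack.res_id = np.asarray(ensemble.res_ids, dtype=int)
    stack.res_name = np.asarray(ensemble.res_names)
    stack.chain_id = np.full(ensemble.n_atoms, "A")
    stack.element = np.asarray([name[0] for name in ensemble.atom_names])
    stack.hetero = np.asarray(ensemble.res_ids) == 0
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def read_ensemble(path) -> Ensemble3D:
    """Read a multi-model PDB written by :func:`write_ensemble`.

    Models must share one atom table; a mismatch in per-model atom counts is
    reported with the offending MODEL number.
    """
    from biotite.structure.io.pdb import PDBFile

    _check_model_atom_counts(path)
    try:
        pdb = PDBFile.read(str(path))
        stack = pdb.get_structure(model=None)
    except Exception as exc:  # biotite raises various parse errors
        raise PDBFormatError(f"cannot parse {path}: {exc}") from exc
    if stack.array_length() == 0:
        raise PDBFormatError(f"{path} contains no atoms")
    return Ensemble3D(
        atom_names=tuple(stack.atom_name),
        res_ids=np.asarray(stack.res_id, dtype=int),
        res_names=tuple(stack.res_name),
        # file stores exact 3-decimal values; undo float32 parse noise
        coords=np.round(np.asarray(stack.coord, dtype=float), 3),
    )


def _check_model_atom_counts(path) -> None:
    counts: list[int] = []
    model_lines: list[int] = []
    current = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                current = 0
                model_lines.append(lineno)
            elif rec in ("ATOM", "HETATM"):
                if current is None:
                    current = 0
                    model_lines.append(lineno)
                current += 1
            elif rec == "ENDMDL":
                counts.append(current or 0)
                current = None
    if current is not None:
        counts.append(current)
    if not counts or all(c == 0 for c in counts):
        raise PDBFormatError(f"{path} contains no ATOM records")
    if len(set(counts)) > 1:
        bad = next(i for i, c in enumerate(counts) if c != counts[0])
        raise PDBFormatError(
            f"{path}: model starting at line {model_lines[bad]} has {counts[bad]} atoms, "
            f"expected {counts[0]}"
        )
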