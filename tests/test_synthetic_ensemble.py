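"""Sampler statistics, coordinate building and ensemble I/O."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import norm

from strandscope._geometry import bond_angle, wrap_angle
from strandscope.synthetic_ensemble import (
    BackboneGeometry,
    BasinModel,
    DihedralEnsemble,
    PDBFormatError,
    PeptideSpec,
    ResidueBasin,
    build_coordinates,
    measure_dihedrals,
    mixture_window_mass,
    read_ensemble,
    sample_dihedrals,
    write_ensemble,
)

from conftest import constant_dihedrals


class TestPeptideSpec:
    def test_eight_systems_have_expected_central_residue(self):
        assert PeptideSpec.pentapeptide("1a").sequence[2] == "SER"
        assert PeptideSpec.pentapeptide("2b").sequence[2] == "THR"
        assert PeptideSpec.pentapeptide("3a").sequence[2] == "TFR"
        assert PeptideSpec.pentapeptide("4b").sequence[2] == "TFS"
        assert PeptideSpec.pentapeptide("4a").n_terminus == "boc"
        assert PeptideSpec.pentapeptide("4b").n_terminus == "free-amine"

    @pytest.mark.parametrize(
        "bad", [("ALA",), ("ALA", "XYZ"), ()], ids=["too-short", "unknown-code", "empty"]
    )
    def test_invalid_sequences_rejected(self, bad):
        with pytest.raises(ValueError):
            PeptideSpec(bad)


class TestSampler:
    def test_degenerate_beta_mixture_collapses_to_beta_center(self, pentapeptide_spec):
        model = BasinModel.uniform(5, beta_weight=1.0, beta_sd=0.01)
        ens = sample_dihedrals(pentapeptide_spec, model, 500, seed=0)
        assert np.all(np.abs(ens.psi - 140.0) < 0.1)

    def test_pure_alpha_beta_window_mass_matches_numerical_integral(self, pentapeptide_spec):
        # independent oracle: numerically integrate the wrapped alpha
        # component over [90, 180] and compare the empirical fraction
        sd, center = 15.0, -30.0

        def wrapped_pdf(x):
            return sum(norm.pdf(x + 360.0 * k, center, sd) for k in range(-3, 4))

        expected, _ = quad(wrapped_pdf, 90.0, 180.0)
        n = 50_000
        model = BasinModel.uniform(5, beta_weight=0.0, alpha_sd=sd)
        ens = sample_dihedrals(pentapeptide_spec, model, n, seed=7)
        frac = np.mean((ens.psi >= 90.0) & (ens.psi <= 180.0))
        se = np.sqrt(max(expected, 1e-12) * (1 - expected) / (n * 5))
        assert abs(frac - expected) <= 3 * se + 1e-9

    def test_same_seed_is_bitwise_identical(self, pentapeptide_spec):
        model = BasinModel.uniform(5, beta_weight=0.3)
        a = sample_dihedrals(pentapeptide_spec, model, 100, seed=42)
        b = sample_dihedrals(pentapeptide_spec, model, 100, seed=42)
        for name in ("phi", "psi", "omega", "chi1"):
            assert np.array_equal(getattr(a, name), getattr(b, name))

    def test_invalid_weight_names_residue(self, pentapeptide_spec):
        with pytest.raises(ValueError, match="beta_weight"):
            BasinModel.uniform(5, beta_weight=1.5)

    def test_model_length_mismatch_rejected(self, pentapeptide_spec):
        with pytest.raises(ValueError, match="residues"):
            sample_dihedrals(pentapeptide_spec, BasinModel.uniform(3), 10, seed=0)

    def test_angles_wrapped_even_for_centers_near_180(self, pentapeptide_spec):
        # beta basin hugging +180: draws beyond the boundary must wrap, not truncate
        model = BasinModel.uniform(5, beta_weight=1.0, beta_center=175.0, beta_sd=20.0)
        ens = sample_dihedrals(pentapeptide_spec, model, 5_000, seed=3)
        assert np.all((ens.psi > -180.0) & (ens.psi <= 180.0))
        # wrap-around means some mass lands just above -180
        assert np.any(ens.psi < -150.0)

    def test_empirical_beta_fraction_converges_to_analytic_mixture_mass(
        self, pentapeptide_spec
    ):
        n = 50_000
        model = BasinModel.uniform(5, beta_weight=0.827)
        ens = sample_dihedrals(pentapeptide_spec, model, n, seed=5)
        expected = mixture_window_mass(model[0], 90.0, 180.0)
        for j in range(5):
            frac = np.mean((ens.psi[:, j] >= 90.0) & (ens.psi[:, j] <= 180.0))
            se = np.sqrt(expected * (1 - expected) / n)
            assert abs(frac - expected) <= 3 * se


class TestWrapAngle:
    def test_interval_is_half_open_on_the_left(self):
        assert wrap_angle(-180.0) == 180.0
        assert wrap_angle(180.0) == 180.0
        assert wrap_angle(540.0) == 180.0
        assert np.isclose(wrap_angle(-190.0), 170.0)
        assert np.isclose(wrap_angle(370.0), 10.0)


class TestBuildCoordinates:
    def test_round_trip_recovers_all_dihedrals(self, small_ensemble, small_coordinates):
        back = measure_dihedrals(small_coordinates)
        for name in ("phi", "psi", "omega"):
            diff = np.abs(getattr(back, name) - getattr(small_ensemble, name))
            diff = np.minimum(diff, 360.0 - diff)
            assert diff.max() < 1e-6

    def test_bond_lengths_match_geometry_table(self, small_coordinates):
        g = BackboneGeometry()
        x = small_coordinates.coords
        pairs = [("N", 1, "CA", 1, g.n_ca), ("CA", 1, "C", 1, g.ca_c),
                 ("C", 1, "N", 2, g.c_n), ("C", 3, "O", 3, g.c_o),
                 ("N", 2, "H", 2, g.n_h), ("CA", 4, "CB", 4, g.ca_cb)]
        for a, ra, b, rb, expected in pairs:
            d = np.linalg.norm(
                x[:, small_coordinates.atom_index(b, rb)]
                - x[:, small_coordinates.atom_index(a, ra)],
                axis=1,
            )
            assert np.abs(d - expected).max() < 1e-6

    def test_bond_angles_match_geometry_table(self, small_coordinates):
        g = BackboneGeometry()
        x = small_coordinates.coords
        i, j, k = (small_coordinates.atom_index(n, r) for n, r in
                   (("N", 2), ("CA", 2), ("C", 2)))
        ang = bond_angle(x[:, i], x[:, j], x[:, k])
        assert np.abs(ang - g.ang_n_ca_c).max() < 1e-6

    def test_extended_chain_longer_than_alpha_chain(self, pentapeptide_spec):
        # oracle: direct N(1)..C(5) distance on both built conformers
        def e2e(phi, psi):
            ens = constant_dihedrals(pentapeptide_spec, phi, psi)
            x = build_coordinates(ens)
            return np.linalg.norm(
                x.coords[0, x.atom_index("C", 5)] - x.coords[0, x.atom_index("N", 1)]
            )

        assert e2e(-179.9, 180.0) > e2e(-57.0, -47.0)

    def test_building_is_deterministic_and_frame_order_independent(self, small_ensemble):
        a = build_coordinates(small_ensemble).coords
        perm = np.random.default_rng(0).permutation(small_ensemble.n_frames)
        shuffled = DihedralEnsemble(
            spec=small_ensemble.spec,
            phi=small_ensemble.phi[perm],
            psi=small_ensemble.psi[perm],
            omega=small_ensemble.omega[perm],
            chi1=small_ensemble.chi1[perm],
        )
        b = build_coordinates(shuffled).coords
        assert np.array_equal(a[perm], b)


class TestEnsembleIO:
    def test_pdb_round_trip_within_format_precision(self, small_coordinates, tmp_path):
        path = tmp_path / "ens.pdb"
        write_ensemble(small_coordinates, path)
        back = read_ensemble(path)
        assert back.n_models == small_coordinates.n_models
        assert back.atom_names == small_coordinates.atom_names
        assert np.abs(back.coords - small_coordinates.coords).max() <= 0.0005

    def test_mismatched_model_atom_counts_rejected(self, small_coordinates, tmp_path):
        path = tmp_path / "ens.pdb"
        write_ensemble(small_coordinates, path)
        lines = path.read_text().splitlines(keepends=True)
        drop = next(i for i, l in enumerate(lines) if l.startswith("ATOM"))
        (tmp_path / "bad.pdb").write_text("".join(lines[:drop] + lines[drop + 1:]))
        with pytest.raises(PDBFormatError, match="line"):
            read_ensemble(tmp_path / "bad.pdb")

    def test_empty_ensemble_refused(self, small_coordinates, tmp_path):
        import dataclasses

        empty = dataclasses.replace(
            small_coordinates, coords=small_coordinates.coords[:0],
            provenance=None,
        )
        with pytest.raises(ValueError, match="empty"):
            write_ensemble(empty, tmp_path / "empty.pdb")

    def test_dihedral_csv_round_trip(self, small_ensemble, tmp_path):
        path = tmp_path / "dihedrals.csv"
        small_ensemble.to_csv(path)
        back = DihedralEnsemble.from_csv(path, spec=small_ensemble.spec)
        for name in ("phi", "psi", "omega", "chi1"):
            assert np.allclose(getattr(back, name), getattr(small_ensemble, name))


class TestResidueBasinValidation:
    @pytest.mark.parametrize("kw", [{"beta_weight": -0.1}, {"beta_weight": 1.01},
                                    {"alpha_sd": 0.0}, {"phi_sd": -1.0}])
    def test_invalid_parameters_rejected(self, kw):
        with pytest.raises(ValueError):
            ResidueBasin(**kw)
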