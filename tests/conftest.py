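import numpy as np
import pytest

from strandscope.pipeline import make_fixtures
from strandscope.synthetic_ensemble import (
    BasinModel,
    DihedralEnsemble,
    PeptideSpec,
    build_coordinates,
    sample_dihedrals,
)


@pytest.fixture(scope="session")
def tables_dir(tmp_path_factory):
    """The bundled NMR/propensity tables written as CSV fixtures."""
    outdir = tmp_path_factory.mktemp("tables")
    make_fixtures(outdir)
    return outdir


@pytest.fixture(scope="session")
def pentapeptide_spec():
    return PeptideSpec.pentapeptide("4a")


@pytest.fixture(scope="session")
def small_ensemble(pentapeptide_spec):
    """200-frame mixed-basin ensemble used by several metric tests."""
    model = BasinModel.uniform(5, beta_weight=0.7)
    return sample_dihedrals(pentapeptide_spec, model, 200, seed=11)


@pytest.fixture(scope="session")
def small_coordinates(small_ensemble):
    return build_coordinates(small_ensemble)


def constant_dihedrals(spec, phi=-120.0, psi=140.0, n_frames=1):
    """Ensemble with every frame/residue at the same (phi, psi)."""
    m = len(spec)
    return DihedralEnsemble(
        spec=spec,
        phi=np.full((n_frames, m), float(phi)),
        psi=np.full((n_frames, m), float(psi)),
        omega=np.full((n_frames, m), 180.0),
        chi1=np.full((n_frames, m), 60.0),
    )
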