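from pathlib import Path

import pytest

from nmrens.modelfree import FieldConfig
from nmrens.structure_io import Ensemble
from nmrens.synthetic import (
    EnsembleSpec,
    default_sigma_profile,
    make_cxxc_template,
    make_template,
    perturb_ensemble,
)

REPO_ROOT = Path(__file__).resolve().parent.parent
#: local copy of the 20-model NMR deposit (PDB 4D4W); not redistributed here
DEPOSIT_PATH = REPO_ROOT / "data" / "4D4W.pdb"


@pytest.fixture(scope="session")
def cfg() -> FieldConfig:
    return FieldConfig()


@pytest.fixture(scope="session")
def cxxc_template():
    template, meta = make_cxxc_template(seed=1)
    return template, meta


@pytest.fixture(scope="session")
def cxxc_ensemble(cxxc_template) -> Ensemble:
    """20-model ensemble with rigid core and flexible loop/termini."""
    template, _ = cxxc_template
    spec = EnsembleSpec(
        n_models=20, template=template, sigma_profile=default_sigma_profile(), seed=7
    )
    return perturb_ensemble(spec)


@pytest.fixture(scope="session")
def helix_ensemble() -> Ensemble:
    conf = make_template(12, "helix")
    return Ensemble([conf], {a.res_seq: a.res_name for a in conf.atoms})
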