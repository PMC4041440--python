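import numpy as np
import pytest

from ensdyn.structure_io import Atom, MonomerModel, ResidueRecord, StructureEnsemble
from ensdyn.synthetic_data import SyntheticSpec


def toy_model(coords, model_id="1", chain_id="A", atom_name="CA", start=1,
              b=20.0):
    """MonomerModel with one named atom per residue at the given coordinates."""
    residues = [
        ResidueRecord(start + i, "A", [Atom(atom_name, x, y, z, b, 1.0)])
        for i, (x, y, z) in enumerate(coords)
    ]
    return MonomerModel(model_id, chain_id, residues)


@pytest.fixture
def spec():
    return SyntheticSpec(seed=20)


@pytest.fixture(scope="session")
def small_ensemble():
    """8 perturbed models with mobile loops, under random rigid motions."""
    from ensdyn.synthetic_data import make_ensemble

    spec = SyntheticSpec(seed=21, n_models=8)
    ens, sigma = make_ensemble(spec, rigid_transforms=True)
    return spec, ens, sigma


@pytest.fixture(scope="session")
def dimer_crystal():
    from ensdyn.synthetic_data import make_toy_crystal

    spec = SyntheticSpec(seed=22)
    return make_toy_crystal(spec, mode="dimer_contact")


def rng(seed=0):
    return np.random.default_rng(seed)
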