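import warnings

import numpy as np
import pytest

from ovoidtim.model import BarrelModel, Residue
from ovoidtim.structure_analysis import assign_strands, fit_barrel_axis, fit_cross_section
from ovoidtim.synthetic_data import preset, preset_blueprint

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def ovoid_bp():
    return preset_blueprint("ovoid")[0]


@pytest.fixture(scope="session")
def ovoid_params():
    return preset_blueprint("ovoid")[1]


@pytest.fixture(scope="session")
def ovoid_model():
    return preset("ovoid")


@pytest.fixture(scope="session")
def circular_model():
    return preset("circular")


@pytest.fixture(scope="session")
def ovoid_strands(ovoid_model):
    return assign_strands(ovoid_model)


@pytest.fixture(scope="session")
def ovoid_shape(ovoid_model, ovoid_strands):
    axis = fit_barrel_axis(ovoid_model, ovoid_strands)
    return fit_cross_section(ovoid_model, ovoid_strands, axis)


def make_toy_model(sequence: str = "VVVV", spacing: float = 6.0) -> BarrelModel:
    """Minimal valid model: residues in a row with CA/CB (+backbone)."""
    residues = []
    for k, aa1 in enumerate(sequence):
        from ovoidtim.model import aa1to3

        ca = np.array([k * spacing, 0.0, 0.0])
        atoms = {
            "N": ca + np.array([-1.2, 0.3, 0.0]),
            "CA": ca,
            "C": ca + np.array([1.2, 0.3, 0.0]),
            "O": ca + np.array([1.4, 1.5, 0.0]),
        }
        aa = aa1to3(aa1)
        if aa != "GLY":
            atoms["CB"] = ca + np.array([0.0, -1.0, 1.2])
        residues.append(Residue(index=k + 1, aa=aa, atoms=atoms))
    return BarrelModel(residues)
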