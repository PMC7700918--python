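import numpy as np
import pytest

from tangentplan.phantom import PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def default_patient():
    """The default seeded fine-grid phantom (shared; treat as read-only)."""
    return generate_phantom(PhantomConfig(seed=1))


@pytest.fixture(scope="session")
def coarse_patient():
    """A small 5 mm phantom for fast pipeline mechanics tests."""
    return generate_phantom(
        PhantomConfig(seed=1, grid_spacing=0.5, extents=(48, 44, 24))
    )


@pytest.fixture(scope="session")
def default_geometry(default_patient):
    from tangentplan.geometry import build_tangent_geometry

    return build_tangent_geometry(default_patient)


@pytest.fixture(scope="session")
def default_engine(default_patient):
    from tangentplan.dose import DoseEngine

    return DoseEngine(default_patient)


def water_box_patient(shape=(40, 40, 20), spacing=0.5, density=1.0):
    """Homogeneous water block with External covering everything except a
    one-voxel air rind; used for closed-form dose checks."""
    from tangentplan.phantom import PatientModel

    ext = np.zeros(shape, dtype=bool)
    ext[1:-1, 1:-1, 1:-1] = True
    dens = np.where(ext, density, 0.0)
    ptv = np.zeros(shape, dtype=bool)
    ptv[shape[0] // 2 - 4 : shape[0] // 2 + 4,
        shape[1] // 2 - 4 : shape[1] // 2 + 4,
        shape[2] // 2 - 2 : shape[2] // 2 + 2] = True
    origin = -0.5 * spacing * np.array(shape, dtype=float)
    structures = {
        "External": ext,
        "PTV_Breast": ptv,
        "PTV_planning": ptv.copy(),
        "Ipsilateral Lung": np.zeros(shape, bool),
        "Contralateral Lung": np.zeros(shape, bool),
        "Heart": np.zeros(shape, bool),
        "Contralateral Breast": np.zeros(shape, bool),
    }
    tattoo = np.array([0.0, origin[1] + 1.5 * spacing, 0.0])
    return PatientModel(
        density=dens, structures=structures, tattoo=tattoo,
        laterality="left", spacing=spacing, origin=origin,
    )


@pytest.fixture()
def water_patient():
    return water_box_patient()
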