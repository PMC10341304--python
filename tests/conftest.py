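import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import hypofx as hx

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_geometry(shape=(4, 4, 4), spacing=(1.0, 1.0, 1.0)):
    return hx.GridGeometry(shape=shape, spacing=spacing)


def make_mask(occupancy, geometry=None, name="m"):
    occ = np.asarray(occupancy, dtype=bool)
    geom = geometry or make_geometry(occ.shape)
    return hx.StructureMask(name, occ, geom)


def make_plan(dose_values, masks, patient_id="P01", modality="photon_like", spacing=(1.0, 1.0, 1.0)):
    """Assemble a Plan from a dose array and {name: bool array} masks."""
    dose_values = np.asarray(dose_values, dtype=float)
    geom = make_geometry(dose_values.shape, spacing)
    structures = hx.StructureSet(geom)
    for name, occ in masks.items():
        structures.add(hx.StructureMask(name, np.asarray(occ, dtype=bool), geom))
    return hx.Plan(
        patient_id=patient_id,
        modality=modality,
        dose=hx.DoseGrid(dose_values, geom),
        structures=structures,
    )


@pytest.fixture(scope="session")
def demo_patient():
    """One default-resolution synthetic patient with both plans (seeded)."""
    return hx.generate_cohort(1, master_seed=1)[0]


@pytest.fixture(scope="session")
def small_cohort():
    """Two coarse-grid patients for fast cohort-level tests."""
    return hx.generate_cohort(2, master_seed=3, geometry=hx.coarse_geometry())
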