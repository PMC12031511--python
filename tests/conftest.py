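import numpy as np
import pytest

from fedprog.records_io import (DYNAMIC, STATIC, FeatureManifest,
                                InstitutionDataset, PatientRecord)
from fedprog.synthetic_cohort import CohortConfig, generate_cohorts


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def tiny_manifest():
    """Two institutions, two shared + one private dynamic feature each."""
    return FeatureManifest.from_site_manifests({
        "hospA": {"hr": DYNAMIC, "creat": DYNAMIC, "troponin": DYNAMIC,
                  "age": STATIC, "gender": STATIC},
        "hospB": {"hr": DYNAMIC, "creat": DYNAMIC, "lactate": DYNAMIC,
                  "age": STATIC, "gender": STATIC},
    })


def make_record(pid, dynamics, mask=None, demo=(60.0, 1.0), mortality=0,
                los=None):
    dynamics = np.asarray(dynamics, dtype=float)
    mask = np.ones_like(dynamics, dtype=bool) if mask is None \
        else np.asarray(mask, dtype=bool)
    return PatientRecord(patient_id=pid, dynamics=dynamics,
                         observed_mask=mask,
                         demographics=np.asarray(demo, dtype=float),
                         mortality=mortality,
                         los_remaining=None if los is None
                         else np.asarray(los, dtype=float))


@pytest.fixture
def tiny_dataset():
    """One 3-feature institution with two short-stay patients."""
    recs = [
        make_record("p1", [[1.0, 3.0], [0.5, 0.7], [2.0, 2.5]],
                    mask=[[True, True], [True, False], [True, True]],
                    mortality=1, los=[1.0, 0.0]),
        make_record("p2", [[2.0, 0.0, 4.0], [1.0, 1.5, 2.0], [0.0, 0.1, 0.2]],
                    mask=[[True, False, True]] * 3,
                    mortality=0, los=[2.0, 1.0, 0.0]),
    ]
    return InstitutionDataset("hospA", "both", ("creat", "hr", "troponin"),
                              ("age", "gender"), recs)


@pytest.fixture(scope="session")
def small_cohort():
    """A small three-institution cohort shared across tests (read-only)."""
    cfg = CohortConfig(n_patients=(60, 90, 50), T_range=(3, 6), seed=11)
    datasets, manifest, truth = generate_cohorts(cfg)
    return cfg, datasets, manifest, truth
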