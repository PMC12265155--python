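import numpy as np
import pytest
from hypothesis import settings

from watchtox.synthetic import SyntheticConfig, generate
from watchtox.types import DrugRecord, Label, ProteinStructureProfile, TargetActivity

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_signal_config():
    """A fast strong-signal condition for unit tests (not the shipped one)."""
    return SyntheticConfig(
        seed=7,
        n_drugs=160,
        withdrawn_fraction=0.5,
        n_proteins=15,
        n_toxic_proteins=3,
        toxic_hit_prob=(0.85, 0.1),
        chem_effect_sizes={"alogp": 2.0},
        n_fingerprint_bits=64,
        fingerprint_signal_bits=6,
        fingerprint_flip_prob=0.1,
        atc_enrichment={"N": (0.5, 0.1)},
        n_investigational=20,
    )


@pytest.fixture(scope="session")
def small_bundle(small_signal_config):
    return generate(small_signal_config)


@pytest.fixture
def toy_drugs():
    """Three hand-built drug records with a missing psa value."""
    fp = np.array([1, 0, 1, 0])
    return [
        DrugRecord(
            "d1", Label.WITHDRAWN,
            withdrawal_reasons=["Hepatic toxicity"],
            atc_codes=["A02BC01", "C07AB02"],
            chem_features={"alogp": 1.0, "psa": 50.0, "prodrug": True,
                           "chirality": "achiral"},
            fingerprint=fp,
        ),
        DrugRecord(
            "d2", Label.NOT_WITHDRAWN,
            atc_codes=["N05BA01"],
            chem_features={"alogp": 3.0, "psa": 90.0, "prodrug": False,
                           "chirality": "racemic"},
            fingerprint=fp,
        ),
        DrugRecord(
            "d3", Label.NOT_WITHDRAWN,
            chem_features={"alogp": 2.0, "prodrug": False,
                           "chirality": "achiral"},
            fingerprint=np.array([0, 0, 1, 1]),
        ),
    ]


@pytest.fixture
def toy_activities():
    return [
        TargetActivity("d1", "P1", 50.0),
        TargetActivity("d1", "P1", 200.0),
        TargetActivity("d1", "P2", 10.0),
        TargetActivity("d2", "P1", 1000.0),
    ]


@pytest.fixture
def toy_profiles():
    return [
        ProteinStructureProfile("P1", 100, {"helix_residues": 50.0, "contacts": 300.0}),
        ProteinStructureProfile("P2", 200, {"helix_residues": 20.0, "contacts": 100.0}),
    ]
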