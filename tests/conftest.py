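import numpy as np
import pytest

from submito.cnn_model import CompartmentLabel
from submito.encoding import encode_protein
from submito.io_formats import ProteinRecord, PSSMProfile
from submito.synthetic_data import SyntheticSpec, generate_profiles, generate_proteome


@pytest.fixture
def peptide():
    return ProteinRecord(id="pep1", sequence="MKTAYIA")


@pytest.fixture
def peptide_profile(peptide):
    rng = np.random.default_rng(42)
    matrix = rng.integers(-8, 9, size=(len(peptide), 20))
    return PSSMProfile(protein_id=peptide.id, matrix=matrix)


@pytest.fixture(scope="session")
def small_labelled_dataset():
    """40 motif-planted proteins (10 per compartment), encoded."""
    spec = SyntheticSpec(n_per_class=10, length_range=(40, 60), seed=7)
    labelled = generate_proteome(spec)
    records = [rec for rec, _ in labelled]
    profiles = generate_profiles(records, noise=1.0, seed=8)
    return [
        (encode_protein(rec, profiles[rec.id]), label) for rec, label in labelled
    ]


@pytest.fixture
def all_labels():
    return list(CompartmentLabel)
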