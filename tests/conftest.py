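import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ncscreen.chem import CompoundRecord, parse_and_canonicalize
from ncscreen.fixtures import REFERENCE_COMPOUNDS

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def flavonoids() -> dict[str, str]:
    """Reference flavonoid SMILES shared across modules."""
    return dict(REFERENCE_COMPOUNDS)


def make_record(compound_id: str, smiles: str, **kwargs) -> CompoundRecord:
    return CompoundRecord(
        id=compound_id,
        smiles=smiles,
        canonical_smiles=parse_and_canonicalize(smiles),
        **kwargs,
    )


@pytest.fixture(scope="session")
def small_molecules() -> list[CompoundRecord]:
    """A varied handful of valid structures for property tests."""
    smiles = [
        "c1ccccc1",          # benzene
        "C1CCCCC1",          # cyclohexane
        "CCO",               # ethanol
        "CC(C)=O",           # acetone
        "O=Cc1ccccc1",       # benzaldehyde
        "OC(=O)c1ccccc1",    # benzoic acid
        "COc1ccccc1",        # anisole
        "O=c1ccc2ccccc2o1",  # coumarin
        "CC(=O)OC",          # methyl acetate
        "C",                 # methane
    ]
    return [make_record(f"M{i}", s) for i, s in enumerate(smiles)]


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
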