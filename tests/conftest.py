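import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from redoxpath.atoms import AtomRecord, Structure

settings.register_profile(
    "ci", deadline=None, derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def make_structure(points, element="C", chain="A", res_name="GLY", het=False, b=10.0):
    """Structure of single-atom residues at the given coordinates."""
    atoms = [
        AtomRecord(
            serial=i + 1,
            name="CA",
            element=element,
            res_name=res_name,
            chain_id=chain,
            res_seq=i + 1,
            position=np.asarray(p, float),
            b_factor=b,
            het=het,
        )
        for i, p in enumerate(points)
    ]
    return Structure(atoms)


@pytest.fixture
def random_cloud():
    rng = np.random.default_rng(7)
    return rng.normal(size=(40, 3)) * 4.0


@pytest.fixture
def two_body():
    from redoxpath.synthetic import make_two_body_complex

    structure, truth = make_two_body_complex(3.0, n_contact_pairs=9, hbond_distance=2.3, seed=11)
    return structure, truth
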