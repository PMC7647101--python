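import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pepdau import Proteome, synth_proteome
from pepdau.alphabets import reset_registry

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(autouse=True)
def _clean_scheme_registry():
    reset_registry()
    yield
    reset_registry()


@pytest.fixture(scope="session")
def small_proteome() -> Proteome:
    """150 uniform-composition proteins, 300-700 residues."""
    return synth_proteome(150, (300, 700), seed=101)


@pytest.fixture()
def tiny_proteome() -> Proteome:
    return Proteome(
        [("p1", "MKKDEAST"), ("p2", "MASARKKD"), ("p3", "KDEASTRK")],
        species="toy",
    )


@pytest.fixture()
def fasta_file(tmp_path):
    path = tmp_path / "toy.fasta"
    path.write_text(">p1\nMKKD\n>p2 description text\nMA\nSA\n")
    return path


AA_INDEX = {aa: i for i, aa in enumerate("ACDEFGHIKLMNPQRSTVWY")}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(7)
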