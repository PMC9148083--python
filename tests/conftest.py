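import numpy as np
import pytest

from cyp_repertoire.sequence_io import ProteinRecord
from cyp_repertoire.synthetic_data import SynthConfig, make_dataset, make_panel


def make_p450_like(
    length: int = 450,
    exxr_at: int | None = 310,
    cxg_at: int | None = 430,
    exxr_text: str = "ETLR",
    cxg_text: str = "CLG",
    protein_id: str = "q1",
    species_id: str = "sp1",
) -> ProteinRecord:
    """Poly-alanine background with motifs planted at 1-based positions.

    A poly-A background contains no E..R or C.G substring, so the planted
    motifs are the only hits by construction.
    """
    chars = ["A"] * length
    if exxr_at is not None:
        chars[exxr_at - 1 : exxr_at + 3] = list(exxr_text)
    if cxg_at is not None:
        chars[cxg_at - 1 : cxg_at + 2] = list(cxg_text)
    return ProteinRecord(protein_id, species_id, "".join(chars))


@pytest.fixture(scope="session")
def small_dataset():
    """One small labelled synthetic dataset shared across tests."""
    config = SynthConfig(seed=20, species_per_class=3, decoy_count_per_species=5)
    return make_dataset(config)


@pytest.fixture(scope="session")
def small_panel():
    """A 3-family reference panel with its seed sequences and anchors."""
    config = SynthConfig(seed=11, n_seed_families=3)
    rng = np.random.default_rng(config.seed)
    return make_panel(config, rng)
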