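import numpy as np
import pytest

from pepimpute.datamodel import PeptideDataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_dataset(abundance, proteins=None, sample_groups=None):
    """Small helper: build a PeptideDataset from a raw-scale matrix."""
    abundance = np.asarray(abundance, dtype=float)
    n, s = abundance.shape
    peptide_ids = [f"PEP{i:03d}K" for i in range(n)]
    if proteins is None:
        proteins = [{f"P{i // 3}"} for i in range(n)]
    sample_ids = [f"S{j}" for j in range(s)]
    return PeptideDataset(abundance, peptide_ids, list(proteins), sample_ids, sample_groups=sample_groups)


@pytest.fixture
def random_dataset(rng):
    """60 peptides x 6 samples, ~20% missing, 3-peptide proteins."""
    A = np.exp(rng.normal(5, 1, size=(60, 6)))
    A[rng.random((60, 6)) < 0.2] = np.nan
    # keep at least one observed value per row and column
    A[:, 0] = np.where(np.isfinite(A[:, 0]), A[:, 0], np.exp(5.0))
    return make_dataset(A)
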