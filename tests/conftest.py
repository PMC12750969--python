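import numpy as np
import pytest

from vertmorph import (
    fit_pca,
    generalized_procrustes,
    make_truth,
    simulate_dataset,
)


def random_rotation(rng):
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1.0
    return q


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture(scope="session")
def small_study():
    """One simulated study (18 species, LF + LM) shared across tests."""
    truth = make_truth(18, seed=11)
    dataset, ecology = simulate_dataset(truth, positions=("LF", "LM"))
    return truth, dataset, ecology


@pytest.fixture(scope="session")
def lf_block(small_study):
    _, dataset, _ = small_study
    sub = dataset.at_position("LF")
    coords = np.stack([c.coords for c in sub.configurations])
    ids = [c.specimen_id for c in sub.configurations]
    return generalized_procrustes(coords, position="LF", specimen_ids=ids)


@pytest.fixture(scope="session")
def lf_space(lf_block):
    return fit_pca(lf_block)
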