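"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import logging

import numpy as np
import pytest

from coevoclust.autocluster import Embedding

# silence the intentional branch-length-default warnings in fixtures
logging.getLogger("coevoclust.trees").setLevel(logging.ERROR)


#: Centers of the three-blob fixture: mutually >= 1 apart, sigma = 0.05,
#: 10 points per blob.
BLOB_CENTERS = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.5, 0.9, 0.0]])


def make_blobs(seed: int, n_per_blob: int = 10, sigma: float = 0.05):
    """Three well-separated 3-D Gaussian blobs plus their true labels."""
    rng = np.random.default_rng(seed)
    x = np.vstack(
        [c + rng.normal(0.0, sigma, (n_per_blob, 3)) for c in BLOB_CENTERS]
    )
    truth = np.repeat(np.arange(3), n_per_blob)
    return x, truth


def blob_embedding(seed: int) -> tuple[Embedding, np.ndarray]:
    x, truth = make_blobs(seed)
    emb = Embedding(
        gene_ids=[f"p{i}" for i in range(len(x))],
        scores=x,
        variance_explained=np.array([0.5, 0.3, 0.2]),
        source="strict",
    )
    return emb, truth


@pytest.fixture
def three_blobs():
    return blob_embedding(seed=0)
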