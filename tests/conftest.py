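"""Shared fixtures: the reference desk-scale training run is expensive
(minutes), so it is trained once per session and shared by every test
that needs a trained segmenter."""

import numpy as np
import pytest

from craniometry import cli


@pytest.fixture(scope="session")
def reference_phantoms():
    """Phantom set for the reference training run (native geometry); a
    fraction is rendered on plain backgrounds so the learned engine also
    covers uncluttered scenes."""
    return cli.generate_phantoms(100, seed=53, plain_fraction=0.15)


@pytest.fixture(scope="session")
def reference_model(reference_phantoms):
    """The reference desk-scale training run (seeded, ~10 min single CPU)."""
    model, history = cli.train_reference_model(reference_phantoms, seed=49,
                                               epochs=30, copies=0)
    return model, history
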