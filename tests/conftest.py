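import numpy as np
import pytest

from champ.fixtures import demo_complex, template_params


@pytest.fixture(scope="session")
def template():
    """Idealized antiparallel small-X6-small template parameters."""
    return template_params()


@pytest.fixture(scope="session")
def template_pair(template):
    from champ.geometry import generate_crick_backbone

    return generate_crick_backbone(template, 25)


@pytest.fixture(scope="session")
def complex_model():
    """Target TM helix oriented in the bilayer with the binder placed."""
    return demo_complex()


@pytest.fixture(scope="session")
def design_candidates(complex_model):
    """A small deterministic design run shared across tests."""
    from champ.design import design_sequences, packing_score

    cands = design_sequences(complex_model, n_designs=6, seed=11, n_perturbations=1)
    for c in cands:
        packing_score(c)
    return cands


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
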