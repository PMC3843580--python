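import numpy as np
import pytest

from fluxkit import fixtures


@pytest.fixture
def chain():
    return fixtures.make_chain_model()


@pytest.fixture
def branched():
    return fixtures.make_branched_model()


@pytest.fixture
def two_substrate():
    return fixtures.make_two_substrate_model()


@pytest.fixture(scope="session")
def core_like():
    return fixtures.make_core_like_model()


def models_equal(a, b, check_id=False) -> bool:
    """Field-for-field model equality (canonical rule text for GPRs)."""
    return (
        (not check_id or a.model_id == b.model_id)
        and a.reactions == b.reactions
        and a.metabolites == b.metabolites
        and np.array_equal(a.lower_bound, b.lower_bound)
        and np.array_equal(a.upper_bound, b.upper_bound)
        and np.array_equal(a.objective_coef, b.objective_coef)
        and (a.S != b.S).nnz == 0
        and [r.to_text() for r in a.gpr] == [r.to_text() for r in b.gpr]
        and a.subsystem == b.subsystem
    )
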