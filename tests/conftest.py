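import numpy as np
import pytest

from fluctedit.models import DEFAULT_GRID, FieldContext


@pytest.fixture(scope="session")
def field600():
    return FieldContext(600.0)


@pytest.fixture(scope="session")
def field750():
    return FieldContext(750.0)


@pytest.fixture(scope="session")
def nu_grid():
    return np.array(DEFAULT_GRID.nu_cpmg)
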