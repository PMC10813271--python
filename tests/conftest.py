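import pytest

from famprio import run_cascade
from famprio.reference_study import reference_study


@pytest.fixture(scope="session")
def ref_inputs():
    """The bundled FNMTC reference study inputs."""
    return reference_study()


@pytest.fixture(scope="session")
def ref_table(ref_inputs):
    """The cascade's output on the reference study."""
    variants, gt, annotations, ped, config = ref_inputs
    return run_cascade(variants, gt, annotations, ped, config)
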