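import pytest

import endoleakseg as es


@pytest.fixture(scope="session")
def phantom_config():
    return es.PhantomConfig(seed=42)


@pytest.fixture(scope="session")
def small_cohort(phantom_config):
    """5 positive + 3 control phantom cases."""
    return es.generate_cohort(phantom_config, 5, 3)


@pytest.fixture(scope="session")
def positive_case(phantom_config):
    return es.generate_case(phantom_config, es.POSITIVE, case_seed=314)


@pytest.fixture(scope="session")
def control_case(phantom_config):
    return es.generate_case(phantom_config, es.CONTROL, case_seed=2718)


@pytest.fixture(scope="session")
def leak_slice(positive_case):
    """(slice, maskset) pair from a phantom case whose endoleak mask is non-empty."""
    for sl, ms in zip(positive_case.slices, positive_case.masks):
        if ms.has_endoleak:
            return sl, ms
    raise AssertionError("positive phantom case has no endoleak slice")
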