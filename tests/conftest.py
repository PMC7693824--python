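import pytest

import ocellatin as oc


@pytest.fixture(scope="session")
def catalogue():
    return oc.load_catalogue()


@pytest.fixture(scope="session")
def family(catalogue):
    return oc.family_members(catalogue)


@pytest.fixture(scope="session")
def activity():
    return oc.load_activity()


@pytest.fixture(scope="session")
def by_name(catalogue):
    return {r.name: r for r in catalogue}
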