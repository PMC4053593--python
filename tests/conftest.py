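import pytest

from nanowaste import packaged_profile, packaged_rule_tables


@pytest.fixture(scope="session")
def textile_bundle():
    return packaged_profile("nanosilver_textile")


@pytest.fixture(scope="session")
def sunscreen_bundle():
    return packaged_profile("tio2_sunscreen")


@pytest.fixture(scope="session")
def racquet_bundle():
    return packaged_profile("cnt_racquet")


@pytest.fixture(scope="session")
def rule_tables():
    return packaged_rule_tables()
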