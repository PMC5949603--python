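import pytest

from bbpkit.synthetic import load_fixtures


@pytest.fixture(scope="session")
def sequences_df():
    return load_fixtures("sequences")


@pytest.fixture(scope="session")
def temp_coeffs_df():
    return load_fixtures("temp_coeffs")


def parse_flags(flags: str) -> dict:
    """Fixture flags column -> parse_bbp keyword arguments."""
    return {
        "amide": "amide" in flags,
        "thioether": "thioether" in flags,
    }
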