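import pytest

from permscreen.ratios import load_reference_summaries


@pytest.fixture(scope="session")
def reference_summaries():
    return load_reference_summaries()


@pytest.fixture(scope="session")
def summaries_by_drug(reference_summaries):
    by_drug = {}
    for s in reference_summaries:
        by_drug.setdefault(s.drug_id, []).append(s)
    return by_drug
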