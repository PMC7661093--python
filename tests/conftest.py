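import pytest

from dwcforge import casestudy
from dwcforge.synth import GeneratorParams, generate_checklist
from dwcforge.transforms import map_checklist


@pytest.fixture(scope="session")
def case_spec():
    return casestudy.load_spec()


@pytest.fixture(scope="session")
def case_checklist():
    return casestudy.load_checklist()


@pytest.fixture(scope="session")
def case_metadata():
    return casestudy.load_dataset_metadata()


@pytest.fixture(scope="session")
def case_bundle(case_checklist, case_spec, case_metadata):
    return map_checklist(case_checklist, case_spec, metadata=case_metadata)


@pytest.fixture(scope="session")
def clean_checklist_200():
    """Defect-free synthetic checklist (n=200, seed=3) plus its ledger."""
    return generate_checklist(GeneratorParams(n_taxa=200, seed=3))


@pytest.fixture(scope="session")
def synthetic_bundle(clean_checklist_200, case_spec):
    checklist, _ = clean_checklist_200
    return map_checklist(checklist, case_spec)
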