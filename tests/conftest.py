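import pytest

from aquarisk import (
    Rubric,
    builtin_case_study,
    default_grade_scale,
    default_hierarchy,
)


@pytest.fixture(scope="session")
def hierarchy():
    return default_hierarchy()


@pytest.fixture(scope="session")
def rubric():
    return Rubric.from_config(None)


@pytest.fixture(scope="session")
def grade_scale():
    return default_grade_scale()


@pytest.fixture(scope="session")
def case_study():
    return builtin_case_study()


@pytest.fixture()
def chain_config():
    """Degenerate but valid model: a single weight-1 child at every level."""
    return {
        "model_name": "chain",
        "model_version": "1",
        "nodes": [
            {"id": "T", "label": "total", "level": "total"},
            {"id": "A", "label": "primary", "level": "primary",
             "parent": "T", "weight": 1.0},
            {"id": "B", "label": "secondary", "level": "secondary",
             "parent": "A", "weight": 1.0},
            {"id": "c", "label": "tertiary", "level": "tertiary",
             "parent": "B", "weight": 1.0},
        ],
    }
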