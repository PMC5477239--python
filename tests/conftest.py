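from __future__ import annotations

import pytest
from hypothesis import settings

from nearmiss.records import PatientRecord, ToolConfig
from nearmiss.simulate import preset_tool_config

settings.register_profile("suite", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_config() -> ToolConfig:
    """WHO defaults: threshold 5 units, no correction, everything available."""
    return ToolConfig()


@pytest.fixture(scope="session")
def study_config() -> ToolConfig:
    """Tool configuration matching the three studies' local facilities."""
    return preset_tool_config()


@pytest.fixture
def make_record():
    """Factory for minimal patient records with keyword overrides."""

    def _make(**kwargs) -> PatientRecord:
        base = {"cohort_id": "X", "setting": "high_resource", "died": False}
        base.update(kwargs)
        return PatientRecord(**base)

    return _make
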