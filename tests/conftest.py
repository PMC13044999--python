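"""Shared fixtures: small synthetic cohorts generated fresh per session."""

from __future__ import annotations

import pytest

from pdms_etl.governance import SaltConfig
from pdms_etl.synthetic_pdms import SyntheticConfig, generate_fixture


def case_ids(n: int) -> "list[str]":
    return [f"C{i:06d}" for i in range(1, n + 1)]


@pytest.fixture(scope="session")
def salt() -> SaltConfig:
    return SaltConfig(salt=b"unit-test-salt-0123456789")


@pytest.fixture(scope="session")
def clean_fixture(tmp_path_factory):
    """Pathology-free 30-case cohort: no missing ends, no reverification,
    no identifier conflicts, every case closed."""
    cfg = SyntheticConfig(
        n_cases=30,
        seed=101,
        p_missing_end=0.0,
        p_reverify=0.0,
        p_case_patient_conflict=0.0,
        p_open_case=0.0,
        mean_drug_events_per_case=25.0,
    )
    path = tmp_path_factory.mktemp("clean") / "fixture.db"
    handle, truth = generate_fixture(cfg, path)
    yield handle, truth, cfg, path
    handle.close()


@pytest.fixture(scope="session")
def pathological_fixture(tmp_path_factory):
    """60-case cohort with all documentation pathologies at default rates."""
    cfg = SyntheticConfig(
        n_cases=60,
        seed=202,
        mean_drug_events_per_case=25.0,
    )
    path = tmp_path_factory.mktemp("patho") / "fixture.db"
    handle, truth = generate_fixture(cfg, path)
    yield handle, truth, cfg, path
    handle.close()
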