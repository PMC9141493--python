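"""Shared fixtures: small synthetic cohorts generated once per session."""

import pytest

from dicomdeid import CohortSpec, builtin_policy, read_dataset, write_cohort

SMALL_SPEC = CohortSpec(n_cases=3, slices_per_series=3, image_size=32, seed=11)


@pytest.fixture(scope="session")
def small_cohort_dir(tmp_path_factory):
    """A 3-case, 3-slice, 32-px pre-export cohort (fast unit-test scale)."""
    out = tmp_path_factory.mktemp("raw_cohort")
    write_cohort(SMALL_SPEC, out)
    return out


@pytest.fixture(scope="session")
def small_cohort_spec():
    return SMALL_SPEC


@pytest.fixture()
def policy():
    return builtin_policy(salt="unit-test-salt")


@pytest.fixture()
def raw_slice(small_cohort_dir):
    """One pre-export slice, freshly parsed (function-scoped: tests mutate it)."""
    case = sorted(p for p in small_cohort_dir.iterdir() if p.is_dir())[0]
    return read_dataset(sorted(case.iterdir())[0])
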