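"""Shared fixtures: small synthetic cohorts and pipeline runs."""

from __future__ import annotations

import pytest

from snvaudit.pipeline import RunConfig, run
from snvaudit.synthetic import CohortConfig, generate_bundle, generate_cohort


@pytest.fixture(scope="session")
def small_config() -> CohortConfig:
    """A small cohort (~250 variants, 60 genes, 10 epigenomes) for fast tests."""
    return CohortConfig(seed=11, n_genes=60, n_epigenomes=10)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return generate_bundle(small_config)


@pytest.fixture(scope="session")
def small_cohort_dir(small_config, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("cohort")
    return generate_cohort(small_config, outdir)


@pytest.fixture(scope="session")
def run_config_factory(small_cohort_dir, tmp_path_factory):
    """Build a RunConfig over the small cohort with a fresh output directory."""

    def _make(**overrides) -> RunConfig:
        out = tmp_path_factory.mktemp("run")
        params = dict(
            variants=str(small_cohort_dir["variants"]),
            genes=str(small_cohort_dir["genes"]),
            expression=str(small_cohort_dir["expression"]),
            degrees=str(small_cohort_dir["degrees"]),
            chromatin=str(small_cohort_dir["chromatin"]),
            quartets=str(small_cohort_dir["quartets"]),
            out=str(out),
        )
        params.update(overrides)
        return RunConfig(**params)

    return _make


@pytest.fixture(scope="session")
def small_summary(run_config_factory):
    """One full pipeline run over the small cohort."""
    return run(run_config_factory())
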