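import pytest
from hypothesis import HealthCheck, settings

from vaersvasc import synthetic_data, vaers_io
from vaersvasc.case_extraction import extract_cases

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def fixture_triplet(tmp_path_factory):
    """The hand-written 12-report fixture triplet plus its sidecar truth."""
    root = tmp_path_factory.mktemp("fixture_small")
    paths, truth = synthetic_data.fixture_small(root)
    return root, paths, truth


@pytest.fixture(scope="session")
def fixture_reports(fixture_triplet):
    root, _, _ = fixture_triplet
    return vaers_io.load_year_range(root, 2019, 2019)


@pytest.fixture(scope="session")
def fixture_cases(fixture_reports):
    return extract_cases(fixture_reports)


def _cohort_config(seed: int, n_per_vaccine: int) -> synthetic_data.SimConfig:
    """Study-condition cohort: background 20/100k everywhere, one stratum
    with a vaccine-attributable excess, child and adult age mixes."""
    return synthetic_data.SimConfig(
        vaccine_specs=[
            synthetic_data.VaccineSpec("MENB", n_per_vaccine, excess_rate_per_100k=180.0),
            synthetic_data.VaccineSpec("HIBV", n_per_vaccine),
            synthetic_data.VaccineSpec("PNC13", n_per_vaccine),
            synthetic_data.VaccineSpec("MMR", n_per_vaccine),
            synthetic_data.VaccineSpec(
                "COVID19", n_per_vaccine, age_dist=("uniform", 1.0, 60.0)
            ),
        ],
        seed=seed,
    )


@pytest.fixture(scope="session")
def cohort(tmp_path_factory):
    """Medium synthetic cohort (5 x 600 reports) for unit/property tests."""
    root = tmp_path_factory.mktemp("cohort")
    config = _cohort_config(seed=20240701, n_per_vaccine=600)
    paths, truth = synthetic_data.generate(config, root)
    reports = vaers_io.load_year_range(root, config.year, config.year)
    return {"root": root, "paths": paths, "truth": truth, "reports": reports,
            "config": config}


@pytest.fixture(scope="session")
def big_cohort(tmp_path_factory):
    """10,000-report cohort (5 x 2,000) for round-trip and distribution checks."""
    root = tmp_path_factory.mktemp("big_cohort")
    config = _cohort_config(seed=7, n_per_vaccine=2000)
    paths, truth = synthetic_data.generate(config, root)
    reports = vaers_io.load_year_range(root, config.year, config.year)
    return {"root": root, "paths": paths, "truth": truth, "reports": reports,
            "config": config}
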