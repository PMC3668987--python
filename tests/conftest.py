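import pytest

from capri import (
    add_validation_scenarios,
    builtin_pnd_attributes,
    generate_plan,
    population_from_table6,
    profile_from_labels,
    simulate_ratings,
)


@pytest.fixture(scope="session")
def pnd_attrs():
    return builtin_pnd_attributes()


@pytest.fixture(scope="session")
def pnd_plan(pnd_attrs):
    """Default 16-run estimation plan with 5 dominance holdouts."""
    return add_validation_scenarios(generate_plan(pnd_attrs, "auto", seed=0), 5, seed=0)


@pytest.fixture(scope="session")
def table6_population():
    return population_from_table6()


@pytest.fixture(scope="session")
def noiseless_responses(table6_population, pnd_plan):
    """Continuous, homogeneous, noise-free ratings: exact-recovery regime."""
    spec = table6_population.replace(
        heterogeneity_sd=0.0,
        noise_sd=0.0,
        continuous_output=True,
        scale_midpoint=0.0,
        n_respondents=5,
    )
    return simulate_ratings(spec, pnd_plan)


@pytest.fixture(scope="session")
def innovation_a(pnd_attrs):
    """The worked hypothetical example: significant impact, moderate cost,
    high prevalence, meeting standards, strong evidence, both priorities,
    no local expertise."""
    return profile_from_labels(
        pnd_attrs,
        {
            "impact": "Significant improvement",
            "cost": "Moderate",
            "needs": "High prevalence",
            "standards": "Yes, meeting minimum standards.",
            "evidence": "Strong supporting evidence.",
            "priority": "Both local and national priority.",
            "expertise": "No, there is no local expertise.",
        },
    )
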