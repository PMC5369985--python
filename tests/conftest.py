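import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=100,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def patient1_cohort():
    """One simulated patient-1-like cohort, shared across tests."""
    from clonedeconv.simulate import scenario_like_patient1, simulate_cohort

    scenario = scenario_like_patient1(seed=1)
    return scenario, simulate_cohort(scenario)


@pytest.fixture(scope="session")
def patient1_result(patient1_cohort):
    """Full pipeline result on the shared patient-1-like cohort."""
    from clonedeconv.io import counts_to_frame
    from clonedeconv.pipeline import analyze_patient

    scenario, sim = patient1_cohort
    return analyze_patient(
        scenario.cohort_table(),
        counts_to_frame(sim.counts_deep),
        windows=sim.windows,
        counts_wes=counts_to_frame(sim.counts_wes),
        annotations=sim.annotations,
    )
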