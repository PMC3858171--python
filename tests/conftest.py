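import pytest

from pinlineage.synthetic_data import (
    GeneratorConfig,
    generate_stage_series,
    generate_truth,
)

# A reduced-scale synthetic study used by the fast integration tests:
# 200 proteins, 8 planted modules of 10, two of them silenced late in the
# disease condition.  The full-scale study conditions live in
# tests/test_acceptance.py.
MINI = GeneratorConfig(
    n_proteins=200,
    n_interactions=600,
    n_planted_modules=8,
    planted_sizes=(10,) * 8,
    disrupted_module_ids=(0, 1),
    disruption_schedule=(0.0, 0.0, 0.6, 1.0),
    seed=7,
)


@pytest.fixture(scope="session")
def mini_truth():
    return generate_truth(MINI)


@pytest.fixture(scope="session")
def mini_datasets(mini_truth):
    return {
        c: generate_stage_series(mini_truth, c) for c in ("stable", "disease")
    }


@pytest.fixture(scope="session")
def mini_bundle(mini_truth, mini_datasets):
    from pinlineage.pipeline import AnalysisParams, analyze

    return analyze(
        mini_truth.interactions,
        mini_datasets,
        mini_truth.annotations,
        AnalysisParams(trials=10, null_reps=60, seed=7),
    )
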