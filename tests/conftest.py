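import pytest

from huntshift import report, synthetic


@pytest.fixture(scope="session")
def sim_config():
    # 8 location pairs keep the whole suite fast while exercising every stage
    return synthetic.SimConfig(n_location_pairs=8, seed=3)


@pytest.fixture(scope="session")
def study(sim_config):
    return synthetic.simulate_study(sim_config)


@pytest.fixture(scope="session")
def study_paths(study, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("study")
    return synthetic.write_study(study, outdir)


@pytest.fixture(scope="session")
def run_config(study_paths, tmp_path_factory):
    return report.RunConfig(
        detections=study_paths["detections"],
        deployments=study_paths["deployments"],
        hunting_calendar=study_paths["hunting"],
        outdir=str(tmp_path_factory.mktemp("report")),
        bootstrap_reps=100,
        seed=11,
    )


@pytest.fixture(scope="session")
def pipeline_result(run_config):
    return report.run_pipeline(run_config)
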