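import logging
from pathlib import Path

import pytest

from homeobias.pipeline import PipelineConfig, run_pipeline
from homeobias.simdata import SimConfig, simulate_experiment, write_fixture

FIXTURE20 = Path(__file__).parent / "data" / "fixture20"

logging.getLogger("homeobias").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def fixture20_dir() -> Path:
    return FIXTURE20


@pytest.fixture(scope="session")
def fixture20_report(tmp_path_factory):
    """Full pipeline run on the committed 20-pair fixture."""
    out = tmp_path_factory.mktemp("fixture20_run")
    cfg = PipelineConfig.from_yaml(FIXTURE20 / "config.yaml")
    cfg.out_dir = str(out)
    return cfg, run_pipeline(cfg)


@pytest.fixture(scope="session")
def planted_run(tmp_path_factory):
    """A 2000-pair single-condition simulation with strong planted effects
    (4-fold parental separation, ~10% replicate CV), pushed through the
    whole pipeline.  Shared by classifier-recovery tests."""
    cfg = SimConfig(
        n_pairs=2000,
        conditions=("C1",),
        baseline_mean=1000.0,
        baseline_log_sd=0.0,
        dispersion=0.009,
        parental_fold=4.0,
        transgressive_fold=4.0,
        pattern_frequencies={
            "no_change": 0.60,
            "ELD_P2": 0.15,
            "ELD_P1": 0.10,
            "additivity": 0.10,
            "transgressive_up": 0.025,
            "transgressive_down": 0.025,
        },
        seed=11,
    )
    sim = simulate_experiment(cfg)
    d = tmp_path_factory.mktemp("planted")
    paths = write_fixture(sim, d)
    pcfg = PipelineConfig.from_yaml(paths["config"])
    report = run_pipeline(pcfg)
    return sim, report
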