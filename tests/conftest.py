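import pytest

from essefate.io import read_site_table
from essefate.pipeline import PipelineConfig, run_pipeline
from essefate.simulate import SimulationConfig, generate_study

STUDY_SEED = 11


@pytest.fixture(scope="session")
def study(tmp_path_factory):
    """One synthetic study plus a full pipeline run, shared by the session."""
    base = tmp_path_factory.mktemp("study")
    paths, truth = generate_study(SimulationConfig(seed=STUDY_SEED), base / "inputs")
    cfg = PipelineConfig.for_study(base / "inputs", base / "out", seed=STUDY_SEED)
    summary = run_pipeline(cfg)
    table = read_site_table(cfg.out("site_table.tsv"))
    return {
        "cfg": cfg,
        "paths": paths,
        "truth": truth,
        "summary": summary,
        "table": table,
    }
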