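import pathlib

import pytest

from qremap.pipeline import RunConfig, run_pipeline
from qremap.simulate import SimConfig, simulate_fixture

FIXTURE_SEED = 11


@pytest.fixture(scope="session")
def sim_dir(tmp_path_factory) -> pathlib.Path:
    """Default-condition synthetic fixture, generated once per session."""
    d = tmp_path_factory.mktemp("fixture")
    simulate_fixture(SimConfig(seed=FIXTURE_SEED), d)
    return d


@pytest.fixture(scope="session")
def sim_truth(sim_dir):
    from qremap.simulate import TruthTable

    return TruthTable.from_json(sim_dir / "truth.json")


def make_run_config(sim_dir: pathlib.Path, outdir: pathlib.Path, **overrides) -> RunConfig:
    kwargs = dict(
        genome=str(sim_dir / "genome.fa"),
        annotation=str(sim_dir / "annotation.gtf"),
        sites=str(sim_dir / "mirna_sites.tsv"),
        mirna_expression=str(sim_dir / "mirna_expression.tsv"),
        peaks={
            "rep1": str(sim_dir / "eclip_rep1.narrowPeak"),
            "rep2": str(sim_dir / "eclip_rep2.narrowPeak"),
        },
        outdir=str(outdir),
    )
    kwargs.update(overrides)
    return RunConfig(**kwargs)


@pytest.fixture(scope="session")
def pipeline_result(sim_dir, tmp_path_factory):
    """Full pipeline run over the session fixture."""
    outdir = tmp_path_factory.mktemp("pipeline_out")
    return run_pipeline(make_run_config(sim_dir, outdir))
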