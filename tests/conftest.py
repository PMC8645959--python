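import pytest

from spinecouple import CoupledPipeline
from spinecouple.config import PipelineConfig
from spinecouple.motions import COUPLED_MOTIONS
from spinecouple.pipeline import VARIANTS


@pytest.fixture(scope="session")
def pipeline():
    return CoupledPipeline(PipelineConfig())


@pytest.fixture(scope="session")
def geometry(pipeline):
    return pipeline.geometry


@pytest.fixture(scope="session")
def fascicles(pipeline):
    return pipeline.fascicles


@pytest.fixture(scope="session")
def run_matrix(pipeline):
    """Full A->B->C coupling runs for both variants and all four motions."""
    return {(variant, motion): pipeline.run(variant, motion)
            for variant in VARIANTS for motion in COUPLED_MOTIONS}
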