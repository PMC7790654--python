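"""Shared study configuration for the numbered analysis scripts.

Every script drives the same seeded synthetic study (the bundled scenario:
100 x 100 grid of 2.5 arc-minute cells, three autocorrelated predictors,
500 expected presences) through the pipeline stages it needs. Stages cache
their artifacts under results/run, so the scripts can be run in order or
individually; an earlier stage rerun is a cheap cache hit.
"""

from pathlib import Path

from ppmsdm import pipeline

RESULTS = Path(__file__).resolve().parent.parent / "results"
RUN_DIR = RESULTS / "run"
STUDY_SEED = 42


def study_config() -> pipeline.RunConfig:
    return pipeline.RunConfig(seed=STUDY_SEED)


def study_run() -> pipeline.PipelineRun:
    RUN_DIR.mkdir(parents=True, exist_ok=True)
    return pipeline.PipelineRun(study_config(), RUN_DIR)
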