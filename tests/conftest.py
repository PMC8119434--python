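"""Shared fixtures: one default synthetic study, generated and analysed once."""

from __future__ import annotations

import numpy as np
import pytest

from vectorvirome.io_formats import PipelineConfig
from vectorvirome.pipeline import run_study
from vectorvirome.synthetic_data import (SpeciesSpec, StudySpec, gen_study)

STUDY_SEED = 1


@pytest.fixture(scope="session")
def study_bundle():
    """Default-design study: 3 species x 2 datasets with ground truth."""
    return gen_study(seed=STUDY_SEED)


@pytest.fixture(scope="session")
def study_results(study_bundle):
    """Full pipeline output over the default study."""
    return run_study(study_bundle, PipelineConfig(rng_seed=STUDY_SEED))


def tiny_study_spec() -> StudySpec:
    """A small two-species design for fast pipeline-level tests."""
    return StudySpec(
        species=(
            SpeciesSpec("MEAM1", n_datasets=1, core_virus="core_MEAM1",
                        core_segments=(800,)),
            SpeciesSpec("MED", n_datasets=1, core_virus="core_MED",
                        core_segments=(950,)),
        ),
        n_viral_reads=3000, n_host_reads=200, n_decoys=2, decoy_len=600,
        srna_n_reads=1500,
    )


def random_dna(n: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
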