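import logging

import numpy as np
import pandas as pd
import pytest

from redoxsig.normalize import (
    filter_completeness,
    median_center_rows,
    sequential_batch_correct,
)
from redoxsig.quantify import (
    ROLE_PARTICIPANT,
    PlexDesign,
    abundance_correct,
    assemble_matrix,
)
from redoxsig.synthetic import SimConfig, simulate_study

logging.getLogger("redoxsig").setLevel(logging.ERROR)


def noise_free_config(**overrides) -> SimConfig:
    """Default design with every stochastic nuisance switched off."""
    base = dict(
        noise_sd=0.0,
        channel_loading_sd=0.0,
        plex_batch_location_sd=0.0,
        plex_batch_scale_range=(1.0, 1.0),
        collection_site_batch_sd=0.0,
        abundance_log2_sd=0.0,
        missing_rate_mcar=0.0,
        mnar_slope=0.0,
        phenotype_missing_rate=0.0,
    )
    base.update(overrides)
    return SimConfig(**base)


def small_config(**overrides) -> SimConfig:
    """Smaller background set for fast unit tests."""
    base = dict(n_background_proteins=60)
    base.update(overrides)
    return SimConfig(**base)


def participant_sample_map(study):
    return {
        (d.plex_id, ch): sid
        for d in study.designs
        for ch, (sid, role) in d.channels.items()
        if role == ROLE_PARTICIPANT
    }


def sample_global_medians(study):
    sm = participant_sample_map(study)
    return {
        sm[(p, ch)]: med
        for p, meds in study.global_medians.items()
        for ch, med in meds.items()
        if (p, ch) in sm
    }


def analysis_ready_matrix(study, tau=0.75):
    """Standard preprocessing chain up to the analysis-ready matrix."""
    matrix = assemble_matrix(study.tables, study.designs)
    matrix, _ = abundance_correct(matrix, sample_global_medians(study))
    cohort = study.cohort.set_index("participant_id")
    plex = pd.Series({
        sid: d.plex_id for d in study.designs
        for ch, (sid, role) in d.channels.items() if role == ROLE_PARTICIPANT
    })
    site = cohort["biopsy_site"].reindex(matrix.data.columns)
    matrix, _ = sequential_batch_correct(matrix, plex, site)
    matrix = filter_completeness(matrix, tau)
    return median_center_rows(matrix)


@pytest.fixture(scope="session")
def default_study():
    return simulate_study(SimConfig(seed=11))


@pytest.fixture(scope="session")
def small_study():
    return simulate_study(small_config(seed=5))


@pytest.fixture(scope="session")
def small_ready(small_study):
    return analysis_ready_matrix(small_study)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
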