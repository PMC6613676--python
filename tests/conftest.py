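"""Shared fixtures: small synthetic records and session-scoped studies.

The two study fixtures are deliberately session-scoped: generating and
measuring ~1000 synthetic ECGs takes tens of seconds, and several tests
share the same study conditions (reduced designs of 8 subjects x 8
timepoints x triplicates).
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from tvv import pipeline
from tvv.io import BeatAnnotation, EcgRecord
from tvv.synthetic import (
    GROUP1_ARMS,
    GROUP2_ARMS,
    DipoleBeatParams,
    RepolWarp,
    discrimination_design,
    forward_project_12lead,
    recovery_design,
    simulate_dipole_beat,
    simulate_study,
)

warnings.filterwarnings("ignore", module="statsmodels")


def make_noiseless_record(beat, n_beats: int = 5, **meta) -> EcgRecord:
    """Tile one synthetic beat into a clean 12-lead record."""
    xyz = np.tile(beat.vcg_xyz, (1, n_beats))
    leads = forward_project_12lead(xyz)
    a, bl = beat.annotation, beat.n_samples
    beats = [
        BeatAnnotation(a.p_idx + k * bl, a.q_idx + k * bl, a.j_idx + k * bl,
                       a.tend_idx + k * bl, rr_ms=beat.params.rr_ms)
        for k in range(n_beats)
    ]
    return EcgRecord(signals=leads, sampling_rate=beat.params.fs, beats=beats,
                     **meta)


@pytest.fixture()
def default_beat():
    return simulate_dipole_beat(DipoleBeatParams(),
                                warp=RepolWarp(base_duration_ms=230.0))


@pytest.fixture()
def clean_record(default_beat):
    return make_noiseless_record(default_beat)


@pytest.fixture(scope="session")
def recovery_study():
    """Reduced 5-period recovery study (placebo/null/hERG/sodium/combined)."""
    study = simulate_study(recovery_design(), seed=11)
    table = pipeline.biomarker_table(study.records)
    corrected, rate_results = pipeline.rate_corrected_table(table)
    return {"study": study, "table": table, "corrected": corrected,
            "rate_results": rate_results}


@pytest.fixture(scope="session")
def discrimination_fixture():
    """Reduced group I vs group II study with labelled ddP observations."""
    study = simulate_study(discrimination_design(), seed=7)
    table = pipeline.biomarker_table(study.records)
    corrected, _ = pipeline.rate_corrected_table(table)
    obs = pipeline.discrimination_observations(
        corrected, list(GROUP1_ARMS), list(GROUP2_ARMS))
    return {"study": study, "corrected": corrected, "observations": obs}
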