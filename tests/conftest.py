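import numpy as np
import pytest

from emgfpca import AnalysisConfig, EmgRecording, SimulationParams
from emgfpca.preprocessing import NormalizedCurve


@pytest.fixture
def grid():
    return np.linspace(0.0, 100.0, 101)


@pytest.fixture
def config():
    return AnalysisConfig()


def make_curve(values, grid=None, subject="S01", group="elite",
               leg="supporting", muscle="rectus_femoris", trial=1):
    values = np.asarray(values, float)
    if grid is None:
        grid = np.linspace(0.0, 100.0, values.size)
    return NormalizedCurve(
        grid=grid, values=values, subject_id=subject, group=group,
        leg=leg, muscle=muscle, trial=trial,
    )


def make_recording(samples, fs=2000.0, stage="raw", subject="S01",
                   group="elite", leg="supporting",
                   muscle="rectus_femoris", trial=1):
    return EmgRecording(
        subject_id=subject, group=group, leg=leg, muscle=muscle,
        trial=trial, fs=fs, samples=np.asarray(samples, float), stage=stage,
    )


def cohort_curves(cohort):
    """Simulated envelope recordings as NormalizedCurve objects (no
    amplitude normalization), for direct FPCA on the generative scale."""
    grid = cohort.params.grid
    return [
        NormalizedCurve(
            grid=grid, values=r.samples, subject_id=r.subject_id,
            group=r.group, leg=r.leg, muscle=r.muscle, trial=r.trial,
        )
        for r in cohort.recordings
    ]


@pytest.fixture
def small_cohort_params():
    return SimulationParams(
        n_per_group=5, n_trials=3, muscles=("rectus_femoris",),
        legs=("supporting",), seed=11,
    )
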