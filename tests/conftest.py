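"""Shared fixtures: the simulated study cohort, built once per session.

The heavy fixtures mirror the study's acquisition - 7 subjects x 5 runs of
the 460 s finger-opposition paradigm on the dual 4x8 pads, with two runs
contaminated so channel QC rejects them (33 accepted runs) - and feed the
end-to-end classification tests.  Runs are simulated and preprocessed one
at a time so raw 39 Hz recordings never accumulate in memory.
"""

import pytest

from nirsblock.geometry import build_motor_layout, enumerate_channels
from nirsblock.preprocess import (
    WindowedDataset,
    discard_long_channels,
    preprocess_run,
)
from nirsblock.simulate import iter_study_runs, study_cohort_plan

COHORT_SEED = 7


@pytest.fixture(scope="session")
def motor_geometry():
    layout = build_motor_layout()
    table = enumerate_channels(layout, max_nn=3)
    return layout, table


@pytest.fixture(scope="session")
def study_dataset(motor_geometry):
    """33 accepted runs -> pooled windowed dataset (1023 examples)."""
    layout, table = motor_geometry
    _, contaminated = study_cohort_plan(seed=COHORT_SEED)
    windowed = []
    n_rejected = 0
    for run in iter_study_runs(layout, table, seed=COHORT_SEED):
        wr, qc = preprocess_run(run, table)
        if wr is None:
            n_rejected += 1
            continue
        windowed.append(wr)
    ds = WindowedDataset.from_runs(windowed, discard_long_channels(table)[0])
    ds.n_rejected_runs = n_rejected
    ds.contaminated = contaminated
    return ds
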