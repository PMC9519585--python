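"""Shared fixtures: a small, fast synthetic subject.

The small world uses an 8 x 6 grid (48 vertices), 2 runs of 60 timepoints
and 80 non-ROI sources per block, which keeps every pipeline stage under a
second while preserving the structural constraints (runs splittable
odd/even, more stacked sources than timepoints per split).
"""

import numpy as np
import pytest

import connectopy as cp


@pytest.fixture(scope="session")
def small_grid():
    return cp.make_retinotopic_grid((8, 6))


@pytest.fixture(scope="session")
def small_config():
    return cp.SimulationConfig(
        grid_shape=(8, 6),
        timepoints_per_run=60,
        n_runs=2,
        correlation_length=1.5,
        noise_sd=0.5,
        n_nonroi_sources=80,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_subject(small_grid, small_config):
    """(roi_ts, sources dict, latents) for the small world."""
    roi, latents = cp.simulate_roi_timeseries(
        small_grid, small_config, return_latents=True
    )
    sources = {
        "cortex": cp.simulate_nonroi_timeseries(latents, small_config, "cortex"),
        "subcortex": cp.simulate_nonroi_timeseries(latents, small_config, "subcortex"),
    }
    return roi, sources, latents


@pytest.fixture(scope="session")
def small_fingerprints(small_subject):
    """Fingerprints (source mode 'all') from the odd split of the small world."""
    roi, sources, _ = small_subject
    odd_roi, _ = cp.split_odd_even(roi)
    odd_sources = {k: cp.split_odd_even(v)[0] for k, v in sources.items()}
    return cp.build_connectivity(odd_roi, odd_sources, mode="all")


@pytest.fixture(scope="session")
def grid_coords():
    """Noise-free 2-D grid coordinates of a 12 x 10 sheet (n=120)."""
    ii, jj = np.meshgrid(np.arange(12, dtype=float), np.arange(10, dtype=float),
                         indexing="ij")
    return np.column_stack([ii.ravel(), jj.ravel()])
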