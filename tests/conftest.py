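"""Shared fixtures and independent brute-force oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from arimap import GeneratorConfig, generate_cohort, measure_dataset
from arimap.beats import smoothed


def brute_force_extremum_index(samples, fs, i0, i1, kind, lpf_hz):
    """Per-sample scan for the finite-difference derivative extremum.

    Independent of the detector's vectorized search path: smooths the trace,
    then walks every sample of the window computing the central difference
    and tracking the running extremum with the earliest-tie rule.
    """
    s = smoothed(np.asarray(samples, dtype=float), fs, lpf_hz)
    best_idx = None
    best_val = None
    for i in range(i0, i1 + 1):
        d = (s[i + 1] - s[i - 1]) / 2.0
        better = (best_val is None
                  or (d < best_val if kind == "min" else d > best_val))
        if better:
            best_val = d
            best_idx = i
    return best_idx


def expand_frontier(grid, core):
    """Set-expansion oracle for the border zone: scan all lead pairs for
    4-neighborhood adjacency to the core, independent of the package's
    adjacency-list construction."""
    pos = {row.lead: (row.row, row.col) for row in grid.itertuples()}
    border = set()
    for lead, (r, c) in pos.items():
        if lead in core:
            continue
        for other in core:
            ro, co = pos[other]
            if abs(r - ro) + abs(c - co) == 1:
                border.add(lead)
                break
    return border


@pytest.fixture(scope="session")
def small_cohort():
    """Three-animal cohort with signals at default noise."""
    return generate_cohort(GeneratorConfig(n_animals=3, seed=101))


@pytest.fixture(scope="session")
def small_measurements(small_cohort):
    return measure_dataset(small_cohort.traces)


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Two-animal noiseless cohort (epicardial only) for exact recovery checks."""
    return generate_cohort(GeneratorConfig(
        n_animals=2, seed=202, noise_sd=0.0, include_ecg=False))
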