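"""Shared fixtures: scaled-down imaging cohorts that keep the suite fast.

The image fixtures use a coarser lateral grid (120 nm instead of 60 nm), a
smaller nucleus and shorter fibers than the full acquisition defaults; the
geometry and noise structure are unchanged, only the problem size shrinks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from chromofold.morphology import measure_domain
from chromofold.synthetic import SceneSpec, generate_cohort

COARSE = dict(
    voxel_spacing=(0.2, 0.12, 0.12),
    nucleus_radius=2.2,
    sphere_radius=0.8,
    array_amplitude=200.0,
    nucleoplasm_level=20.0,
    gaussian_noise_sigma=10.0,  # 5% of array amplitude
)


def coarse_sphere_spec(**overrides) -> SceneSpec:
    kw = {**COARSE, "shape_kind": "sphere"}
    kw.update(overrides)
    return SceneSpec(**kw)


def coarse_fiber_spec(**overrides) -> SceneSpec:
    kw = {**COARSE, "shape_kind": "fiber", "fiber_length": 12.0}
    kw.update(overrides)
    return SceneSpec(**kw)


@pytest.fixture(scope="session")
def sphere_fiber_cohort() -> tuple[pd.DataFrame, pd.DataFrame]:
    """30 compact + 30 unfolded synthetic cells, measured end to end.

    Returns (measured cohort table, generator manifest with ground truth).
    """
    stacks, manifest = generate_cohort(
        [coarse_sphere_spec(), coarse_fiber_spec()],
        n_per_spec=30,
        master_seed=7,
        labels=["sphere", "fiber"],
        oversample=2,
    )
    rows = []
    for stack, (_, m) in zip(stacks, manifest.iterrows()):
        dom = measure_domain(stack, "lacR")
        rows.append({
            "cell_id": m["cell_id"],
            "construct_label": m["construct_label"],
            "true_surface_factor": m["true_surface_factor"],
            **dom.as_row(),
        })
    return pd.DataFrame(rows), manifest
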