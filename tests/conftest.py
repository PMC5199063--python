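"""Shared fixtures: small synthetic volumes, masks and feature tables.

Everything is generated programmatically at test time; no binary fixtures.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from qifagree import (
    FeatureTable,
    ImageVolume,
    PhantomSpec,
    SegmentationMask,
    generate_phantom,
)


@pytest.fixture(scope="session")
def ball_volume_mask():
    """Digital ball of radius 5 mm on a 0.5 mm isotropic grid, uniform interior."""
    spec = PhantomSpec(
        semi_axes_mm=(5.0, 5.0, 5.0),
        lobulation_amplitude=0.0,
        texture_amplitude_hu=0.0,
        noise_sd_hu=0.0,
        seed=11,
    )
    return generate_phantom(spec, spacing_mm=0.5)


@pytest.fixture(scope="session")
def textured_lesion():
    """A textured lobulated lesion at 0.5 mm spacing for feature smoke tests."""
    spec = PhantomSpec(
        semi_axes_mm=(7.0, 8.0, 9.0),
        lobulation_amplitude=0.08,
        texture_amplitude_hu=50.0,
        edge_width_mm=0.8,
        noise_sd_hu=0.0,
        seed=23,
    )
    return generate_phantom(spec, spacing_mm=0.5)


def cube_mask(side_vox: int, pad: int = 4, spacing: float = 0.5) -> SegmentationMask:
    n = side_vox + 2 * pad
    arr = np.zeros((n, n, n), dtype=bool)
    arr[pad : pad + side_vox, pad : pad + side_vox, pad : pad + side_vox] = True
    return SegmentationMask(arr, (spacing,) * 3)


@pytest.fixture
def random_table():
    """Factory: random rectangular feature table (tumors x settings x features)."""

    def make(n_tumors=4, settings=("1.25L", "5S"), features=("f1", "f2", "f3"), seed=0):
        rng = np.random.default_rng(seed)
        records = []
        for t in range(n_tumors):
            for s in settings:
                for f in features:
                    records.append((f"T{t:02d}", s, f, float(rng.normal())))
        return FeatureTable.from_records(records)

    return make


@pytest.fixture
def synthetic_s1_export(tmp_path):
    """Synthetic stand-in for the supplementary 32x6x89 feature export.

    Synthetic: generated from seeded noise with realistic inter-feature
    correlation structure, used only to exercise the ingestion contract.
    """
    rng = np.random.default_rng(99)
    tumors = [f"Case{i + 1:02d}" for i in range(32)]
    settings = ["1.25L", "1.25S", "2.5L", "2.5S", "5L", "5S"]
    features = [f"QIF_{i + 1:03d}" for i in range(89)]
    base = rng.normal(size=(32, 89))
    rows = []
    for si, s in enumerate(settings):
        jitter = rng.normal(scale=0.3, size=(32, 89))
        vals = base + jitter + 0.1 * si
        for ti, t in enumerate(tumors):
            for fi, f in enumerate(features):
                rows.append((t, s, f, vals[ti, fi]))
    df = pd.DataFrame(rows, columns=["tumor", "setting", "feature", "value"])
    path = tmp_path / "s1_synthetic_export.csv"
    df.to_csv(path, index=False)
    return path
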