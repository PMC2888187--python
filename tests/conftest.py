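"""Shared fixtures: rendered fields and a calibrated positivity model.

Everything is generated at test time from the synthetic renderer with
fixed seeds; heavyweight artifacts are session-scoped so the pipeline
runs once per pattern, not once per test.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from hep2 import FieldSpec, render_field
from hep2.interpretation import interpret_field, calibrate


@pytest.fixture(scope="session")
def rendered():
    """Cache of (pattern, level, seed) -> (FieldOfView, GroundTruth)."""
    cache = {}

    def get(pattern, intensity=0.7, seed=42, **kw):
        key = (pattern, intensity, seed, tuple(sorted(kw.items())))
        if key not in cache:
            cache[key] = render_field(
                FieldSpec(pattern=pattern, intensity_level=intensity, seed=seed, **kw)
            )
        return cache[key]

    return get


@pytest.fixture(scope="session")
def negative_calibration():
    """Calibration from 60 synthetic normal-donor fields (U(0, 0.1) strength)."""
    rng = np.random.default_rng(11)
    ris = []
    for _ in range(60):
        level = float(rng.uniform(0, 0.1))
        seed = int(rng.integers(0, 2**31 - 1))
        fov, _ = render_field(FieldSpec(pattern="negative", intensity_level=level, seed=seed))
        ris.append(interpret_field(fov).ri.value)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return calibrate(ris)


@pytest.fixture(scope="session")
def field_aggregates(rendered):
    """Per-pattern FieldAggregate at intensity 0.7 (seed 42)."""
    aggs = {}
    for pattern in ("homogeneous", "speckled_fine", "speckled_coarse", "nucleolar",
                    "centromere", "nuclear_dots", "cytoplasmic", "nuclear_membrane",
                    "golgi"):
        fov, _ = rendered(pattern)
        aggs[pattern] = interpret_field(fov).aggregate
    return aggs
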