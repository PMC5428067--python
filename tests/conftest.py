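"""Shared fixtures: phantoms and expensive pipeline products are built once
per session and reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from wmgm4d.levelset import refine_intracranial
from wmgm4d.phantom import PhantomSpec, build_phantom, stroke_protocol, temporal_contrast_only_spec
from wmgm4d.pipeline import PipelineConfig, compare_variants, phantom_case, run_loocv
from wmgm4d.wta import weighted_temporal_average


@pytest.fixture(scope="session")
def default_phantom():
    """Default 96×96×64 phantom with the 19-acquisition protocol."""
    return build_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def default_wta(default_phantom):
    series, _ = default_phantom
    return weighted_temporal_average(series)


@pytest.fixture(scope="session")
def small_phantom():
    """A 48³ phantom for cheap unit tests."""
    return build_phantom(PhantomSpec(grid_shape=(48, 48, 48), rng_seed=7))


@pytest.fixture(scope="session")
def refined_intracranial(default_phantom, default_wta):
    """GAC refinement of the true intracranial mask on the default phantom."""
    _, truth = default_phantom
    return refine_intracranial(default_wta, truth.intracranial)


@pytest.fixture(scope="session")
def loocv_default():
    """3-case LOOCV on default phantoms (full feature set)."""
    cases = [phantom_case(PhantomSpec(rng_seed=i), f"case{i}") for i in range(3)]
    return run_loocv(PipelineConfig(seed=0), cases), cases


@pytest.fixture(scope="session")
def variant_comparison():
    """Full vs no-temporal LOOCV on phantoms whose WM/GM differ only temporally."""
    cases = [
        phantom_case(temporal_contrast_only_spec(PhantomSpec(rng_seed=i)), f"tcase{i}")
        for i in range(3)
    ]
    return compare_variants(PipelineConfig(seed=0), cases, n_boot=1000)
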