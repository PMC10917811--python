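"""Shared fixtures: small scenes and layouts for desk-scale pipeline runs."""

import numpy as np
import pytest

from nuctrans import ImageField, OpticsSpec, ResponseModel, SceneSpec


@pytest.fixture
def small_scene() -> SceneSpec:
    """A reduced field (crop of the binned sensor) for fast pipeline tests."""
    return SceneSpec(field_shape=(320, 384), n_cells_mean=16)


@pytest.fixture
def ideal_optics() -> OpticsSpec:
    return OpticsSpec.ideal()


@pytest.fixture
def default_optics() -> OpticsSpec:
    return OpticsSpec()


@pytest.fixture
def dose_model() -> ResponseModel:
    return ResponseModel()


def make_field(nuclear: np.ndarray, gfp: np.ndarray, **kw) -> ImageField:
    return ImageField(
        channels={"nuclear_marker": nuclear.astype(float), "gfp": gfp.astype(float)},
        **kw,
    )
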