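"""Shared fixtures: quick-study phantoms generated once per session."""

from __future__ import annotations

import numpy as np
import pytest

import shrinkvec as sv


@pytest.fixture(scope="session")
def small_contraction_pair():
    """72³ phantom pair with a 1% contraction, no pose, no noise."""
    spec = sv.small_spec(seed=101)
    deformation = sv.DeformationModel(kind="uniform_contraction",
                                      center=spec.floor_center,
                                      contraction_fraction=0.01)
    pre, post, truth = sv.generate_phantom(spec, deformation, None)
    return spec, deformation, pre, post, truth


@pytest.fixture(scope="session")
def small_static_pair():
    """72³ phantom pair with no deformation, no pose, no noise."""
    spec = sv.small_spec(seed=202)
    pre, post, truth = sv.generate_phantom(spec, None, None)
    return spec, pre, post, truth


@pytest.fixture()
def cavity_mask_for(small_static_pair):
    spec, pre, _, _ = small_static_pair

    def _make(volume, transform=None, margin=2.0):
        cav = (spec.cavity_axis_xy[0], spec.cavity_axis_xy[1],
               spec.cavity_top_z)
        return sv.make_cavity_mask(volume, cav, spec.cavity_diameter,
                                   spec.cavity_depth, margin_voxels=margin,
                                   transform=transform)

    return _make


@pytest.fixture()
def rng():
    return np.random.default_rng(20210127)
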