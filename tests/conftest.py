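"""Shared fixtures: synthetic scenes and small hand-built objects."""

from __future__ import annotations

import numpy as np
import pytest

import punctaloc as pl
from punctaloc.cli import DEFAULT_CONFIG, run_coloc_stack


@pytest.fixture(scope="session")
def default_scene():
    """One default synthetic scene (256x256x20, c = 0.5), fixed seed."""
    return pl.generate_stack(seed=1)


@pytest.fixture(scope="session")
def pipeline_result(default_scene):
    """Full colocalization pipeline output on the default scene."""
    stack, _ = default_scene
    return run_coloc_stack(stack, DEFAULT_CONFIG, seed=1)


@pytest.fixture(scope="session")
def small_scene_params():
    """A compact scene for fast I/O and CLI tests."""
    return pl.SceneParams(
        shape=(10, 128, 128),
        cell_radius=52.0,
        n_vacuoles=1,
        vacuole_radius=(6.0, 9.0),
        n_puncta_green=3,
        n_puncta_red=3,
        punctum_diameter_um=(0.8, 1.5),
        punctum_edge_margin=12.0,
        min_separation=6,
    )


def make_punctum(pid: int, channel: str, voxels, intensity_per_voxel: float = 1.0):
    """Build a Punctum3D from a list of (z, y, x) voxels (one slice per z)."""
    voxels = np.asarray(voxels, dtype=int)
    slices = []
    for z in sorted(set(voxels[:, 0].tolist())):
        pix = voxels[voxels[:, 0] == z][:, 1:]
        slices.append(
            pl.Punctum2D(
                layer=int(z),
                pixels=pix,
                intensity=intensity_per_voxel * len(pix),
                seed=(float(pix[0, 0]), float(pix[0, 1]), 1.0),
            )
        )
    return pl.Punctum3D(id=pid, channel=channel, slices=slices)


@pytest.fixture
def punctum_factory():
    return make_punctum
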