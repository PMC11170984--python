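"""Shared fixtures: analytic cell phantoms rendered without blur or noise
(so every expected intensity is known exactly) and small helpers."""

import numpy as np
import pytest

from memloc.synthgen import CellGroundTruth, ImagingModel, render_scene

CLEAN = dict(psf_sigma=0.0, background=50.0, read_noise_sd=0.0,
             shot_noise=False)


def make_cell(center=(48.0, 48.0), radius=25.0, eccentricity=0.0,
              orientation=0.0, shell=3.0, cyto=80.0, mem=131.0,
              gpit=600.0, nucleus=8.0, cell_id=0, group="healthy"):
    return CellGroundTruth(
        cell_id=cell_id, group=group, center=center, radius=radius,
        eccentricity=eccentricity, orientation=orientation,
        shell_thickness=shell, cyto_amp=cyto, mem_amp=mem, gpit_amp=gpit,
        nucleus_radius=nucleus)


def clean_scene(cells, canvas=(96, 96), background=50.0, psf_sigma=0.0):
    """Noise-free scene; with psf_sigma=0 every pixel value is analytic."""
    model = ImagingModel(psf_sigma=psf_sigma, background=background,
                         read_noise_sd=0.0, shot_noise=False)
    return render_scene(cells, model, canvas)


@pytest.fixture
def disk_cell():
    return make_cell()


@pytest.fixture
def disk_scene(disk_cell):
    return clean_scene([disk_cell])


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
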