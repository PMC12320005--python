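"""Shared fixtures: tiny handcrafted subjects and module-scoped synthetic ones."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from strokefc.io_core import SubjectContext, VolumeImage
from strokefc.synthdata import SynthParams, generate_subject


def make_tiny_ctx(shape=(8, 8, 4), lesion_voxels=(), wm_prob=None, csf_prob=None,
                  gm_prob=None, affected_side="left", n_volumes=20):
    """Fully handcrafted SubjectContext on a small grid.

    Default tissue layout: CSF at x<2, WM at x>=6, GM in between.
    """
    affine = np.eye(4)
    brain = np.ones(shape, dtype=np.int16)
    csf = np.zeros(shape)
    wm = np.zeros(shape)
    gm = np.zeros(shape)
    csf[:2] = 1.0
    wm[6:] = 1.0
    gm[2:6] = 1.0
    if csf_prob is not None:
        csf = csf_prob
    if wm_prob is not None:
        wm = wm_prob
    if gm_prob is not None:
        gm = gm_prob
    lesion = np.zeros(shape, dtype=np.int16)
    for vox in lesion_voxels:
        lesion[tuple(vox)] = 1
    motion = pd.DataFrame(
        np.zeros((n_volumes, 6)), columns=list(SubjectContext.MOTION_COLUMNS))
    return SubjectContext(
        brain_mask=VolumeImage(brain, affine, name="brain_mask"),
        gm_prob=VolumeImage(gm, affine, name="gm_prob"),
        wm_prob=VolumeImage(wm, affine, name="wm_prob"),
        csf_prob=VolumeImage(csf, affine, name="csf_prob"),
        lesion_mask=VolumeImage(lesion, affine, name="lesion_mask"),
        affected_side=affected_side,
        motion=motion,
    )


@pytest.fixture(scope="session")
def default_subject():
    """Plain synthetic subject: no artifact spread, no lags."""
    return generate_subject(SynthParams(seed=7))


@pytest.fixture(scope="session")
def artifact_subject():
    """Subject with a GM lesion carrying an artifact bled into 3 remote regions."""
    params = SynthParams(seed=11, lesion_n_voxels=250, artifact_amplitude=2.0,
                         n_contaminated_regions=3, contamination_amplitude=1.0,
                         noise_sd=0.5)
    return params, generate_subject(params)


@pytest.fixture(scope="session")
def lag_subject():
    """Subject with an injected integer-TR lag field and a shared global signal."""
    params = SynthParams(seed=5, lag_values_trs=(-2, -1, 0, 1, 2),
                         lag_zero_frac=0.6, global_amplitude=0.7, noise_sd=0.0)
    return params, generate_subject(params)
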