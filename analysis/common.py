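"""Shared study configuration for the analysis scripts.

One synthetic cohort stands in for a population of imaged subjects: a
straight white-matter-like bundle (FA 0.6, MD 0.7e-3 mm^2/s, 4 mm radius)
in a 32^3 grid of 1 mm voxels, perturbed per subject by a rigid tilt
(SD 10 degrees) and an FA offset (SD 0.05). The desk-scale cohort size is
25 subjects so every script finishes in seconds; the dispersion-recovery
test in the package's suite runs the same pipeline at n = 485.
"""

from pathlib import Path

import numpy as np

from axonvar import synthetic_data as sd
from axonvar import tensor_fit as tf

RESULTS = Path(__file__).resolve().parent.parent / "results"

N_SUBJECTS = 25
ANGLE_SD_DEG = 10.0
FA_SD = 0.05
SEED = 20260923

ROI_LABEL = 1

SPEC = sd.PhantomSpec(
    bundle_kind="straight",
    extent=28.0,
    bundle_radius=4.0,
    fa_inside=0.6,
    fa_outside=0.0,
    grid_shape=(32, 32, 32),
    voxel_size=1.0,
)
POP = sd.PopulationSpec(
    n_subjects=N_SUBJECTS, angle_sd=ANGLE_SD_DEG, fa_sd=FA_SD, seed=SEED
)


def gradient_table(n_dirs: int = 32, b: float = 1000.0) -> tf.GradientTable:
    """One b = 0 volume plus quasi-uniform single-shell directions."""
    i = np.arange(n_dirs) + 0.5
    phi = np.arccos(1 - 2 * i / n_dirs)
    theta = np.pi * (1 + 5**0.5) * i
    dirs = np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1
    )
    return tf.GradientTable(
        np.r_[0.0, np.full(n_dirs, b)], np.vstack([np.zeros(3), dirs])
    )


def cohort() -> list[sd.SubjectPhantom]:
    return sd.make_population(SPEC, POP)
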