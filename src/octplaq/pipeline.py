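"""End-to-end convenience wrappers: phantom -> lumen -> optics -> features.

These functions wire the pipeline stages together for simulation studies;
each stage remains available individually.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .lumen import detect_guidewire_shadow, segment_lumen
from .optics import SystemParams, attenuation_map, estimate_noise_floor
from .phantom import PhantomSpec, generate_phantom, phantom_suite_specs
from .texture import build_feature_stack

__all__ = ["process_phantom", "make_study_stacks"]


def process_phantom(spec: PhantomSpec, params_by_label=None,
                    sys: SystemParams | None = None,
                    pixels_per_image: int | None = None,
                    use_true_boundary: bool = False,
                    seed: int = 0) -> pd.DataFrame:
    """Render one phantom and run the full feature pipeline on it.

    Lumen segmentation and guide-wire detection run on the rendered image
    (set ``use_true_boundary`` to bypass them with the simulator's ground
    truth).  If ``pixels_per_image`` is given, that many ROI pixels are
    subsampled uniformly at random (seeded) to keep feature extraction and
    training tractable.  Returns the feature stack with a ``label`` column
    holding the true tissue label of each pixel.
    """
    img, labels, true_boundary = generate_phantom(spec, params_by_label, sys)
    sys = sys or SystemParams()
    if use_true_boundary:
        boundary = true_boundary
    else:
        shadow = detect_guidewire_shadow(img)
        boundary = segment_lumen(img, shadow)
    maps = attenuation_map(img, boundary, sys,
                           noise_floor=estimate_noise_floor(img, boundary))
    px = None
    if pixels_per_image is not None:
        rows, cols = np.nonzero(maps.roi)
        rng = np.random.default_rng(seed)
        take = min(pixels_per_image, rows.size)
        pick = rng.choice(rows.size, take, replace=False)
        px = np.stack([rows[pick], cols[pick]], axis=1)
    stack = build_feature_stack(img, maps, boundary, pixels=px)
    stack["label"] = labels.labels[stack["row"].to_numpy(),
                                   stack["col"].to_numpy()]
    # pixels outside annotated tissue (band extending past a thin sector)
    # carry no ground truth and are dropped from labelled stacks
    return stack[stack["label"] > 0].reset_index(drop=True)


def make_study_stacks(n_images: int = 50, n_patients: int = 10,
                      seed: int = 0, pixels_per_image: int = 600,
                      guidewire: bool = True):
    """Feature stacks for a multi-patient phantom study.

    Returns ``(stacks, patient_ids)``: one labelled feature stack per
    image, grouped into synthetic patients as in
    :func:`octplaq.phantom.phantom_suite_specs`.
    """
    specs = phantom_suite_specs(n_images, n_patients, seed=seed,
                                guidewire=guidewire)
    rng = np.random.default_rng(seed + 1)
    stacks, pids = [], []
    for spec, pid in specs:
        stacks.append(process_phantom(
            spec, pixels_per_image=pixels_per_image,
            seed=int(rng.integers(2 ** 31))))
        pids.append(pid)
    return stacks, pids
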