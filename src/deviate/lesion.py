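"""Lesion-mask algebra and template compositing.

Automated surface pipelines cannot extract cortical surfaces through a
lesion cavity, so the lesioned portion of a subject's T1 volume is replaced
by the corresponding portion of a co-registered template before processing;
thickness is then read out only over intact cortex. This module implements
the mask subtraction and the voxelwise compositing. Registration of the
template to the subject is deliberately left to external tools — the inputs
must already share one lattice, and mismatches are refused rather than
resampled.
"""

from __future__ import annotations

import warnings

import numpy as np

from .errors import DataError
from .volume import MaskVolume, VolumeImage


def _check_lattice(a: VolumeImage, b: VolumeImage, what: str) -> None:
    if not a.same_lattice(b):
        raise DataError(f"{what}: lattices differ (shape/affine mismatch)")


def subtract_mask(brain_mask: MaskVolume, lesion_mask: MaskVolume) -> MaskVolume:
    """Voxelwise ``brain AND NOT lesion`` on a shared lattice."""
    _check_lattice(brain_mask, lesion_mask, "subtract_mask")
    out = brain_mask.as_bool & ~lesion_mask.as_bool
    return MaskVolume(out.astype(np.float64), brain_mask.affine.copy(), tag="composite-support")


def composite_brain(
    subject: VolumeImage,
    template: VolumeImage,
    lesion_mask: MaskVolume,
    blend_intensity: bool = False,
) -> VolumeImage:
    """Replace lesioned voxels of the subject with the template's.

    ``out(v) = template(v)`` where the mask is 1, else ``subject(v)``.
    With ``blend_intensity`` the template is first linearly rescaled so its
    median over non-lesion brain voxels (both volumes positive) matches the
    subject's, avoiding a visible seam when intensities are miscalibrated.
    Voxels outside the mask are bit-identical to the subject input.
    """
    _check_lattice(subject, lesion_mask, "composite_brain(subject, mask)")
    _check_lattice(subject, template, "composite_brain(subject, template)")
    m = lesion_mask.as_bool
    if m.all():
        warnings.warn("lesion mask covers the whole volume; output is pure template",
                      stacklevel=2)
    tdata = template.data
    if blend_intensity:
        support = ~m & (subject.data > 0) & (template.data > 0)
        if support.any():
            t_med = np.median(template.data[support])
            if t_med > 0:
                tdata = template.data * (np.median(subject.data[support]) / t_med)
        else:
            warnings.warn("no overlapping brain voxels to calibrate intensities on",
                          stacklevel=2)
    out = subject.data.copy()
    out[m] = tdata[m]
    return VolumeImage(out, subject.affine.copy())
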