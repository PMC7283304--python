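"""Bring a reference infarct mask onto the CTP grid and define the
evaluable voxel set.

Real acquisitions deliver the follow-up infarct mask on its own grid; it
is reformatted to the CTP voxel dimensions with nearest-neighbour
resampling (the conventional choice for label images — it preserves
binarity).  Registration itself is delegated: masks must already be in
CTP space.  Synthetic subjects share a grid, so resampling is the
identity there.  Brain not covered by the CTP field of view is excluded
from every downstream overlap statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["EvaluationMask", "EmptyEvaluationError", "resample_mask", "make_eval_mask"]


class EmptyEvaluationError(RuntimeError):
    """Raised when no voxel at all is evaluable (empty coverage∩valid)."""


@dataclass
class EvaluationMask:
    """The reference mask on the CTP grid plus the evaluable voxel set."""

    fiv_on_ctp: np.ndarray   # bool, reference infarct mask on the CTP grid
    eval_mask: np.ndarray    # bool, coverage ∩ valid

    def __post_init__(self) -> None:
        if self.fiv_on_ctp.shape != self.eval_mask.shape:
            raise ValueError("mask shapes must agree")


def resample_mask(
    mask: np.ndarray,
    affine: np.ndarray,
    target_shape: tuple[int, int, int],
    target_affine: np.ndarray,
) -> np.ndarray:
    """Nearest-neighbour resampling of a binary mask between voxel grids.

    ``affine`` / ``target_affine`` map voxel indices to world (mm)
    coordinates, as in NIfTI headers.  Resampling a mask onto its own grid
    is the identity.  Non-overlapping fields of view produce an all-zero
    mask and a warning.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.shape == tuple(target_shape) and np.allclose(affine, target_affine):
        return mask.copy()
    # voxel_target -> world -> voxel_source
    trans = np.linalg.inv(affine) @ target_affine
    out = ndimage.affine_transform(
        mask.astype(np.uint8),
        matrix=trans[:3, :3],
        offset=trans[:3, 3],
        output_shape=tuple(target_shape),
        order=0,
        mode="constant",
        cval=0,
    ).astype(bool)
    if mask.any() and not out.any():
        warnings.warn(
            "resampled mask is empty: source and target fields of view "
            "do not overlap on the reference region",
            stacklevel=2,
        )
    return out


def make_eval_mask(study, map_set) -> np.ndarray:
    """Evaluable voxels: CTP coverage ∩ valid deconvolution.

    Reference-mask voxels outside this set are dropped from all confusion
    counts downstream.
    """
    if study.coverage_mask.shape != map_set.valid_mask.shape:
        raise ValueError("study and map set live on different grids")
    eval_mask = study.coverage_mask & map_set.valid_mask
    if not eval_mask.any():
        raise EmptyEvaluationError(
            f"subject {study.subject_id}: no evaluable voxels "
            "(empty coverage ∩ valid)"
        )
    return eval_mask
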