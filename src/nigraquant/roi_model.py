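"""ROI algebra for the SNc measurement rules.

The measurement protocol works on a consensus ("mean") ROI between two raters,
restricted to the three lowest axial slices where the SNc is visible, split by
hemisphere, and intersected with regional functional-territory templates
(sensorimotor, associative, limbic).  This module implements exactly those set
operations; it performs no registration and no resampling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .imaging_io import GeometryError, RoiMask, check_same_geometry

__all__ = [
    "SliceSet",
    "SliceSelectionError",
    "TemplateError",
    "consensus_mask",
    "select_lowest_slices",
    "split_hemispheres",
    "regional_intersection",
    "REGION_LABELS",
]

logger = logging.getLogger(__name__)

REGION_LABELS = ("sensorimotor", "associative", "limbic")


class SliceSelectionError(ValueError):
    """No contiguous run of >= 3 non-empty axial slices exists."""


class TemplateError(ValueError):
    """Regional template masks overlap when they must be disjoint."""


@dataclass(frozen=True)
class SliceSet:
    """Three contiguous axial slice indices, most inferior first."""

    indices: tuple[int, int, int]

    def __post_init__(self) -> None:
        idx = tuple(int(i) for i in self.indices)
        if len(idx) != 3:
            raise ValueError(f"a SliceSet holds exactly 3 indices, got {idx}")
        if not (idx[0] + 1 == idx[1] and idx[1] + 1 == idx[2]):
            raise ValueError(f"slice indices must be contiguous and increasing, got {idx}")
        if idx[0] < 0:
            raise ValueError(f"slice indices must be non-negative, got {idx}")
        object.__setattr__(self, "indices", idx)

    def __iter__(self):
        return iter(self.indices)


def consensus_mask(rater1: RoiMask, rater2: RoiMask, threshold: float = 0.5) -> RoiMask:
    """Mean ROI between two raters, thresholded to a binary consensus.

    The voxelwise mean of two binary masks is kept where it reaches
    ``threshold``.  With the default inclusive 0.5 this is the raters' union,
    the common dialect of mask-averaging command-line tools; ``threshold``
    slightly above 0.5 yields the intersection instead.
    """
    check_same_geometry(rater1, rater2, "rater masks")
    mean = (rater1.data.astype(np.float32) + rater2.data.astype(np.float32)) / 2.0
    return RoiMask(
        data=mean >= threshold, voxel_size_mm=rater1.voxel_size_mm, label="consensus"
    )


def select_lowest_slices(mask: RoiMask) -> SliceSet:
    """Three most-inferior slices of the lowest contiguous run of visible SNc.

    Non-empty axial slices are scanned from the inferior end; the first
    contiguous run of length >= 3 is taken and its three lowest indices
    returned.  Isolated stray slices below that run are treated as
    segmentation noise and ignored.
    """
    nonempty = mask.nonempty_slices()
    if nonempty.size == 0:
        raise SliceSelectionError("mask is empty; no slices to select")
    # Partition the non-empty indices into maximal contiguous runs.
    breaks = np.flatnonzero(np.diff(nonempty) > 1)
    runs = np.split(nonempty, breaks + 1)
    for run in runs:  # runs are ordered inferior -> superior
        if run.size >= 3:
            return SliceSet(indices=(int(run[0]), int(run[1]), int(run[2])))
    raise SliceSelectionError(
        f"no contiguous run of >= 3 non-empty slices (non-empty slices: {nonempty.tolist()})"
    )


def split_hemispheres(mask: RoiMask, midline: int | None = None) -> tuple[RoiMask, RoiMask]:
    """Partition a bilateral mask into (left, right) at the grid x-midplane.

    Synthetic space is constructed midline-centered, so the default midline is
    ``nx // 2`` with voxels at ``x < midline`` labeled left.  For an odd grid
    the midline column is assigned to the left hemisphere and logged.  Real
    data with a different midline can pass it explicitly.
    """
    nx = mask.shape[0]
    if midline is None:
        if nx % 2:
            midline = nx // 2 + 1
            col = mask.data[nx // 2].sum()
            if col:
                logger.warning(
                    "odd x-extent %d: %d midline-column voxels assigned to the left hemisphere",
                    nx,
                    int(col),
                )
        else:
            midline = nx // 2
    left = np.zeros(mask.shape, dtype=bool)
    right = np.zeros(mask.shape, dtype=bool)
    left[:midline] = mask.data[:midline]
    right[midline:] = mask.data[midline:]
    return (
        RoiMask(data=left, voxel_size_mm=mask.voxel_size_mm, label="snc_left"),
        RoiMask(data=right, voxel_size_mm=mask.voxel_size_mm, label="snc_right"),
    )


def regional_intersection(
    whole: RoiMask, templates: dict[str, RoiMask]
) -> dict[str, RoiMask]:
    """Intersect a whole-SNc mask with the regional territory templates.

    ``templates`` maps region label -> mask; templates must be pairwise
    disjoint.  Returns possibly-empty masks, one per region.
    """
    names = list(templates)
    for name in names:
        check_same_geometry(whole, templates[name], f"whole mask and template {name!r}")
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            overlap = int(np.logical_and(templates[a].data, templates[b].data).sum())
            if overlap:
                raise TemplateError(
                    f"templates {a!r} and {b!r} overlap in {overlap} voxels"
                )
    out: dict[str, RoiMask] = {}
    for name in names:
        out[name] = RoiMask(
            data=np.logical_and(whole.data, templates[name].data),
            voxel_size_mm=whole.voxel_size_mm,
            label=templates[name].label,
        )
    return out
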