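"""Imaging measurements: CNR, volume, TIV-corrected volume, Dice, ICC.

The contrast-to-noise ratio of the SNc is computed per axial slice as
``(Sig_SNc - Sig_BND) / STD_BND`` — mean SNc intensity minus mean background
intensity, divided by the background standard deviation on that slice — and
averaged over the three selected slices.  Volume is the voxel count of the ROI
on those slices times the voxel volume; the corrected volume C_vol divides the
volume (mm^3) by total intracranial volume (mL) to normalise for head size.
Reliability between segmentations is summarised by the Dice overlap and a
two-way absolute-agreement single-measurement intraclass correlation ICC(2,1).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .imaging_io import RoiMask, VolumeImage, check_same_geometry
from .roi_model import (
    REGION_LABELS,
    SliceSet,
    consensus_mask,
    regional_intersection,
    select_lowest_slices,
    split_hemispheres,
)

__all__ = [
    "MeasurementError",
    "SliceSignalStats",
    "HemiValue",
    "SncMeasures",
    "slice_signal_stats",
    "compute_cnr",
    "compute_volume",
    "corrected_volume",
    "subject_measures",
    "dice",
    "icc",
]

logger = logging.getLogger(__name__)


class MeasurementError(ValueError):
    """A measurement precondition is violated (empty ROI, zero SD, bad TIV)."""


@dataclass(frozen=True)
class SliceSignalStats:
    """Per-slice signal summaries entering the CNR formula."""

    slice_index: int
    sig_snc: float    # mean intensity inside the SNc ROI on this slice
    sig_bnd: float    # mean intensity inside the background ROI on this slice
    std_bnd: float    # sample SD (n-1 denominator) of the background intensities

    @property
    def cnr(self) -> float:
        return (self.sig_snc - self.sig_bnd) / self.std_bnd


def slice_signal_stats(
    image: VolumeImage, snc: RoiMask, background: RoiMask, slice_index: int
) -> SliceSignalStats:
    check_same_geometry(image, snc, "image and SNc mask")
    check_same_geometry(image, background, "image and background mask")
    plane = image.data[:, :, slice_index]
    snc_vals = plane[snc.data[:, :, slice_index]]
    bnd_vals = plane[background.data[:, :, slice_index]]
    if snc_vals.size == 0:
        raise MeasurementError(f"SNc ROI is empty on slice {slice_index}")
    if bnd_vals.size < 2:
        raise MeasurementError(
            f"background ROI has {bnd_vals.size} voxels on slice {slice_index}; need >= 2"
        )
    std_bnd = float(np.std(bnd_vals, ddof=1))
    if std_bnd == 0.0:
        raise MeasurementError(f"background SD is zero on slice {slice_index}")
    return SliceSignalStats(
        slice_index=int(slice_index),
        sig_snc=float(np.mean(snc_vals)),
        sig_bnd=float(np.mean(bnd_vals)),
        std_bnd=std_bnd,
    )


def compute_cnr(
    image: VolumeImage, snc: RoiMask, background: RoiMask, slices: SliceSet
) -> float:
    """Mean over the selected slices of (Sig_SNc - Sig_BND) / STD_BND."""
    return float(
        np.mean([slice_signal_stats(image, snc, background, s).cnr for s in slices])
    )


def compute_volume(mask: RoiMask, slices: SliceSet) -> float:
    """ROI volume in mm^3 on the selected slices (voxel count x voxel volume)."""
    count = int(mask.data[:, :, list(slices)].sum())
    return count * mask.voxel_volume_mm3


def corrected_volume(volume_mm3: float, tiv_ml: float) -> float:
    """C_vol: SNc volume (mm^3) divided by total intracranial volume (mL)."""
    if not tiv_ml > 0:
        raise MeasurementError(f"TIV must be positive, got {tiv_ml}")
    return float(volume_mm3) / float(tiv_ml)


def dice(a: RoiMask, b: RoiMask) -> float:
    """Dice overlap 2|A n B| / (|A| + |B|); two empty masks count as 1."""
    check_same_geometry(a, b, "masks")
    na, nb = a.count, b.count
    if na == 0 and nb == 0:
        warnings.warn("Dice of two empty masks defined as 1.0", stacklevel=2)
        return 1.0
    inter = int(np.logical_and(a.data, b.data).sum())
    return 2.0 * inter / (na + nb)


def icc(session1, session2) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measurement.

    Computed from the two-way ANOVA mean squares of the n-subjects x 2-sessions
    table.  Absolute agreement (rather than consistency) penalises a constant
    offset between sessions, the convention for test-retest of one rater.
    """
    x = np.column_stack([np.asarray(session1, float), np.asarray(session2, float)])
    if x.shape[0] < 3:
        raise ValueError(f"need >= 3 paired observations, got {x.shape[0]}")
    if np.any(~np.isfinite(x)):
        raise ValueError("ICC inputs must be finite")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    if np.allclose(row_means, row_means[0]):
        raise MeasurementError("zero between-subject variance: ICC undefined")
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sse = np.sum((x - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    return float((msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n))


@dataclass(frozen=True)
class HemiValue:
    """A measurement per hemisphere with its left-right average."""

    left: float
    right: float

    @property
    def mean(self) -> float:
        vals = [v for v in (self.left, self.right) if not math.isnan(v)]
        return float(np.mean(vals)) if vals else float("nan")


@dataclass
class SncMeasures:
    """Whole- and regional-SNc measurements for one subject."""

    subject_id: str
    tiv_ml: float
    volume_mm3: HemiValue
    c_vol: HemiValue
    cnr: HemiValue
    regional_volume_mm3: dict[str, HemiValue] = field(default_factory=dict)
    regional_cnr: dict[str, HemiValue] = field(default_factory=dict)

    def to_row(self) -> dict[str, float | str]:
        row: dict[str, float | str] = {"subject_id": self.subject_id, "tiv_ml": self.tiv_ml}
        for name, hv in (
            ("volume_mm3", self.volume_mm3),
            ("c_vol", self.c_vol),
            ("cnr", self.cnr),
        ):
            row[f"{name}_left"], row[f"{name}_right"], name_mean = hv.left, hv.right, hv.mean
            row[f"{name}_mean"] = name_mean
        for region in REGION_LABELS:
            for kind, table in (
                ("volume_mm3", self.regional_volume_mm3),
                ("cnr", self.regional_cnr),
            ):
                hv = table.get(region)
                if hv is None:
                    hv = HemiValue(float("nan"), float("nan"))
                row[f"{region}_{kind}_left"] = hv.left
                row[f"{region}_{kind}_right"] = hv.right
                row[f"{region}_{kind}_mean"] = hv.mean
        return row


def _regional_cnr_one_hemi(
    image: VolumeImage,
    region_mask: RoiMask,
    background: RoiMask,
    slices: SliceSet,
    region: str,
    hemi: str,
) -> float:
    """Regional CNR over the whole-SNc SliceSet, skipping slices where the
    regional intersection is empty; a fully empty region is missing (NaN)."""
    vals = []
    for s in slices:
        if region_mask.data[:, :, s].any():
            vals.append(slice_signal_stats(image, region_mask, background, s).cnr)
        else:
            logger.warning(
                "region %s (%s) empty on slice %d; slice skipped for regional CNR",
                region,
                hemi,
                s,
            )
    if not vals:
        return float("nan")
    return float(np.mean(vals))


def subject_measures(
    image: VolumeImage,
    rater1: tuple[RoiMask, RoiMask],
    rater2: tuple[RoiMask, RoiMask],
    background: RoiMask,
    templates: dict[str, RoiMask],
    tiv_ml: float,
    subject_id: str = "",
    consensus_threshold: float = 0.5,
) -> SncMeasures:
    """Full per-subject measurement: consensus, slice selection, whole and
    regional volume/CNR per hemisphere, left-right averages, and C_vol.

    ``rater1`` and ``rater2`` are (left, right) whole-SNc masks from the two
    raters.  Slice selection is done per hemisphere on the consensus mask.
    """
    if not tiv_ml > 0:
        raise MeasurementError(f"TIV must be positive, got {tiv_ml}")
    hemis: dict[str, dict[str, float]] = {}
    regional: dict[str, dict[str, dict[str, float]]] = {"volume_mm3": {}, "cnr": {}}
    for hemi, r1, r2 in (("left", rater1[0], rater2[0]), ("right", rater1[1], rater2[1])):
        cons = consensus_mask(r1, r2, threshold=consensus_threshold)
        slices = select_lowest_slices(cons)
        vol = compute_volume(cons, slices)
        cnr = compute_cnr(image, cons, background, slices)
        hemis[hemi] = {"volume_mm3": vol, "cnr": cnr, "c_vol": corrected_volume(vol, tiv_ml)}
        regions = regional_intersection(cons, templates)
        for region, rmask in regions.items():
            regional["volume_mm3"].setdefault(region, {})[hemi] = compute_volume(
                rmask, slices
            )
            regional["cnr"].setdefault(region, {})[hemi] = _regional_cnr_one_hemi(
                image, rmask, background, slices, region, hemi
            )
    hv = lambda kind: HemiValue(hemis["left"][kind], hemis["right"][kind])  # noqa: E731
    regional_volume = {
        region: HemiValue(vals["left"], vals["right"])
        for region, vals in regional["volume_mm3"].items()
    }
    regional_cnr = {
        region: HemiValue(vals["left"], vals["right"])
        for region, vals in regional["cnr"].items()
    }
    # Fully empty regional volume (0 mm^3) stays 0; fully empty regional CNR is NaN.
    return SncMeasures(
        subject_id=subject_id,
        tiv_ml=float(tiv_ml),
        volume_mm3=hv("volume_mm3"),
        c_vol=hv("c_vol"),
        cnr=hv("cnr"),
        regional_volume_mm3=regional_volume,
        regional_cnr=regional_cnr,
    )
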