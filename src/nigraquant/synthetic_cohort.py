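"""Synthetic midbrain phantom cohorts for the SNc measurement pipeline.

The generator emulates a three-group NM-MRI study — healthy controls (HC),
asymptomatic LRRK2 carriers, and idiopathic PD — on a shared axial slab grid:

* a homoscedastic Gaussian background (the CNR estimator is then analytically
  checkable), with the bilateral SNc as per-slice half-ellipse footprints
  dorsal to a simulated cerebral-peduncle/tegmentum background band;
* two simulated raters per subject, modelled as smooth level-set perturbations
  of the true contour calibrated to a target Dice overlap;
* regional functional-territory templates (dorsolateral sensorimotor,
  dorsomedial limbic, ventral associative) that partition the grid, so
  regional measurements always add up to the whole;
* clinical scores drawn from a conditional-Gaussian (copula) model so that
  score-measure Pearson correlations hit configured targets.

Group contrast and volume targets are calibrated on the *measurement* scale:
the reference study's reported values are rater-consensus measurements, so the
cohort generator sizes each true mask so that the realized consensus voxel
count matches the subject's volume target, and scales the true contrast by the
inverse consensus purity so that the expected measured CNR equals the
subject's contrast target.  ``generate_phantom`` itself stays literal: it
places exactly the requested true-mask volume and contrast.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import truncnorm

from .imaging_io import GeometryError, RoiMask, VolumeImage
from .nm_metrics import SncMeasures, subject_measures

__all__ = [
    "CohortConfig",
    "SubjectRecord",
    "GroundTruth",
    "SubjectData",
    "Cohort",
    "PhantomGeometry",
    "generate_cohort",
    "generate_phantom",
    "simulate_rater",
    "generate_clinical_scores",
    "GROUPS",
    "MEASURE_KEYS",
]

GROUPS = ("HC", "LRRK2", "PD")
MEASURE_KEYS = ("volume", "c_vol", "cnr")

#: Clinical scores generated per group (scores not applicable to a group are
#: absent, mirroring "not applicable" dashes in clinical tables).
GROUP_SCORES = {
    "HC": ("updrs1", "updrs2", "updrs3"),
    "LRRK2": ("updrs1", "updrs2", "updrs3"),
    "PD": ("updrs1", "updrs2", "updrs3", "updrs4", "hy", "duration", "ledd"),
}

#: (group, score) -> (mean, sd) of the marginal score distribution.
DEFAULT_SCORE_PARAMS = {
    ("HC", "updrs1"): (2.23, 3.15),
    ("HC", "updrs2"): (0.13, 0.43),
    ("HC", "updrs3"): (1.53, 2.42),
    ("LRRK2", "updrs1"): (3.33, 3.29),
    ("LRRK2", "updrs2"): (0.93, 1.87),
    ("LRRK2", "updrs3"): (1.60, 2.10),
    ("PD", "updrs1"): (10.73, 7.26),
    ("PD", "updrs2"): (11.82, 5.79),
    ("PD", "updrs3"): (30.77, 11.38),
    ("PD", "updrs4"): (0.64, 1.87),
    ("PD", "hy"): (2.09, 0.65),
    ("PD", "duration"): (5.25, 4.28),
    ("PD", "ledd"): (524.4, 301.2),
}

#: (group, score, measure) -> target Pearson r between the score and the
#: whole-SNc measure within the group.  Pairs not listed default to 0.
DEFAULT_CLINICAL_CORRELATIONS = {
    ("HC", "updrs3", "volume"): 0.089,
    ("HC", "updrs3", "c_vol"): 0.047,
    ("HC", "updrs3", "cnr"): -0.350,
    ("LRRK2", "updrs1", "volume"): -0.596,
    ("LRRK2", "updrs1", "c_vol"): -0.355,
    ("LRRK2", "updrs1", "cnr"): -0.225,
    ("LRRK2", "updrs2", "volume"): -0.444,
    ("LRRK2", "updrs2", "c_vol"): -0.479,
    ("LRRK2", "updrs2", "cnr"): 0.223,
    ("LRRK2", "updrs3", "volume"): -0.177,
    ("LRRK2", "updrs3", "c_vol"): -0.529,
    ("LRRK2", "updrs3", "cnr"): 0.177,
    ("PD", "updrs1", "volume"): -0.123,
    ("PD", "updrs1", "c_vol"): -0.102,
    ("PD", "updrs1", "cnr"): -0.423,
    ("PD", "updrs2", "volume"): -0.091,
    ("PD", "updrs2", "c_vol"): -0.153,
    ("PD", "updrs2", "cnr"): -0.201,
    ("PD", "updrs3", "volume"): -0.474,
    ("PD", "updrs3", "c_vol"): -0.473,
    ("PD", "updrs3", "cnr"): 0.110,
    ("PD", "updrs4", "volume"): -0.033,
    ("PD", "updrs4", "c_vol"): 0.039,
    ("PD", "updrs4", "cnr"): 0.265,
    ("PD", "hy", "volume"): 0.020,
    ("PD", "hy", "c_vol"): 0.044,
    ("PD", "hy", "cnr"): -0.180,
    ("PD", "duration", "volume"): -0.157,
    ("PD", "duration", "c_vol"): -0.127,
    ("PD", "duration", "cnr"): -0.093,
    ("PD", "ledd", "volume"): 0.107,
    ("PD", "ledd", "c_vol"): 0.174,
    ("PD", "ledd", "cnr"): 0.065,
}

SUBJECT_CSV_COLUMNS = [
    "subject_id",
    "group",
    "mutation",
    "age",
    "sex",
    "updrs1",
    "updrs2",
    "updrs3",
    "updrs4",
    "hy",
    "duration",
    "ledd",
    "tiv_ml",
]


@dataclass
class CohortConfig:
    """All generator parameters; the defaults are the emulated study's values."""

    n_hc: int = 30
    n_lrrk2: int = 15
    n_pd: int = 22
    grid_shape: tuple[int, int, int] = (112, 112, 7)
    voxel_size_mm: tuple[float, float, float] = (0.35, 0.35, 3.0)
    group_cnr_mean: dict = field(
        default_factory=lambda: {"HC": 1.51, "LRRK2": 1.38, "PD": 1.32}
    )
    group_cnr_sd: dict = field(
        default_factory=lambda: {"HC": 0.19, "LRRK2": 0.19, "PD": 0.13}
    )
    group_volume_mean: dict = field(
        default_factory=lambda: {"HC": 394.2, "LRRK2": 359.4, "PD": 324.6}
    )
    group_volume_sd: dict = field(
        default_factory=lambda: {"HC": 57.4, "LRRK2": 62.6, "PD": 60.8}
    )
    tiv_mean: float = 1460.0
    tiv_sd: float = 130.0
    rater_dice_target: float = 0.81
    clinical_correlations: dict = field(
        default_factory=lambda: dict(DEFAULT_CLINICAL_CORRELATIONS)
    )
    score_params: dict = field(default_factory=lambda: dict(DEFAULT_SCORE_PARAMS))
    age_mean: dict = field(
        default_factory=lambda: {"HC": 64.4, "LRRK2": 67.1, "PD": 64.2}
    )
    age_sd: dict = field(default_factory=lambda: {"HC": 4.2, "LRRK2": 4.8, "PD": 6.4})
    sex_male_frac: dict = field(
        default_factory=lambda: {"HC": 16 / 30, "LRRK2": 10 / 15, "PD": 11 / 22}
    )
    background_mean: float = 100.0
    background_sd: float = 10.0
    integerize_scores: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name, n in (("n_hc", self.n_hc), ("n_lrrk2", self.n_lrrk2), ("n_pd", self.n_pd)):
            if not (isinstance(n, (int, np.integer)) and n > 0):
                raise ValueError(f"{name} must be a positive integer, got {n}")
        self.grid_shape = tuple(int(v) for v in self.grid_shape)
        if len(self.grid_shape) != 3 or self.grid_shape[2] < 7:
            raise ValueError(
                f"grid_shape must be 3D with z-extent >= 7, got {self.grid_shape}"
            )
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError(f"voxel sizes must be positive, got {self.voxel_size_mm}")
        for g in GROUPS:
            for table, name in (
                (self.group_cnr_sd, "group_cnr_sd"),
                (self.group_volume_sd, "group_volume_sd"),
            ):
                if table[g] < 0:
                    raise ValueError(f"{name}[{g}] must be >= 0, got {table[g]}")
        if self.tiv_sd < 0 or not self.tiv_mean > 0:
            raise ValueError("TIV mean must be positive and SD non-negative")
        if not (0.0 < self.rater_dice_target <= 1.0):
            raise ValueError(
                f"rater_dice_target must be in (0, 1], got {self.rater_dice_target}"
            )
        for key, r in self.clinical_correlations.items():
            if not -1.0 <= r <= 1.0:
                raise ValueError(f"correlation target {key} = {r} outside [-1, 1]")
        if not self.background_sd > 0:
            raise ValueError("background_sd must be positive")

    @property
    def group_sizes(self) -> dict:
        return {"HC": self.n_hc, "LRRK2": self.n_lrrk2, "PD": self.n_pd}

    @property
    def n_total(self) -> int:
        return self.n_hc + self.n_lrrk2 + self.n_pd


@dataclass
class SubjectRecord:
    """Demographics, mutation subtype, clinical scores and TIV for a subject."""

    subject_id: str
    group: str
    mutation: str
    age: float
    sex: str
    tiv_ml: float
    scores: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be 'M' or 'F', got {self.sex!r}")
        if (self.group == "LRRK2") != (self.mutation != "none"):
            raise ValueError(
                f"mutation ({self.mutation!r}) must be set iff group is LRRK2 "
                f"({self.group!r})"
            )
        if self.mutation not in ("none", "G2385R", "R1628P"):
            raise ValueError(f"unknown mutation {self.mutation!r}")

    def to_row(self) -> dict:
        row = {
            "subject_id": self.subject_id,
            "group": self.group,
            "mutation": self.mutation,
            "age": self.age,
            "sex": self.sex,
            "tiv_ml": self.tiv_ml,
        }
        for score in ("updrs1", "updrs2", "updrs3", "updrs4", "hy", "duration", "ledd"):
            row[score] = self.scores.get(score, np.nan)
        return row


@dataclass
class GroundTruth:
    """Per-subject ground truth (plus the cohort-shared masks it references)."""

    true_snc_mask_left: RoiMask
    true_snc_mask_right: RoiMask
    background_mask: RoiMask
    regional_template_masks: dict[str, RoiMask]
    true_cnr: float       # contrast actually placed in the image (in units of background SD)
    true_volume: float    # total bilateral true-mask volume, mm^3


@dataclass
class SubjectData:
    record: SubjectRecord
    image: VolumeImage
    rater1: tuple[RoiMask, RoiMask]   # (left, right)
    rater2: tuple[RoiMask, RoiMask]
    ground_truth: GroundTruth
    target_cnr: float = float("nan")       # measurement-scale draw the phantom was calibrated to
    target_volume: float = float("nan")    # per-hemisphere measurement-scale volume draw, mm^3
    measures: SncMeasures | None = None


@dataclass
class Cohort:
    config: CohortConfig
    subjects: pd.DataFrame
    data: list[SubjectData]
    templates: dict[str, RoiMask]
    background: RoiMask


# ---------------------------------------------------------------------------
# Phantom geometry
# ---------------------------------------------------------------------------

POOL_SCALE = 1.3          # candidate pool extends to this multiple of the nominal axes
WINDOW_MARGIN = 8         # voxels of slack around the pool for rater excursions
FIELD_SIGMA = 2.5         # smoothing length (voxels) of the rater noise field
MIN_RATER_MASK_VOXELS = 20


@dataclass(frozen=True)
class PhantomGeometry:
    """Derived layout of the synthetic midbrain slab.

    The SNc occupies axial slices ``z_slices`` as one half-ellipse footprint
    per hemisphere, dorsal (+y) of a rectangular background band emulating the
    tegmentum and cerebral peduncles.
    """

    grid_shape: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float]

    @property
    def midline(self) -> int:
        return self.grid_shape[0] // 2

    @property
    def cx(self) -> dict[str, int]:
        off = round(0.24 * self.grid_shape[0])
        return {"left": self.midline - off, "right": self.grid_shape[0] - 1 - (self.midline - off)}

    @property
    def cy(self) -> int:
        return round(0.54 * self.grid_shape[1])

    @property
    def semi_axes(self) -> tuple[float, float]:
        return 0.18 * self.grid_shape[0], 0.11 * self.grid_shape[1]

    @property
    def z_slices(self) -> tuple[int, int, int]:
        return (2, 3, 4)

    @property
    def background_bounds(self) -> tuple[int, int, int, int]:
        nx, ny, _ = self.grid_shape
        return (round(0.14 * nx), round(0.86 * nx), round(0.39 * ny), round(0.50 * ny))

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.voxel_size_mm
        return dx * dy * dz

    def validate(self) -> None:
        nx, ny, nz = self.grid_shape
        a0, b0 = self.semi_axes
        a_pool = a0 * POOL_SCALE
        b_pool = b0 * POOL_SCALE
        cxl = self.cx["left"]
        problems = []
        if nz < 7:
            problems.append(f"z-extent {nz} < 7")
        if cxl - a_pool < 1:
            problems.append("SNc footprint exceeds the lateral grid edge")
        if cxl + a_pool >= self.midline:
            problems.append("SNc footprint crosses the grid midline")
        if self.cy + b_pool >= ny - 1:
            problems.append("SNc footprint exceeds the dorsal grid edge")
        x0, x1, y0, y1 = self.background_bounds
        if (x1 - x0) * (y1 - y0) < 50:
            problems.append("background band smaller than 50 voxels per slice")
        if problems:
            raise GeometryError(
                f"grid {self.grid_shape} too small for the SNc geometry: "
                + "; ".join(problems)
            )

    def background_mask(self) -> RoiMask:
        data = np.zeros(self.grid_shape, dtype=bool)
        x0, x1, y0, y1 = self.background_bounds
        data[x0:x1, y0:y1, :] = True
        return RoiMask(data=data, voxel_size_mm=self.voxel_size_mm, label="background")

    def template_masks(self) -> dict[str, RoiMask]:
        """Sensorimotor / associative / limbic partition of the whole grid.

        Ventral of ``cy + 3`` is associative; the dorsal remainder is split at
        a fixed distance from the midline into lateral (sensorimotor) and
        medial (limbic) territories.  The three masks are pairwise disjoint
        and jointly cover the grid, so regional measurements of any SNc mask
        always sum to the whole-SNc measurement.
        """
        nx, ny, nz = self.grid_shape
        x = np.arange(nx)[:, None, None]
        y = np.arange(ny)[None, :, None]
        lat_split = round(0.24 * nx)
        dorsal = np.broadcast_to(y >= self.cy + 3, self.grid_shape)
        lateral = np.broadcast_to(np.abs(x - (self.midline - 0.5)) >= lat_split, self.grid_shape)
        assoc = ~dorsal
        sens = dorsal & lateral
        limbic = dorsal & ~lateral
        mk = lambda arr, label: RoiMask(  # noqa: E731
            data=np.ascontiguousarray(arr), voxel_size_mm=self.voxel_size_mm, label=label
        )
        return {
            "sensorimotor": mk(sens, "sensorimotor"),
            "associative": mk(assoc, "associative"),
            "limbic": mk(limbic, "limbic"),
        }

    def footprint_order(self, hemi: str) -> np.ndarray:
        """Candidate voxels (x, y) for one hemisphere footprint, sorted by
        elliptical distance from the footprint base center (ties: y then x)."""
        nx, ny, _ = self.grid_shape
        a0, b0 = self.semi_axes
        cx, cy = self.cx[hemi], self.cy
        a_pool = int(math.ceil(a0 * POOL_SCALE))
        b_pool = int(math.ceil(b0 * POOL_SCALE))
        xs = np.arange(max(0, cx - a_pool), min(nx, cx + a_pool + 1))
        ys = np.arange(cy, min(ny, cy + b_pool + 1))
        gx, gy = np.meshgrid(xs, ys, indexing="ij")
        score = ((gx - cx) / a0) ** 2 + ((gy - cy) / b0) ** 2
        keep = score <= POOL_SCALE**2
        flat = np.argsort(
            score[keep] + 1e-9 * gy[keep] + 1e-12 * gx[keep], kind="stable"
        )
        coords = np.column_stack([gx[keep], gy[keep]])[flat]
        return coords


# ---------------------------------------------------------------------------
# Rater simulation (level-set boundary perturbation)
# ---------------------------------------------------------------------------


def _smooth_unit_field(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    field = ndimage.gaussian_filter(rng.standard_normal(shape), FIELD_SIGMA, mode="constant")
    sd = field.std()
    return field / sd if sd > 0 else field


def _signed_edt(mask2d: np.ndarray) -> np.ndarray:
    """In-plane signed Euclidean distance to the mask boundary (inside > 0)."""
    inside = ndimage.distance_transform_edt(mask2d)
    outside = ndimage.distance_transform_edt(~mask2d)
    return inside - outside


def _clean_slice(mask2d: np.ndarray) -> np.ndarray:
    """Keep the largest 4-connected component and fill its holes, so the
    per-slice contour stays simply connected."""
    labels, nlab = ndimage.label(mask2d)
    if nlab == 0:
        return mask2d
    sizes = ndimage.sum_labels(mask2d, labels, index=np.arange(1, nlab + 1))
    keep = labels == (1 + int(np.argmax(sizes)))
    return ndimage.binary_fill_holes(keep)


def _dice_arrays(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int(np.logical_and(a, b).sum()) / (na + nb)


def _perturb_levelset(
    truth_slices: list[np.ndarray],
    fields: list[np.ndarray],
    dice_target: float,
    clean: bool = True,
) -> list[np.ndarray]:
    """Perturb a stack of 2D truth slices to an overall Dice ~= target.

    The rater mask on each slice is the super-level set ``{d + A*eta > 0}`` of
    the signed distance ``d`` plus a smooth unit-variance noise field ``eta``;
    a single amplitude ``A`` shared by all slices is bisected per draw so the
    realized (3D) Dice against the truth matches the target.
    """
    dists = [_signed_edt(t) for t in truth_slices]

    def realize(amp: float) -> list[np.ndarray]:
        return [d + amp * f > 0 for d, f in zip(dists, fields)]

    def dice_at(amp: float) -> float:
        pred = np.concatenate([p.ravel() for p in realize(amp)])
        true = np.concatenate([t.ravel() for t in truth_slices])
        return _dice_arrays(pred, true)

    lo, hi = 0.0, 1.0
    for _ in range(12):
        if dice_at(hi) < dice_target:
            break
        hi *= 2.0
    else:
        raise ValueError(
            f"dice target {dice_target} unreachable for this mask (too small or "
            "noise field too coarse)"
        )
    for _ in range(26):
        mid = 0.5 * (lo + hi)
        if dice_at(mid) > dice_target:
            lo = mid
        else:
            hi = mid
    amp = 0.5 * (lo + hi)
    out = realize(amp)
    if clean:
        out = [_clean_slice(p) for p in out]
    return out


def simulate_rater(true_mask: RoiMask, dice_target: float, seed) -> RoiMask:
    """Simulate a human rater's segmentation of a true SNc mask.

    Stochastic, spatially smooth boundary erosion/dilation calibrated per draw
    so that Dice(true, perturbed) is close to ``dice_target``.  A target of
    1.0 returns the truth unchanged.
    """
    if not (0.0 < dice_target <= 1.0):
        raise ValueError(f"dice_target must be in (0, 1], got {dice_target}")
    if true_mask.count < MIN_RATER_MASK_VOXELS:
        raise ValueError(
            f"mask has {true_mask.count} voxels; rater simulation needs >= "
            f"{MIN_RATER_MASK_VOXELS}"
        )
    if dice_target >= 0.999:
        return RoiMask(
            data=true_mask.data.copy(),
            voxel_size_mm=true_mask.voxel_size_mm,
            label="rater",
        )
    rng = np.random.default_rng(seed)
    nz_slices = true_mask.nonempty_slices()
    xs, ys, _ = np.nonzero(true_mask.data)
    m = WINDOW_MARGIN
    x0, x1 = max(0, xs.min() - m), min(true_mask.shape[0], xs.max() + 1 + m)
    y0, y1 = max(0, ys.min() - m), min(true_mask.shape[1], ys.max() + 1 + m)
    truth_slices = [np.ascontiguousarray(true_mask.data[x0:x1, y0:y1, s]) for s in nz_slices]
    fields = [_smooth_unit_field(rng, truth_slices[0].shape) for _ in nz_slices]
    perturbed = _perturb_levelset(truth_slices, fields, dice_target)
    out = np.zeros(true_mask.shape, dtype=bool)
    for s, p in zip(nz_slices, perturbed):
        out[x0:x1, y0:y1, s] = p
    return RoiMask(data=out, voxel_size_mm=true_mask.voxel_size_mm, label="rater")


# ---------------------------------------------------------------------------
# Phantom construction
# ---------------------------------------------------------------------------


def _allocate_slices(n: int, n_slices: int = 3) -> list[int]:
    """Split a voxel budget over slices: equal thirds, remainder to the middle
    then the most inferior slice (deterministic)."""
    base, rem = divmod(n, n_slices)
    alloc = [base] * n_slices
    order = [1, 0, 2]  # middle, inferior, superior
    for k in range(rem):
        alloc[order[k]] += 1
    return alloc


def _truth_slices_from_order(
    order: np.ndarray, n_true: int, shape2d: tuple[int, int], offset: tuple[int, int]
) -> list[np.ndarray]:
    alloc = _allocate_slices(n_true)
    out = []
    for n_s in alloc:
        sl = np.zeros(shape2d, dtype=bool)
        coords = order[:n_s]
        sl[coords[:, 0] - offset[0], coords[:, 1] - offset[1]] = True
        out.append(sl)
    return out


def _build_hemisphere(
    geom: PhantomGeometry,
    order: np.ndarray,
    consensus_target: int,
    dice_target: float,
    rng: np.random.Generator,
):
    """Construct truth + two rater masks for one hemisphere such that the
    rater-consensus (union) voxel count matches ``consensus_target``.

    Returns (truth, rater1, rater2) as lists of window 2D arrays plus the
    window offset; the window covers the candidate pool with a safety margin.
    """
    m = WINDOW_MARGIN
    x0 = max(0, int(order[:, 0].min()) - m)
    x1 = min(geom.grid_shape[0], int(order[:, 0].max()) + 1 + m)
    y0 = max(0, int(order[:, 1].min()) - m)
    y1 = min(geom.grid_shape[1], int(order[:, 1].max()) + 1 + m)
    shape2d = (x1 - x0, y1 - y0)
    fields1 = [_smooth_unit_field(rng, shape2d) for _ in range(3)]
    fields2 = [_smooth_unit_field(rng, shape2d) for _ in range(3)]
    pool = order.shape[0]

    def realize(n_true: int):
        truth = _truth_slices_from_order(order, n_true, shape2d, (x0, y0))
        if dice_target >= 0.999:
            r1 = [t.copy() for t in truth]
            r2 = [t.copy() for t in truth]
        else:
            r1 = _perturb_levelset(truth, fields1, dice_target)
            r2 = _perturb_levelset(truth, fields2, dice_target)
        union = sum(int(np.logical_or(a, b).sum()) for a, b in zip(r1, r2))
        return truth, r1, r2, union

    lo = max(MIN_RATER_MASK_VOXELS, int(0.45 * consensus_target))
    hi = min(pool * 3, int(1.1 * consensus_target) + 12)
    if hi <= lo or consensus_target > pool * 3:
        raise GeometryError(
            f"hemisphere footprint pool ({pool * 3} voxels over 3 slices) cannot "
            f"reach the target consensus size {consensus_target}"
        )
    best = None
    for _ in range(14):
        if hi - lo <= 1:
            break
        mid = (lo + hi) // 2
        res = realize(mid)
        if best is None or abs(res[3] - consensus_target) < abs(best[1][3] - consensus_target):
            best = (mid, res)
        if res[3] < consensus_target:
            lo = mid
        else:
            hi = mid
    # local refinement around the bisection result
    center = best[0] if best is not None else lo
    for n in range(max(MIN_RATER_MASK_VOXELS, center - 2), min(pool * 3, center + 3)):
        res = realize(n)
        if best is None or abs(res[3] - consensus_target) < abs(best[1][3] - consensus_target):
            best = (n, res)
    truth, r1, r2, _ = best[1]
    return truth, r1, r2, (x0, y0)


def _window_to_grid(
    slices2d: list[np.ndarray], offset: tuple[int, int], geom: PhantomGeometry
) -> np.ndarray:
    out = np.zeros(geom.grid_shape, dtype=bool)
    x0, y0 = offset
    for z, sl in zip(geom.z_slices, slices2d):
        out[x0 : x0 + sl.shape[0], y0 : y0 + sl.shape[1], z] = sl
    return out


def generate_phantom(subject_params: dict, geometry: PhantomGeometry, seed=0):
    """Generate one phantom with exactly the requested true volume and contrast.

    ``subject_params`` requires ``cnr`` (dimensionless contrast, in units of
    the background SD) and ``volume_mm3`` (total bilateral true-mask volume);
    optional ``background_mean``/``background_sd``.  Returns
    ``(VolumeImage, GroundTruth)`` where the true mask holds
    ``round(volume_mm3 / voxel_volume)`` voxels split over both hemispheres
    and three contiguous slices, SNc voxels distributed
    ``N(mu_b + cnr * sigma_b, sigma_b)`` and everything else ``N(mu_b, sigma_b)``.
    """
    geometry.validate()
    cnr = float(subject_params["cnr"])
    volume = float(subject_params["volume_mm3"])
    if volume <= 0:
        raise ValueError(f"volume_mm3 must be positive, got {volume}")
    mu = float(subject_params.get("background_mean", 100.0))
    sigma = float(subject_params.get("background_sd", 10.0))
    n_total = int(round(volume / geometry.voxel_volume_mm3))
    n_left = n_total // 2
    n_right = n_total - n_left
    masks = {}
    for hemi, n_h in (("left", n_left), ("right", n_right)):
        order = geometry.footprint_order(hemi)
        if n_h > 3 * order.shape[0]:
            raise GeometryError(
                f"grid too small: {hemi} hemisphere needs {n_h} voxels but the "
                f"footprint pool holds {3 * order.shape[0]}"
            )
        alloc = _allocate_slices(n_h)
        data = np.zeros(geometry.grid_shape, dtype=bool)
        for z, n_s in zip(geometry.z_slices, alloc):
            coords = order[:n_s]
            data[coords[:, 0], coords[:, 1], z] = True
        masks[hemi] = RoiMask(
            data=data, voxel_size_mm=geometry.voxel_size_mm, label=f"snc_{hemi}"
        )
    rng = np.random.default_rng(seed)
    intensities = mu + sigma * rng.standard_normal(geometry.grid_shape)
    both = masks["left"].data | masks["right"].data
    intensities[both] += cnr * sigma
    image = VolumeImage(
        data=intensities.astype(np.float32), voxel_size_mm=geometry.voxel_size_mm
    )
    gt = GroundTruth(
        true_snc_mask_left=masks["left"],
        true_snc_mask_right=masks["right"],
        background_mask=geometry.background_mask(),
        regional_template_masks=geometry.template_masks(),
        true_cnr=cnr,
        true_volume=n_total * geometry.voxel_volume_mm3,
    )
    return image, gt


# ---------------------------------------------------------------------------
# Clinical score generation (conditional Gaussian / copula)
# ---------------------------------------------------------------------------


def measure_correlation_model(config: CohortConfig) -> np.ndarray:
    """Population correlation of (volume, c_vol, cnr) implied by the generator.

    Volume and CNR are drawn independently; C_vol = volume / TIV with an
    independent TIV, so corr(volume, c_vol) follows from the coefficients of
    variation.  Group CVs are averaged into one matrix (they differ little).
    """
    rho = []
    for g in GROUPS:
        cv_vol = config.group_volume_sd[g] / config.group_volume_mean[g]
        cv_tiv = config.tiv_sd / config.tiv_mean
        rho.append(cv_vol / math.hypot(cv_vol, cv_tiv) if cv_vol > 0 else 0.0)
    r = float(np.mean(rho))
    return np.array([[1.0, r, 0.0], [r, 1.0, 0.0], [0.0, 0.0, 1.0]])


def generate_clinical_scores(
    measures: pd.DataFrame,
    config: CohortConfig,
    seed,
    measure_corr: np.ndarray | None = None,
) -> pd.DataFrame:
    """Draw clinical score columns correlated with imaging measures.

    ``measures`` needs a ``group`` column plus one column per measure key
    present among :data:`MEASURE_KEYS`.  Within each group, each score is a
    conditional-Gaussian draw given the (empirically standardized) measures,
    with regression weights chosen so that the population Pearson correlation
    between the score and each measure equals the configured target; scores
    are conditionally independent given the measures.  ``measure_corr`` is the
    measure correlation matrix used for those weights (columns ordered as
    :data:`MEASURE_KEYS` restricted to the available columns); when omitted it
    is estimated from the sample, which at small n can render jointly
    infeasible targets (an error).  Scores stay continuous unless
    ``config.integerize_scores`` is set (rounding and clipping at zero
    attenuate Pearson correlations and are off by default).
    """
    rng = np.random.default_rng(seed)
    measure_cols = [m for m in MEASURE_KEYS if m in measures.columns]
    if not measure_cols:
        raise ValueError(f"measures must contain at least one of {MEASURE_KEYS}")
    out = pd.DataFrame(index=measures.index)
    for group in GROUPS:
        idx = measures.index[measures["group"] == group]
        if len(idx) == 0:
            continue
        M = measures.loc[idx, measure_cols].to_numpy(float)
        n = M.shape[0]
        sd = M.std(axis=0, ddof=1) if n > 1 else np.zeros(M.shape[1])
        usable = sd > 0
        Z = np.zeros_like(M)
        Z[:, usable] = (M[:, usable] - M[:, usable].mean(axis=0)) / sd[usable]
        if measure_corr is not None:
            keep = [i for i, m in enumerate(MEASURE_KEYS) if m in measure_cols]
            sigma = measure_corr[np.ix_(keep, keep)][np.ix_(usable, usable)]
        else:
            sigma = (Z[:, usable].T @ Z[:, usable]) / max(n - 1, 1)
        for score in GROUP_SCORES[group]:
            mean, sdev = config.score_params[(group, score)]
            r_full = np.array(
                [
                    config.clinical_correlations.get((group, score, m), 0.0)
                    for m in measure_cols
                ]
            )
            r = r_full[usable]
            if r.size and np.any(r != 0):
                b = np.linalg.solve(sigma, r)
                cond_var = 1.0 - float(r @ b)
                if cond_var < -1e-8:
                    worst = measure_cols[int(np.argmax(np.abs(r_full)))]
                    raise ValueError(
                        "requested correlation targets are not jointly achievable "
                        f"(not positive semi-definite) for group {group}, score "
                        f"{score}; offending pair: ({score}, {worst})"
                    )
                latent = Z[:, usable] @ b + math.sqrt(max(cond_var, 0.0)) * rng.standard_normal(n)
            else:
                latent = rng.standard_normal(n)
            vals = mean + sdev * latent
            if config.integerize_scores and score != "duration":
                vals = np.clip(np.round(vals), 0, None)
            out.loc[idx, score] = vals
    return out


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, size=None):
    """Normal(mean, sd) truncated to positive values (redraw-by-truncation)."""
    if sd == 0:
        if mean <= 0:
            raise ValueError(f"degenerate draw at non-positive mean {mean}")
        return np.full(size, mean) if size is not None else mean
    a = (0.0 - mean) / sd
    return truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def _subject_rng(master_seed: int, index: int) -> np.random.Generator:
    """Counter-based per-subject stream: stable under cohort subsetting."""
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(index,)))


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate the full synthetic study: phantoms, rater masks, ground truth,
    measurements, and a subjects table with correlated clinical scores.

    Deterministic given ``config`` (including its seed).  Per-group measured
    CNR and volume means converge to the configured targets as n grows
    (measurement-referenced calibration; see the module docstring).
    """
    geom = PhantomGeometry(config.grid_shape, config.voxel_size_mm)
    geom.validate()
    background = geom.background_mask()
    x0, x1, y0, y1 = geom.background_bounds
    if (x1 - x0) * (y1 - y0) < 50:
        raise GeometryError("background band has fewer than 50 voxels per slice")
    templates = geom.template_masks()
    orders = {h: geom.footprint_order(h) for h in ("left", "right")}
    vvol = geom.voxel_volume_mm3

    groups = (
        ["HC"] * config.n_hc + ["LRRK2"] * config.n_lrrk2 + ["PD"] * config.n_pd
    )
    n_g2385r = round(8 / 15 * config.n_lrrk2)
    data: list[SubjectData] = []
    for i, group in enumerate(groups):
        rng = _subject_rng(config.seed, i)
        target_cnr = float(
            _truncated_normal(rng, config.group_cnr_mean[group], config.group_cnr_sd[group])
        )
        target_vol = float(
            _truncated_normal(
                rng, config.group_volume_mean[group], config.group_volume_sd[group]
            )
        )
        tiv = float(_truncated_normal(rng, config.tiv_mean, config.tiv_sd))
        age = float(rng.normal(config.age_mean[group], config.age_sd[group]))
        sex = "M" if rng.random() < config.sex_male_frac[group] else "F"
        if group == "LRRK2":
            lrrk2_index = i - config.n_hc
            mutation = "G2385R" if lrrk2_index < n_g2385r else "R1628P"
        else:
            mutation = "none"

        consensus_target = int(round(target_vol / vvol))
        hemi_parts = {}
        for hemi in ("left", "right"):
            truth, r1, r2, offset = _build_hemisphere(
                geom, orders[hemi], consensus_target, config.rater_dice_target, rng
            )
            hemi_parts[hemi] = {
                "truth": _window_to_grid(truth, offset, geom),
                "r1": _window_to_grid(r1, offset, geom),
                "r2": _window_to_grid(r2, offset, geom),
            }

        # Measurement-referenced contrast: the expected measured CNR equals the
        # target when the true contrast is inflated by the inverse purity of the
        # rater-consensus mask (fraction of consensus voxels that are true SNc).
        purities = []
        for hemi in ("left", "right"):
            union = hemi_parts[hemi]["r1"] | hemi_parts[hemi]["r2"]
            truth = hemi_parts[hemi]["truth"]
            for z in geom.z_slices:
                u = union[:, :, z]
                purities.append((u & truth[:, :, z]).sum() / max(u.sum(), 1))
        purity = float(np.mean(purities))
        true_cnr = target_cnr / purity if purity > 0 else target_cnr

        both_truth = hemi_parts["left"]["truth"] | hemi_parts["right"]["truth"]
        intensities = config.background_mean + config.background_sd * rng.standard_normal(
            geom.grid_shape
        )
        intensities[both_truth] += true_cnr * config.background_sd
        image = VolumeImage(
            data=intensities.astype(np.float32), voxel_size_mm=geom.voxel_size_mm
        )

        mask = lambda arr, label: RoiMask(  # noqa: E731
            data=arr, voxel_size_mm=geom.voxel_size_mm, label=label
        )
        gt = GroundTruth(
            true_snc_mask_left=mask(hemi_parts["left"]["truth"], "snc_left"),
            true_snc_mask_right=mask(hemi_parts["right"]["truth"], "snc_right"),
            background_mask=background,
            regional_template_masks=templates,
            true_cnr=true_cnr,
            true_volume=int(both_truth.sum()) * vvol,
        )
        record = SubjectRecord(
            subject_id=f"sub-{i + 1:03d}",
            group=group,
            mutation=mutation,
            age=age,
            sex=sex,
            tiv_ml=tiv,
        )
        data.append(
            SubjectData(
                record=record,
                image=image,
                rater1=(mask(hemi_parts["left"]["r1"], "rater"), mask(hemi_parts["right"]["r1"], "rater")),
                rater2=(mask(hemi_parts["left"]["r2"], "rater"), mask(hemi_parts["right"]["r2"], "rater")),
                ground_truth=gt,
                target_cnr=target_cnr,
                target_volume=target_vol,
            )
        )

    # Measure every subject through the full pipeline and anchor the clinical
    # scores to the measured whole-SNc values.
    rows = []
    for sd_ in data:
        sd_.measures = subject_measures(
            sd_.image,
            sd_.rater1,
            sd_.rater2,
            background,
            templates,
            sd_.record.tiv_ml,
            subject_id=sd_.record.subject_id,
        )
        rows.append(
            {
                "group": sd_.record.group,
                "volume": sd_.measures.volume_mm3.mean,
                "c_vol": sd_.measures.c_vol.mean,
                "cnr": sd_.measures.cnr.mean,
            }
        )
    measures_df = pd.DataFrame(rows, index=[sd_.record.subject_id for sd_ in data])
    score_seed = np.random.SeedSequence(config.seed, spawn_key=(2**20,))
    scores = generate_clinical_scores(
        measures_df, config, score_seed, measure_corr=measure_correlation_model(config)
    )
    for sd_ in data:
        row = scores.loc[sd_.record.subject_id]
        sd_.record.scores = {k: float(v) for k, v in row.items() if not pd.isna(v)}

    subjects = pd.DataFrame([sd_.record.to_row() for sd_ in data])[SUBJECT_CSV_COLUMNS]
    return Cohort(
        config=config,
        subjects=subjects,
        data=data,
        templates=templates,
        background=background,
    )
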