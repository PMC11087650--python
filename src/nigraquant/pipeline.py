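"""End-to-end orchestration: generate -> measure -> analyze -> report.

The on-disk layout is one directory per subject (image + two raters' left and
right SNc masks + background mask) plus cohort-level ``templates/`` and
``subjects.csv``, so real segmentations could replace the synthetic ones with
no code change:

    <cohort_dir>/
        subjects.csv
        templates/{sensorimotor,associative,limbic}.nii.gz
        sub-001/
            image.nii.gz
            rater1_L.nii.gz  rater1_R.nii.gz
            rater2_L.nii.gz  rater2_R.nii.gz
            background.nii.gz

Reports mirror the study's tables: demographics, measures-by-group with
ANCOVA/post-hoc/percent changes, permutation-corrected correlations, ROC AUCs,
a rater-reliability grid, and the mutation-subtype t-tests.  In synthetic mode
re-running with the same configuration reproduces every CSV bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .imaging_io import RoiMask, load_mask, load_volume, save_mask, save_volume
from .nm_metrics import compute_cnr, compute_volume, dice, icc, subject_measures
from .roi_model import REGION_LABELS, select_lowest_slices
from .group_stats import (
    GROUP_PAIRS,
    ancova_group_effect,
    anova_oneway,
    chi_square_proportion,
    percent_change,
    permutation_corrected_correlations,
    posthoc_ttests,
    roc_auc,
    subgroup_ttest,
    trend_flag,
)
from .synthetic_cohort import (
    GROUPS,
    GROUP_SCORES,
    Cohort,
    CohortConfig,
    generate_cohort,
)

__all__ = [
    "RunConfig",
    "StatsConfig",
    "run_pipeline",
    "save_cohort",
    "measure_cohort_dir",
    "analyze_measures",
    "write_reports",
]

logger = logging.getLogger(__name__)

RATER_FILES = {
    ("rater1", "L"): "rater1_L.nii.gz",
    ("rater1", "R"): "rater1_R.nii.gz",
    ("rater2", "L"): "rater2_L.nii.gz",
    ("rater2", "R"): "rater2_R.nii.gz",
}

MEASURE_COLUMNS = {"volume": "volume_mm3_mean", "c_vol": "c_vol_mean", "cnr": "cnr_mean"}

TABLE2_MEASURES = [
    ("volume_mm3_mean", "whole_volume_mm3"),
    ("c_vol_mean", "whole_c_vol"),
    ("cnr_mean", "whole_cnr"),
    ("limbic_volume_mm3_mean", "limbic_volume_mm3"),
    ("limbic_cnr_mean", "limbic_cnr"),
    ("associative_volume_mm3_mean", "associative_volume_mm3"),
    ("associative_cnr_mean", "associative_cnr"),
    ("sensorimotor_volume_mm3_mean", "sensorimotor_volume_mm3"),
    ("sensorimotor_cnr_mean", "sensorimotor_cnr"),
]


@dataclasses.dataclass
class StatsConfig:
    alpha: float = 0.05
    n_perm: int = 10_000
    trend_band: tuple[float, float] = (0.05, 0.09)

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.n_perm < 1000:
            raise ValueError(f"n_perm must be >= 1000, got {self.n_perm}")
        self.trend_band = tuple(float(v) for v in self.trend_band)


@dataclasses.dataclass
class RunConfig:
    cohort: CohortConfig = dataclasses.field(default_factory=CohortConfig)
    stats: StatsConfig = dataclasses.field(default_factory=StatsConfig)
    out_dir: str = "nigraquant_run"

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known_top = {"cohort", "stats", "io"}
        unknown = sorted(set(raw) - known_top)
        if unknown:
            raise ValueError(f"unknown config keys: {unknown}")
        cohort_raw = dict(raw.get("cohort", {}))
        cohort_fields = {f.name for f in dataclasses.fields(CohortConfig)}
        unknown = sorted(set(cohort_raw) - cohort_fields)
        if unknown:
            raise ValueError(f"unknown cohort config keys: {unknown}")
        stats_raw = dict(raw.get("stats", {}))
        stats_fields = {f.name for f in dataclasses.fields(StatsConfig)}
        unknown = sorted(set(stats_raw) - stats_fields)
        if unknown:
            raise ValueError(f"unknown stats config keys: {unknown}")
        io_raw = dict(raw.get("io", {}))
        unknown = sorted(set(io_raw) - {"out_dir"})
        if unknown:
            raise ValueError(f"unknown io config keys: {unknown}")
        return cls(
            cohort=CohortConfig(**cohort_raw),
            stats=StatsConfig(**stats_raw),
            out_dir=str(io_raw.get("out_dir", "nigraquant_run")),
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        return cls.from_dict(raw)

    def to_canonical_json(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            raise TypeError(f"cannot serialize {type(o)}")

        payload = {
            "cohort": {
                k: ({str(kk): vv for kk, vv in v.items()} if isinstance(v, dict) else v)
                for k, v in dataclasses.asdict(self.cohort).items()
            },
            "stats": dataclasses.asdict(self.stats),
            "io": {"out_dir": self.out_dir},
        }
        return json.dumps(payload, sort_keys=True, default=default)


# ---------------------------------------------------------------------------
# Stage 1: synthesize to disk
# ---------------------------------------------------------------------------


def save_cohort(cohort: Cohort, cohort_dir) -> Path:
    cohort_dir = Path(cohort_dir)
    cohort_dir.mkdir(parents=True, exist_ok=True)
    (cohort_dir / "templates").mkdir(exist_ok=True)
    for region in REGION_LABELS:
        save_mask(cohort.templates[region], cohort_dir / "templates" / f"{region}.nii.gz")
    for sd in cohort.data:
        sub_dir = cohort_dir / sd.record.subject_id
        sub_dir.mkdir(exist_ok=True)
        save_volume(sd.image, sub_dir / "image.nii.gz")
        save_mask(sd.rater1[0], sub_dir / "rater1_L.nii.gz")
        save_mask(sd.rater1[1], sub_dir / "rater1_R.nii.gz")
        save_mask(sd.rater2[0], sub_dir / "rater2_L.nii.gz")
        save_mask(sd.rater2[1], sub_dir / "rater2_R.nii.gz")
        save_mask(cohort.background, sub_dir / "background.nii.gz")
    cohort.subjects.to_csv(cohort_dir / "subjects.csv", index=False)
    return cohort_dir


# ---------------------------------------------------------------------------
# Stage 2: measure from disk
# ---------------------------------------------------------------------------


def _bilateral(left: RoiMask, right: RoiMask) -> RoiMask:
    return RoiMask(
        data=left.data | right.data, voxel_size_mm=left.voxel_size_mm, label="consensus"
    )


def measure_cohort_dir(cohort_dir, consensus_threshold: float = 0.5) -> pd.DataFrame:
    """Measure every subject found in a cohort directory.

    Subjects with missing or unreadable files are skipped with a logged
    reason; if more than 20% of subjects are skipped the run aborts.
    Returns one row per measured subject (whole and regional measures per
    hemisphere and left-right averaged, per-rater whole-SNc measures, and the
    inter-rater Dice), merged with the subjects table.
    """
    cohort_dir = Path(cohort_dir)
    subjects = pd.read_csv(cohort_dir / "subjects.csv")
    rows = []
    skipped = []
    templates = None
    for _, subj in subjects.iterrows():
        sid = subj["subject_id"]
        sub_dir = cohort_dir / sid
        try:
            image = load_volume(sub_dir / "image.nii.gz")
            if templates is None:
                templates = {
                    region: load_mask(
                        cohort_dir / "templates" / f"{region}.nii.gz", image, label=region
                    )
                    for region in REGION_LABELS
                }
            background = load_mask(sub_dir / "background.nii.gz", image, label="background")
            r1 = (
                load_mask(sub_dir / RATER_FILES[("rater1", "L")], image),
                load_mask(sub_dir / RATER_FILES[("rater1", "R")], image),
            )
            r2 = (
                load_mask(sub_dir / RATER_FILES[("rater2", "L")], image),
                load_mask(sub_dir / RATER_FILES[("rater2", "R")], image),
            )
            measures = subject_measures(
                image,
                r1,
                r2,
                background,
                templates,
                float(subj["tiv_ml"]),
                subject_id=sid,
                consensus_threshold=consensus_threshold,
            )
            row = measures.to_row()
            # per-rater whole-SNc measures + inter-rater overlap, for reliability
            for rater_name, (ml, mr) in (("rater1", r1), ("rater2", r2)):
                vols, cnrs = [], []
                for hemi_mask in (ml, mr):
                    slices = select_lowest_slices(hemi_mask)
                    vols.append(compute_volume(hemi_mask, slices))
                    cnrs.append(compute_cnr(image, hemi_mask, background, slices))
                row[f"{rater_name}_volume_mm3"] = float(np.mean(vols))
                row[f"{rater_name}_cnr"] = float(np.mean(cnrs))
            row["dice_inter_rater"] = dice(_bilateral(*r1), _bilateral(*r2))
            rows.append(row)
            logger.info("measured %s: volume=%.1f mm^3 cnr=%.3f", sid, row["volume_mm3_mean"], row["cnr_mean"])
        except (OSError, ValueError) as exc:
            skipped.append(sid)
            logger.warning("skipping %s: %s", sid, exc)
    if len(skipped) > 0.2 * len(subjects):
        raise RuntimeError(
            f"{len(skipped)}/{len(subjects)} subjects unreadable "
            f"({', '.join(skipped[:5])}...); aborting"
        )
    measured = pd.DataFrame(rows)
    return subjects.merge(measured, on="subject_id", how="inner")


# ---------------------------------------------------------------------------
# Stage 3: analysis tables
# ---------------------------------------------------------------------------


def _group_mean_sd(df: pd.DataFrame, col: str) -> dict[str, tuple[float, float]]:
    out = {}
    for g in GROUPS:
        vals = df.loc[df["group"] == g, col].astype(float)
        out[g] = (float(vals.mean()), float(vals.std(ddof=1)))
    return out


def demographics_table(df: pd.DataFrame, stats_cfg: StatsConfig) -> pd.DataFrame:
    """Demographics/clinical analogue: one-way ANOVA across groups (Fisher-LSD
    gated post-hoc pairwise t-tests), chi-square for the sex proportion."""
    rows = []
    shared_scores = [s for s in GROUP_SCORES["HC"]]
    for col in ["age", *shared_scores]:
        stats_by_group = _group_mean_sd(df, col)
        f, p = anova_oneway(df[col].to_numpy(float), df["group"].to_numpy())
        ph = posthoc_ttests(
            df[col].to_numpy(float), df["group"].to_numpy(), gate_p=p, alpha=stats_cfg.alpha
        )
        row = {"variable": col, "test": "anova", "statistic": f, "p": p, "flag": trend_flag(p, stats_cfg.alpha, stats_cfg.trend_band)}
        for g in GROUPS:
            row[f"mean_{g.lower()}"], row[f"sd_{g.lower()}"] = stats_by_group[g]
        for a, b in GROUP_PAIRS:
            row[f"p_{a.lower()}_{b.lower()}"] = ph[(a, b)]
        rows.append(row)
    counts = np.array(
        [
            [
                int(((df["group"] == g) & (df["sex"] == "M")).sum()),
                int(((df["group"] == g) & (df["sex"] == "F")).sum()),
            ]
            for g in GROUPS
        ]
    )
    chi2, p = chi_square_proportion(counts)
    sex_row = {"variable": "sex_male_frac", "test": "chi2", "statistic": chi2, "p": p, "flag": trend_flag(p, stats_cfg.alpha, stats_cfg.trend_band)}
    for g, (m, f_) in zip(GROUPS, counts):
        sex_row[f"mean_{g.lower()}"] = m / (m + f_)
        sex_row[f"sd_{g.lower()}"] = float("nan")
    for a, b in GROUP_PAIRS:
        sex_row[f"p_{a.lower()}_{b.lower()}"] = float("nan")
    rows.append(sex_row)
    for col in ("updrs4", "hy", "duration", "ledd"):
        vals = df.loc[df["group"] == "PD", col].astype(float)
        rows.append(
            {
                "variable": col,
                "test": "",
                "statistic": float("nan"),
                "p": float("nan"),
                "flag": "",
                "mean_hc": float("nan"),
                "sd_hc": float("nan"),
                "mean_lrrk2": float("nan"),
                "sd_lrrk2": float("nan"),
                "mean_pd": float(vals.mean()),
                "sd_pd": float(vals.std(ddof=1)),
                **{f"p_{a.lower()}_{b.lower()}": float("nan") for a, b in GROUP_PAIRS},
            }
        )
    return pd.DataFrame(rows)


def measures_table(df: pd.DataFrame, stats_cfg: StatsConfig) -> pd.DataFrame:
    """Measures-by-group analogue: per-group mean/SD, ANCOVA (age, sex) group
    effect, gated post-hoc t-tests, and pairwise percent changes."""
    rows = []
    for col, name in TABLE2_MEASURES:
        sub = df[np.isfinite(df[col].astype(float))]
        stats_by_group = _group_mean_sd(sub, col)
        res = ancova_group_effect(
            sub[col].to_numpy(float),
            sub["group"].to_numpy(),
            sub["age"].to_numpy(float),
            sub["sex"].to_numpy(),
            measure_name=name,
        )
        ph = posthoc_ttests(
            sub[col].to_numpy(float),
            sub["group"].to_numpy(),
            gate_p=res.p_value,
            alpha=stats_cfg.alpha,
        )
        row = {
            "measure": name,
            "ancova_f": res.f_stat,
            "ancova_p": res.p_value,
            "flag": trend_flag(res.p_value, stats_cfg.alpha, stats_cfg.trend_band),
        }
        for g in GROUPS:
            row[f"mean_{g.lower()}"], row[f"sd_{g.lower()}"] = stats_by_group[g]
        for a, b in GROUP_PAIRS:
            row[f"p_{a.lower()}_{b.lower()}"] = ph[(a, b)]
            row[f"pct_{a.lower()}_{b.lower()}"] = percent_change(
                stats_by_group[a][0], stats_by_group[b][0]
            )
        rows.append(row)
    return pd.DataFrame(rows)


def correlations_table(df: pd.DataFrame, stats_cfg: StatsConfig, seed: int) -> pd.DataFrame:
    """Permutation-FWE Pearson correlations, one family per (group, measure)."""
    rows = []
    for gi, group in enumerate(GROUPS):
        sub = df[df["group"] == group]
        score_cols = [s for s in GROUP_SCORES[group] if s in sub.columns]
        scores = sub[score_cols]
        for mi, (mkey, col) in enumerate(MEASURE_COLUMNS.items()):
            fam_seed = int(
                np.random.SeedSequence(seed, spawn_key=(3_000_000 + gi * 10 + mi,)).generate_state(1)[0]
                % (2**31)
            )
            results = permutation_corrected_correlations(
                scores,
                sub[col].to_numpy(float),
                n_perm=stats_cfg.n_perm,
                seed=fam_seed,
                group=group,
                measure_name=mkey,
            )
            for res in results:
                rows.append(
                    {
                        "group": res.group,
                        "measure": res.measure,
                        "score": res.score,
                        "n": res.n,
                        "r": res.r,
                        "p_fwe": res.p_fwe,
                        "n_perm": res.n_perm,
                        "flag": trend_flag(res.p_fwe, stats_cfg.alpha, stats_cfg.trend_band)
                        if np.isfinite(res.p_fwe)
                        else "",
                    }
                )
    return pd.DataFrame(rows)


def roc_table(df: pd.DataFrame) -> pd.DataFrame:
    """Pairwise diagnostic AUCs for the whole-SNc measures.  The later-stage
    group of each pair is disease-positive; lower measures indicate disease."""
    order = {g: i for i, g in enumerate(GROUPS)}
    rows = []
    for a, b in GROUP_PAIRS:
        pos = b if order[b] > order[a] else a
        sub = df[df["group"].isin([a, b])]
        labels = (sub["group"] == pos).to_numpy()
        for mkey, col in MEASURE_COLUMNS.items():
            auc = roc_auc(sub[col].to_numpy(float), labels, positive_lower=True)
            rows.append(
                {
                    "pair": f"{a}_vs_{b}",
                    "positive": pos,
                    "measure": mkey,
                    "auc": auc,
                    "n_neg": int((~labels).sum()),
                    "n_pos": int(labels.sum()),
                }
            )
    return pd.DataFrame(rows)


def reliability_table(df: pd.DataFrame) -> pd.DataFrame:
    """Inter-rater reliability grid: Dice overlap plus ICC(2,1) between the
    two raters' whole-SNc volume and CNR series."""
    rows = [
        {
            "comparison": "inter_rater",
            "metric": "dice",
            "value": float(df["dice_inter_rater"].mean()),
            "sd": float(df["dice_inter_rater"].std(ddof=1)),
            "n": int(df["dice_inter_rater"].notna().sum()),
        }
    ]
    for measure in ("volume_mm3", "cnr"):
        s1 = df[f"rater1_{measure}"].to_numpy(float)
        s2 = df[f"rater2_{measure}"].to_numpy(float)
        rows.append(
            {
                "comparison": "inter_rater",
                "metric": f"icc_{measure}",
                "value": icc(s1, s2),
                "sd": float("nan"),
                "n": len(s1),
            }
        )
    return pd.DataFrame(rows)


def mutation_table(df: pd.DataFrame) -> pd.DataFrame:
    """G2385R vs R1628P t-tests on whole-SNc measures within the carrier group."""
    sub = df[df["group"] == "LRRK2"]
    pvals = subgroup_ttest(
        sub[[c for _, c in MEASURE_COLUMNS.items()]].rename(
            columns={v: k for k, v in MEASURE_COLUMNS.items()}
        ),
        sub["mutation"].to_numpy(),
    )
    return pd.DataFrame(
        [{"measure": m, "p": p} for m, p in pvals.items()]
    )


def analyze_measures(df: pd.DataFrame, stats_cfg: StatsConfig, seed: int) -> dict[str, pd.DataFrame]:
    return {
        "table1_demographics": demographics_table(df, stats_cfg),
        "table2_measures": measures_table(df, stats_cfg),
        "table3_correlations": correlations_table(df, stats_cfg, seed),
        "roc": roc_table(df),
        "reliability": reliability_table(df),
        "mutation_ttest": mutation_table(df),
    }


# ---------------------------------------------------------------------------
# Reports + manifest
# ---------------------------------------------------------------------------


def write_reports(tables: dict[str, pd.DataFrame], report_dir) -> dict[str, Path]:
    report_dir = Path(report_dir)
    report_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, table in tables.items():
        path = report_dir / f"{name}.csv"
        table.to_csv(path, index=False)
        paths[name] = path
    return paths


def _manifest(config: RunConfig) -> dict:
    import nibabel
    import scipy
    import sklearn
    import statsmodels

    canonical = config.to_canonical_json()
    return {
        "seed": config.cohort.seed,
        "config": json.loads(canonical),
        "config_sha256": hashlib.sha256(canonical.encode()).hexdigest(),
        "versions": {
            "nigraquant": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "statsmodels": statsmodels.__version__,
            "scikit-learn": sklearn.__version__,
            "nibabel": nibabel.__version__,
        },
    }


def run_pipeline(config: RunConfig, out_dir=None) -> dict[str, Path]:
    """Synthesize, measure (from disk), analyze, and write all report files.

    Returns a name -> path map of everything written.  Deterministic for a
    fixed configuration: re-running reproduces all CSVs bit-identically.
    """
    out_dir = Path(out_dir if out_dir is not None else config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(config.cohort)
    cohort_dir = save_cohort(cohort, out_dir / "cohort")
    measured = measure_cohort_dir(cohort_dir)
    measures_path = out_dir / "measures.csv"
    measured.to_csv(measures_path, index=False)
    tables = analyze_measures(measured, config.stats, seed=config.cohort.seed)
    paths = write_reports(tables, out_dir / "reports")
    manifest_path = out_dir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(_manifest(config), fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths.update({"cohort": cohort_dir, "measures": measures_path, "manifest": manifest_path})
    return paths
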