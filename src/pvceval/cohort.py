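"""Synthetic longitudinal SUVR cohorts.

Generates long-format cohorts with the statistical structure the mixed
model assumes: per-subject random intercepts and slopes on the natural-log
SUVR scale, group-specific baseline levels and annual slopes, jittered
visit schedules with dropout, and multiplicative residual noise.  The
numeric defaults of the two study presets come from the published cohort
tables (group sizes, baseline regional SUVR, annualized percent changes,
visit-interval statistics, covariate summaries).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from pvceval.roi import (
    ScanRecord,
    SubjectRecord,
    stratify_tau_levels,
    weeks_to_years,
)

__all__ = [
    "CohortConfig",
    "GeneratedCohort",
    "GroupConfig",
    "generate_cohort",
    "nhs_default_config",
    "tauriel_default_config",
]

ROIS = ("MT", "mTMP", "rest_of_temporal", "parietal", "occipital", "frontal", "TMP", "WCG")


def _ln(values: dict[str, float]) -> dict[str, float]:
    return {k: math.log(v) for k, v in values.items()}


def _slopes(pct_per_year: dict[str, float]) -> dict[str, float]:
    """Annualized percent change -> ln-scale slope per year."""
    return {k: math.log1p(v / 100.0) for k, v in pct_per_year.items()}


@dataclass
class GroupConfig:
    """Generative parameters for one diagnostic group."""

    n: int
    baseline_lnsuvr: dict[str, float]
    slope_ln_per_year: dict[str, float]
    sd_intercept: float
    sd_slope: float
    sd_residual: float
    age_mean: float = 70.0
    age_sd: float = 7.0
    female_fraction: float = 0.5
    apoe4_fractions: tuple[float, float, float] = (0.5, 0.5, 0.0)
    centiloid_mean: float | None = None
    centiloid_sd: float = 30.0
    centiloid_missing_fraction: float = 0.0

    def validate(self) -> None:
        if self.n < 0:
            raise ValueError("n must be >= 0")
        for name in ("sd_intercept", "sd_slope", "sd_residual", "age_sd", "centiloid_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if set(self.baseline_lnsuvr) != set(self.slope_ln_per_year):
            raise ValueError("baseline and slope ROI sets must match")
        if abs(sum(self.apoe4_fractions) - 1.0) > 1e-9:
            raise ValueError("apoe4_fractions must sum to 1")


@dataclass
class CohortConfig:
    """Full cohort description: groups, visit schedule, covariate effects."""

    study: str
    groups: dict[str, GroupConfig]
    visit_weeks: tuple[float, ...]
    jitter_sd_weeks: float = 3.0
    retention: tuple[float, ...] = ()
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: {"apoe4": 0.0, "age": 0.0, "sex": 0.0, "ctl": 0.0}
    )
    rise_fall_fraction: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not self.groups:
            raise ValueError("at least one group required")
        for cfg in self.groups.values():
            cfg.validate()
        weeks = list(self.visit_weeks)
        if weeks != sorted(weeks) or weeks[0] != 0:
            raise ValueError("visit_weeks must be sorted and start at 0")
        if self.jitter_sd_weeks < 0:
            raise ValueError("jitter_sd_weeks must be >= 0")
        if len(self.retention) not in (0, len(weeks) - 1):
            raise ValueError("retention must have one entry per follow-up visit")
        for p in self.retention:
            if not 0.0 < p <= 1.0:
                raise ValueError("retention probabilities must lie in (0, 1]")
        if not 0.0 <= self.rise_fall_fraction <= 1.0:
            raise ValueError("rise_fall_fraction must lie in [0, 1]")

    def scaled(self, n_factor: float) -> "CohortConfig":
        """Copy with every group size multiplied by ``n_factor``."""
        groups = {
            name: replace(cfg, n=max(1, int(round(cfg.n * n_factor))))
            for name, cfg in self.groups.items()
        }
        return replace(self, groups=groups)


@dataclass
class GeneratedCohort:
    """Subjects, scans, and the exact generative truth per subject."""

    subjects: list[SubjectRecord]
    scans: list[ScanRecord]
    truth: dict

    def subjects_frame(self) -> pd.DataFrame:
        rows = [
            {
                "subject_id": s.subject_id,
                "study": s.study,
                "group": s.diagnostic_group,
                "tau_level": s.tau_level,
                "age_years": s.age_years,
                "sex": s.sex,
                "apoe4": s.apoe4,
                "centiloid": np.nan if s.centiloid is None else s.centiloid,
            }
            for s in self.subjects
        ]
        return pd.DataFrame(rows)

    def scans_frame(self) -> pd.DataFrame:
        """Tidy long format: one row per subject-visit-ROI."""
        subj = {s.subject_id: s for s in self.subjects}
        rows = []
        for scan in self.scans:
            s = subj[scan.subject_id]
            for roi, suvr in scan.suvr.items():
                rows.append(
                    {
                        "subject_id": scan.subject_id,
                        "study": s.study,
                        "group": s.diagnostic_group,
                        "tau_level": s.tau_level,
                        "visit_week": scan.visit_week,
                        "time_years": scan.time_years,
                        "method": scan.method,
                        "roi": roi,
                        "suvr": suvr,
                    }
                )
        return pd.DataFrame(rows)


def generate_cohort(config: CohortConfig) -> GeneratedCohort:
    """Draw a cohort from the generative model.

    For subject i of group g at visit time t: ``lnSUVR = mu_g_roi +
    beta'x_i + u_i + (b_g_roi + v_i) t + eps`` with independent
    ``u_i ~ N(0, sd_intercept^2)``, ``v_i ~ N(0, sd_slope^2)`` and
    ``eps ~ N(0, sd_residual^2)`` per ROI and visit.  Deterministic per
    ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    effects = config.covariate_effects
    retention = config.retention or tuple(1.0 for _ in config.visit_weeks[1:])

    subjects: list[SubjectRecord] = []
    scans: list[ScanRecord] = []
    truth_subjects: dict[str, dict] = {}
    midpoint_years = weeks_to_years(config.visit_weeks[-1]) / 2.0

    for group_name, g in config.groups.items():
        if g.n == 0:
            import warnings

            warnings.warn(f"group {group_name!r} has n = 0 and is skipped", stacklevel=2)
            continue
        rois = list(g.baseline_lnsuvr)
        for i in range(g.n):
            sid = f"{config.study}-{group_name}-{i:04d}"
            age = float(rng.normal(g.age_mean, g.age_sd))
            sex = "F" if rng.random() < g.female_fraction else "M"
            apoe4 = str(rng.choice(["carrier", "noncarrier", "unknown"], p=g.apoe4_fractions))
            if g.centiloid_mean is None or rng.random() < g.centiloid_missing_fraction:
                centiloid = None
            else:
                centiloid = float(rng.normal(g.centiloid_mean, g.centiloid_sd))
            u = float(rng.normal(0.0, g.sd_intercept))
            v = float(rng.normal(0.0, g.sd_slope))
            rise_fall = bool(rng.random() < config.rise_fall_fraction)

            cov_shift = (
                effects.get("apoe4", 0.0) * (apoe4 == "carrier")
                + effects.get("age", 0.0) * (age - g.age_mean)
                + effects.get("sex", 0.0) * (sex == "F")
                + (
                    effects.get("ctl", 0.0) * (centiloid - g.centiloid_mean)
                    if centiloid is not None and g.centiloid_mean is not None
                    else 0.0
                )
            )

            subjects.append(
                SubjectRecord(
                    subject_id=sid,
                    study=config.study,
                    diagnostic_group=group_name,
                    tau_level="CU" if group_name == "CU" else "low",
                    age_years=age,
                    sex=sex,
                    apoe4=apoe4,
                    centiloid=centiloid,
                )
            )
            truth_subjects[sid] = {
                "group": group_name,
                "u": u,
                "v": v,
                "cov_shift": cov_shift,
                "rise_fall": rise_fall,
            }

            for k, week in enumerate(config.visit_weeks):
                if k > 0 and rng.random() > retention[k - 1]:
                    continue
                realized_week = (
                    0.0 if k == 0 else float(week + rng.normal(0.0, config.jitter_sd_weeks))
                )
                t = weeks_to_years(realized_week)
                suvr = {}
                for roi in rois:
                    slope = g.slope_ln_per_year[roi] + v
                    if rise_fall and t > midpoint_years:
                        trend = slope * midpoint_years - slope * (t - midpoint_years)
                    else:
                        trend = slope * t
                    ln_value = (
                        g.baseline_lnsuvr[roi]
                        + cov_shift
                        + u
                        + trend
                        + float(rng.normal(0.0, g.sd_residual))
                    )
                    suvr[roi] = math.exp(ln_value)
                scans.append(
                    ScanRecord(
                        subject_id=sid,
                        visit_week=realized_week,
                        time_years=t,
                        suvr=suvr,
                        method="none",
                    )
                )

    # quartile tau levels from realized baseline TMP SUVR of the AD subjects
    baseline_tmp = {
        scan.subject_id: scan.suvr["TMP"]
        for scan in scans
        if scan.visit_week == 0 and "TMP" in scan.suvr
    }
    ad_ids = [s.subject_id for s in subjects if s.diagnostic_group != "CU"]
    cutpoints = None
    if len(ad_ids) >= 4 and all(sid in baseline_tmp for sid in ad_ids):
        try:
            levels, cutpoints = stratify_tau_levels(baseline_tmp, ad_ids)
        except ValueError:
            levels = {}
        for s in subjects:
            if s.subject_id in levels:
                s.tau_level = levels[s.subject_id]

    truth = {
        "config": config,
        "subjects": truth_subjects,
        "tau_cutpoints": cutpoints,
        "group_parameters": {
            name: {
                "baseline_lnsuvr": dict(g.baseline_lnsuvr),
                "slope_ln_per_year": dict(g.slope_ln_per_year),
                "sd_intercept": g.sd_intercept,
                "sd_slope": g.sd_slope,
                "sd_residual": g.sd_residual,
            }
            for name, g in config.groups.items()
        },
    }
    return GeneratedCohort(subjects=subjects, scans=scans, truth=truth)


# ---------------------------------------------------------------------------
# Study presets.  Baseline SUVR, annualized percent changes, group sizes,
# covariate summaries, visit schedules and realized retention are the
# published cohort values; between-subject SDs are derived from the
# meta-temporal SUVR summary (CV of the baseline mean) and the reported
# whole-cortical-gray effect sizes (mean percent change over effect size).
# ---------------------------------------------------------------------------


def nhs_default_config(seed: int = 0) -> CohortConfig:
    """Single-site natural-history-study preset: four diagnostic groups,
    visits at 0/26/52/78 weeks."""
    baselines = {
        "CU": {"MT": 1.30, "mTMP": 1.28, "rest_of_temporal": 1.16, "parietal": 1.16,
               "occipital": 1.24, "frontal": 1.09, "TMP": 1.28, "WCG": 1.16},
        "prodromal": {"MT": 1.36, "mTMP": 1.37, "rest_of_temporal": 1.18, "parietal": 1.19,
                      "occipital": 1.26, "frontal": 1.08, "TMP": 1.37, "WCG": 1.18},
        "mild": {"MT": 1.47, "mTMP": 1.67, "rest_of_temporal": 1.32, "parietal": 1.35,
                 "occipital": 1.39, "frontal": 1.17, "TMP": 1.63, "WCG": 1.32},
        "moderate": {"MT": 1.63, "mTMP": 1.98, "rest_of_temporal": 1.54, "parietal": 1.62,
                     "occipital": 1.60, "frontal": 1.33, "TMP": 1.91, "WCG": 1.52},
    }
    pct_slopes = {
        "CU": {"MT": -1.70, "mTMP": -1.07, "rest_of_temporal": -2.37, "parietal": -1.75,
               "occipital": -1.19, "frontal": -2.35, "TMP": -1.22, "WCG": -1.77},
        "prodromal": {"MT": 2.37, "mTMP": 3.10, "rest_of_temporal": 1.96, "parietal": 2.09,
                      "occipital": 2.64, "frontal": 1.50, "TMP": 2.96, "WCG": 2.09},
        "mild": {"MT": 0.04, "mTMP": 2.35, "rest_of_temporal": 0.88, "parietal": 2.24,
                 "occipital": 1.95, "frontal": 1.00, "TMP": 2.00, "WCG": 1.48},
        "moderate": {"MT": -0.52, "mTMP": 3.33, "rest_of_temporal": 1.83, "parietal": 3.72,
                     "occipital": 4.24, "frontal": 2.76, "TMP": 2.63, "WCG": 2.96},
    }
    demo = {
        # n, age (mean, sd), female fraction, apoe4 (carrier, noncarrier, unknown),
        # centiloid (mean, sd), intercept SD, slope SD
        "CU": (10, (67.2, 6.2), 0.70, (4, 6, 0), (37.4, 43.9), 0.11 / 1.28, 0.0099),
        "prodromal": (24, (69.5, 7.1), 0.67, (16, 3, 5), (77.7, 33.2), 0.17 / 1.37, 0.0087),
        "mild": (15, (73.1, 4.4), 0.47, (9, 5, 1), (77.1, 29.2), 0.25 / 1.63, 0.0138),
        "moderate": (14, (70.4, 7.1), 0.29, (13, 0, 1), (87.4, 34.4), 0.38 / 1.91, 0.0121),
    }
    groups = {}
    for name, (n, age, female, apoe, ctl, sd_u, sd_v) in demo.items():
        total = sum(apoe)
        groups[name] = GroupConfig(
            n=n,
            baseline_lnsuvr=_ln(baselines[name]),
            slope_ln_per_year=_slopes(pct_slopes[name]),
            sd_intercept=sd_u,
            sd_slope=sd_v,
            sd_residual=0.03,
            age_mean=age[0],
            age_sd=age[1],
            female_fraction=female,
            apoe4_fractions=tuple(x / total for x in apoe),
            centiloid_mean=ctl[0],
            centiloid_sd=ctl[1],
        )
    return CohortConfig(
        study="NHS",
        groups=groups,
        visit_weeks=(0.0, 26.0, 52.0, 78.0),
        jitter_sd_weeks=3.0,
        retention=(1.0, 56.0 / 63.0, 51.0 / 63.0),
        seed=seed,
    )


def tauriel_default_config(seed: int = 0) -> CohortConfig:
    """Multisite clinical-trial preset: prodromal and mild AD, visits at
    0/49/73 weeks, no centiloid covariate in the default model."""
    baselines = {
        "prodromal": {"MT": 1.45, "mTMP": 1.50, "rest_of_temporal": 1.23, "parietal": 1.27,
                      "occipital": 1.31, "frontal": 1.13, "TMP": 1.49, "WCG": 1.24},
        "mild": {"MT": 1.49, "mTMP": 1.62, "rest_of_temporal": 1.30, "parietal": 1.36,
                 "occipital": 1.38, "frontal": 1.16, "TMP": 1.59, "WCG": 1.30},
    }
    pct_slopes = {
        "prodromal": {"MT": 0.66, "mTMP": 3.46, "rest_of_temporal": 2.46, "parietal": 2.93,
                      "occipital": 2.20, "frontal": 2.47, "TMP": 2.98, "WCG": 2.51},
        "mild": {"MT": 0.81, "mTMP": 4.04, "rest_of_temporal": 3.38, "parietal": 3.31,
                 "occipital": 2.77, "frontal": 3.46, "TMP": 3.47, "WCG": 3.15},
    }
    demo = {
        "prodromal": (122, (70.2, 7.1), 0.53, (90, 32, 0), (90.7, 33.3), 0.26 / 1.49, 0.0244),
        "mild": (212, (69.1, 6.9), 0.55, (163, 49, 0), (89.5, 30.6), 0.31 / 1.59, 0.0239),
    }
    groups = {}
    for name, (n, age, female, apoe, ctl, sd_u, sd_v) in demo.items():
        total = sum(apoe)
        groups[name] = GroupConfig(
            n=n,
            baseline_lnsuvr=_ln(baselines[name]),
            slope_ln_per_year=_slopes(pct_slopes[name]),
            sd_intercept=sd_u,
            sd_slope=sd_v,
            sd_residual=0.035,
            age_mean=age[0],
            age_sd=age[1],
            female_fraction=female,
            apoe4_fractions=tuple(x / total for x in apoe),
            centiloid_mean=ctl[0],
            centiloid_sd=ctl[1],
            centiloid_missing_fraction=20.0 / 334.0,
        )
    return CohortConfig(
        study="Tauriel",
        groups=groups,
        visit_weeks=(0.0, 49.0, 73.0),
        jitter_sd_weeks=3.3,
        retention=(314.0 / 334.0, 288.0 / 334.0),
        seed=seed,
    )
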