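"""Regional SUVR quantification: composite ROIs, reference scaling,
tau-level stratification, and annualized percent change."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from pvceval.phantom import ActivityVolume, LabelVolume

__all__ = [
    "WEEKS_PER_YEAR",
    "RoiScheme",
    "ScanRecord",
    "SubjectRecord",
    "annualized_pct_change",
    "classify_amyloid",
    "compute_suvr",
    "default_scheme",
    "roi_means",
    "stratify_tau_levels",
    "weeks_to_years",
]

#: 365.25-day year
WEEKS_PER_YEAR = 52.1775


def weeks_to_years(weeks: float) -> float:
    return weeks / WEEKS_PER_YEAR


DIAGNOSTIC_GROUPS = ("CU", "prodromal", "mild", "moderate")
TAU_LEVELS = ("CU", "low", "mid", "high")


@dataclass
class ScanRecord:
    """One subject-visit: per-composite SUVR values under one PVC method."""

    subject_id: str
    visit_week: float
    time_years: float
    suvr: dict[str, float]
    method: str = "none"

    def __post_init__(self) -> None:
        if self.visit_week == 0 and self.time_years != 0:
            raise ValueError("baseline record must have time_years = 0")
        bad = {k: v for k, v in self.suvr.items() if not (np.isfinite(v) and v > 0)}
        if bad:
            raise ValueError(f"SUVR values must be finite and positive: {bad}")


@dataclass
class SubjectRecord:
    """Per-subject covariates and group assignments."""

    subject_id: str
    study: str
    diagnostic_group: str
    tau_level: str
    age_years: float
    sex: str
    apoe4: str
    centiloid: float | None = None

    def __post_init__(self) -> None:
        if self.diagnostic_group not in DIAGNOSTIC_GROUPS:
            raise ValueError(f"unknown diagnostic group {self.diagnostic_group!r}")
        if self.tau_level not in TAU_LEVELS:
            raise ValueError(f"unknown tau level {self.tau_level!r}")
        if self.apoe4 not in ("carrier", "noncarrier", "unknown"):
            raise ValueError(f"unknown APOE4 status {self.apoe4!r}")


@dataclass
class RoiScheme:
    """Mapping from composite ROI names to sets of atomic label names.

    Must contain a ``reference`` composite; when the temporal composites are
    present, ``TMP`` must contain ``MT`` and ``mTMP`` must equal their
    difference, and the reference must be disjoint from every target.
    """

    composite_map: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.composite_map = {k: set(v) for k, v in self.composite_map.items()}
        if "reference" not in self.composite_map:
            raise ValueError("scheme must define a 'reference' composite")
        ref = self.composite_map["reference"]
        for name, members in self.composite_map.items():
            if name != "reference" and ref & members:
                raise ValueError(f"reference overlaps target composite {name!r}")
        cm = self.composite_map
        if {"TMP", "MT"} <= cm.keys() and not cm["MT"] <= cm["TMP"]:
            raise ValueError("TMP must contain MT")
        if {"TMP", "MT", "mTMP"} <= cm.keys() and cm["mTMP"] != cm["TMP"] - cm["MT"]:
            raise ValueError("mTMP must equal TMP minus MT")

    @property
    def target_names(self) -> list[str]:
        return [n for n in self.composite_map if n != "reference"]


def default_scheme() -> RoiScheme:
    """Scheme matching the default phantom's cortical sector labels."""
    cortical = {"mt", "mtmp", "rest_of_temporal", "parietal", "occipital", "frontal"}
    return RoiScheme(
        composite_map={
            "MT": {"mt"},
            "mTMP": {"mtmp"},
            "TMP": {"mt", "mtmp"},
            "rest_of_temporal": {"rest_of_temporal"},
            "parietal": {"parietal"},
            "occipital": {"occipital"},
            "frontal": {"frontal"},
            "WCG": set(cortical),
            "white_matter": {"white_matter"},
            "csf": {"csf"},
            "reference": {"cerebellum_reference"},
        }
    )


def roi_means(
    img: ActivityVolume, labels: LabelVolume, scheme: RoiScheme
) -> dict[str, float]:
    """Unweighted mean over the member voxels of each composite."""
    if img.grid != labels.grid:
        raise ValueError(f"grid mismatch: image {img.grid} vs labels {labels.grid}")
    out: dict[str, float] = {}
    for name, members in scheme.composite_map.items():
        mask = labels.union_mask(members)  # raises KeyError for unknown labels
        if not mask.any():
            raise ValueError(f"composite {name!r} has no voxels")
        out[name] = float(img.values[mask].mean())
    return out


def compute_suvr(means: dict[str, float], scheme: RoiScheme) -> dict[str, float]:
    """Divide every target mean by the reference mean; drop the reference."""
    if "reference" not in means:
        raise ValueError("means must include the 'reference' composite")
    ref = means["reference"]
    if ref <= 0:
        raise ValueError(f"reference mean must be positive, got {ref}")
    return {name: value / ref for name, value in means.items() if name != "reference"}


def stratify_tau_levels(
    baseline_tmp_suvr: dict[str, float],
    ad_subjects,
    quantile_method: str = "linear",
    cutpoints_override: tuple[float, float] | None = None,
):
    """Assign AD subjects to low/mid/high tau levels from baseline TMP SUVR.

    Cut points are the first and third quartiles of the AD subjects'
    values (linear-interpolation quantiles by default); ``low`` is <= Q1,
    ``high`` is > Q3, matching the closed/open pattern of the published
    fixed thresholds, which can be supplied via ``cutpoints_override``
    (e.g. ``(1.30, 1.75)``).  Subjects not in ``ad_subjects`` are left out.
    Returns ``(subject -> level, (q1, q3))``.
    """
    ad_subjects = list(ad_subjects)
    values = np.array([baseline_tmp_suvr[s] for s in ad_subjects], dtype=float)
    if cutpoints_override is not None:
        q1, q3 = map(float, cutpoints_override)
    else:
        if len(ad_subjects) < 4:
            raise ValueError("need >= 4 AD subjects for quartile stratification")
        if np.ptp(values) == 0:
            raise ValueError("degenerate quartiles: all baseline values identical")
        q1, q3 = (
            float(np.quantile(values, 0.25, method=quantile_method)),
            float(np.quantile(values, 0.75, method=quantile_method)),
        )
    if not q1 <= q3:
        raise ValueError(f"invalid cut points ({q1}, {q3})")
    levels = {}
    for subject, value in zip(ad_subjects, values):
        if value <= q1:
            levels[subject] = "low"
        elif value <= q3:
            levels[subject] = "mid"
        else:
            levels[subject] = "high"
    return levels, (q1, q3)


def annualized_pct_change(
    baseline_suvr: float, followup_suvr: float, time_years: float
) -> float:
    """100 * (followup/baseline - 1) / years."""
    if baseline_suvr <= 0:
        raise ValueError("baseline SUVR must be positive")
    if time_years <= 0:
        raise ValueError("time_years must be positive")
    return 100.0 * (followup_suvr / baseline_suvr - 1.0) / time_years


def classify_amyloid(centiloid: float | None, threshold: float = 26.0) -> str:
    """Positive iff centiloid strictly exceeds the threshold."""
    if centiloid is None:
        return "unknown"
    centiloid = float(centiloid)
    if not np.isfinite(centiloid):
        raise ValueError("centiloid must be finite")
    return "positive" if centiloid > threshold else "negative"
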