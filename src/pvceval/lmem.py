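"""Linear mixed-effects analysis of longitudinal log-SUVR.

Fits the model ``lnSUVR ~ covariates + time * group`` with independent
per-subject random intercept and random slope, and derives every
evaluation statistic: residual percent CV, group-slope contrast t-scores,
slope-based annualized percent change, per-subject changes from BLUPs,
longitudinal effect sizes, parametric bootstrap intervals, Spearman
correlation of baseline level vs change, and the per-method tradeoff
table (within-subject variability vs group separability).
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "LmemFit",
    "LmemSpec",
    "MethodEvaluation",
    "annualized_pct_from_slope",
    "bootstrap_ci",
    "evaluate_methods",
    "fit_lmem",
    "group_slope",
    "group_slope_se",
    "interaction_tscores",
    "longitudinal_effect_size",
    "residual_pct_cv",
    "spearman_baseline_vs_change",
    "subject_annualized_changes",
]

#: normal-approximation significance threshold for contrast t-scores
T_SIGNIFICANT = 1.96


@dataclass
class LmemSpec:
    """What to fit: ROI, PVC method tag, covariates, grouping factor.

    ``group_vars`` may name one subject column (e.g. ``group`` or
    ``tau_level``) or two, in which case the crossed cells (e.g.
    diagnostic x tau level) form the interaction factor.
    """

    roi: str
    method: str = "none"
    covariates: tuple[str, ...] = ()
    group_vars: tuple[str, ...] = ("group",)
    reference_group: str = "CU"
    reml: bool = True

    _ALLOWED_COVARIATES = ("apoe4", "age", "sex", "ctl")

    def __post_init__(self) -> None:
        if isinstance(self.group_vars, str):
            self.group_vars = (self.group_vars,)
        self.group_vars = tuple(self.group_vars)
        self.covariates = tuple(self.covariates)
        bad = [c for c in self.covariates if c not in self._ALLOWED_COVARIATES]
        if bad:
            raise ValueError(f"unsupported covariates {bad}; allowed: {self._ALLOWED_COVARIATES}")
        if not 1 <= len(self.group_vars) <= 2:
            raise ValueError("group_vars must name one or two subject columns")


@dataclass
class LmemFit:
    """Fitted fixed effects, variance components, and subject BLUPs."""

    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    cov_beta: pd.DataFrame
    sigma: float
    sigma_u: float
    sigma_v: float
    blups: dict[str, tuple[float, float]]
    loglik: float
    converged: bool
    n_obs: int
    n_subjects: int
    spec: LmemSpec
    group_levels: tuple[str, ...]
    subject_groups: dict[str, str]
    interaction_terms: dict[str, str] = field(default_factory=dict)

    def slope(self, group: str) -> float:
        return group_slope(self, group)


_COVARIATE_TERMS = {
    "apoe4": "C(apoe4)",
    "age": "age_years",
    "sex": "C(sex)",
    "ctl": "centiloid",
}


def _prepare_data(scans: pd.DataFrame, subjects: pd.DataFrame, spec: LmemSpec) -> pd.DataFrame:
    data = scans[(scans["roi"] == spec.roi) & (scans["method"] == spec.method)].copy()
    if data.empty:
        raise ValueError(f"no scans for roi={spec.roi!r} method={spec.method!r}")
    subj_cols = [c for c in subjects.columns if c not in data.columns or c == "subject_id"]
    data = data.merge(subjects[subj_cols], on="subject_id", how="left", validate="many_to_one")
    if (data["suvr"] <= 0).any() or not np.isfinite(data["suvr"]).all():
        raise ValueError("SUVR must be finite and strictly positive before the log transform")
    data["lnsuvr"] = np.log(data["suvr"].to_numpy())
    data["time"] = data["time_years"].astype(float)

    if len(spec.group_vars) == 1:
        data["grp"] = data[spec.group_vars[0]].astype(str)
    else:
        a, b = spec.group_vars
        data["grp"] = data[a].astype(str) + ":" + data[b].astype(str)
        # a crossed cell with no subjects makes the interaction inestimable
        observed = set(data["grp"].unique())
        expected = {
            f"{x}:{y}" for x in data[a].astype(str).unique() for y in data[b].astype(str).unique()
        }
        empty = sorted(expected - observed)
        if empty:
            raise ValueError(
                f"empty interaction cells {empty}; the {a} x {b} x time interaction "
                "cannot be estimated on this sample"
            )
    if spec.reference_group not in set(data["grp"]):
        raise ValueError(f"reference group {spec.reference_group!r} not present")
    if "ctl" in spec.covariates and data["centiloid"].isna().any():
        raise ValueError("centiloid covariate requested but some values are missing")
    return data


def _formula(spec: LmemSpec) -> str:
    terms = [_COVARIATE_TERMS[c] for c in spec.covariates]
    terms.append(f"time * C(grp, Treatment('{spec.reference_group}'))")
    return "lnsuvr ~ " + " + ".join(terms)


def fit_lmem(scans: pd.DataFrame, subjects: pd.DataFrame, spec: LmemSpec) -> LmemFit:
    """Fit the mixed model for one (ROI, method) on a tidy scan table.

    ``scans`` columns: subject_id, visit_week, time_years, method, roi,
    suvr.  ``subjects`` columns: subject_id, group, tau_level, age_years,
    sex, apoe4, centiloid.  REML by default; the random intercept and
    random slope are independent.
    """
    data = _prepare_data(scans, subjects, spec)
    model = smf.mixedlm(
        _formula(spec),
        data,
        groups=data["subject_id"],
        re_formula="1",
        vc_formula={"slope": "0 + time"},
    )
    rank = np.linalg.matrix_rank(model.exog)
    if rank < model.exog.shape[1]:
        raise ValueError(
            f"singular fixed-effect design (rank {rank} < {model.exog.shape[1]}); "
            "check for empty or confounded interaction cells"
        )
    result = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        for method in ("lbfgs", "powell", "bfgs"):
            result = model.fit(reml=spec.reml, method=method)
            if result.converged:
                break
    if result is None or not result.converged:
        raise RuntimeError(f"LMEM did not converge for {spec}")

    fe_names = list(result.fe_params.index)
    params = result.fe_params.copy()
    cov_beta = result.cov_params().loc[fe_names, fe_names]
    bse = pd.Series(np.sqrt(np.diag(cov_beta.to_numpy())), index=fe_names)
    tvalues = params / bse

    sigma = float(np.sqrt(result.scale))
    sigma_u = float(np.sqrt(max(result.cov_re.to_numpy()[0, 0], 0.0)))
    sigma_v = float(np.sqrt(max(result.vcomp[0], 0.0))) if len(result.vcomp) else 0.0

    blups = {}
    for sid, effects in result.random_effects.items():
        u = float(effects.get("Group", 0.0))
        slope_keys = [k for k in effects.index if k.startswith("slope")]
        v = float(effects[slope_keys[0]]) if slope_keys else 0.0
        blups[str(sid)] = (u, v)

    interaction_terms = {}
    pattern = re.compile(r"^time:.*\[T\.(.+)\]$")
    for name in fe_names:
        m = pattern.match(name)
        if m:
            interaction_terms[m.group(1)] = name

    subject_groups = (
        data.drop_duplicates("subject_id").set_index("subject_id")["grp"].astype(str).to_dict()
    )
    return LmemFit(
        params=params,
        bse=bse,
        tvalues=tvalues,
        cov_beta=cov_beta,
        sigma=sigma,
        sigma_u=sigma_u,
        sigma_v=sigma_v,
        blups=blups,
        loglik=float(result.llf),
        converged=bool(result.converged),
        n_obs=int(len(data)),
        n_subjects=int(data["subject_id"].nunique()),
        spec=spec,
        group_levels=tuple(sorted(data["grp"].unique())),
        subject_groups=subject_groups,
        interaction_terms=interaction_terms,
    )


def group_slope(fit: LmemFit, group: str) -> float:
    """Fixed ln-scale slope per year for a group (reference slope plus its
    interaction contrast)."""
    if group not in fit.group_levels:
        raise KeyError(f"unknown group {group!r}")
    slope = float(fit.params["time"])
    if group != fit.spec.reference_group:
        slope += float(fit.params[fit.interaction_terms[group]])
    return slope


def group_slope_se(fit: LmemFit, group: str) -> float:
    if group == fit.spec.reference_group:
        return float(fit.bse["time"])
    term = fit.interaction_terms[group]
    v = (
        fit.cov_beta.loc["time", "time"]
        + fit.cov_beta.loc[term, term]
        + 2.0 * fit.cov_beta.loc["time", term]
    )
    return float(np.sqrt(v))


def residual_pct_cv(sigma: float) -> float:
    """Percent CV implied by the ln-scale residual SD:
    ``100 * sqrt(exp(sigma^2) - 1)`` (approximately ``100 * sigma`` for
    small sigma)."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    return 100.0 * math.sqrt(math.expm1(sigma**2))


def interaction_tscores(fit: LmemFit, reference_group: str | None = None) -> dict[str, float]:
    """t-score of each group-vs-reference slope contrast.

    With the model's own reference these are the interaction coefficients'
    t-values; for any other reference, contrasts are re-formed from the
    coefficient covariance.
    """
    if not fit.converged:
        raise RuntimeError("fit did not converge")
    ref = reference_group or fit.spec.reference_group
    if ref not in fit.group_levels:
        raise KeyError(f"reference group {ref!r} not present")
    out = {}
    for g in fit.group_levels:
        if g == ref:
            continue
        diff = group_slope(fit, g) - group_slope(fit, ref)
        if g == fit.spec.reference_group or ref == fit.spec.reference_group:
            other = g if ref == fit.spec.reference_group else ref
            se = float(fit.bse[fit.interaction_terms[other]])
        else:
            tg, tr = fit.interaction_terms[g], fit.interaction_terms[ref]
            v = (
                fit.cov_beta.loc[tg, tg]
                + fit.cov_beta.loc[tr, tr]
                - 2.0 * fit.cov_beta.loc[tg, tr]
            )
            se = float(np.sqrt(v))
        out[g] = diff / se
    return out


def annualized_pct_from_slope(slope_ln_per_year: float) -> float:
    """ln-scale slope per year -> annualized percent change."""
    if not np.isfinite(slope_ln_per_year):
        raise ValueError("slope must be finite")
    return 100.0 * math.expm1(slope_ln_per_year)


def subject_annualized_changes(fit: LmemFit, subjects=None) -> dict[str, float]:
    """Per-subject annualized percent change: group fixed slope plus the
    subject's random-slope BLUP, exponentiated.

    Covariates enter the model as intercept shifts only, so they do not
    alter per-subject slopes.
    """
    ids = list(subjects) if subjects is not None else list(fit.blups)
    out = {}
    for sid in ids:
        if sid not in fit.blups:
            raise KeyError(f"subject {sid!r} absent from fit")
        group = fit.subject_groups[sid]
        slope = group_slope(fit, group) + fit.blups[sid][1]
        out[sid] = annualized_pct_from_slope(slope)
    return out


def longitudinal_effect_size(changes) -> float:
    """Mean of the change values divided by their standard deviation."""
    values = np.asarray(list(changes), dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values")
    sd = float(values.std(ddof=1))
    if sd == 0:
        raise ValueError("zero standard deviation: effect size undefined")
    return float(values.mean()) / sd


def bootstrap_ci(statistic_fn, fit: LmemFit, n_draws: int = 1000, seed: int = 0):
    """Parametric bootstrap of a statistic of the fixed effects.

    Draws coefficient vectors from ``N(beta_hat, V_hat)`` and recomputes
    ``statistic_fn(beta: pd.Series) -> float`` per draw.  Returns
    ``(mean, lo95, hi95)`` with a percentile interval.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    cov = fit.cov_beta.to_numpy()
    draws = rng.multivariate_normal(fit.params.to_numpy(), cov, size=n_draws, method="svd")
    values = np.empty(n_draws)
    for i, row in enumerate(draws):
        try:
            values[i] = float(statistic_fn(pd.Series(row, index=fit.params.index)))
        except Exception as exc:  # noqa: BLE001 - annotate failing draw
            raise RuntimeError(f"statistic failed on bootstrap draw {i}") from exc
    lo, hi = np.percentile(values, [2.5, 97.5])
    return float(values.mean()), float(lo), float(hi)


def group_change_statistic(fit: LmemFit, group: str):
    """Statistic factory: annualized percent change of a group's fixed
    slope, as a function of a fixed-effect draw (for bootstrap_ci)."""

    def statistic(beta: pd.Series) -> float:
        slope = float(beta["time"])
        if group != fit.spec.reference_group:
            slope += float(beta[fit.interaction_terms[group]])
        return annualized_pct_from_slope(slope)

    return statistic


def spearman_baseline_vs_change(
    baseline: dict[str, float],
    change: dict[str, float],
    n_boot: int = 1000,
    seed: int = 0,
):
    """Spearman rank correlation (tie-corrected) between baseline SUVR and
    annualized change, with a subject-resampling bootstrap CI.

    Returns ``(rho, lo95, hi95)``.
    """
    ids = [s for s in baseline if s in change]
    if len(ids) < 3:
        raise ValueError("need at least 3 paired subjects")
    x = np.array([baseline[s] for s in ids], dtype=float)
    y = np.array([change[s] for s in ids], dtype=float)
    rho = float(stats.spearmanr(x, y).statistic)
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, len(ids), size=len(ids))
        if np.ptp(x[idx]) == 0 or np.ptp(y[idx]) == 0:
            continue
        boots.append(stats.spearmanr(x[idx], y[idx]).statistic)
    if boots:
        lo, hi = np.percentile(boots, [2.5, 97.5])
    else:
        lo = hi = rho
    return rho, float(lo), float(hi)


@dataclass
class MethodEvaluation:
    """Per-method, per-ROI tradeoff rows and the dominance summary."""

    table: pd.DataFrame
    dominance: pd.DataFrame
    failures: list[tuple[str, str, str]] = field(default_factory=list)


def evaluate_methods(
    scan_tables: dict[str, pd.DataFrame],
    subjects: pd.DataFrame,
    rois,
    group_vars=("group",),
    reference_group: str = "CU",
    covariates: tuple[str, ...] = (),
    reml: bool = True,
) -> MethodEvaluation:
    """Fit one LMEM per (method, ROI) and tabulate residual %CV and
    contrast t-scores.

    ``scan_tables`` maps a method tag to its tidy scan table (all methods
    must cover the same subjects and visits).  Method A dominates method B
    for an (ROI, contrast) cell when A has strictly lower %CV and strictly
    higher t-score.  Failed fits are recorded and skipped.
    """
    rows = []
    failures: list[tuple[str, str, str]] = []
    for method, scans in scan_tables.items():
        for roi in rois:
            spec = LmemSpec(
                roi=roi,
                method=method,
                covariates=tuple(covariates),
                group_vars=tuple(group_vars),
                reference_group=reference_group,
                reml=reml,
            )
            try:
                fit = fit_lmem(scans, subjects, spec)
                cv = residual_pct_cv(fit.sigma)
                for contrast, t in interaction_tscores(fit).items():
                    rows.append(
                        {
                            "method": method,
                            "roi": roi,
                            "contrast": f"{contrast} vs {reference_group}",
                            "residual_pct_cv": cv,
                            "t_score": t,
                            "significant": bool(t > T_SIGNIFICANT),
                        }
                    )
            except Exception as exc:  # noqa: BLE001 - evaluation continues per spec
                failures.append((method, roi, str(exc)))
    table = pd.DataFrame(
        rows,
        columns=["method", "roi", "contrast", "residual_pct_cv", "t_score", "significant"],
    )

    dom_rows = []
    methods = list(scan_tables)
    for (roi, contrast), cell in table.groupby(["roi", "contrast"]):
        by_method = cell.set_index("method")
        for a in methods:
            for b in methods:
                if a == b or a not in by_method.index or b not in by_method.index:
                    continue
                dominates = bool(
                    by_method.loc[a, "residual_pct_cv"] < by_method.loc[b, "residual_pct_cv"]
                    and by_method.loc[a, "t_score"] > by_method.loc[b, "t_score"]
                )
                dom_rows.append(
                    {"roi": roi, "contrast": contrast, "method": a, "other": b,
                     "dominates": dominates}
                )
    dominance = pd.DataFrame(
        dom_rows, columns=["roi", "contrast", "method", "other", "dominates"]
    )
    return MethodEvaluation(table=table, dominance=dominance, failures=failures)
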