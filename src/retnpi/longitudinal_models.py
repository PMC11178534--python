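"""Mixed-model repeated-measures (MMRM) analysis of longitudinal eye data.

Both eyes of each patient are followed over visits, so observations are
correlated within patient (longitudinally) and between fellow eyes. The
model is a linear mixed model

    y_ijt = b0 + s1 * min(t, 1) + s2 * max(t - 1, 0) + covariates
            + u_i + v_ij + e_ijt

with a random intercept u_i per patient and v_ij per eye within patient,
fitted by REML. The piecewise time basis gives separate year-1 (s1) and
year-2 (s2) annual rates of change; a Wald contrast tests s1 = s2.

Secondary analyses: exact Wilcoxon signed-rank symmetry tests between
fellow eyes, Mann-Whitney comparison against a normative sample, age/sex
covariate and subgroup refits, and a completer-vs-dropout severity contrast.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf

TIME_BASIS = ("time_y1", "time_y2")


class DesignError(ValueError):
    """The cohort cannot support the requested model."""


@dataclass
class MMRMFit:
    """Fitted piecewise-slope mixed model."""

    slope_year1: float
    slope_year2: float
    ci_year1: tuple[float, float]
    ci_year2: tuple[float, float]
    se_year1: float
    se_year2: float
    slope_difference_p: float | None
    intercept: float
    sd_patient: float
    sd_eye: float
    sd_residual: float
    covariate_effects: dict = field(default_factory=dict)
    fixed_effects: dict = field(default_factory=dict)
    fit_meta: dict = field(default_factory=dict)

    @property
    def converged(self) -> bool:
        return bool(self.fit_meta.get("converged", False))


@dataclass
class TestResult:
    """A scalar hypothesis-test result."""

    statistic: float
    pvalue: float
    n: int
    flag: str | None = None


def _prepare(cohort: pd.DataFrame, response: str) -> pd.DataFrame:
    df = cohort.copy()
    required = {"patient_id", "eye", "visit_time", response}
    missing = required - set(df.columns)
    if missing:
        raise DesignError(f"cohort missing columns: {sorted(missing)}")
    if df["patient_id"].nunique() < 2:
        raise DesignError("need at least 2 patients")
    if df["visit_time"].nunique() < 2:
        raise DesignError("need at least 2 visits")
    t = df["visit_time"].astype(float)
    df["time_y1"] = np.minimum(t, 1.0)
    df["time_y2"] = np.maximum(t - 1.0, 0.0)
    df["eye_uid"] = df["patient_id"].astype(str) + ":" + df["eye"].astype(str)
    return df


def _formula(response: str, covariates) -> str:
    terms = ["time_y1", "time_y2"] + [str(c) for c in covariates]
    return f"{response} ~ " + " + ".join(terms)


def fit_mmrm(
    cohort: pd.DataFrame,
    response: str = "npi_overall",
    covariates: tuple[str, ...] = (),
    random_effects: tuple[str, ...] = ("patient", "eye"),
) -> MMRMFit:
    """Fit the piecewise-slope MMRM by REML.

    ``random_effects`` selects the variance components: ``("patient", "eye")``
    is the full model; ``()`` constrains both variances to zero, in which
    case the fixed effects are the ordinary least-squares solution on the
    same design matrix.

    If the response is numerically noise-free (zero residual after OLS),
    the mixed likelihood is singular and the exact interpolating OLS fit is
    returned with zero variance components.
    """
    df = _prepare(cohort, response)
    formula = _formula(response, covariates)

    ols = smf.ols(formula, data=df).fit()
    scale = float(np.mean(np.square(df[response] - df[response].mean()))) or 1.0
    noise_free = float(ols.ssr) <= 1e-12 * max(scale, 1.0) * len(df)

    if noise_free or not random_effects:
        params = ols.params
        if noise_free:
            se = {k: 0.0 for k in params.index}
            ci = {k: (float(params[k]), float(params[k])) for k in params.index}
            p_diff = None
            resid_sd = 0.0
        else:
            se = {k: float(ols.bse[k]) for k in params.index}
            conf = ols.conf_int()
            ci = {k: (float(conf.loc[k, 0]), float(conf.loc[k, 1])) for k in params.index}
            p_diff = float(ols.t_test("time_y1 - time_y2 = 0").pvalue)
            resid_sd = float(np.sqrt(ols.mse_resid))
        return MMRMFit(
            slope_year1=float(params["time_y1"]),
            slope_year2=float(params["time_y2"]),
            ci_year1=ci["time_y1"],
            ci_year2=ci["time_y2"],
            se_year1=se["time_y1"],
            se_year2=se["time_y2"],
            slope_difference_p=p_diff,
            intercept=float(params["Intercept"]),
            sd_patient=0.0,
            sd_eye=0.0,
            sd_residual=resid_sd,
            covariate_effects={
                c: {"estimate": float(params[c]), "se": se[c], "ci": ci[c]}
                for c in params.index
                if c not in ("Intercept", "time_y1", "time_y2")
            },
            fixed_effects={k: float(v) for k, v in params.items()},
            fit_meta={
                "method": "OLS (noise-free data)" if noise_free else "OLS",
                "converged": True,
                "n_obs": len(df),
            },
        )

    vc = {}
    re_formula = "1" if "patient" in random_effects else "0"
    if "eye" in random_effects:
        vc["eye"] = "0 + C(eye_uid)"
    model = smf.mixedlm(
        formula,
        data=df,
        groups="patient_id",
        re_formula=re_formula,
        vc_formula=vc or None,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=True, method=["lbfgs", "powell"])

    fe = res.fe_params
    conf = res.conf_int()
    sd_patient = (
        float(np.sqrt(max(res.cov_re.iloc[0, 0], 0.0)))
        if "patient" in random_effects else 0.0
    )
    sd_eye = float(np.sqrt(max(res.vcomp[0], 0.0))) if "eye" in random_effects else 0.0
    contrast = np.zeros((1, len(fe)))
    contrast[0, list(fe.index).index("time_y1")] = 1.0
    contrast[0, list(fe.index).index("time_y2")] = -1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p_diff = float(res.t_test(contrast).pvalue)

    def _ci(name):
        return (float(conf.loc[name, 0]), float(conf.loc[name, 1]))

    return MMRMFit(
        slope_year1=float(fe["time_y1"]),
        slope_year2=float(fe["time_y2"]),
        ci_year1=_ci("time_y1"),
        ci_year2=_ci("time_y2"),
        se_year1=float(res.bse_fe["time_y1"]),
        se_year2=float(res.bse_fe["time_y2"]),
        slope_difference_p=p_diff,
        intercept=float(fe["Intercept"]),
        sd_patient=sd_patient,
        sd_eye=sd_eye,
        sd_residual=float(np.sqrt(res.scale)),
        covariate_effects={
            c: {"estimate": float(fe[c]), "se": float(res.bse_fe[c]), "ci": _ci(c)}
            for c in fe.index
            if c not in ("Intercept", "time_y1", "time_y2")
        },
        fixed_effects={k: float(v) for k, v in fe.items()},
        fit_meta={
            "method": "REML MixedLM",
            "converged": bool(res.converged),
            "n_obs": len(df),
        },
    )


def symmetry_test(
    cohort: pd.DataFrame,
    visit: float,
    response: str = "npi_overall",
    alternative: str = "two-sided",
) -> TestResult:
    """Wilcoxon matched-pairs signed-rank test of OD vs OS at one visit.

    Exact null distribution for n <= 25 pairs (no ties), normal
    approximation above. All-zero differences give p = 1 with a flag.
    """
    at = cohort[np.isclose(cohort["visit_time"].astype(float), visit)]
    wide = at.pivot_table(index="patient_id", columns="eye", values=response)
    if not {"OD", "OS"} <= set(wide.columns):
        raise DesignError("need both OD and OS measurements at this visit")
    wide = wide.dropna(subset=["OD", "OS"])
    d = (wide["OD"] - wide["OS"]).to_numpy(dtype=float)
    n = len(d)
    if n == 0:
        raise DesignError("no complete OD/OS pairs at this visit")
    if np.all(d == 0):
        return TestResult(statistic=0.0, pvalue=1.0, n=n, flag="all differences zero")
    method = "exact" if n <= 25 and not _has_wilcoxon_ties(d) else "approx"
    stat, p = stats.wilcoxon(d, alternative=alternative, method=method)
    return TestResult(statistic=float(stat), pvalue=float(p), n=n)


def _has_wilcoxon_ties(d: np.ndarray) -> bool:
    d = d[d != 0]
    return np.any(d == 0) or len(np.unique(np.abs(d))) < len(d)


def wilcoxon_signed_rank(differences, alternative: str = "two-sided") -> TestResult:
    """Exact-when-possible Wilcoxon signed-rank test on raw paired differences."""
    d = np.asarray(differences, dtype=float)
    d = d[~np.isnan(d)]
    if np.all(d == 0):
        return TestResult(0.0, 1.0, len(d), flag="all differences zero")
    method = "exact" if len(d) <= 25 and not _has_wilcoxon_ties(d) else "approx"
    stat, p = stats.wilcoxon(d, alternative=alternative, method=method)
    return TestResult(float(stat), float(p), len(d))


def normative_comparison(values, normative, alternative: str = "two-sided") -> TestResult:
    """Mann-Whitney U test of a sample against a normative sample
    (tie-corrected; exact when both samples are small and tie-free)."""
    x = np.asarray(values, dtype=float)
    y = np.asarray(normative, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DesignError("both samples must be non-empty")
    stat, p = stats.mannwhitneyu(x, y, alternative=alternative)
    return TestResult(float(stat), float(p), int(x.size + y.size))


def covariate_and_subgroup_analysis(
    cohort: pd.DataFrame,
    response: str = "npi_overall",
    age_split: float = 45.0,
    alpha: float = 0.05,
) -> dict:
    """Refit the MMRM with age and sex covariates and by age subgroup.

    Reports whether adding each covariate changes the significance of the
    year-1 time effect, and the per-subgroup time effects for eyes of
    patients younger/older than ``age_split`` years.
    """
    report: dict = {}
    base = fit_mmrm(cohort, response=response)
    report["base"] = base
    base_sig = _year1_significant(base, alpha)

    for cov in ("age", "sex"):
        if cov not in cohort.columns:
            continue
        f = fit_mmrm(cohort, response=response, covariates=(cov,))
        report[f"with_{cov}"] = f
        report[f"{cov}_changes_time_significance"] = (
            _year1_significant(f, alpha) != base_sig
        )

    if "age" in cohort.columns:
        subgroups = {}
        for name, sel in (
            ("younger", cohort["age"] < age_split),
            ("older", cohort["age"] >= age_split),
        ):
            sub = cohort[sel]
            if sub["patient_id"].nunique() < 2:
                warnings.warn(f"age subgroup {name!r} too small; skipped", stacklevel=2)
                continue
            subgroups[name] = fit_mmrm(sub, response=response)
        report["age_subgroups"] = subgroups
    return report


def _year1_significant(fit: MMRMFit, alpha: float) -> bool:
    lo, hi = fit.ci_year1
    return not (lo <= 0.0 <= hi)


def dropout_contrast(
    cohort: pd.DataFrame,
    responses: tuple[str, ...] = ("npi_overall",),
) -> dict:
    """Completer-vs-dropout severity contrast from the MMRM.

    Adds a dropout fixed effect (1 = withdrew, 0 = completed) to the
    piecewise-time mixed model; the coefficient is how much more
    nonperfusion dropouts carry, with its standard error, per response
    (overall and/or per zone).
    """
    if "completer" not in cohort.columns:
        raise DesignError("cohort lacks a 'completer' column")
    df = cohort.copy()
    df["dropout"] = (~df["completer"].astype(bool)).astype(float)
    strata = set(df["dropout"].unique())
    if strata != {0.0, 1.0}:
        raise DesignError("need both completer and dropout strata")
    out = {}
    for resp in responses:
        fit = fit_mmrm(df, response=resp, covariates=("dropout",))
        eff = fit.covariate_effects["dropout"]
        se = eff["se"]
        z = eff["estimate"] / se if se > 0 else float("inf")
        out[resp] = {
            "estimate": eff["estimate"],
            "se": se,
            "ci": eff["ci"],
            "z": z,
            "p": 2.0 * float(stats.norm.sf(abs(z))) if np.isfinite(z) else 0.0,
        }
    return out
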