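"""Group statistics for structure volumes.

Implements the statistical core of the study:

* **w-scores** — structure volume is regressed on total brain volume (TBV)
  within a reference group, ``V = b0 + b1*T + e``; a subject's w-score is the
  z-score of its residual against the reference residual distribution. This
  residual normalization removes the TBV confound more effectively than
  dividing by TBV, and puts every structure on a common scale.
* **longitudinal change rates** — per-subject, per-structure least-squares
  slope of volume against age, ``V(t) = V(t0) + R*(t - t0) + e``.
* **hypothesis tests** — paired/unpaired t-tests, one-way ANOVA with
  Bonferroni post hoc pairs, and Benjamini-Hochberg FDR across structures.
  Degenerate (zero-variance) t-tests return flagged limiting p-values so
  structure-wise sweeps never abort.
* **linear mixed-effects models** — three variants of the longitudinal model
  ``V ~ time * group``: fixed effects only, + random intercept, + random
  intercept and slope (with covariance). Fitted by REML (statsmodels MixedLM);
  models are compared by AIC = -2*loglik + 2*(fixed + variance + residual
  parameters) and boundary-corrected likelihood-ratio tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.formula.api import mixedlm, ols
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "WScoreModel",
    "ChangeRateFit",
    "TestResult",
    "LMEFit",
    "fit_wscore",
    "wscore",
    "change_rate",
    "paired_test",
    "unpaired_test",
    "anova_bonferroni",
    "bh_fdr",
    "fit_lme",
    "compare_lme",
    "relative_residuals",
    "LME_FORMS",
]


# ---------------------------------------------------------------------------
# w-score normalization


@dataclass(frozen=True)
class WScoreModel:
    """Fitted volume-on-TBV regression plus reference residual moments."""

    beta0: float        # intercept, mm^3
    beta1: float        # TBV coefficient, dimensionless
    resid_mean: float   # reference-group residual mean (0 by OLS construction)
    resid_sd: float     # reference-group residual SD (ddof 1)
    reference_group: str = "UT"
    n_ref: int = 0

    def residual(self, volume, tbv):
        return np.asarray(volume) - self.beta0 - self.beta1 * np.asarray(tbv)

    def wscore(self, volume, tbv):
        return (self.residual(volume, tbv) - self.resid_mean) / self.resid_sd


def fit_wscore(volumes, tbvs, reference_group: str = "UT") -> WScoreModel:
    """OLS of structure volume on TBV over the reference group.

    Requires >= 3 reference subjects, non-constant TBV, and non-degenerate
    residuals (a perfectly collinear reference would give SD 0).
    """
    v = np.asarray(volumes, dtype=float)
    t = np.asarray(tbvs, dtype=float)
    if v.shape != t.shape or v.ndim != 1:
        raise ValueError("volumes and TBVs must be 1-D arrays of equal length")
    if v.size < 3:
        raise ValueError("need at least 3 reference subjects")
    if np.ptp(t) == 0:
        raise ValueError("reference TBVs are all equal; slope unidentifiable")
    beta1, beta0 = np.polyfit(t, v, 1)
    resid = v - beta0 - beta1 * t
    sd = float(resid.std(ddof=1))
    if sd <= 0 or not np.isfinite(sd):
        raise ValueError("degenerate reference: residual SD is zero")
    return WScoreModel(float(beta0), float(beta1), float(resid.mean()), sd,
                       reference_group, int(v.size))


def wscore(model: WScoreModel, volume: float, tbv: float) -> float:
    """Standardized residual (z-score against the reference residuals)."""
    return float(model.wscore(volume, tbv))


# ---------------------------------------------------------------------------
# longitudinal change rate


@dataclass(frozen=True)
class ChangeRateFit:
    intercept: float    # volume at the first timepoint, mm^3
    slope: float        # change rate R, mm^3/month
    resid_sd: float     # residual SD (0 when df <= 0)
    timepoints: tuple[float, ...]


def change_rate(times, volumes) -> ChangeRateFit:
    """Least-squares volume-vs-age line for one subject and structure."""
    t = np.asarray(times, dtype=float)
    v = np.asarray(volumes, dtype=float)
    if t.shape != v.shape or t.ndim != 1:
        raise ValueError("times and volumes must be 1-D arrays of equal length")
    if np.unique(t).size < 2:
        raise ValueError("change rate needs at least two distinct timepoints")
    t0 = t[0]
    slope, intercept = np.polyfit(t - t0, v, 1)
    resid = v - (intercept + slope * (t - t0))
    dof = t.size - 2
    sd = float(np.sqrt((resid ** 2).sum() / dof)) if dof > 0 else 0.0
    return ChangeRateFit(float(intercept), float(slope), sd, tuple(t))


# ---------------------------------------------------------------------------
# hypothesis tests


@dataclass
class TestResult:
    statistic: float
    p: float
    df: float
    family: str
    p_adjusted: float | None = None
    degenerate: bool = False


def _finish(stat, p, df, family, degenerate=False) -> TestResult:
    return TestResult(float(stat), float(p), float(df), family, None, degenerate)


def paired_test(a, b, alternative: str = "two-sided") -> TestResult:
    """Paired Student t-test; zero-variance differences yield flagged limits."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("paired test needs two equal-length samples, n >= 2")
    d = a - b
    if d.std(ddof=1) == 0:
        return _finish(0.0 if d.mean() == 0 else np.inf,
                       1.0 if d.mean() == 0 else 0.0,
                       a.size - 1, "paired-t", degenerate=True)
    res = sps.ttest_rel(a, b, alternative=alternative)
    return _finish(res.statistic, res.pvalue, a.size - 1, "paired-t")


def unpaired_test(a, b, alternative: str = "two-sided",
                  equal_var: bool = True) -> TestResult:
    """Unpaired Student (or Welch) t-test with degenerate-variance flagging."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("unpaired test needs n >= 2 per sample")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        same = a.mean() == b.mean()
        return _finish(0.0 if same else np.inf, 1.0 if same else 0.0,
                       a.size + b.size - 2, "unpaired-t", degenerate=True)
    res = sps.ttest_ind(a, b, alternative=alternative, equal_var=equal_var)
    df = a.size + b.size - 2 if equal_var else res.df
    return _finish(res.statistic, res.pvalue, df, "unpaired-t")


def anova_bonferroni(groups: list) -> dict:
    """One-way ANOVA with Bonferroni-corrected pairwise post hoc t-tests.

    Returns {"anova": TestResult, "pairs": {(i, j): TestResult}} with the
    pairwise adjusted p multiplied by the number of pairs (capped at 1).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("ANOVA needs >= 2 groups with n >= 2 each")
    f = sps.f_oneway(*groups)
    k = len(groups)
    n = sum(g.size for g in groups)
    out = _finish(f.statistic, f.pvalue, k - 1, "anova")
    pairs = {}
    n_pairs = k * (k - 1) // 2
    for i in range(k):
        for j in range(i + 1, k):
            t = unpaired_test(groups[i], groups[j])
            t.family = "anova-posthoc"
            t.p_adjusted = min(1.0, t.p * n_pairs)
            pairs[(i, j)] = t
    return {"anova": out, "pairs": pairs, "df_within": n - k}


def bh_fdr(pvalues, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (adjusted p, rejection flags at level q)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    reject, p_adj, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


# ---------------------------------------------------------------------------
# linear mixed-effects models

LME_FORMS = ("fixed", "intercept", "intercept_slope")


@dataclass
class LMEFit:
    form: str
    fixed_effects: dict
    cov_re: np.ndarray          # random-effect covariance (empty for "fixed")
    sigma2: float               # residual variance
    loglik: float               # REML (mixed) or ML (fixed) log-likelihood
    aic: float
    n_params: int
    n_obs: int
    fitted: np.ndarray = field(repr=False, default=None)   # conditional predictions
    converged: bool = True
    reml: bool = True
    _data_key: tuple = field(repr=False, default=())

    @property
    def sigma_b1(self) -> float:
        return float(np.sqrt(self.cov_re[0, 0])) if self.cov_re.size else 0.0

    @property
    def sigma_b2(self) -> float:
        return float(np.sqrt(self.cov_re[1, 1])) if self.cov_re.shape[0] > 1 else 0.0


def _data_key(df: pd.DataFrame) -> tuple:
    v = np.asarray(df["volume"], dtype=float)
    return (len(df), float(v.sum()), float((v ** 2).sum()))


def fit_lme(df: pd.DataFrame, form: str = "intercept_slope",
            diagonal_cov: bool = False) -> LMEFit:
    """Fit one longitudinal model variant for a single structure.

    ``df`` needs columns subject, group, time, volume. Time is centered at
    the first timepoint internally; reported fixed effects are on the
    centered-time scale. The "fixed" variant is an ordinary least-squares
    fit of ``volume ~ time * group`` (individuals not modelled); the mixed
    variants add a per-subject random intercept, or random intercept + slope
    with covariance (``diagonal_cov=True`` drops the covariance term).
    """
    if form not in LME_FORMS:
        raise ValueError(f"form must be one of {LME_FORMS}")
    for col in ("subject", "group", "time", "volume"):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r}")
    data = df.copy()
    data["time_c"] = data["time"] - data["time"].min()
    per_subject = data.groupby("subject")["time"].nunique()
    if form == "intercept_slope" and per_subject.max() < 2:
        raise ValueError("random slope unidentifiable: one timepoint per subject")
    gterm = "group" if pd.api.types.is_numeric_dtype(data["group"]) else "C(group)"
    formula = f"volume ~ time_c * {gterm}"
    key = _data_key(data)

    if form == "fixed":
        res = ols(formula, data=data).fit()
        k = res.df_model + 1 + 1  # coefficients + residual variance
        ll = float(res.llf)
        return LMEFit(form, dict(res.params), np.empty((0, 0)), float(res.scale),
                      ll, -2 * ll + 2 * k, int(k), len(data),
                      fitted=np.asarray(res.fittedvalues), reml=False,
                      _data_key=key)

    re_formula = "1" if form == "intercept" else "1 + time_c"
    model = mixedlm(formula, data=data, groups=data["subject"],
                    re_formula=re_formula)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)  # boundary (singular) cov_re
        try:
            res = model.fit(reml=True, method="lbfgs", maxiter=200)
        except Exception:
            res = model.fit(reml=True, method="powell", maxiter=500)
    cov_re = np.asarray(res.cov_re)
    if form == "intercept_slope" and diagonal_cov:
        cov_re = np.diag(np.diag(cov_re))
    n_fixed = len(res.fe_params)
    n_vc = 1 if form == "intercept" else (2 if diagonal_cov else 3)
    k = n_fixed + n_vc + 1
    ll = float(res.llf)
    fitted = np.asarray(res.fittedvalues)  # includes BLUP random effects
    return LMEFit(form, dict(res.fe_params), cov_re, float(res.scale),
                  ll, -2 * ll + 2 * k, int(k), len(data), fitted=fitted,
                  converged=bool(getattr(res, "converged", True)),
                  _data_key=key)


def compare_lme(fits: list[LMEFit]) -> pd.DataFrame:
    """Model-comparison table: AIC, ΔAIC, boundary-corrected LRT p-values.

    All fits must be on identical data. Successive nested random-effect
    structures are compared with a likelihood-ratio test whose null
    distribution is the 50:50 chi-square mixture appropriate at a variance
    boundary. Comparisons that cross the fixed/mixed divide mix ML and REML
    likelihoods (as in common practice for this design) and are flagged.
    """
    if len(fits) < 1:
        raise ValueError("need at least one fit")
    if any(f._data_key != fits[0]._data_key for f in fits):
        raise ValueError("fits are not on identical data")
    rows = []
    aics = [f.aic for f in fits]
    best = int(np.argmin(aics))
    prev = None
    for i, f in enumerate(fits):
        row = {"form": f.form, "aic": f.aic, "loglik": f.loglik,
               "n_params": f.n_params, "delta_aic": f.aic - aics[best],
               "aic_best": i == best, "lrt_stat": np.nan, "lrt_p": np.nan,
               "lrt_caveat": ""}
        if prev is not None:
            stat = max(0.0, 2.0 * (f.loglik - prev.loglik))
            q = f.n_params - prev.n_params
            if q <= 1:
                p = 0.5 * sps.chi2.sf(stat, 1) + (0.5 if stat == 0 else 0.0)
            else:
                p = 0.5 * (sps.chi2.sf(stat, q - 1) + sps.chi2.sf(stat, q))
            row["lrt_stat"] = stat
            row["lrt_p"] = p
            if prev.reml != f.reml:
                row["lrt_caveat"] = "ML-vs-REML comparison across fixed/mixed forms"
        rows.append(row)
        prev = f
    return pd.DataFrame(rows)


def relative_residuals(fit: LMEFit, df: pd.DataFrame) -> pd.DataFrame:
    """Signed relative residuals, 100 * (predicted - observed) / observed.

    Predictions are the fit's conditional fitted values (BLUP random effects
    included for the mixed forms). Adds per-group/timepoint mean-absolute
    summaries in ``df.attrs['summary']``.
    """
    if fit.fitted is None or fit._data_key != _data_key(df):
        raise ValueError("fit was not produced from these rows")
    obs = np.asarray(df["volume"], dtype=float)
    if np.any(obs == 0):
        raise ValueError("observed volume of zero; relative residual undefined")
    rel = 100.0 * (fit.fitted - obs) / obs
    out = df.copy()
    out["relative_residual_pct"] = rel
    summary = (out.assign(abs_rel=np.abs(rel))
               .groupby(["group", "time"], observed=True)["abs_rel"]
               .agg(["mean", "std", "count"]).reset_index())
    out.attrs["summary"] = summary.to_dict("records")
    return out
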