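"""Association statistics linking brain-PAD, amyloid and cognition.

Thin, validated wrappers over statsmodels/scipy estimators (OLS, binary
and ordinal logistic regression, Welch/Student t-tests, Pearson
correlation, Fisher's exact test), returning a uniform tidy
``ModelResult``, plus :func:`run_cohort_models`, which fits the full
battery of cohort models: group differences in brain-PAD and ICV,
logistic prediction of PiB status from brain-PAD adjusting for age,
linear models of amyloid burden, the CAMCOG ~ brain-PAD x PiB-status
interaction, ordinal prediction of CAMDEX class, and the supporting
correlations and t-tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.miscmodels.ordinal_model import OrderedModel
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

__all__ = [
    "ModelResult",
    "linear_model",
    "logistic_model",
    "ordinal_logistic",
    "two_sample_t",
    "one_sample_t",
    "pearson_cor",
    "fisher_exact",
    "run_cohort_models",
]


@dataclass
class ModelResult:
    """Tidy summary of one fitted model.

    ``terms`` has one row per coefficient: term, estimate, se, statistic,
    p, ci_low, ci_high.
    """

    model_name: str
    terms: pd.DataFrame
    n: int
    statistic_kind: str              # "t" | "z"
    r_squared: float | None = None
    flags: list[str] = field(default_factory=list)

    def term(self, name: str) -> pd.Series:
        row = self.terms[self.terms["term"] == name]
        if row.empty:
            raise KeyError(f"no term {name!r} in model {self.model_name!r}")
        return row.iloc[0]

    def tidy(self) -> pd.DataFrame:
        t = self.terms.copy()
        t.insert(0, "model_name", self.model_name)
        return t


def _tidy_terms(params, bse, stat, pvals, ci) -> pd.DataFrame:
    return pd.DataFrame({
        "term": list(params.index),
        "estimate": params.to_numpy(float),
        "se": bse.to_numpy(float),
        "statistic": np.asarray(stat, dtype=float),
        "p": np.asarray(pvals, dtype=float),
        "ci_low": ci.iloc[:, 0].to_numpy(float),
        "ci_high": ci.iloc[:, 1].to_numpy(float),
    })


def _design(design: pd.DataFrame, add_intercept: bool) -> pd.DataFrame:
    X = design.astype(float)
    if add_intercept:
        X = sm.add_constant(X, has_constant="add")
        X = X.rename(columns={"const": "intercept"})
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify which columns can be dropped without losing rank
        redundant = []
        base = X.to_numpy()
        for j, col in enumerate(X.columns):
            if np.linalg.matrix_rank(np.delete(base, j, axis=1)) == rank:
                redundant.append(col)
        raise ValueError(f"design is rank deficient; collinear terms: {redundant}")
    return X


def linear_model(outcome, design: pd.DataFrame, model_name: str = "linear",
                 add_intercept: bool = True) -> ModelResult:
    """Ordinary least squares with Wald t statistics and 95% CIs."""
    y = np.asarray(outcome, dtype=float)
    X = _design(design, add_intercept)
    if y.size <= X.shape[1]:
        raise ValueError("need more observations than parameters")
    fit = sm.OLS(y, X).fit()
    terms = _tidy_terms(fit.params, fit.bse, fit.tvalues, fit.pvalues,
                        fit.conf_int())
    return ModelResult(model_name, terms, int(fit.nobs), "t",
                       r_squared=float(fit.rsquared))


def logistic_model(outcome, design: pd.DataFrame, model_name: str = "logistic",
                   add_intercept: bool = True) -> ModelResult:
    """Binary logistic regression (ML / IRLS) with Wald z CIs on log-odds."""
    y = np.asarray(outcome, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("logistic outcome must be 0/1")
    X = _design(design, add_intercept)
    if y.size <= X.shape[1]:
        raise ValueError("need more observations than parameters")
    flags = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = sm.Logit(y, X)
        try:
            fit = model.fit(disp=0, maxiter=200)
        except np.linalg.LinAlgError:
            # singular Hessian under (near-)complete separation: fall back
            # to a gradient method and report the estimates flagged
            fit = model.fit(disp=0, maxiter=500, method="bfgs")
            flags.append("possible complete separation; estimates unreliable")
        if any(issubclass(w.category, PerfectSeparationWarning) for w in caught):
            flags.append("possible complete separation; estimates unreliable")
    if np.any(np.abs(fit.params) > 15):
        flags.append("extreme coefficients; possible separation")
    terms = _tidy_terms(fit.params, fit.bse, fit.tvalues, fit.pvalues,
                        fit.conf_int())
    return ModelResult(model_name, terms, int(fit.nobs), "z", flags=flags)


def ordinal_logistic(outcome, design: pd.DataFrame,
                     model_name: str = "ordinal",
                     levels: list | None = None) -> ModelResult:
    """Proportional-odds (cumulative logit) ordinal regression.

    ``outcome`` is an ordered categorical (or codable as one via
    ``levels``).  Thresholds are reported as ``cut_*`` terms and are
    strictly increasing by construction.
    """
    y = pd.Series(outcome).reset_index(drop=True)
    if levels is not None:
        y = pd.Categorical(y, categories=levels, ordered=True)
    elif not isinstance(y.dtype, pd.CategoricalDtype):
        y = pd.Categorical(y, categories=sorted(pd.unique(y)), ordered=True)
    else:
        y = pd.Categorical(y, categories=y.cat.categories, ordered=True)
    y = pd.Series(y, name="outcome")
    counts = y.value_counts()
    empty = [lv for lv in y.cat.categories if counts.get(lv, 0) == 0]
    if empty:
        raise ValueError(f"empty outcome level(s): {empty}")
    X = _design(design, add_intercept=False).reset_index(drop=True)
    fit = OrderedModel(y, X, distr="logit").fit(method="bfgs", disp=0,
                                                maxiter=1000, gtol=1e-08)
    terms = _tidy_terms(fit.params, fit.bse, fit.tvalues, fit.pvalues,
                        fit.conf_int())
    return ModelResult(model_name, terms, int(len(y)), "z")


def two_sample_t(group_a, group_b, welch: bool = True) -> dict:
    """Two-sample t-test comparing group means (Welch by default)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if np.var(a) == 0 and np.var(b) == 0:
        raise ValueError("degenerate: zero variance in both groups")
    res = sps.ttest_ind(a, b, equal_var=not welch)
    return {"statistic": float(res.statistic), "p": float(res.pvalue),
            "df": float(res.df), "mean_diff": float(a.mean() - b.mean())}


def one_sample_t(values, reference_mean: float = 0.0) -> dict:
    """One-sample t-test of the mean against a reference value."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need n >= 2")
    if np.var(v) == 0:
        raise ValueError("zero variance")
    res = sps.ttest_1samp(v, reference_mean)
    return {"statistic": float(res.statistic), "p": float(res.pvalue),
            "df": float(v.size - 1), "mean": float(v.mean())}


def pearson_cor(x, y) -> dict:
    """Pearson correlation with the two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need n >= 3")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("Pearson r undefined: zero variance")
    res = sps.pearsonr(x, y)
    return {"r": float(res.statistic), "p": float(res.pvalue), "n": int(x.size)}


def fisher_exact(table) -> dict:
    """Fisher's exact test on a 2x2 table (two-sided, point-probability)."""
    t = np.asarray(table)
    if t.shape != (2, 2) or np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        t = t.astype(float)
        if t.shape != (2, 2) or np.any(t < 0) or np.any(t != np.round(t)):
            raise ValueError("need a 2x2 table of nonnegative integers")
        t = t.astype(int)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("a margin of the table is all zero")
    res = sps.fisher_exact(t, alternative="two-sided")
    return {"odds_ratio": float(res.statistic), "p": float(res.pvalue)}


_REQUIRED_COLUMNS = [
    "subject_id", "group", "age_years", "brain_pad", "icv_l", "sex",
]


def run_cohort_models(table: pd.DataFrame,
                     reference_brainpad_mean: float = 0.0) -> list[ModelResult]:
    """Fit the full battery of cohort association models.

    ``table`` is the merged per-subject analysis table (cohort + brain-age
    predictions + amyloid profiles).  Rows with group "train" are ignored;
    amyloid and cognition models use the DS rows, with listwise deletion
    of missing CAMCOG.  The returned list has exactly 12 entries, in
    order:

    1.  ``brainpad_group``            brain-PAD ~ group (DS vs control, OLS)
    2.  ``icv_group``                 ICV ~ group (OLS)
    3.  ``pib_status_logistic``       PiB+ ~ brain-PAD + age (DS, logistic)
    4.  ``mean_cortical_bpnd_linear`` mean cortical BP_ND ~ brain-PAD + age (DS)
    5.  ``abnormal_count_linear``     abnormal-ROI count ~ brain-PAD + age (DS)
    6.  ``camcog_brainpad``           CAMCOG ~ brain-PAD (DS)
    7.  ``camcog_interaction``        CAMCOG ~ brain-PAD * PiB-status (DS)
    8.  ``camdex_ordinal``            CAMDEX class ~ brain-PAD (DS, ordinal)
    9.  ``camcog_bpnd_brainpad``      CAMCOG ~ mean BP_ND + brain-PAD (DS)
    10. ``brainpad_group_stable``     brain-PAD ~ group, CAMDEX-stable DS only
    11. ``cor_brainpad_icv``          brain-PAD ~ ICV correlation per group
    12. ``ttests``                    brain-PAD by sex (per group) and APOE (DS)

    Entries 11 and 12 are packaged as pseudo-models whose terms carry the
    correlation/t statistics.  A one-sample t of DS brain-PAD against
    ``reference_brainpad_mean`` (the training-set mean; 0 under unbiased
    cross-validation) is attached to entry 1's flags-free terms as
    ``ds_vs_reference``.
    """
    missing = [c for c in _REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"missing required column(s): {missing}")
    test = table[table["group"].isin(["DS", "control"])].copy()
    ds = test[test["group"] == "DS"].copy()
    is_ds = (test["group"] == "DS").astype(float)

    results: list[ModelResult] = []

    # 1. brain-PAD ~ group
    m1 = linear_model(test["brain_pad"], pd.DataFrame({"group_ds": is_ds}),
                      "brainpad_group")
    ref = one_sample_t(ds["brain_pad"], reference_brainpad_mean)
    m1.terms = pd.concat([m1.terms, pd.DataFrame([{
        "term": "ds_vs_reference", "estimate": ref["mean"], "se": np.nan,
        "statistic": ref["statistic"], "p": ref["p"],
        "ci_low": np.nan, "ci_high": np.nan}])], ignore_index=True)
    results.append(m1)

    # 2. ICV ~ group
    results.append(linear_model(test["icv_l"],
                                pd.DataFrame({"group_ds": is_ds}), "icv_group"))

    # DS-only amyloid models
    pib = (ds["pib_status"] == "positive").astype(float)
    X_pad_age = pd.DataFrame({"brain_pad": ds["brain_pad"],
                              "age_years": ds["age_years"]})
    results.append(logistic_model(pib, X_pad_age, "pib_status_logistic"))
    results.append(linear_model(ds["mean_cortical_bpnd"], X_pad_age,
                                "mean_cortical_bpnd_linear"))
    results.append(linear_model(ds["abnormal_count"], X_pad_age,
                                "abnormal_count_linear"))

    # cognition models: listwise deletion of missing CAMCOG
    dsc = ds.dropna(subset=["camcog"])
    results.append(linear_model(dsc["camcog"],
                                pd.DataFrame({"brain_pad": dsc["brain_pad"]}),
                                "camcog_brainpad"))
    pibc = (dsc["pib_status"] == "positive").astype(float)
    results.append(linear_model(
        dsc["camcog"],
        pd.DataFrame({
            "brain_pad": dsc["brain_pad"],
            "pib_positive": pibc,
            "brain_pad_x_pib": dsc["brain_pad"] * pibc,
        }),
        "camcog_interaction"))

    # 8. ordinal CAMDEX ~ brain-PAD
    dsx = ds.dropna(subset=["camdex_class"])
    results.append(ordinal_logistic(
        dsx["camdex_class"],
        pd.DataFrame({"brain_pad": dsx["brain_pad"]}),
        "camdex_ordinal",
        levels=["stable", "declining", "dementia"]))

    # 9. CAMCOG ~ mean BP_ND + brain-PAD
    results.append(linear_model(
        dsc["camcog"],
        pd.DataFrame({"mean_cortical_bpnd": dsc["mean_cortical_bpnd"],
                      "brain_pad": dsc["brain_pad"]}),
        "camcog_bpnd_brainpad"))

    # 10. group effect restricted to CAMDEX-stable DS + all controls
    stable = test[(test["group"] == "control")
                  | (test["camdex_class"] == "stable")]
    results.append(linear_model(
        stable["brain_pad"],
        pd.DataFrame({"group_ds": (stable["group"] == "DS").astype(float)}),
        "brainpad_group_stable"))

    # 11. brain-PAD ~ ICV correlations per group
    rows = []
    for gname, sub in (("DS", ds), ("control", test[test["group"] == "control"])):
        c = pearson_cor(sub["brain_pad"], sub["icv_l"])
        rows.append({"term": f"r_{gname}", "estimate": c["r"], "se": np.nan,
                     "statistic": np.nan, "p": c["p"],
                     "ci_low": np.nan, "ci_high": np.nan})
    results.append(ModelResult("cor_brainpad_icv", pd.DataFrame(rows),
                               int(len(test)), "t"))

    # 12. t-tests: brain-PAD by sex within each group, and by APOE in DS
    rows = []
    for gname, sub in (("DS", ds), ("control", test[test["group"] == "control"])):
        tt = two_sample_t(sub.loc[sub["sex"] == "male", "brain_pad"],
                          sub.loc[sub["sex"] == "female", "brain_pad"])
        rows.append({"term": f"sex_{gname}", "estimate": tt["mean_diff"],
                     "se": np.nan, "statistic": tt["statistic"], "p": tt["p"],
                     "ci_low": np.nan, "ci_high": np.nan})
    apoe = ds.dropna(subset=["apoe_e4_carrier"])
    if apoe["apoe_e4_carrier"].nunique() == 2:
        tt = two_sample_t(
            apoe.loc[apoe["apoe_e4_carrier"] == "yes", "brain_pad"],
            apoe.loc[apoe["apoe_e4_carrier"] == "no", "brain_pad"])
        rows.append({"term": "apoe_DS", "estimate": tt["mean_diff"],
                     "se": np.nan, "statistic": tt["statistic"], "p": tt["p"],
                     "ci_low": np.nan, "ci_high": np.nan})
    results.append(ModelResult("ttests", pd.DataFrame(rows), int(len(test)), "t"))

    return results
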