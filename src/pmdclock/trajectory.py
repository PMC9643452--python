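"""Methylation-vs-population-doubling trajectory analysis.

Per-CpG ordinary least squares of beta on cumulative PD gives loss/gain
rates in beta units per doubling (the effect-size scale); hypothesis
tests run on logit-transformed m-values. CpGs are categorized into
stably methylated / variable / stably unmethylated groups from their
first-to-last methylation change, and per-CpG rates can be binned by a
covariate (replication-timing WA score, gene expression) and compared
with a Kruskal-Wallis omnibus test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .meth_io import beta_to_m

MIN_SAMPLES_PER_FIT = 3


def median_context_methylation(
    beta: pd.DataFrame,
    annotation: pd.DataFrame,
    *,
    probe_filter=None,
    filter_name: str = "context filter",
) -> pd.Series:
    """Per-sample median beta over the probes selected by ``probe_filter``.

    ``probe_filter`` is a boolean mask over ``annotation`` rows (indexed
    like the beta matrix) or a callable annotation -> mask. Missing betas
    are excluded per sample; a sample with no observed probe gets NaN.
    """
    if callable(probe_filter):
        mask = probe_filter(annotation)
    elif probe_filter is None:
        mask = pd.Series(True, index=annotation.index)
    else:
        mask = pd.Series(probe_filter, index=annotation.index)
    probes = annotation.index[mask.to_numpy(dtype=bool)]
    probes = beta.index.intersection(probes)
    if len(probes) == 0:
        raise ValueError(f"no probes match {filter_name!r}")
    return beta.loc[probes].median(axis=0, skipna=True)


def solo_wcgw_pmd_mask(annotation: pd.DataFrame) -> pd.Series:
    """The canonical erosion-prone context: PMD solo-WCGW outside CGIs."""
    return (
        (annotation["domain"] == "commonPMD")
        & annotation["solo"]
        & (annotation["flank_class"] == "WCGW")
        & ~annotation["in_cgi"]
    )


def fit_cpg_slopes(beta: pd.DataFrame, pds) -> pd.DataFrame:
    """Per-probe OLS of beta on PD.

    Returns a table indexed by probe with slope (delta beta per PD),
    intercept (beta at PD 0), n, r_squared and slope standard error.
    Probes with fewer than three non-missing samples get NaN rows.
    """
    pds = pd.Series(pds, index=beta.columns).astype(float)
    if pds.nunique() < 2:
        raise ValueError("PDs are constant across samples; cannot fit slopes")
    x_all = pds.to_numpy()
    y_all = beta.to_numpy(dtype=float)
    out = pd.DataFrame(
        index=beta.index,
        columns=["slope", "intercept", "n", "r_squared", "slope_se"],
        dtype=float,
    )

    obs = ~np.isnan(y_all)
    n_obs = obs.sum(axis=1)
    full = obs.all(axis=1)

    def _fill(rows: np.ndarray, x: np.ndarray, y: np.ndarray) -> None:
        # vectorized simple-regression formulas over many probes at once
        n = len(x)
        xm = x.mean()
        sxx = ((x - xm) ** 2).sum()
        ym = y.mean(axis=1)
        sxy = ((x - xm) * (y - ym[:, None])).sum(axis=1)
        slope = sxy / sxx
        intercept = ym - slope * xm
        resid = y - intercept[:, None] - slope[:, None] * x
        sse = (resid**2).sum(axis=1)
        sst = ((y - ym[:, None]) ** 2).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = np.where(sst > 0, 1 - sse / sst, np.nan)
            se = np.sqrt(sse / np.maximum(n - 2, 1) / sxx)
        out.iloc[rows, 0] = slope
        out.iloc[rows, 1] = intercept
        out.iloc[rows, 2] = n
        out.iloc[rows, 3] = r2
        out.iloc[rows, 4] = se

    full_rows = np.flatnonzero(full)
    if len(full_rows):
        _fill(full_rows, x_all, y_all[full_rows])
    for i in np.flatnonzero(~full & (n_obs >= MIN_SAMPLES_PER_FIT)):
        m = obs[i]
        if pd.Series(x_all[m]).nunique() < 2:
            continue
        _fill(np.array([i]), x_all[m], y_all[i : i + 1, m])
    return out


def categorize_cpgs(
    beta: pd.DataFrame,
    pds,
    change_threshold: float = 0.10,
    high: float = 0.70,
    low: float = 0.30,
) -> pd.DataFrame:
    """Classify probes by first-to-last methylation behaviour.

    ``beta_first`` is the probe's mean over the samples sharing the
    earliest PD (replicate-averaged), ``beta_last`` the mean at the
    latest PD. A probe is ``variable`` if |last - first| exceeds
    ``change_threshold``; otherwise ``stable_methylated`` if first >= high,
    ``stable_unmethylated`` if first <= low, and the nearer bound decides
    the remaining intermediate-start stable probes. Variable probes also
    get a loss/gain direction and a quartile (1-4) of starting
    methylation within the variable set.
    """
    if low >= high:
        raise ValueError(f"require low < high, got low={low}, high={high}")
    pds = pd.Series(pds, index=beta.columns).astype(float)
    first_cols = pds.index[pds == pds.min()]
    last_cols = pds.index[pds == pds.max()]
    b_first = beta[first_cols].mean(axis=1)
    b_last = beta[last_cols].mean(axis=1)
    delta = b_last - b_first

    variable = delta.abs() > change_threshold
    label = pd.Series("", index=beta.index, dtype=object)
    label[variable] = "variable"
    stable = ~variable
    label[stable & (b_first >= high)] = "stable_methylated"
    label[stable & (b_first <= low)] = "stable_unmethylated"
    mid = label == ""
    label[mid] = np.where(
        (high - b_first[mid]) <= (b_first[mid] - low),
        "stable_methylated",
        "stable_unmethylated",
    )

    direction = pd.Series(pd.NA, index=beta.index, dtype=object)
    direction[variable & (delta < 0)] = "loss"
    direction[variable & (delta > 0)] = "gain"

    quartile = pd.Series(pd.NA, index=beta.index, dtype="Int64")
    if variable.sum() >= 4:
        quartile[variable] = (
            pd.qcut(b_first[variable], 4, labels=False, duplicates="drop") + 1
        )
    elif variable.any():
        quartile[variable] = 1

    return pd.DataFrame(
        {
            "label": label,
            "beta_first": b_first,
            "beta_last": b_last,
            "delta": delta,
            "direction": direction,
            "start_quartile": quartile,
        }
    )


def compare_slopes(
    values,
    pds,
    groups,
    subculture=None,
    on_m_scale: bool = True,
) -> pd.Series:
    """Test whether methylation-vs-PD slopes differ between groups.

    Fits an OLS of (m-transformed) values on PD, group, and PD x group,
    optionally with subculture as a fixed covariate — a fixed-effects
    approximation to a mixed model with random subculture effects. For
    two groups the returned estimate is the interaction coefficient
    (slope difference, group 2 minus group 1) with its standard error and
    two-sided p; with more groups the p is the joint F-test of all
    interaction terms (estimate/se refer to the first contrast).
    """
    y = np.asarray(values, dtype=float)
    pds = np.asarray(pds, dtype=float)
    groups = pd.Series(groups).astype(str).reset_index(drop=True)
    levels = groups.unique()
    if len(levels) < 2:
        raise ValueError("need >=2 groups to compare slopes")
    counts = groups.value_counts()
    if (counts < 3).any():
        small = counts[counts < 3].index.tolist()
        raise ValueError(f"groups with <3 samples: {small}")
    for lv in levels:
        if pd.Series(pds[groups == lv]).nunique() < 2:
            raise ValueError(f"PDs constant within group {lv!r}")
    if on_m_scale:
        y = beta_to_m(y)

    data = pd.DataFrame({"pd": pds, "group": groups.to_numpy()})
    X = pd.get_dummies(data["group"], prefix="g", drop_first=True, dtype=float)
    inter_cols = []
    for col in list(X.columns):
        name = f"pd_x_{col}"
        X[name] = X[col] * data["pd"]
        inter_cols.append(name)
    X["pd"] = data["pd"]
    if subculture is not None:
        sub = pd.get_dummies(
            pd.Series(subculture).astype(str).reset_index(drop=True),
            prefix="sub",
            drop_first=True,
            dtype=float,
        )
        X = pd.concat([X, sub], axis=1)
    X = sm.add_constant(X)
    fit = sm.OLS(y, X).fit()

    est = float(fit.params[inter_cols[0]])
    se = float(fit.bse[inter_cols[0]])
    if len(inter_cols) == 1:
        p = float(fit.pvalues[inter_cols[0]])
        if est == 0.0:
            p = 1.0  # degenerate identical-group data
    else:
        contrast = np.zeros((len(inter_cols), len(fit.params)))
        for i, name in enumerate(inter_cols):
            contrast[i, list(fit.params.index).index(name)] = 1.0
        p = float(fit.f_test(contrast).pvalue)
    return pd.Series({"estimate": est, "se": se, "p_value": p})


def test_methylation_change(
    beta: pd.DataFrame,
    pre_samples,
    post_samples,
    alternative: str = "less",
) -> float:
    """One-sided paired test for a methylation shift between two sample groups.

    Each probe contributes the difference between its mean m-value over
    ``post_samples`` and over ``pre_samples``; a one-sample t-test over
    probes tests the stated alternative (default ``less``: methylation is
    lost). Identical pre/post data (all differences zero) returns 0.5.
    """
    pre = list(pre_samples)
    post = list(post_samples)
    if not pre or not post:
        raise ValueError("pre and post sample groups must be non-empty")
    m = beta_to_m(beta)
    diff = (m[post].mean(axis=1) - m[pre].mean(axis=1)).dropna()
    if len(diff) < 2:
        raise ValueError("need >=2 probes with observed pre and post values")
    if np.allclose(diff, 0):
        return 0.5
    res = stats.ttest_1samp(diff, 0.0, alternative=alternative)
    return float(res.pvalue)


def bin_and_compare(
    slopes, covariate, k: int = 5
) -> tuple[pd.DataFrame, float]:
    """Quantile-bin per-probe slopes by a covariate and run Kruskal-Wallis.

    Returns (per-bin summary with counts/medians, omnibus p-value). Bins
    are equal-count covariate quantiles (up to ties); probes missing
    either value are dropped.
    """
    if k < 2:
        raise ValueError(f"need k >= 2 bins, got {k}")
    tab = pd.DataFrame({"slope": slopes, "covariate": covariate}).dropna()
    if len(tab) < k:
        raise ValueError(f"only {len(tab)} probes with covariate; need >= {k}")
    tab["bin"] = pd.qcut(tab["covariate"], k, labels=False, duplicates="drop") + 1
    summary = tab.groupby("bin").agg(
        n=("slope", "size"),
        slope_median=("slope", "median"),
        covariate_median=("covariate", "median"),
    )
    groups = [grp["slope"].to_numpy() for _, grp in tab.groupby("bin")]
    if len(groups) < 2:
        raise ValueError("covariate ties collapsed all bins; cannot test")
    p = float(stats.kruskal(*groups).pvalue)
    return summary, p
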