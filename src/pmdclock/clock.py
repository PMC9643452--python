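"""Replicative-history estimators ("mitotic clocks") from methylation.

The central tool is an elastic-net linear model of cumulative population
doublings (PDs) on probe-level beta values, restricted to CpGs inside
common partially methylated domains, where methylation erodes with each
division. Training follows a two-stage scheme:

1. a reference model is trained on the youngest available lineage and
   used to predict each other lineage's starting PD, anchoring every
   lineage's observed culture PDs onto a shared replicative-history axis
   (``normalize_pds``);
2. the final clock is trained on the normalized PDs of a randomized
   sample-level train split and evaluated on the held-out test split
   (``train_replitali``).

A dual-set estimator in the style of hypermethylation/hypomethylation
max-rule clocks is also provided: it scores a gaining probe set and a
losing probe set separately and reports the larger estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.model_selection import KFold, train_test_split

from .meth_io import ClockModel

DEFAULT_ALPHA = 0.5  # elastic-net mixing (1 = lasso, 0 = ridge)
DEFAULT_CV_FOLDS = 10


def _prepare_training_matrix(beta: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Samples x probes design matrix with mean imputation of missing betas."""
    all_missing = beta.isna().all(axis=1)
    if all_missing.any():
        warnings.warn(
            f"dropping {int(all_missing.sum())} probes with no observed beta",
            stacklevel=3,
        )
        beta = beta.loc[~all_missing]
    means = beta.mean(axis=1)
    filled = beta.T.fillna(means)
    return filled, means


def _fit_elastic_net(
    X: pd.DataFrame,
    y: np.ndarray,
    alpha: float,
    seed: int,
    cv_folds: int = DEFAULT_CV_FOLDS,
    penalty: float | None = None,
) -> tuple[float, pd.Series, float]:
    """Elastic net of y on standardized X; coefficients returned on the
    original beta scale. Penalty chosen at minimum mean CV error unless
    fixed explicitly."""
    mu = X.mean(axis=0).to_numpy()
    sigma = X.std(axis=0, ddof=0).to_numpy()
    keep = sigma > 0
    Xs = (X.to_numpy()[:, keep] - mu[keep]) / sigma[keep]
    if penalty is None:
        cv = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        est = ElasticNetCV(
            l1_ratio=alpha, cv=cv, alphas=100, max_iter=20000, random_state=seed
        )
        est.fit(Xs, y)
        penalty = float(est.alpha_)
        coef_std, intercept_std = est.coef_, float(est.intercept_)
    else:
        est = ElasticNet(l1_ratio=alpha, alpha=penalty, max_iter=20000)
        est.fit(Xs, y)
        coef_std, intercept_std = est.coef_, float(est.intercept_)
    coef = np.zeros(X.shape[1])
    coef[keep] = coef_std / sigma[keep]
    intercept = intercept_std - float((coef_std * (mu[keep] / sigma[keep])).sum())
    return intercept, pd.Series(coef, index=X.columns), penalty


def train_reference_model(
    beta_ref: pd.DataFrame,
    pds_ref,
    alpha: float = DEFAULT_ALPHA,
    seed: int = 0,
    cv_folds: int = DEFAULT_CV_FOLDS,
    penalty: float | None = None,
) -> ClockModel:
    """Elastic-net fit of PD on beta for the reference lineage.

    ``beta_ref`` is probes x samples; ``pds_ref`` the observed cumulative
    PDs of the same samples. Deterministic given ``seed`` (CV fold
    assignment and coordinate descent are both seeded).
    """
    pds = pd.Series(pds_ref, index=beta_ref.columns).astype(float)
    if pds.nunique() < 2:
        raise ValueError("reference PDs are constant; cannot train")
    X, means = _prepare_training_matrix(beta_ref)
    intercept, coefs, chosen = _fit_elastic_net(
        X, pds.to_numpy(), alpha, seed, cv_folds, penalty
    )
    return ClockModel(
        intercept=intercept,
        coefficients=coefs,
        training_means=means,
        metadata={
            "alpha": alpha,
            "penalty": chosen,
            "seed": seed,
            "training_samples": list(beta_ref.columns),
        },
    )


def apply_clock(
    model: ClockModel, beta: pd.DataFrame, impute: bool = False
) -> pd.DataFrame:
    """Linear predictor per sample: intercept + sum(coef * beta).

    Missing model probes (absent rows or NaN values) are a hard error
    unless ``impute=True``, in which case the stored training means stand
    in and the per-sample imputation count is reported.
    """
    absent = model.probes.difference(beta.index)
    if len(absent) and not impute:
        raise ValueError(
            f"{len(absent)} model probes missing from beta matrix "
            f"(e.g. {list(absent[:5])}); pass impute=True to use training means"
        )
    sub = beta.reindex(model.probes)
    missing = sub.isna()
    if missing.any().any() and not impute:
        bad = sub.index[missing.any(axis=1)]
        raise ValueError(
            f"{len(bad)} model probes have missing values "
            f"(e.g. {list(bad[:5])}); pass impute=True to use training means"
        )
    filled = sub.apply(
        lambda col: col.fillna(model.training_means), axis=0
    )
    est = model.intercept + filled.mul(model.coefficients, axis=0).sum(axis=0)
    return pd.DataFrame(
        {"estimate": est, "n_imputed": missing.sum(axis=0).astype(int)}
    )


def normalize_pds(
    reference: ClockModel,
    sheet: pd.DataFrame,
    beta: pd.DataFrame,
    reference_lineage: str | None = None,
    impute: bool = False,
) -> pd.DataFrame:
    """Anchor each lineage's observed culture PDs on the reference scale.

    The reference model predicts the replicative history of each
    lineage's earliest-PD sample; that prediction becomes the lineage's
    normalized starting PD and every later sample adds its observed PD
    increment. The reference lineage itself keeps its observed PDs.

    ``sheet`` needs sample_id, lineage and cum_pd columns (see
    :func:`pmdclock.meth_io.read_sample_sheet`).
    """
    out = sheet[["sample_id", "lineage", "cum_pd"]].copy()
    out["normalized_pd"] = np.nan
    out["predicted_start"] = np.nan
    for lineage, grp in out.groupby("lineage", sort=False):
        obs = grp["cum_pd"].astype(float)
        if lineage == reference_lineage:
            out.loc[grp.index, "normalized_pd"] = obs
            out.loc[grp.index, "predicted_start"] = obs.min()
            continue
        first_sample = grp.loc[obs.idxmin(), "sample_id"]
        if first_sample not in beta.columns:
            raise ValueError(
                f"lineage {lineage!r}: earliest sample {first_sample!r} "
                f"has no beta column"
            )
        start = float(
            apply_clock(reference, beta[[first_sample]], impute=impute)[
                "estimate"
            ].iloc[0]
        )
        out.loc[grp.index, "normalized_pd"] = start + (obs - obs.min())
        out.loc[grp.index, "predicted_start"] = start
    return out


def train_replitali(
    beta: pd.DataFrame,
    normalized_pds,
    annotation: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    test_fraction: float = 0.33,
    seed: int = 0,
    cv_folds: int = DEFAULT_CV_FOLDS,
    stratify_by=None,
) -> tuple[ClockModel, dict]:
    """Train the final PMD-restricted replicative-history clock.

    Eligible probes are all CpGs with domain == commonPMD in the
    probe-level ``annotation`` (any flank context — restriction to the
    erosion-prone solo-WCGW context would narrow the usable dynamic
    range). Samples are split at random into train/test (seeded); the
    elastic net is fit on the training set and evaluated on the held-out
    test set.

    Returns (model, metrics) where metrics carries test-set ``rmse``,
    ``r2`` and the observed-vs-predicted ``pairs`` table.
    """
    pds = pd.Series(normalized_pds, index=beta.columns).astype(float)
    pmd_probes = annotation.index[annotation["domain"] == "commonPMD"]
    pmd_probes = beta.index.intersection(pmd_probes)
    if len(pmd_probes) == 0:
        raise ValueError("no common-PMD probes available for training")
    if len(beta.columns) < 20:
        raise ValueError("need >=20 samples to train and evaluate")
    train_ids, test_ids = train_test_split(
        list(beta.columns),
        test_size=test_fraction,
        random_state=seed,
        stratify=None if stratify_by is None else list(stratify_by),
    )
    X, means = _prepare_training_matrix(beta.loc[pmd_probes, train_ids])
    intercept, coefs, chosen = _fit_elastic_net(
        X, pds[train_ids].to_numpy(), alpha, seed, cv_folds
    )
    model = ClockModel(
        intercept=intercept,
        coefficients=coefs,
        training_means=means,
        metadata={
            "alpha": alpha,
            "penalty": chosen,
            "seed": seed,
            "training_samples": list(train_ids),
            "test_samples": list(test_ids),
        },
    )
    pred = apply_clock(model, beta[test_ids], impute=True)["estimate"]
    obs = pds[test_ids]
    resid = obs - pred
    ss_res = float((resid**2).sum())
    ss_tot = float(((obs - obs.mean()) ** 2).sum())
    metrics = {
        "rmse": float(np.sqrt((resid**2).mean())),
        "r2": 1.0 - ss_res / ss_tot,
        "pairs": pd.DataFrame({"observed": obs, "predicted": pred}),
    }
    return model, metrics


@dataclass
class DualSetClock:
    """Max-rule estimator over a gaining and a losing probe set.

    Each set scores linearly in its mean methylation (the losing set with
    a negative slope so erosion raises the estimate); the reported
    mitotic age is the larger of the two scores.
    """

    hyper_probes: pd.Index
    hyper_intercept: float
    hyper_slope: float
    hypo_probes: pd.Index
    hypo_intercept: float
    hypo_slope: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.hyper_probes = pd.Index(self.hyper_probes)
        self.hypo_probes = pd.Index(self.hypo_probes)
        if len(self.hyper_probes) == 0 or len(self.hypo_probes) == 0:
            raise ValueError("both probe sets must be non-empty")
        if len(self.hyper_probes.intersection(self.hypo_probes)):
            raise ValueError("hyper and hypo probe sets must be disjoint")


def fit_dual_clock(
    beta: pd.DataFrame, pds, hyper_probes, hypo_probes
) -> DualSetClock:
    """Calibrate each set's linear score by regressing PD on mean set beta."""
    pds = pd.Series(pds, index=beta.columns).astype(float)

    def _fit(probes):
        probes = beta.index.intersection(pd.Index(probes))
        if len(probes) == 0:
            raise ValueError("probe set absent from beta matrix")
        x = beta.loc[probes].mean(axis=0)
        slope, intercept = np.polyfit(x, pds, 1)
        return float(intercept), float(slope)

    hyper_i, hyper_s = _fit(hyper_probes)
    hypo_i, hypo_s = _fit(hypo_probes)
    return DualSetClock(
        pd.Index(hyper_probes), hyper_i, hyper_s,
        pd.Index(hypo_probes), hypo_i, hypo_s,
    )


def apply_dual_clock(clock: DualSetClock, beta: pd.DataFrame) -> pd.DataFrame:
    """Per-sample max of the hyper- and hypo-set scores.

    Returns both component scores, the selected set, and a tie flag.
    """
    hyper = beta.index.intersection(clock.hyper_probes)
    hypo = beta.index.intersection(clock.hypo_probes)
    if len(hyper) == 0:
        raise ValueError("no hypermethylation-set probes present in beta")
    if len(hypo) == 0:
        raise ValueError("no hypomethylation-set probes present in beta")
    score_hyper = (
        clock.hyper_intercept + clock.hyper_slope * beta.loc[hyper].mean(axis=0)
    )
    score_hypo = (
        clock.hypo_intercept + clock.hypo_slope * beta.loc[hypo].mean(axis=0)
    )
    est = np.maximum(score_hyper, score_hypo)
    return pd.DataFrame(
        {
            "estimate": est,
            "score_hyper": score_hyper,
            "score_hypo": score_hypo,
            "selected": np.where(
                score_hyper == score_hypo,
                "tie",
                np.where(score_hyper > score_hypo, "hyper", "hypo"),
            ),
        }
    )


def context_class(annotation: pd.DataFrame) -> pd.Series:
    """Coarse context label per probe: soloWCGW_PMD / other_PMD / nonPMD."""
    in_pmd = annotation["domain"] == "commonPMD"
    solo_wcgw = in_pmd & annotation["solo"] & (annotation["flank_class"] == "WCGW")
    return pd.Series(
        np.where(solo_wcgw, "soloWCGW_PMD", np.where(in_pmd, "other_PMD", "nonPMD")),
        index=annotation.index,
    )


def summarize_model(model: ClockModel, annotation: pd.DataFrame) -> pd.DataFrame:
    """Composition report: probe counts and mean coefficients per context class.

    ``annotation`` is probe-indexed with flank_class/solo/domain columns.
    Probes absent from the annotation are listed in a warning and excluded
    from class rows (they still count toward the overall mean). Classes
    with no probes appear with count 0 and NaN mean.
    """
    coefs = model.coefficients
    unannotated = coefs.index.difference(annotation.index)
    if len(unannotated):
        warnings.warn(
            f"{len(unannotated)} model probes lack annotation and are "
            f"excluded from class rows: {list(unannotated[:5])}",
            stacklevel=2,
        )
    annotated = coefs.index.intersection(annotation.index)
    classes = context_class(annotation.loc[annotated])
    rows = []
    for cls in ["soloWCGW_PMD", "other_PMD", "nonPMD"]:
        probes = classes.index[classes == cls]
        sub = coefs.loc[probes]
        rows.append(
            {
                "class": cls,
                "n_probes": len(sub),
                "fraction": len(sub) / len(coefs) if len(coefs) else np.nan,
                "mean_coefficient": float(sub.mean()) if len(sub) else np.nan,
            }
        )
    rows.append(
        {
            "class": "all",
            "n_probes": len(coefs),
            "fraction": 1.0,
            "mean_coefficient": float(coefs.mean()),
        }
    )
    return pd.DataFrame(rows).set_index("class")
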