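"""Methylation matrices, sample sheets, clock files, and value transforms.

A beta matrix is a probes x samples pandas DataFrame of fractional
methylation values in [0, 1] (NaN = missing). Sample sheets carry the
serial-passage bookkeeping needed to compute cumulative population
doublings (PDs) from viable cell yield and inoculum at each passage:

    PD = 3.32 * (log10(yield) - log10(inoculum)) + X

with X the PD of the inoculum. Chaining this across passages of a
lineage (feeding each passage's PD in as the next X) gives cumulative PD.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PD_LOG_CONSTANT = 3.32

SHEET_REQUIRED = ["sample_id", "lineage", "passage", "cell_yield", "inoculum"]


def compute_population_doublings(
    cell_yield: float, inoculum: float, inoculum_pd: float = 0.0
) -> float:
    """Cumulative PD after one passage from viable yield and inoculum counts."""
    if cell_yield <= 0 or inoculum <= 0:
        raise ValueError(
            f"cell counts must be positive, got yield={cell_yield}, "
            f"inoculum={inoculum}"
        )
    if inoculum_pd < 0:
        raise ValueError(f"inoculum PD must be >= 0, got {inoculum_pd}")
    return PD_LOG_CONSTANT * (np.log10(cell_yield) - np.log10(inoculum)) + inoculum_pd


def beta_to_m(beta, eps: float = 1e-6):
    """Logit-transform beta to an m-value: m = log2(b / (1 - b)).

    Betas are clipped to [eps, 1 - eps] first so the transform is finite
    at the boundaries. Strictly increasing; inverse is :func:`m_to_beta`.
    """
    if not 0 < eps < 0.5:
        raise ValueError(f"eps must lie in (0, 0.5), got {eps}")
    b = np.clip(np.asarray(beta, dtype=float), eps, 1 - eps)
    out = np.log2(b / (1 - b))
    if np.isscalar(beta) or np.ndim(beta) == 0:
        return float(out)
    if isinstance(beta, (pd.Series, pd.DataFrame)):
        return type(beta)(out, index=beta.index).__finalize__(beta) if isinstance(
            beta, pd.Series
        ) else pd.DataFrame(out, index=beta.index, columns=beta.columns)
    return out


def m_to_beta(m):
    """Inverse of :func:`beta_to_m` (exact on the clipped range)."""
    m = np.asarray(m, dtype=float)
    out = 1.0 / (1.0 + 2.0 ** (-m))
    return float(out) if out.ndim == 0 else out


def _open(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _sep_for(path, sep=None):
    if sep is not None:
        return sep
    p = str(path)
    if p.endswith(".gz"):
        p = p[:-3]
    return "," if p.endswith(".csv") else "\t"


def validate_beta_matrix(beta: pd.DataFrame) -> pd.DataFrame:
    if beta.index.duplicated().any():
        dups = beta.index[beta.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate probe ids: {dups[:5]}")
    if beta.columns.duplicated().any():
        dups = beta.columns[beta.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids: {dups[:5]}")
    vals = beta.to_numpy(dtype=float)
    bad = (vals < 0) | (vals > 1)
    if np.any(bad & ~np.isnan(vals)):
        i, j = np.argwhere(bad & ~np.isnan(vals))[0]
        raise ValueError(
            f"beta value out of [0, 1] at probe {beta.index[i]!r}, "
            f"sample {beta.columns[j]!r}: {vals[i, j]}"
        )
    return beta.astype(float)


def read_beta_matrix(path, sep=None) -> pd.DataFrame:
    """Read a probes x samples beta matrix (first column = probe id)."""
    with _open(path) as fh:
        beta = pd.read_csv(fh, sep=_sep_for(path, sep), index_col=0)
    beta.index.name = "probe_id"
    return validate_beta_matrix(beta)


def write_beta_matrix(beta: pd.DataFrame, path, sep=None) -> None:
    validate_beta_matrix(beta)
    with _open(path, "wt") as fh:
        beta.to_csv(fh, sep=_sep_for(path, sep), index_label="probe_id")


def read_probe_manifest(path, sep=None, base: int = 0) -> pd.DataFrame:
    """Probe manifest: probe_id, contig, pos columns; ``base`` declares the
    coordinate base of the file (1-based manifests converted to 0-based)."""
    with _open(path) as fh:
        man = pd.read_csv(fh, sep=_sep_for(path, sep))
    for col in ("probe_id", "contig", "pos"):
        if col not in man.columns:
            raise ValueError(f"manifest missing required column {col!r}")
    if man["probe_id"].duplicated().any():
        raise ValueError("manifest contains duplicate probe ids")
    if base not in (0, 1):
        raise ValueError("base must be 0 or 1")
    man = man.set_index("probe_id")
    if base == 1:
        man["pos"] = man["pos"] - 1
    return man


def cumulative_pds(sheet: pd.DataFrame) -> pd.Series:
    """Cumulative PD per sample, chaining the PD equation within each lineage.

    Rows are ordered by passage index within lineage. The first passage of a
    lineage takes its ``inoculum_pd`` column (default 0) as starting X;
    subsequent passages chain from the previous passage's cumulative PD.
    """
    out = pd.Series(index=sheet.index, dtype=float)
    for _, grp in sheet.groupby("lineage", sort=False):
        grp = grp.sort_values("passage")
        x = float(grp["inoculum_pd"].iloc[0]) if "inoculum_pd" in grp else 0.0
        for idx, row in grp.iterrows():
            x = compute_population_doublings(
                row["cell_yield"], row["inoculum"], x
            )
            out.loc[idx] = x
    return out


def read_sample_sheet(path, sep=None) -> pd.DataFrame:
    """Read a sample sheet CSV/TSV and append the computed ``cum_pd`` column.

    Required columns: sample_id, lineage, passage, cell_yield, inoculum.
    Optional: inoculum_pd (starting PD of each lineage's first passage),
    days, plus arbitrary condition labels.
    """
    with _open(path) as fh:
        sheet = pd.read_csv(fh, sep=_sep_for(path, sep))
    for col in SHEET_REQUIRED:
        if col not in sheet.columns:
            raise ValueError(f"sample sheet missing required column {col!r}")
    if sheet["sample_id"].duplicated().any():
        raise ValueError("sample sheet contains duplicate sample ids")
    sheet["cum_pd"] = cumulative_pds(sheet)
    return sheet


@dataclass
class ClockModel:
    """A linear replicative-history estimator.

    estimate = intercept + sum_i coef_i * beta_i over the model's probes.
    ``training_means`` stores each probe's mean training beta for optional
    imputation when a probe is missing at application time.
    """

    intercept: float
    coefficients: pd.Series  # probe id -> weight, nonzero entries only
    training_means: pd.Series  # probe id -> mean training beta
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coefficients = self.coefficients[self.coefficients != 0.0]
        if len(self.coefficients) == 0:
            raise ValueError("clock model must have >=1 nonzero coefficient")
        missing = self.coefficients.index.difference(self.training_means.index)
        if len(missing):
            raise ValueError(
                f"coefficient probes lack training means: {list(missing[:5])}"
            )
        self.training_means = self.training_means.loc[self.coefficients.index]

    @property
    def probes(self) -> pd.Index:
        return self.coefficients.index


def write_clock(model: ClockModel, path) -> None:
    """TSV clock format: header, one (Intercept) row, then probe rows."""
    rows = [{"probe_id": "(Intercept)", "coefficient": model.intercept,
             "training_mean": np.nan}]
    for probe in model.probes:
        rows.append(
            {
                "probe_id": probe,
                "coefficient": model.coefficients[probe],
                "training_mean": model.training_means[probe],
            }
        )
    with _open(path, "wt") as fh:
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)


def read_clock(path) -> ClockModel:
    with _open(path) as fh:
        tab = pd.read_csv(fh, sep="\t")
    for col in ("probe_id", "coefficient"):
        if col not in tab.columns:
            raise ValueError(f"clock file missing required column {col!r}")
    is_int = tab["probe_id"] == "(Intercept)"
    if is_int.sum() != 1:
        raise ValueError("clock file must contain exactly one (Intercept) row")
    intercept = float(tab.loc[is_int, "coefficient"].iloc[0])
    probes = tab.loc[~is_int].set_index("probe_id")
    if probes.index.duplicated().any():
        raise ValueError("clock file contains duplicate probe ids")
    means = (
        probes["training_mean"]
        if "training_mean" in probes
        else pd.Series(np.nan, index=probes.index)
    )
    return ClockModel(
        intercept=intercept,
        coefficients=probes["coefficient"].astype(float),
        training_means=means.astype(float),
    )
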