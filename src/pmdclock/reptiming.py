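"""Repli-seq weighted-average (WA) replication-timing scores.

Six-fraction Repli-seq signal (G1b, S1, S2, S3, S4, G2) is percent-
normalized per genomic bin and combined with fixed weights

    WA = 0.917*G1b + 0.750*S1 + 0.583*S2 + 0.417*S3 + 0.250*S4 + 0*G2

so WA ranges over [0, 0.917] with higher scores marking earlier
replication. CpGs inherit the WA of the bin containing them.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

FRACTIONS = ("G1b", "S1", "S2", "S3", "S4", "G2")
WA_WEIGHTS = np.array([0.917, 0.750, 0.583, 0.417, 0.250, 0.0])


def wa_score(profile, normalize: bool = True):
    """WA score for one six-fraction profile or an (n, 6) array of them.

    Fractions are ordered (G1b, S1, S2, S3, S4, G2) and must be
    non-negative. With ``normalize`` the raw signal is divided by its sum
    first, making the score invariant to positive rescaling. An all-zero
    profile scores NaN with a warning.
    """
    arr = np.asarray(profile, dtype=float)
    squeeze = arr.ndim == 1
    arr = np.atleast_2d(arr)
    if arr.shape[1] != len(FRACTIONS):
        raise ValueError(
            f"expected {len(FRACTIONS)} fractions {FRACTIONS}, "
            f"got shape {arr.shape}"
        )
    if np.any(arr < 0):
        raise ValueError("fraction signals must be non-negative")
    totals = arr.sum(axis=1)
    zero = totals == 0
    if np.any(zero):
        warnings.warn(
            f"{int(zero.sum())} all-zero profile(s) scored as NaN", stacklevel=2
        )
    if normalize:
        safe = np.where(zero, 1.0, totals)
        arr = arr / safe[:, None]
    scores = arr @ WA_WEIGHTS
    scores[zero] = np.nan
    return float(scores[0]) if squeeze else scores


def read_repliseq(path, sep="\t") -> pd.DataFrame:
    """Long-format Repli-seq TSV: contig, start, end, fraction, value.

    Returns one row per bin with the six fraction columns.
    """
    tab = pd.read_csv(path, sep=sep)
    for col in ("contig", "start", "end", "fraction", "value"):
        if col not in tab.columns:
            raise ValueError(f"repli-seq table missing column {col!r}")
    bad = set(tab["fraction"]) - set(FRACTIONS)
    if bad:
        raise ValueError(f"unknown fractions {sorted(bad)}; expected {FRACTIONS}")
    wide = tab.pivot_table(
        index=["contig", "start", "end"], columns="fraction", values="value"
    ).reindex(columns=list(FRACTIONS)).fillna(0.0)
    return wide.reset_index()


def read_repliseq_bedgraphs(paths: dict[str, str]) -> pd.DataFrame:
    """Six bedGraph files keyed by fraction name -> wide bin table."""
    missing = set(FRACTIONS) - set(paths)
    if missing:
        raise ValueError(f"missing bedGraph for fractions {sorted(missing)}")
    frames = []
    for frac in FRACTIONS:
        bg = pd.read_csv(
            paths[frac],
            sep="\t",
            comment="#",
            header=None,
            names=["contig", "start", "end", "value"],
        )
        bg["fraction"] = frac
        frames.append(bg)
    return read_repliseq_long(pd.concat(frames, ignore_index=True))


def read_repliseq_long(tab: pd.DataFrame) -> pd.DataFrame:
    wide = tab.pivot_table(
        index=["contig", "start", "end"], columns="fraction", values="value"
    ).reindex(columns=list(FRACTIONS)).fillna(0.0)
    return wide.reset_index()


def score_bins(bins: pd.DataFrame, normalize: bool = True) -> pd.DataFrame:
    """Append a ``wa`` column to a wide bin table."""
    out = bins.copy()
    out["wa"] = wa_score(out[list(FRACTIONS)].to_numpy(), normalize=normalize)
    return out


def map_cpgs_to_wa(annotation: pd.DataFrame, bins: pd.DataFrame) -> pd.Series:
    """Per-CpG WA: each CpG takes the WA of its containing bin, NaN if uncovered.

    ``annotation`` needs contig/pos columns; ``bins`` needs contig/start/
    end/wa with non-overlapping 0-based half-open intervals.
    """
    if "wa" not in bins.columns:
        raise ValueError("bins must carry a 'wa' column (see score_bins)")
    out = pd.Series(np.nan, index=annotation.index, name="wa")
    for contig, grp in bins.groupby("contig"):
        grp = grp.sort_values("start")
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        if np.any(starts[1:] < ends[:-1]):
            raise ValueError(f"overlapping bins on contig {contig!r}")
        mask = annotation["contig"] == contig
        if not mask.any():
            continue
        pos = annotation.loc[mask, "pos"].to_numpy()
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = (idx >= 0) & (pos < ends[np.clip(idx, 0, None)])
        vals = np.full(len(pos), np.nan)
        vals[ok] = grp["wa"].to_numpy()[idx[ok]]
        out.loc[mask] = vals
    return out
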