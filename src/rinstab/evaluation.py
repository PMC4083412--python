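"""Regression evaluation statistics for ddG prediction benchmarks.

Implements Pearson r, Spearman rho (Pearson on average ranks), Kendall tau
in the concordant-minus-discordant form tau = (CP - DP) / (0.5 * n * (n-1))
with tied pairs counting in neither CP nor DP, and the standard error
sigma = sqrt(sum((y_i - x_i)^2) / (n - 1)) in kcal/mol.  Also provides the
10%-largest-residual outlier trimming used when comparing predictors, the
common-mutation intersection protocol, and stratified reports by secondary
structure and burial.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "pearson",
    "spearman",
    "kendall",
    "stderr_sigma",
    "metrics_report",
    "trim_outliers",
    "stratified_report",
    "common_mutations",
]

_KEY_COLS = ["pdb_id", "chain", "position", "wt", "mut"]


def _check_pair(x, y, min_n: int = 2) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape[0]} vs {y.shape[0]}")
    if x.shape[0] < min_n:
        raise ValueError(f"need at least {min_n} observations, got {x.shape[0]}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    return x, y


def pearson(x, y) -> float:
    """Pearson correlation between experimental (x) and predicted (y) ddG."""
    x, y = _check_pair(x, y)
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        warnings.warn("zero-variance input; Pearson r reported as 0")
        return 0.0
    return float(stats.pearsonr(x, y).statistic)


def spearman(x, y) -> float:
    """Spearman rho: Pearson correlation of average ranks."""
    x, y = _check_pair(x, y)
    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    if np.std(rx) == 0.0 or np.std(ry) == 0.0:
        warnings.warn("zero-variance ranks; Spearman rho reported as 0")
        return 0.0
    return float(stats.pearsonr(rx, ry).statistic)


def kendall(x, y) -> float:
    """Kendall tau = (CP - DP) / (0.5 * n * (n - 1)).

    CP/DP count the pairs ordered concordantly/discordantly; pairs tied in
    either variable count in neither.  The denominator is the total number
    of pairs, so ties reduce |tau| (tau-a style).
    """
    x, y = _check_pair(x, y)
    n = len(x)
    sx = np.sign(x[:, None] - x[None, :])
    sy = np.sign(y[:, None] - y[None, :])
    prod = sx * sy
    cp = int(np.sum(prod > 0) // 2)
    dp = int(np.sum(prod < 0) // 2)
    return float((cp - dp) / (0.5 * n * (n - 1)))


def stderr_sigma(x, y, denominator: str = "n-1") -> float:
    """Standard error of prediction: sqrt(sum((y - x)^2) / (n - 1)) kcal/mol."""
    x, y = _check_pair(x, y)
    n = len(x)
    denom = n - 1 if denominator == "n-1" else n
    return float(np.sqrt(np.sum((y - x) ** 2) / denom))


def metrics_report(x, y) -> dict:
    """All four statistics for one experimental/predicted pair of vectors."""
    x, y = _check_pair(x, y)
    return {
        "n": int(len(x)),
        "pearson_r": pearson(x, y),
        "spearman_rho": spearman(x, y),
        "kendall_tau": kendall(x, y),
        "sigma": stderr_sigma(x, y),
    }


def trim_outliers(x, y, fraction: float = 0.10) -> np.ndarray:
    """Indices retained after dropping the largest-residual points.

    Fits ordinary least squares y ~ x and removes the ceil(fraction * n)
    points with the largest absolute residual.
    """
    x, y = _check_pair(x, y)
    if not (0.0 <= fraction < 1.0):
        raise ValueError("fraction must be in [0, 1)")
    n = len(x)
    n_drop = math.ceil(fraction * n)
    if n_drop == 0:
        return np.arange(n)
    if np.std(x) == 0.0:
        resid = np.abs(y - np.mean(y))
    else:
        slope, intercept = np.polyfit(x, y, 1)
        resid = np.abs(y - (slope * x + intercept))
    # stable ranking: ties broken by original index
    drop = np.argsort(-resid, kind="stable")[:n_drop]
    keep = np.setdiff1d(np.arange(n), drop)
    return keep


def stratified_report(records: pd.DataFrame, predictions, min_n: int = 3) -> dict:
    """Metrics for ALL plus secondary-structure (H/E/C) and burial strata.

    `records` needs columns ddg_exp, ss and rsa; buried means RSA <= 0.25.
    Strata with fewer than `min_n` points are skipped with a warning.
    """
    y_pred = np.asarray(predictions, dtype=float).ravel()
    if len(records) != len(y_pred):
        raise ValueError("records and predictions length mismatch")
    x = records["ddg_exp"].to_numpy(dtype=float)
    out: dict[str, dict] = {"ALL": metrics_report(x, y_pred)}
    masks = {
        "H": records["ss"].to_numpy() == "H",
        "E": records["ss"].to_numpy() == "E",
        "C": records["ss"].to_numpy() == "C",
        "buried": records["rsa"].to_numpy(dtype=float) <= 0.25,
        "exposed": records["rsa"].to_numpy(dtype=float) > 0.25,
    }
    for name, mask in masks.items():
        if int(mask.sum()) < min_n:
            warnings.warn(f"stratum {name}: fewer than {min_n} records, skipped")
            continue
        out[name] = metrics_report(x[mask], y_pred[mask])
    return out


def common_mutations(tables: list[pd.DataFrame]) -> list[pd.DataFrame]:
    """Restrict several prediction tables to their shared mutation keys.

    Tables are keyed by (pdb_id, chain, position, wt, mut); the returned
    tables contain only rows present in every input, in a common sort order.
    """
    if not tables:
        raise ValueError("need at least one table")
    keys = None
    for t in tables:
        missing = [c for c in _KEY_COLS if c not in t.columns]
        if missing:
            raise ValueError(f"prediction table missing key columns: {missing}")
        tk = set(map(tuple, t[_KEY_COLS].astype(str).to_numpy()))
        keys = tk if keys is None else keys & tk
    out = []
    for t in tables:
        tt = t.copy()
        tt["_key"] = list(map(tuple, tt[_KEY_COLS].astype(str).to_numpy()))
        tt = tt[tt["_key"].isin(keys)].sort_values("_key").drop(columns="_key")
        out.append(tt.reset_index(drop=True))
    return out
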