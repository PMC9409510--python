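"""Per-feature precision (ICC) and accuracy (SDM) across replicates and durations.

Precision is the single-measurement, absolute-agreement, two-way mixed-effects
intraclass correlation with tumors as subjects and replicate frames as raters,
computed from the ANOVA mean squares. Accuracy is the similarity distance
metric (SDM): per replicate, the ratio of the between-tumor variance of the
reference-scan feature values to that variance plus the mean squared distance
between the noisy and reference values, averaged over replicates. Both are
banded as poor (< 0.5), moderate (< 0.75), good (< 0.9) or excellent (>= 0.9);
boundary values take the higher band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateFeatureError

__all__ = [
    "CATEGORY_LABELS",
    "DEFAULT_BANDS",
    "ICCResult",
    "SDMResult",
    "compute_icc",
    "compute_sdm",
    "categorize",
    "score_study",
    "summarize_categories",
]

CATEGORY_LABELS = ("poor", "moderate", "good", "excellent")
DEFAULT_BANDS = (0.5, 0.75, 0.9)


@dataclass(frozen=True)
class ICCResult:
    feature_id: str
    duration: float
    icc: float
    category: str


@dataclass(frozen=True)
class SDMResult:
    feature_id: str
    duration: float
    sdm: float
    n_tumors: int
    n_replicates: int
    sigma_l_sq: float
    mean_sq_dist: float
    category: str


def compute_icc(values: np.ndarray) -> float:
    """ICC (two-way model, absolute agreement, single measurement).

    ``values`` is an (n subjects x k raters) matrix. From the two-way ANOVA
    mean squares MSR (rows), MSC (columns) and MSE (residual):

        ICC = (MSR - MSE) / (MSR + (k - 1) MSE + (k / n)(MSC - MSE))
    """
    x = np.asarray(values, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need an (n >= 2 tumors) x (k >= 2 replicates) matrix")
    if not np.all(np.isfinite(x)):
        raise ValueError("ICC input contains non-finite values")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_total = np.sum((x - grand) ** 2)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    if ss_total == 0:
        raise DegenerateFeatureError("zero total variance; ICC undefined")
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        raise DegenerateFeatureError("zero ICC denominator")
    return float((msr - mse) / denom)


def categorize(value: float, bands: tuple[float, float, float] = DEFAULT_BANDS) -> str:
    """Band a precision/accuracy value; thresholds belong to the higher band."""
    for threshold, label in zip(reversed(bands), reversed(CATEGORY_LABELS[1:])):
        if value >= threshold:
            return label
    return CATEGORY_LABELS[0]


def compute_sdm(
    ref: np.ndarray, noisy: np.ndarray, ddof: int = 1
) -> tuple[float, float, float]:
    """SDM of a tumors x replicates matrix against per-tumor reference values.

    Returns (sdm, sigma_l_sq, mean over replicates of the per-replicate mean
    squared distance). ``ddof=1`` uses the sample variance of the reference
    values; ``ddof=0`` the population variance.
    """
    ref = np.asarray(ref, dtype=np.float64)
    noisy = np.asarray(noisy, dtype=np.float64)
    if noisy.ndim == 1:
        noisy = noisy[:, None]
    n, m = noisy.shape
    if ref.shape != (n,) or n < 2 or m < 1:
        raise ValueError("need ref (n >= 2,) and noisy (n, m >= 1)")
    sigma_sq = float(np.var(ref, ddof=ddof))
    if sigma_sq == 0:
        raise DegenerateFeatureError("zero between-tumor reference variance")
    d_sq = np.mean((noisy - ref[:, None]) ** 2, axis=0)  # per replicate
    sdm = float(np.mean(sigma_sq / (d_sq + sigma_sq)))
    return sdm, sigma_sq, float(np.mean(d_sq))


def score_study(
    features: pd.DataFrame,
    bands: tuple[float, float, float] = DEFAULT_BANDS,
    sdm_ddof: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """ICC and SDM tables for a tidy feature table of one protocol.

    Features with any undefined value at a duration (or zero reference
    variance) are excluded from that duration's scoring.
    """
    icc_rows: list[dict] = []
    sdm_rows: list[dict] = []
    ref = features[features["replicate"] == "reference"]
    noisy = features[features["replicate"] != "reference"]
    ref_map = ref.set_index(["feature_id", "tumor_label"])["value"]
    for (duration, fid), grp in noisy.groupby(["duration_s", "feature_id"], sort=True):
        pivot = grp.pivot_table(
            index="tumor_label", columns="replicate", values="value", aggfunc="first"
        )
        try:
            ref_vals = ref_map.loc[fid].reindex(pivot.index).to_numpy()
        except KeyError:
            continue
        mat = pivot.to_numpy()
        if not (np.all(np.isfinite(mat)) and np.all(np.isfinite(ref_vals))):
            continue
        try:
            icc = compute_icc(mat)
            sdm, sig, msd = compute_sdm(ref_vals, mat, ddof=sdm_ddof)
        except DegenerateFeatureError:
            continue
        icc_rows.append(
            {
                "feature_id": fid,
                "duration_s": duration,
                "icc": icc,
                "category": categorize(icc, bands),
            }
        )
        sdm_rows.append(
            {
                "feature_id": fid,
                "duration_s": duration,
                "sdm": sdm,
                "n_tumors": mat.shape[0],
                "n_replicates": mat.shape[1],
                "sigma_l_sq": sig,
                "mean_sq_dist": msd,
                "category": categorize(sdm, bands),
            }
        )
    return pd.DataFrame(icc_rows), pd.DataFrame(sdm_rows)


def summarize_categories(
    results: pd.DataFrame,
    catalog_families: dict[str, str] | None = None,
    value_col: str = "category",
) -> pd.DataFrame:
    """Percentage of features per (family, duration, category), rows sum to 100.

    ``catalog_families`` maps feature_id -> family; without it a single overall
    row per duration is produced.
    """
    df = results.copy()
    if catalog_families is not None:
        df["family"] = df["feature_id"].map(catalog_families)
        group_cols = ["family", "duration_s"]
    else:
        df["family"] = "all"
        group_cols = ["family", "duration_s"]
    rows = []
    for key, grp in df.groupby(group_cols, sort=True):
        counts = grp[value_col].value_counts()
        total = counts.sum()
        row = {"family": key[0], "duration_s": key[1]}
        for label in CATEGORY_LABELS:
            row[f"pct_{label}"] = round(100.0 * counts.get(label, 0) / total, 2)
        row["n_features"] = int(total)
        rows.append(row)
    return pd.DataFrame(rows)
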