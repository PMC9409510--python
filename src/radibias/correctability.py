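"""Classification of features and the four-gate correctability screen.

Features are first classified at the noisiest duration: ``unusable`` when
ICC < 0.9 (low repeatability), ``ideal`` when both ICC and SDM are at least
0.9, and ``potential`` when ICC >= 0.9 but SDM < 0.9 (high precision with
noise-induced bias). Potential features then pass four gates before being
declared correctable:

1. SDM strictly increases with frame duration (Spearman r exactly 1);
2. per-tumor short-scan medians rank-correlate with the reference values
   (Spearman r >= 0.7);
3. every tumor shows the same monotone trend of the feature median with
   duration (Spearman r >= 0.7 for all tumors, or <= -0.7 for all tumors);
4. the replicate coefficient of variation at the noisiest duration stays
   below 30% for every tumor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrectabilityThresholds",
    "CorrectabilityReport",
    "classify_feature",
    "gate_sdm_monotonic",
    "gate_rank_short_long",
    "gate_trend_direction",
    "gate_cov",
    "screen_features",
    "funnel_summary",
]


@dataclass(frozen=True)
class CorrectabilityThresholds:
    icc_excellent: float = 0.9
    sdm_excellent: float = 0.9
    rank_r: float = 0.7
    trend_r: float = 0.7
    cov_max: float = 0.30


@dataclass(frozen=True)
class CorrectabilityReport:
    feature_id: str
    icc_class: str  # unusable | ideal | potential
    gate_sdm_monotonic: bool
    gate_rank_short_long: bool
    gate_trend_direction: bool
    gate_cov: bool
    correctable: bool


def classify_feature(
    icc_at_worst_noise: float,
    sdm_at_worst_noise: float,
    thresholds: CorrectabilityThresholds = CorrectabilityThresholds(),
) -> str:
    if icc_at_worst_noise < thresholds.icc_excellent:
        return "unusable"
    if sdm_at_worst_noise >= thresholds.sdm_excellent:
        return "ideal"
    return "potential"


def _spearman(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if np.all(a == a[0]) or np.all(b == b[0]):
        return float("nan")
    r, _ = stats.spearmanr(a, b)
    return float(r)


def gate_sdm_monotonic(sdm_by_duration: np.ndarray) -> bool:
    """SDM vs duration must be perfectly concordant (r = 1, so no ties)."""
    sdm = np.asarray(sdm_by_duration, dtype=np.float64)
    r = _spearman(np.arange(len(sdm)), sdm)
    return bool(np.isfinite(r) and r == 1.0)


def gate_rank_short_long(
    short_values: np.ndarray, reference_values: np.ndarray, threshold: float = 0.7
) -> bool:
    r = _spearman(short_values, reference_values)
    return bool(np.isfinite(r) and r >= threshold)


def gate_trend_direction(
    medians_by_tumor: np.ndarray, threshold: float = 0.7
) -> bool:
    """``medians_by_tumor``: (tumors x durations) with durations ascending."""
    med = np.asarray(medians_by_tumor, dtype=np.float64)
    n_dur = med.shape[1]
    rs = np.array([_spearman(np.arange(n_dur), row) for row in med])
    if not np.all(np.isfinite(rs)):
        return False
    return bool(np.all(rs >= threshold) or np.all(rs <= -threshold))


def gate_cov(replicate_values: np.ndarray, cov_max: float = 0.30) -> bool:
    """Replicate SD over |mean| below the cut; a zero mean fails the gate."""
    v = np.asarray(replicate_values, dtype=np.float64)
    mean = v.mean()
    if mean == 0:
        return False
    return bool(np.std(v, ddof=1) / abs(mean) < cov_max)


def screen_features(
    features: pd.DataFrame,
    icc: pd.DataFrame,
    sdm: pd.DataFrame,
    thresholds: CorrectabilityThresholds = CorrectabilityThresholds(),
    worst_duration: float | None = None,
) -> pd.DataFrame:
    """Apply classification and gates to every scored feature of one protocol."""
    durations = sorted(d for d in features["duration_s"].unique() if not _is_ref(features, d))
    worst = worst_duration if worst_duration is not None else durations[0]
    noisy = features[features["replicate"] != "reference"]
    ref = features[features["replicate"] == "reference"]
    ref_map = ref.set_index(["feature_id", "tumor_label"])["value"]
    icc_at = icc[icc["duration_s"] == worst].set_index("feature_id")["icc"]
    sdm_piv = sdm.pivot_table(index="feature_id", columns="duration_s", values="sdm")

    medians = (
        noisy.groupby(["feature_id", "tumor_label", "duration_s"])["value"]
        .median()
        .rename("median")
    )
    rows: list[dict] = []
    for fid in sorted(icc_at.index):
        if fid not in sdm_piv.index or sdm_piv.loc[fid].isna().any():
            continue
        icc_w = float(icc_at.loc[fid])
        sdm_w = float(sdm_piv.loc[fid, worst])
        icc_class = classify_feature(icc_w, sdm_w, thresholds)
        g1 = g2 = g3 = g4 = False
        if icc_class == "potential":
            sdm_series = sdm_piv.loc[fid, durations].to_numpy()
            g1 = gate_sdm_monotonic(sdm_series)
            med = medians.loc[fid].unstack("duration_s")
            short_vals = med[worst].to_numpy()
            ref_vals = ref_map.loc[fid].reindex(med.index).to_numpy()
            g2 = gate_rank_short_long(short_vals, ref_vals, thresholds.rank_r)
            g3 = gate_trend_direction(med[durations].to_numpy(), thresholds.trend_r)
            grp = noisy[(noisy["feature_id"] == fid) & (noisy["duration_s"] == worst)]
            g4 = all(
                gate_cov(sub["value"].to_numpy(), thresholds.cov_max)
                for _, sub in grp.groupby("tumor_label")
            )
        rows.append(
            {
                "feature_id": fid,
                "icc_class": icc_class,
                "gate_sdm_monotonic": g1,
                "gate_rank_short_long": g2,
                "gate_trend_direction": g3,
                "gate_cov": g4,
                "correctable": icc_class == "potential" and g1 and g2 and g3 and g4,
            }
        )
    return pd.DataFrame(rows)


def _is_ref(features: pd.DataFrame, duration: float) -> bool:
    sub = features[features["duration_s"] == duration]
    return bool((sub["replicate"] == "reference").all())


def funnel_summary(report: pd.DataFrame) -> pd.DataFrame:
    """Features surviving each successive correctability step."""
    pot = report[report["icc_class"] == "potential"]
    steps = [
        ("scored", len(report)),
        ("potential", len(pot)),
        ("sdm_monotonic", int(pot["gate_sdm_monotonic"].sum())),
        (
            "rank_short_long",
            int((pot["gate_sdm_monotonic"] & pot["gate_rank_short_long"]).sum()),
        ),
        (
            "trend_direction",
            int(
                (
                    pot["gate_sdm_monotonic"]
                    & pot["gate_rank_short_long"]
                    & pot["gate_trend_direction"]
                ).sum()
            ),
        ),
        ("cov", int(pot["correctable"].sum())),
    ]
    return pd.DataFrame(steps, columns=["step", "n_features"])
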