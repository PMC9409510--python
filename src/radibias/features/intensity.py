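"""Intensity-based feature families: statistics, histogram, IVH, local intensity.

Statistics are computed on the continuous SUV values inside the ROI (population
moments); intensity-histogram features on the fixed-bin-width discretised grey
levels; intensity-volume-histogram features on the continuous values. Features
that are undefined for the given ROI (e.g. skewness of a constant ROI) are
emitted as NaN and excluded from downstream precision/accuracy scoring.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = [
    "statistics_features",
    "intensity_histogram_features",
    "ivh_features",
    "local_intensity_features",
]

NAN = float("nan")


def _dispersion(values: np.ndarray) -> dict[str, float]:
    """Shared location/dispersion descriptors for continuous or discrete values."""
    v = np.asarray(values, dtype=np.float64)
    mean = v.mean()
    var = v.var()  # population variance
    p10, p25, p50, p75, p90 = np.percentile(v, [10, 25, 50, 75, 90])
    sd = np.sqrt(var)
    if var > 0:
        skew = np.mean((v - mean) ** 3) / sd**3
        kurt = np.mean((v - mean) ** 4) / var**2 - 3.0
    else:
        skew = kurt = NAN
    robust = v[(v >= p10) & (v <= p90)]
    out = {
        "mean": mean,
        "variance": var,
        "skewness": skew,
        "kurtosis": kurt,
        "median": p50,
        "minimum": v.min(),
        "p10": p10,
        "p90": p90,
        "maximum": v.max(),
        "interquartile_range": p75 - p25,
        "range": v.max() - v.min(),
        "mean_absolute_deviation": np.mean(np.abs(v - mean)),
        "robust_mean_absolute_deviation": (
            np.mean(np.abs(robust - robust.mean())) if robust.size else NAN
        ),
        "median_absolute_deviation": np.mean(np.abs(v - p50)),
        "coefficient_of_variation": sd / mean if mean != 0 else NAN,
        "quartile_coefficient_of_dispersion": (
            (p75 - p25) / (p75 + p25) if (p75 + p25) != 0 else NAN
        ),
    }
    return out


def statistics_features(values: np.ndarray) -> dict[str, float]:
    v = np.asarray(values, dtype=np.float64)
    out = _dispersion(v)
    out["energy"] = float(np.sum(v**2))
    out["root_mean_square"] = float(np.sqrt(np.mean(v**2)))
    return {f"stat_{k}": float(x) for k, x in out.items()}


def intensity_histogram_features(levels: np.ndarray, n_levels: int) -> dict[str, float]:
    g = np.asarray(levels, dtype=np.float64)
    out = _dispersion(g)
    counts = np.bincount(levels.astype(np.int64), minlength=n_levels + 1)[1:]
    p = counts / counts.sum()
    nz = p > 0
    out["entropy"] = float(-np.sum(p[nz] * np.log2(p[nz])))
    out["uniformity"] = float(np.sum(p**2))
    # mode: most frequent level; ties resolved toward the level closest to the mean
    top = np.flatnonzero(counts == counts.max()) + 1
    out["mode"] = float(top[np.argmin(np.abs(top - out["mean"]))])
    if n_levels >= 2:
        grad = np.gradient(counts.astype(np.float64))
        out["max_gradient"] = float(grad.max())
        out["max_gradient_level"] = float(np.argmax(grad) + 1)
        out["min_gradient"] = float(grad.min())
        out["min_gradient_level"] = float(np.argmin(grad) + 1)
    else:
        out["max_gradient"] = out["max_gradient_level"] = NAN
        out["min_gradient"] = out["min_gradient_level"] = NAN
    out["grey_level_count"] = float(n_levels)
    return {f"ih_{k}": float(x) for k, x in out.items()}


def ivh_features(values: np.ndarray) -> dict[str, float]:
    """Intensity-volume histogram descriptors on continuous intensities.

    V_x: volume fraction with intensity at least the x% fractional intensity;
    I_x: intensity held by at least x% of the ROI volume.
    """
    v = np.asarray(values, dtype=np.float64)
    lo, hi = v.min(), v.max()
    n = v.size

    def vol_frac(gamma: float) -> float:
        thr = lo + gamma * (hi - lo)
        return float(np.mean(v >= thr))

    desc = np.sort(v)[::-1]

    def inten(frac: float) -> float:
        k = max(0, int(np.ceil(frac * n)) - 1)
        return float(desc[k])

    v10, v90 = vol_frac(0.10), vol_frac(0.90)
    i10, i90 = inten(0.10), inten(0.90)
    return {
        "ivh_v10": v10,
        "ivh_v90": v90,
        "ivh_i10": i10,
        "ivh_i90": i90,
        "ivh_v10_minus_v90": v10 - v90,
        "ivh_i10_minus_i90": i10 - i90,
    }


def _sphere_kernel(spacing: tuple[float, float, float], radius_mm: float) -> np.ndarray:
    half = [int(np.floor(radius_mm / s)) for s in spacing]
    axes = [np.arange(-h, h + 1) * s for h, s in zip(half, spacing)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij", sparse=True)
    return (X**2 + Y**2 + Z**2) <= radius_mm**2


def local_intensity_features(
    grid: np.ndarray, mask: np.ndarray, spacing: tuple[float, float, float]
) -> dict[str, float]:
    """Local and global intensity peaks: mean over a 1 cm^3 spherical neighborhood.

    Neighborhood means include voxels outside the ROI; at image borders the
    sphere is truncated to the voxels present.
    """
    radius = (3.0 * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)  # 1 cm^3 sphere, mm
    kernel = _sphere_kernel(spacing, radius).astype(np.float64)
    sums = ndimage.convolve(np.asarray(grid, dtype=np.float64), kernel, mode="constant")
    cnts = ndimage.convolve(np.ones_like(grid, dtype=np.float64), kernel, mode="constant")
    means = sums / cnts
    roi_means = means[mask]
    roi_vals = grid[mask]
    at_max = roi_vals == roi_vals.max()
    return {
        "loc_local_peak": float(roi_means[at_max].max()),
        "loc_global_peak": float(roi_means.max()),
    }
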