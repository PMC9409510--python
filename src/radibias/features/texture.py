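"""Texture matrix construction and scoring for the six grey-level families.

All matrices are computed from an integer grey-level array in which 0 marks
voxels outside the ROI and levels run 1..Ng. Neighborhoods are Chebyshev
distance 1: 26-connected in 3D, 8-connected within an axial slice (the third
array axis indexes slices). Aggregation variants follow the usual conventions:

* co-occurrence / run-length families: per-slice per-direction averaged
  (``2d_avg``), per-slice direction-merged (``2d_mrg``), per-direction
  slice-merged (``2p5d_avg``), fully merged in-plane (``2p5d_mrg``),
  per-direction 3D averaged (``3d_avg``) and fully merged 3D (``3d_mrg``);
* zone / neighborhood families: per-slice averaged (``2d``), slice-merged
  (``2p5d``) and volumetric (``3d``).

Counts-normalising quantities (run/zone percentage, dependence percentage) use
an effective voxel count that is multiplied by the number of merged directions,
so merged and averaged variants stay on comparable scales.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy import ndimage

from .catalog import (
    GLCM_FEATURES,
    GLDZM_FEATURES,
    GLRLM_FEATURES,
    GLSZM_FEATURES,
    NGLDM_FEATURES,
    NGTDM_FEATURES,
)

__all__ = [
    "OFFSETS_3D",
    "OFFSETS_2D",
    "glcm_matrix",
    "glrlm_matrix",
    "glszm_matrix",
    "gldzm_matrix",
    "ngtdm_counts",
    "ngldm_matrix",
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "gldzm_features",
    "ngtdm_features",
    "ngldm_features",
    "texture_family_features",
]

# 13 unique 3D directions (one of each +/- pair), Chebyshev distance 1
OFFSETS_3D: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dz, dy, dx) > (0, 0, 0)
)
# 4 unique in-plane directions for axial slices (axes 0 and 1)
OFFSETS_2D: tuple[tuple[int, int], ...] = ((1, 0), (0, 1), (1, 1), (1, -1))

_STRUCT_3D = np.ones((3, 3, 3), dtype=np.int8)
_STRUCT_2D = np.ones((3, 3), dtype=np.int8)


def _shifted_views(arr: np.ndarray, off: tuple[int, ...]) -> tuple[np.ndarray, np.ndarray]:
    sl_a, sl_b = [], []
    for o, n in zip(off, arr.shape):
        if o >= 0:
            sl_a.append(slice(0, n - o))
            sl_b.append(slice(o, n))
        else:
            sl_a.append(slice(-o, n))
            sl_b.append(slice(0, n + o))
    return arr[tuple(sl_a)], arr[tuple(sl_b)]


# ---------------------------------------------------------------- matrices


def glcm_matrix(levels: np.ndarray, off: tuple[int, ...], n_levels: int) -> np.ndarray:
    """Symmetric co-occurrence counts for one direction (2D or 3D array)."""
    a, b = _shifted_views(levels, off)
    valid = (a > 0) & (b > 0)
    idx = (a[valid] - 1) * n_levels + (b[valid] - 1)
    m = np.bincount(idx, minlength=n_levels * n_levels).reshape(n_levels, n_levels)
    return (m + m.T).astype(np.float64)


def _line_sequences(levels: np.ndarray, direction: tuple[int, ...]) -> np.ndarray:
    """All grid lines along ``direction`` as rows of a zero-padded matrix."""
    shape = levels.shape
    idx = np.indices(shape)
    start = np.zeros(shape, dtype=bool)
    for ax, d in enumerate(direction):
        if d == 1:
            start |= idx[ax] == 0
        elif d == -1:
            start |= idx[ax] == shape[ax] - 1
    starts = np.argwhere(start)
    max_len = min(shape[ax] for ax, d in enumerate(direction) if d != 0)
    seqs = np.zeros((len(starts), max_len), dtype=levels.dtype)
    d = np.asarray(direction)
    for t in range(max_len):
        coords = starts + t * d
        ok = np.ones(len(starts), dtype=bool)
        for ax in range(len(shape)):
            ok &= (coords[:, ax] >= 0) & (coords[:, ax] < shape[ax])
        if not ok.any():
            break
        seqs[ok, t] = levels[tuple(coords[ok].T)]
    return seqs


def glrlm_matrix(levels: np.ndarray, direction: tuple[int, ...], n_levels: int) -> np.ndarray:
    """Run-length counts along one direction; columns index run length."""
    seqs = _line_sequences(levels, direction)
    flat = np.concatenate([seqs, np.zeros((seqs.shape[0], 1), dtype=seqs.dtype)], axis=1).ravel()
    change = np.flatnonzero(np.diff(flat)) + 1
    bounds = np.concatenate([[0], change, [flat.size]])
    vals = flat[bounds[:-1]]
    lens = np.diff(bounds)
    keep = vals > 0
    vals, lens = vals[keep], lens[keep]
    max_len = int(lens.max()) if lens.size else 1
    m = np.zeros((n_levels, max_len))
    np.add.at(m, (vals - 1, lens - 1), 1.0)
    return m


def _zones(levels: np.ndarray, n_levels: int, structure: np.ndarray):
    """Yield (grey level, zone size, zone voxel index tuple) per connected zone."""
    present = np.unique(levels[levels > 0])
    for g in present:
        lab, n = ndimage.label(levels == g, structure=structure)
        if n == 0:
            continue
        objs = ndimage.find_objects(lab)
        for z in range(1, n + 1):
            where = np.nonzero(lab[objs[z - 1]] == z)
            yield int(g), len(where[0]), (objs[z - 1], where)


def glszm_matrix(levels: np.ndarray, n_levels: int) -> np.ndarray:
    structure = _STRUCT_3D if levels.ndim == 3 else _STRUCT_2D
    entries = [(g, s) for g, s, _ in _zones(levels, n_levels, structure)]
    max_size = max((s for _, s in entries), default=1)
    m = np.zeros((n_levels, max_size))
    for g, s in entries:
        m[g - 1, s - 1] += 1.0
    return m


def _distance_map(mask: np.ndarray) -> np.ndarray:
    """City-block distance from each ROI voxel to the nearest border (>=1)."""
    padded = np.pad(mask, 1)
    dmap = ndimage.distance_transform_cdt(padded, metric="taxicab")
    return dmap[tuple(slice(1, -1) for _ in mask.shape)]


def gldzm_matrix(levels: np.ndarray, n_levels: int) -> np.ndarray:
    structure = _STRUCT_3D if levels.ndim == 3 else _STRUCT_2D
    dmap = _distance_map(levels > 0)
    entries = []
    for g, _s, (obj, where) in _zones(levels, n_levels, structure):
        entries.append((g, int(dmap[obj][where].min())))
    max_d = max((d for _, d in entries), default=1)
    m = np.zeros((n_levels, max_d))
    for g, d in entries:
        m[g - 1, d - 1] += 1.0
    return m


def ngtdm_counts(levels: np.ndarray, n_levels: int) -> tuple[np.ndarray, np.ndarray]:
    """Neighborhood grey-tone sums: occurrence counts n_i and deviations s_i."""
    kernel = (_STRUCT_3D if levels.ndim == 3 else _STRUCT_2D).astype(np.float64).copy()
    kernel[tuple(1 for _ in levels.shape)] = 0.0
    roi = levels > 0
    nsum = ndimage.convolve(levels.astype(np.float64) * roi, kernel, mode="constant")
    ncnt = ndimage.convolve(roi.astype(np.float64), kernel, mode="constant")
    valid = roi & (ncnt > 0.5)
    n_i = np.bincount(levels[valid], minlength=n_levels + 1)[1:].astype(np.float64)
    s_i = np.zeros(n_levels)
    dev = np.abs(levels[valid] - nsum[valid] / ncnt[valid])
    np.add.at(s_i, levels[valid] - 1, dev)
    return n_i, s_i


def ngldm_matrix(levels: np.ndarray, n_levels: int) -> np.ndarray:
    """Dependence counts: s(i, j) with j = 1 + number of equal-level neighbors."""
    ndim = levels.ndim
    padded = np.pad(levels, 1)
    dep = np.zeros(levels.shape, dtype=np.int64)
    ranges = [(-1, 0, 1)] * ndim
    shape = levels.shape
    from itertools import product

    for off in product(*ranges):
        if all(o == 0 for o in off):
            continue
        sl = tuple(slice(1 + o, 1 + o + n) for o, n in zip(off, shape))
        dep += padded[sl] == levels
    roi = levels > 0
    j = dep[roi] + 1  # includes the center voxel itself
    i = levels[roi]
    max_j = int(j.max()) if j.size else 1
    m = np.zeros((n_levels, max_j))
    np.add.at(m, (i - 1, j - 1), 1.0)
    return m


# ---------------------------------------------------------------- features

NAN = float("nan")


@lru_cache(maxsize=16)
def _index_grids(n_levels: int):
    i, j = np.indices((n_levels, n_levels)) + 1
    i.setflags(write=False)
    j.setflags(write=False)
    return i, j


def _entropy2(p: np.ndarray) -> float:
    nz = p > 0
    return float(-np.sum(p[nz] * np.log2(p[nz])))


def glcm_features(counts: np.ndarray) -> dict[str, float]:
    total = counts.sum()
    if total == 0:
        return {k: NAN for k in GLCM_FEATURES}
    p = counts / total
    ng = p.shape[0]
    i, j = _index_grids(ng)
    px = p.sum(axis=1)
    lv = np.arange(1, ng + 1)
    mu = float(np.sum(i * p))
    var_marg = float(np.sum((lv - np.sum(lv * px)) ** 2 * px))

    k_diff = np.arange(ng)
    p_diff = np.zeros(ng)
    np.add.at(p_diff, np.abs(i - j).ravel(), p.ravel())
    da = float(np.sum(k_diff * p_diff))
    k_sum = np.arange(2, 2 * ng + 1)
    p_sum = np.zeros(2 * ng - 1)
    np.add.at(p_sum, (i + j - 2).ravel(), p.ravel())
    sa = float(np.sum(k_sum * p_sum))

    hxy = _entropy2(p)
    hx = _entropy2(px)
    pxy = np.outer(px, px)
    nzj = p > 0
    with np.errstate(divide="ignore"):
        hxy1 = float(-np.sum(p[nzj] * np.log2(pxy[nzj])))
    hxy2 = _entropy2(pxy.ravel())

    out: dict[str, float] = {}
    out["joint_maximum"] = float(p.max())
    out["joint_average"] = mu
    out["joint_variance"] = float(np.sum((i - mu) ** 2 * p))
    out["joint_entropy"] = hxy
    out["difference_average"] = da
    out["difference_variance"] = float(np.sum((k_diff - da) ** 2 * p_diff))
    out["difference_entropy"] = _entropy2(p_diff)
    out["sum_average"] = sa
    out["sum_variance"] = float(np.sum((k_sum - sa) ** 2 * p_sum))
    out["sum_entropy"] = _entropy2(p_sum)
    out["angular_second_moment"] = float(np.sum(p**2))
    out["contrast"] = float(np.sum((i - j) ** 2 * p))
    out["dissimilarity"] = float(np.sum(np.abs(i - j) * p))
    out["inverse_difference"] = float(np.sum(p / (1.0 + np.abs(i - j))))
    out["inverse_difference_normalised"] = float(np.sum(p / (1.0 + np.abs(i - j) / ng)))
    out["inverse_difference_moment"] = float(np.sum(p / (1.0 + (i - j) ** 2)))
    out["inverse_difference_moment_normalised"] = float(
        np.sum(p / (1.0 + ((i - j) / ng) ** 2))
    )
    offdiag = i != j
    with np.errstate(divide="ignore", invalid="ignore"):
        iv = np.where(offdiag, p / np.where(offdiag, (i - j) ** 2, 1), 0.0)
    out["inverse_variance"] = float(iv.sum())
    auto = float(np.sum(i * j * p))
    out["correlation"] = (auto - mu * mu) / var_marg if var_marg > 0 else NAN
    out["autocorrelation"] = auto
    out["cluster_tendency"] = float(np.sum((i + j - 2 * mu) ** 2 * p))
    out["cluster_shade"] = float(np.sum((i + j - 2 * mu) ** 3 * p))
    out["cluster_prominence"] = float(np.sum((i + j - 2 * mu) ** 4 * p))
    out["information_correlation_1"] = (hxy - hxy1) / hx if hx > 0 else NAN
    arg = -2.0 * (hxy2 - hxy)
    out["information_correlation_2"] = float(np.sqrt(max(0.0, 1.0 - np.exp(arg))))
    return out


def _run_type_features(m: np.ndarray, n_voxels: float, names: tuple[str, ...]) -> dict[str, float]:
    """Shared scoring for GLRLM/GLSZM/GLDZM-shaped matrices (grey level x size)."""
    ns = m.sum()
    if ns == 0 or n_voxels <= 0:
        return {k: NAN for k in names}
    p = m / ns
    ng, nr = m.shape
    i = (np.arange(1, ng + 1))[:, None]
    j = (np.arange(1, nr + 1))[None, :]
    ri = m.sum(axis=1)
    rj = m.sum(axis=0)
    li = np.arange(1, ng + 1)
    lj = np.arange(1, nr + 1)
    mu_i = float(np.sum(i * p))
    mu_j = float(np.sum(j * p))
    vals = (
        float(np.sum(m / j**2) / ns),
        float(np.sum(m * j**2) / ns),
        float(np.sum(m / i**2) / ns),
        float(np.sum(m * i**2) / ns),
        float(np.sum(m / (i**2 * j**2)) / ns),
        float(np.sum(m * i**2 / j**2) / ns),
        float(np.sum(m * j**2 / i**2) / ns),
        float(np.sum(m * i**2 * j**2) / ns),
        float(np.sum(ri**2) / ns),
        float(np.sum(ri**2) / ns**2),
        float(np.sum(rj**2) / ns),
        float(np.sum(rj**2) / ns**2),
        float(ns / n_voxels),
        float(np.sum((i - mu_i) ** 2 * p)),
        float(np.sum((j - mu_j) ** 2 * p)),
        _entropy2(p.ravel()),
    )
    return dict(zip(names, vals))


def glrlm_features(m: np.ndarray, n_voxels: float) -> dict[str, float]:
    return _run_type_features(m, n_voxels, GLRLM_FEATURES)


def glszm_features(m: np.ndarray, n_voxels: float) -> dict[str, float]:
    return _run_type_features(m, n_voxels, GLSZM_FEATURES)


def gldzm_features(m: np.ndarray, n_voxels: float) -> dict[str, float]:
    return _run_type_features(m, n_voxels, GLDZM_FEATURES)


def ngtdm_features(n_i: np.ndarray, s_i: np.ndarray) -> dict[str, float]:
    nv = n_i.sum()
    if nv == 0:
        return {k: NAN for k in NGTDM_FEATURES}
    p = n_i / nv
    present = np.flatnonzero(p > 0)
    lv = present + 1
    pi = p[present]
    si = s_i[present]
    ngp = len(present)
    out: dict[str, float] = {}
    denom = float(np.sum(pi * si))
    out["coarseness"] = 1.0 / denom if denom > 0 else NAN
    if ngp > 1:
        dif2 = (lv[:, None] - lv[None, :]) ** 2
        out["contrast"] = float(
            np.sum(pi[:, None] * pi[None, :] * dif2) / (ngp * (ngp - 1)) * (si.sum() / nv)
        )
        ipi = lv * pi
        busy_den = float(np.sum(np.abs(ipi[:, None] - ipi[None, :])))
        out["busyness"] = denom / busy_den if busy_den > 0 else NAN
        absdif = np.abs(lv[:, None] - lv[None, :])
        num = (pi[:, None] * si[:, None] + pi[None, :] * si[None, :])
        out["complexity"] = float(
            np.sum(absdif * num / (pi[:, None] + pi[None, :])) / nv
        )
        s_tot = float(si.sum())
        out["strength"] = (
            float(np.sum((pi[:, None] + pi[None, :]) * dif2)) / s_tot if s_tot > 0 else NAN
        )
    else:
        out["contrast"] = out["busyness"] = out["complexity"] = out["strength"] = NAN
    return out


def ngldm_features(m: np.ndarray, n_voxels: float) -> dict[str, float]:
    base = _run_type_features(
        m,
        n_voxels,
        (
            "low_dependence_emphasis", "high_dependence_emphasis",
            "low_grey_level_count_emphasis", "high_grey_level_count_emphasis",
            "low_dependence_low_grey_level_emphasis",
            "low_dependence_high_grey_level_emphasis",
            "high_dependence_low_grey_level_emphasis",
            "high_dependence_high_grey_level_emphasis",
            "grey_level_non_uniformity", "grey_level_non_uniformity_normalised",
            "dependence_count_non_uniformity",
            "dependence_count_non_uniformity_normalised",
            "dependence_count_percentage", "grey_level_variance",
            "dependence_count_variance", "dependence_count_entropy",
        ),
    )
    ns = m.sum()
    base["dependence_count_energy"] = (
        float(np.sum((m / ns) ** 2)) if ns > 0 else NAN
    )
    return {k: base[k] for k in NGLDM_FEATURES}


# ---------------------------------------------------------------- aggregation


def _pad_cols(mats: list[np.ndarray]) -> list[np.ndarray]:
    width = max(m.shape[1] for m in mats)
    return [
        np.pad(m, ((0, 0), (0, width - m.shape[1]))) if m.shape[1] < width else m
        for m in mats
    ]


def _sum_mats(mats: list[np.ndarray]) -> np.ndarray:
    mats = _pad_cols(mats)
    return np.sum(mats, axis=0)


def _avg_dicts(dicts: list[dict[str, float]], keys: tuple[str, ...]) -> dict[str, float]:
    if not dicts:
        return {k: NAN for k in keys}
    return {k: float(np.mean([d[k] for d in dicts])) for k in keys}


def _directed_family(levels: np.ndarray, n_levels: int, build, score, keys, prefix,
                     uses_voxels: bool) -> dict[str, float]:
    """Six-aggregation scoring for co-occurrence / run-length style families."""
    nz = levels.shape[2]
    nv3 = float((levels > 0).sum())

    mats3d = [build(levels, off, n_levels) for off in OFFSETS_3D]
    mats3d = [m for m in mats3d if m.sum() > 0]
    slice_mats: list[list[np.ndarray]] = []  # [slice][direction]
    slice_nv: list[float] = []
    for k in range(nz):
        sl = levels[:, :, k]
        if not (sl > 0).any():
            continue
        ms = [build(sl, off, n_levels) for off in OFFSETS_2D]
        if all(m.sum() == 0 for m in ms):
            continue
        slice_mats.append(ms)
        slice_nv.append(float((sl > 0).sum()))

    def f(mat, nv):
        return score(mat, nv) if uses_voxels else score(mat)

    out: dict[str, float] = {}
    # 2D averaged over slices and directions
    d2 = [
        f(m, nv)
        for ms, nv in zip(slice_mats, slice_nv)
        for m in ms
        if m.sum() > 0
    ]
    out.update({f"{prefix}_{k}_2d_avg": v for k, v in _avg_dicts(d2, keys).items()})
    # 2D direction-merged per slice, then averaged
    d2m = [
        f(_sum_mats(ms), nv * len(OFFSETS_2D))
        for ms, nv in zip(slice_mats, slice_nv)
    ]
    out.update({f"{prefix}_{k}_2d_mrg": v for k, v in _avg_dicts(d2m, keys).items()})
    # 2.5D: slice-merged per direction, averaged over directions
    nv_all = float(np.sum(slice_nv))
    d25 = []
    for di in range(len(OFFSETS_2D)):
        dm = [ms[di] for ms in slice_mats if ms[di].sum() > 0]
        if dm:
            d25.append(f(_sum_mats(dm), nv_all))
    out.update({f"{prefix}_{k}_2p5d_avg": v for k, v in _avg_dicts(d25, keys).items()})
    # 2.5D fully merged
    allm = [m for ms in slice_mats for m in ms]
    if allm:
        merged = f(_sum_mats(allm), nv_all * len(OFFSETS_2D))
    else:
        merged = {k: NAN for k in keys}
    out.update({f"{prefix}_{k}_2p5d_mrg": v for k, v in merged.items()})
    # 3D averaged / merged
    d3 = [f(m, nv3) for m in mats3d]
    out.update({f"{prefix}_{k}_3d_avg": v for k, v in _avg_dicts(d3, keys).items()})
    if mats3d:
        m3 = f(_sum_mats(mats3d), nv3 * len(OFFSETS_3D))
    else:
        m3 = {k: NAN for k in keys}
    out.update({f"{prefix}_{k}_3d_mrg": v for k, v in m3.items()})
    return out


def _undirected_family(levels: np.ndarray, n_levels: int, build, score, keys,
                       prefix) -> dict[str, float]:
    """Three-aggregation scoring for zone / neighborhood style families."""
    nz = levels.shape[2]
    nv3 = float((levels > 0).sum())
    per_slice = []
    for k in range(nz):
        sl = levels[:, :, k]
        if not (sl > 0).any():
            continue
        per_slice.append((build(sl, n_levels), float((sl > 0).sum())))

    out: dict[str, float] = {}
    d2 = [score(m, nv) for m, nv in per_slice]
    out.update({f"{prefix}_{k}_2d": v for k, v in _avg_dicts(d2, keys).items()})
    if per_slice:
        merged = score(_sum_mats([m for m, _ in per_slice]), float(sum(nv for _, nv in per_slice)))
    else:
        merged = {k: NAN for k in keys}
    out.update({f"{prefix}_{k}_2p5d": v for k, v in merged.items()})
    m3 = score(build(levels, n_levels), nv3)
    out.update({f"{prefix}_{k}_3d": v for k, v in m3.items()})
    return out


def _ngtdm_family(levels: np.ndarray, n_levels: int) -> dict[str, float]:
    nz = levels.shape[2]
    per_slice = []
    for k in range(nz):
        sl = levels[:, :, k]
        if not (sl > 0).any():
            continue
        per_slice.append(ngtdm_counts(sl, n_levels))
    out: dict[str, float] = {}
    d2 = [ngtdm_features(n, s) for n, s in per_slice]
    out.update({f"ngtdm_{k}_2d": v for k, v in _avg_dicts(d2, NGTDM_FEATURES).items()})
    if per_slice:
        n_m = np.sum([n for n, _ in per_slice], axis=0)
        s_m = np.sum([s for _, s in per_slice], axis=0)
        merged = ngtdm_features(n_m, s_m)
    else:
        merged = {k: NAN for k in NGTDM_FEATURES}
    out.update({f"ngtdm_{k}_2p5d": v for k, v in merged.items()})
    n3, s3 = ngtdm_counts(levels, n_levels)
    out.update({f"ngtdm_{k}_3d": v for k, v in ngtdm_features(n3, s3).items()})
    return out


def texture_family_features(levels: np.ndarray, n_levels: int, family: str) -> dict[str, float]:
    """All aggregation variants of one texture family for a 3D level array."""
    if family == "glcm":
        return _directed_family(
            levels, n_levels, glcm_matrix, glcm_features, GLCM_FEATURES, "glcm", False
        )
    if family == "glrlm":
        return _directed_family(
            levels, n_levels, glrlm_matrix, glrlm_features, GLRLM_FEATURES, "glrlm", True
        )
    if family == "glszm":
        return _undirected_family(
            levels, n_levels, glszm_matrix, glszm_features, GLSZM_FEATURES, "glszm"
        )
    if family == "gldzm":
        return _undirected_family(
            levels, n_levels, gldzm_matrix, gldzm_features, GLDZM_FEATURES, "gldzm"
        )
    if family == "ngtdm":
        return _ngtdm_family(levels, n_levels)
    if family == "ngldm":
        return _undirected_family(
            levels, n_levels, ngldm_matrix, ngldm_features, NGLDM_FEATURES, "ngldm"
        )
    raise KeyError(f"unknown texture family: {family}")
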