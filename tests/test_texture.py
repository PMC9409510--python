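"""Texture families against brute-force enumeration oracles.

The oracles enumerate voxel pairs, runs and zones with explicit Python loops
and score matrices with plainly written formulas, independently of the
vectorised implementations in the package.
"""

import numpy as np
import pytest

from radibias.features.catalog import GLCM_FEATURES, GLRLM_FEATURES, GLSZM_FEATURES
from radibias.features.texture import (
    OFFSETS_3D,
    glcm_features,
    glcm_matrix,
    gldzm_matrix,
    glrlm_features,
    glrlm_matrix,
    glszm_features,
    glszm_matrix,
    ngldm_matrix,
    ngtdm_counts,
    ngtdm_features,
)

# 4x4 single-slice test grid, levels 1..4
GRID_4X4 = np.array(
    [[1, 2, 2, 3], [1, 2, 3, 3], [4, 2, 4, 1], [4, 1, 1, 1]], dtype=np.int64
)[:, :, None]


# ------------------------------------------------------------------ oracles


def bf_glcm(levels, off, ng):
    m = np.zeros((ng, ng))
    nx, ny, nz = levels.shape
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                a = levels[x, y, z]
                p = (x + off[0], y + off[1], z + off[2])
                if a > 0 and all(0 <= p[i] < levels.shape[i] for i in range(3)):
                    b = levels[p]
                    if b > 0:
                        m[a - 1, b - 1] += 1
                        m[b - 1, a - 1] += 1
    return m


def bf_glrlm(levels, direction, ng):
    runs = []
    nx, ny, nz = levels.shape
    d = direction
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                g = levels[x, y, z]
                if g == 0:
                    continue
                prev = (x - d[0], y - d[1], z - d[2])
                if all(0 <= prev[i] < levels.shape[i] for i in range(3)) and levels[prev] == g:
                    continue  # not the start of a run
                length = 0
                p = (x, y, z)
                while all(0 <= p[i] < levels.shape[i] for i in range(3)) and levels[p] == g:
                    length += 1
                    p = (p[0] + d[0], p[1] + d[1], p[2] + d[2])
                runs.append((g, length))
    width = max(l for _, l in runs)
    m = np.zeros((ng, width))
    for g, l in runs:
        m[g - 1, l - 1] += 1
    return m


def bf_zones(levels):
    """Connected zones per grey level, 26-connectivity, BFS flood fill."""
    seen = np.zeros(levels.shape, bool)
    zones = []
    nx, ny, nz = levels.shape
    offs = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ]
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if levels[x, y, z] == 0 or seen[x, y, z]:
                    continue
                g = levels[x, y, z]
                stack = [(x, y, z)]
                seen[x, y, z] = True
                voxels = []
                while stack:
                    cur = stack.pop()
                    voxels.append(cur)
                    for o in offs:
                        p = (cur[0] + o[0], cur[1] + o[1], cur[2] + o[2])
                        if (
                            all(0 <= p[i] < levels.shape[i] for i in range(3))
                            and not seen[p]
                            and levels[p] == g
                        ):
                            seen[p] = True
                            stack.append(p)
                zones.append((g, voxels))
    return zones


def ref_glcm_features(m):
    p = m / m.sum()
    ng = p.shape[0]
    out = {}
    mu = sum((i + 1) * p[i, j] for i in range(ng) for j in range(ng))
    px = p.sum(axis=1)
    pd = np.zeros(ng)
    ps = np.zeros(2 * ng - 1)
    for i in range(ng):
        for j in range(ng):
            pd[abs(i - j)] += p[i, j]
            ps[i + j] += p[i, j]
    da = sum(k * pd[k] for k in range(ng))
    sa = sum((k + 2) * ps[k] for k in range(len(ps)))
    ent = lambda q: -sum(v * np.log2(v) for v in np.ravel(q) if v > 0)
    mu_marg = sum((i + 1) * px[i] for i in range(ng))
    var_marg = sum((i + 1 - mu_marg) ** 2 * px[i] for i in range(ng))
    hx, hxy = ent(px), ent(p)
    hxy1 = -sum(
        p[i, j] * np.log2(px[i] * px[j])
        for i in range(ng)
        for j in range(ng)
        if p[i, j] > 0
    )
    hxy2 = ent(np.outer(px, px))
    auto = sum((i + 1) * (j + 1) * p[i, j] for i in range(ng) for j in range(ng))
    out["joint_maximum"] = p.max()
    out["joint_average"] = mu
    out["joint_variance"] = sum(
        (i + 1 - mu) ** 2 * p[i, j] for i in range(ng) for j in range(ng)
    )
    out["joint_entropy"] = hxy
    out["difference_average"] = da
    out["difference_variance"] = sum((k - da) ** 2 * pd[k] for k in range(ng))
    out["difference_entropy"] = ent(pd)
    out["sum_average"] = sa
    out["sum_variance"] = sum((k + 2 - sa) ** 2 * ps[k] for k in range(len(ps)))
    out["sum_entropy"] = ent(ps)
    out["angular_second_moment"] = (p**2).sum()
    out["contrast"] = sum((i - j) ** 2 * p[i, j] for i in range(ng) for j in range(ng))
    out["dissimilarity"] = sum(abs(i - j) * p[i, j] for i in range(ng) for j in range(ng))
    out["inverse_difference"] = sum(
        p[i, j] / (1 + abs(i - j)) for i in range(ng) for j in range(ng)
    )
    out["inverse_difference_normalised"] = sum(
        p[i, j] / (1 + abs(i - j) / ng) for i in range(ng) for j in range(ng)
    )
    out["inverse_difference_moment"] = sum(
        p[i, j] / (1 + (i - j) ** 2) for i in range(ng) for j in range(ng)
    )
    out["inverse_difference_moment_normalised"] = sum(
        p[i, j] / (1 + ((i - j) / ng) ** 2) for i in range(ng) for j in range(ng)
    )
    out["inverse_variance"] = sum(
        p[i, j] / (i - j) ** 2 for i in range(ng) for j in range(ng) if i != j
    )
    out["correlation"] = (auto - mu_marg**2) / var_marg
    out["autocorrelation"] = auto
    for k, power in (("cluster_tendency", 2), ("cluster_shade", 3), ("cluster_prominence", 4)):
        out[k] = sum(
            (i + j + 2 - 2 * mu) ** power * p[i, j] for i in range(ng) for j in range(ng)
        )
    out["information_correlation_1"] = (hxy - hxy1) / hx
    out["information_correlation_2"] = np.sqrt(1 - np.exp(-2 * (hxy2 - hxy)))
    return out


def ref_run_features(m, nv, names):
    ns = m.sum()
    ng, nr = m.shape
    p = m / ns
    mu_i = sum((i + 1) * p[i, j] for i in range(ng) for j in range(nr))
    mu_j = sum((j + 1) * p[i, j] for i in range(ng) for j in range(nr))
    S = lambda f: sum(f(i + 1, j + 1) * m[i, j] for i in range(ng) for j in range(nr))
    vals = [
        S(lambda i, j: 1 / j**2) / ns,
        S(lambda i, j: j**2) / ns,
        S(lambda i, j: 1 / i**2) / ns,
        S(lambda i, j: i**2) / ns,
        S(lambda i, j: 1 / (i**2 * j**2)) / ns,
        S(lambda i, j: i**2 / j**2) / ns,
        S(lambda i, j: j**2 / i**2) / ns,
        S(lambda i, j: i**2 * j**2) / ns,
        sum(m[i, :].sum() ** 2 for i in range(ng)) / ns,
        sum(m[i, :].sum() ** 2 for i in range(ng)) / ns**2,
        sum(m[:, j].sum() ** 2 for j in range(nr)) / ns,
        sum(m[:, j].sum() ** 2 for j in range(nr)) / ns**2,
        ns / nv,
        sum((i + 1 - mu_i) ** 2 * p[i, j] for i in range(ng) for j in range(nr)),
        sum((j + 1 - mu_j) ** 2 * p[i, j] for i in range(ng) for j in range(nr)),
        -sum(v * np.log2(v) for v in p.ravel() if v > 0),
    ]
    return dict(zip(names, vals))


# ------------------------------------------------------------------- tests


class TestGLCM:
    def test_two_by_two_horizontal_example(self):
        levels = np.array([[1, 1], [2, 2]], dtype=np.int64)[:, :, None]
        m = glcm_matrix(levels, (0, 1, 0), 2)
        np.testing.assert_array_equal(m, [[2, 0], [0, 2]])
        feats = glcm_features(m)
        assert feats["joint_maximum"] == pytest.approx(0.5)

    def test_uniform_roi_single_cell_zero_entropy(self):
        levels = np.full((3, 3, 3), 2, dtype=np.int64)
        m = glcm_matrix(levels, (1, 0, 0), 2)
        assert (m > 0).sum() == 1
        assert glcm_features(m)["joint_entropy"] == 0.0

    @pytest.mark.parametrize("off", OFFSETS_3D)
    def test_matrices_match_brute_force(self, off):
        m = glcm_matrix(GRID_4X4, off, 4)
        np.testing.assert_array_equal(m, bf_glcm(GRID_4X4, off, 4))

    def test_all_features_match_oracle(self):
        m = glcm_matrix(GRID_4X4, (0, 1, 0), 4)
        got = glcm_features(m)
        want = ref_glcm_features(bf_glcm(GRID_4X4, (0, 1, 0), 4))
        for name in GLCM_FEATURES:
            assert got[name] == pytest.approx(want[name], abs=1e-9), name


class TestGLRLM:
    def test_constant_row_single_run(self):
        levels = np.full((1, 6), 3, dtype=np.int64)[:, :, None]
        m = glrlm_matrix(levels, (0, 1, 0), 3)
        assert m[2, 5] == 1 and m.sum() == 1

    @pytest.mark.parametrize("direction", OFFSETS_3D)
    def test_matrices_match_brute_force(self, direction):
        m = glrlm_matrix(GRID_4X4, direction, 4)
        bf = bf_glrlm(GRID_4X4, direction, 4)
        np.testing.assert_array_equal(m[:, : bf.shape[1]], bf)
        assert m[:, bf.shape[1]:].sum() == 0

    def test_all_features_match_oracle(self):
        nv = int((GRID_4X4 > 0).sum())
        m = glrlm_matrix(GRID_4X4, (1, 0, 0), 4)
        got = glrlm_features(m, nv)
        want = ref_run_features(bf_glrlm(GRID_4X4, (1, 0, 0), 4), nv, GLRLM_FEATURES)
        for name in GLRLM_FEATURES:
            assert got[name] == pytest.approx(want[name], abs=1e-9), name


class TestZoneFamilies:
    def test_glszm_matches_brute_force(self):
        m = glszm_matrix(GRID_4X4, 4)
        zones = bf_zones(GRID_4X4)
        bf = np.zeros_like(m)
        for g, voxels in zones:
            bf[g - 1, len(voxels) - 1] += 1
        np.testing.assert_array_equal(m, bf)
        nv = int((GRID_4X4 > 0).sum())
        got = glszm_features(m, nv)
        want = ref_run_features(bf, nv, GLSZM_FEATURES)
        for name in GLSZM_FEATURES:
            assert got[name] == pytest.approx(want[name], abs=1e-9), name

    def test_gldzm_distances_via_enumeration(self):
        # 5x5 slice fully in ROI: city-block distance to outside is 1 on the
        # border ring and 2 in the 3x3 interior, 3 at the center
        levels = np.ones((5, 5), dtype=np.int64)
        levels[2, 2] = 2
        m = gldzm_matrix(levels, 2)
        # level-2 zone is the single center voxel, distance 3
        assert m[1, 2] == 1
        # level-1 zone is the ring+interior, closest voxel on the border: distance 1
        assert m[0, 0] == 1
        assert m.sum() == 2


class TestNeighborhoodFamilies:
    def test_ngtdm_hand_example(self):
        # uniform 3x3 slice: every |level - neighborhood mean| is zero
        levels = np.full((3, 3, 1), 2, dtype=np.int64)
        n_i, s_i = ngtdm_counts(levels, 2)
        assert n_i[1] == 9 and s_i[1] == 0.0
        feats = ngtdm_features(n_i, s_i)
        assert np.isnan(feats["coarseness"])  # zero denominator flagged

    def test_ngtdm_two_level_strip(self):
        levels = np.array([[1, 1, 2, 2]], dtype=np.int64)[:, :, None]
        n_i, s_i = ngtdm_counts(levels, 2)
        # voxel-wise neighborhood means: [1, 1.5, 1.5, 2] -> deviations [0, .5, .5, 0]
        np.testing.assert_allclose(n_i, [2, 2])
        np.testing.assert_allclose(s_i, [0.5, 0.5], atol=1e-12)

    def test_ngldm_dependence_counts(self):
        levels = np.array([[1, 1, 2], [1, 2, 2]], dtype=np.int64)[:, :, None]
        m = ngldm_matrix(levels, 2)
        # equal-level neighbor counts: three level-1 voxels have 2,2,2 and the
        # level-2 voxels 2,2,2 -> all dependence j = 3
        assert m.shape[1] == 3
        np.testing.assert_allclose(m[:, 2], [3, 3])
        assert m.sum() == 6


def test_avg_and_merged_agree_for_uniform_roi():
    # identical (normalised) per-direction matrices -> averaged == merged
    import radibias as rb
    from radibias.volumetrics import ImageVolume, VOIMask

    grid = np.full((14, 14, 14), 5.0)
    x, y, z = np.meshgrid(*(np.arange(14) - 6.5,) * 3, indexing="ij")
    mask = (x**2 + y**2 + z**2) <= 5.0**2
    feats = rb.extract_features(
        ImageVolume(grid=grid, spacing=(2.0, 2.0, 2.0)),
        VOIMask(grid=mask, spacing=(2.0, 2.0, 2.0)),
    )
    for base in ("joint_maximum", "contrast", "joint_entropy"):
        assert feats[f"glcm_{base}_3d_avg"] == pytest.approx(
            feats[f"glcm_{base}_3d_mrg"], abs=1e-9
        )
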