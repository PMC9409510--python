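"""Enumerable catalog of the non-morphological radiomic feature set.

Ten feature families are active: two intensity-based families computed on
continuous SUV values (local intensity, statistics), two on discretised values
(intensity histogram, intensity-volume histogram), and six texture families.
Texture base features are expanded over aggregation variants: co-occurrence and
run-length families over six (2D/2.5D per-direction vs merged, 3D averaged vs
merged), zone and neighborhood families over three (2D, 2.5D, 3D).

The NGLDM dependence count percentage equals 1 by construction whenever every
ROI voxel contributes a dependence count, carrying no information; its three
aggregation variants are excluded by default, leaving 455 active features.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "FeatureCatalogEntry",
    "build_catalog",
    "family_counts",
    "DEFAULT_EXCLUSIONS",
    "ALL_FAMILIES",
    "AGG_DIRECTED",
    "AGG_UNDIRECTED",
]

AGG_DIRECTED = ("2d_avg", "2d_mrg", "2p5d_avg", "2p5d_mrg", "3d_avg", "3d_mrg")
AGG_UNDIRECTED = ("2d", "2p5d", "3d")

LOCAL_INTENSITY_FEATURES = ("local_peak", "global_peak")

STATISTICS_FEATURES = (
    "mean", "variance", "skewness", "kurtosis", "median", "minimum", "p10", "p90",
    "maximum", "interquartile_range", "range", "mean_absolute_deviation",
    "robust_mean_absolute_deviation", "median_absolute_deviation",
    "coefficient_of_variation", "quartile_coefficient_of_dispersion", "energy",
    "root_mean_square",
)

# 23 standard histogram descriptors plus the grey-level count, so the family
# carries 24 features.
INTENSITY_HISTOGRAM_FEATURES = (
    "mean", "variance", "skewness", "kurtosis", "median", "minimum", "p10", "p90",
    "maximum", "mode", "interquartile_range", "range", "mean_absolute_deviation",
    "robust_mean_absolute_deviation", "median_absolute_deviation",
    "coefficient_of_variation", "quartile_coefficient_of_dispersion", "entropy",
    "uniformity", "max_gradient", "max_gradient_level", "min_gradient",
    "min_gradient_level", "grey_level_count",
)

IVH_FEATURES = (
    "v10", "v90", "i10", "i90", "v10_minus_v90", "i10_minus_i90",
)

GLCM_FEATURES = (
    "joint_maximum", "joint_average", "joint_variance", "joint_entropy",
    "difference_average", "difference_variance", "difference_entropy",
    "sum_average", "sum_variance", "sum_entropy", "angular_second_moment",
    "contrast", "dissimilarity", "inverse_difference",
    "inverse_difference_normalised", "inverse_difference_moment",
    "inverse_difference_moment_normalised", "inverse_variance", "correlation",
    "autocorrelation", "cluster_tendency", "cluster_shade", "cluster_prominence",
    "information_correlation_1", "information_correlation_2",
)

GLRLM_FEATURES = (
    "short_runs_emphasis", "long_runs_emphasis", "low_grey_level_run_emphasis",
    "high_grey_level_run_emphasis", "short_run_low_grey_level_emphasis",
    "short_run_high_grey_level_emphasis", "long_run_low_grey_level_emphasis",
    "long_run_high_grey_level_emphasis", "grey_level_non_uniformity",
    "grey_level_non_uniformity_normalised", "run_length_non_uniformity",
    "run_length_non_uniformity_normalised", "run_percentage",
    "grey_level_variance", "run_length_variance", "run_entropy",
)

GLSZM_FEATURES = (
    "small_zone_emphasis", "large_zone_emphasis", "low_grey_level_zone_emphasis",
    "high_grey_level_zone_emphasis", "small_zone_low_grey_level_emphasis",
    "small_zone_high_grey_level_emphasis", "large_zone_low_grey_level_emphasis",
    "large_zone_high_grey_level_emphasis", "grey_level_non_uniformity",
    "grey_level_non_uniformity_normalised", "zone_size_non_uniformity",
    "zone_size_non_uniformity_normalised", "zone_percentage",
    "grey_level_variance", "zone_size_variance", "zone_size_entropy",
)

GLDZM_FEATURES = (
    "small_distance_emphasis", "large_distance_emphasis",
    "low_grey_level_zone_emphasis", "high_grey_level_zone_emphasis",
    "small_distance_low_grey_level_emphasis",
    "small_distance_high_grey_level_emphasis",
    "large_distance_low_grey_level_emphasis",
    "large_distance_high_grey_level_emphasis", "grey_level_non_uniformity",
    "grey_level_non_uniformity_normalised", "zone_distance_non_uniformity",
    "zone_distance_non_uniformity_normalised", "zone_percentage",
    "grey_level_variance", "zone_distance_variance", "zone_distance_entropy",
)

NGTDM_FEATURES = ("coarseness", "contrast", "busyness", "complexity", "strength")

NGLDM_FEATURES = (
    "low_dependence_emphasis", "high_dependence_emphasis",
    "low_grey_level_count_emphasis", "high_grey_level_count_emphasis",
    "low_dependence_low_grey_level_emphasis",
    "low_dependence_high_grey_level_emphasis",
    "high_dependence_low_grey_level_emphasis",
    "high_dependence_high_grey_level_emphasis", "grey_level_non_uniformity",
    "grey_level_non_uniformity_normalised", "dependence_count_non_uniformity",
    "dependence_count_non_uniformity_normalised", "dependence_count_percentage",
    "grey_level_variance", "dependence_count_variance",
    "dependence_count_entropy", "dependence_count_energy",
)

_FAMILY_SPECS: dict[str, tuple[str, tuple[str, ...], tuple[str, ...]]] = {
    # family -> (id prefix, base features, aggregations)
    "local_intensity": ("loc", LOCAL_INTENSITY_FEATURES, ("none",)),
    "statistics": ("stat", STATISTICS_FEATURES, ("none",)),
    "intensity_histogram": ("ih", INTENSITY_HISTOGRAM_FEATURES, ("none",)),
    "intensity_volume_histogram": ("ivh", IVH_FEATURES, ("none",)),
    "glcm": ("glcm", GLCM_FEATURES, AGG_DIRECTED),
    "glrlm": ("glrlm", GLRLM_FEATURES, AGG_DIRECTED),
    "glszm": ("glszm", GLSZM_FEATURES, AGG_UNDIRECTED),
    "gldzm": ("gldzm", GLDZM_FEATURES, AGG_UNDIRECTED),
    "ngtdm": ("ngtdm", NGTDM_FEATURES, AGG_UNDIRECTED),
    "ngldm": ("ngldm", NGLDM_FEATURES, AGG_UNDIRECTED),
}

ALL_FAMILIES = tuple(_FAMILY_SPECS)

DEFAULT_EXCLUSIONS = tuple(
    f"ngldm_dependence_count_percentage_{agg}" for agg in AGG_UNDIRECTED
)


@dataclass(frozen=True)
class FeatureCatalogEntry:
    family: str
    base_name: str
    aggregation: str
    feature_id: str


def build_catalog(
    exclusions: tuple[str, ...] = DEFAULT_EXCLUSIONS,
    families: tuple[str, ...] = ALL_FAMILIES,
) -> list[FeatureCatalogEntry]:
    """Enumerate the active feature catalog.

    ``exclusions`` are feature ids removed from the active set; unknown ids
    raise. With the default exclusions and all families, 455 entries result.
    """
    entries: list[FeatureCatalogEntry] = []
    for fam in families:
        if fam not in _FAMILY_SPECS:
            raise KeyError(f"unknown feature family: {fam}")
        prefix, bases, aggs = _FAMILY_SPECS[fam]
        for base in bases:
            for agg in aggs:
                fid = f"{prefix}_{base}" if agg == "none" else f"{prefix}_{base}_{agg}"
                entries.append(FeatureCatalogEntry(fam, base, agg, fid))
    known = {e.feature_id for e in entries}
    all_known = {
        (f"{p}_{b}" if a == "none" else f"{p}_{b}_{a}")
        for p, bs, ags in _FAMILY_SPECS.values()
        for b in bs
        for a in ags
    }
    for ex in exclusions:
        if ex not in all_known:
            raise KeyError(f"unknown exclusion id: {ex}")
    excluded = set(exclusions) & known
    return [e for e in entries if e.feature_id not in excluded]


def family_counts(catalog: list[FeatureCatalogEntry]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for e in catalog:
        counts[e.family] = counts.get(e.family, 0) + 1
    return counts
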