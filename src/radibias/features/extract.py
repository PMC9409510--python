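"""Feature extraction for a (volume, VOI) pair and for whole phantom studies."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..errors import DegenerateROIError
from ..phantom import MORPHOLOGIES, PhantomSpec, ReconProtocol, iter_study
from ..volumetrics import (
    DiscretizationSettings,
    ImageVolume,
    ResampleSettings,
    VOIMask,
    crop_to_mask,
    difference_image,
    resample,
)
from .catalog import ALL_FAMILIES, DEFAULT_EXCLUSIONS, build_catalog
from .intensity import (
    intensity_histogram_features,
    ivh_features,
    local_intensity_features,
    statistics_features,
)
from .texture import texture_family_features
from ..volumetrics import discretize

__all__ = ["ExtractionSettings", "extract_features", "extract_study", "estimate_noise"]

_TEXTURE_FAMILIES = ("glcm", "glrlm", "glszm", "gldzm", "ngtdm", "ngldm")


@dataclass(frozen=True)
class ExtractionSettings:
    discretization: DiscretizationSettings = field(default_factory=DiscretizationSettings)
    resampling: ResampleSettings = field(default_factory=ResampleSettings)
    families: tuple[str, ...] = ALL_FAMILIES
    exclusions: tuple[str, ...] = DEFAULT_EXCLUSIONS
    crop_margin_mm: float = 8.0


def extract_features(
    volume: ImageVolume,
    mask: VOIMask,
    settings: ExtractionSettings | None = None,
) -> dict[str, float]:
    """Compute the active feature catalog for one image/VOI pair.

    The pair is cropped around the VOI, resampled to the isotropic target grid
    with tri-linear interpolation and discretised with the fixed bin width.
    Returns a feature_id -> value mapping covering the active catalog, with NaN
    for features undefined on this ROI.
    """
    settings = settings or ExtractionSettings()
    vol_c, mask_c = crop_to_mask(volume, mask, settings.crop_margin_mm)
    vol_r, mask_r = resample(vol_c, mask_c, settings.resampling)
    m = mask_r.grid
    if m.sum() < 2:
        raise DegenerateROIError("ROI has fewer than 2 voxels after preprocessing")
    values = vol_r.grid[m]

    levels_grid = np.zeros(vol_r.grid.shape, dtype=np.int64)
    roi_levels, n_levels = discretize(values, settings.discretization)
    levels_grid[m] = roi_levels

    out: dict[str, float] = {}
    fams = settings.families
    if "local_intensity" in fams:
        out.update(local_intensity_features(vol_r.grid, m, vol_r.spacing))
    if "statistics" in fams:
        out.update(statistics_features(values))
    if "intensity_histogram" in fams:
        out.update(intensity_histogram_features(roi_levels, n_levels))
    if "intensity_volume_histogram" in fams:
        out.update(ivh_features(values))
    for fam in _TEXTURE_FAMILIES:
        if fam in fams:
            out.update(texture_family_features(levels_grid, n_levels, fam))

    catalog = build_catalog(settings.exclusions, fams)
    return {e.feature_id: float(out[e.feature_id]) for e in catalog}


def extract_study(
    spec: PhantomSpec,
    protocol: ReconProtocol,
    settings: ExtractionSettings | None = None,
    seed: int | None = None,
    collect_noise: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a study and extract features frame by frame.

    Returns a tidy feature table (tumor_label, tbr, morphology, duration_s,
    replicate, protocol, feature_id, value) and a noise table with the
    difference-image statistics of replicates 1 and 2 per tumor and duration.
    """
    settings = settings or ExtractionSettings()
    rows: list[dict] = []
    noise_rows: list[dict] = []
    pending_frame1: dict[tuple[int, float], ImageVolume] = {}
    for fs in iter_study(spec, protocol, seed):
        for morph in MORPHOLOGIES:
            label = spec.tumor_label(morph, fs.tbr_index)
            feats = extract_features(fs.volume, fs.masks[label], settings)
            for fid, val in feats.items():
                rows.append(
                    {
                        "tumor_label": label,
                        "tbr": fs.tbr,
                        "morphology": morph,
                        "duration_s": fs.duration,
                        "replicate": str(fs.replicate),
                        "protocol": fs.protocol,
                        "feature_id": fid,
                        "value": val,
                    }
                )
        if collect_noise and fs.replicate in (1, 2):
            key = (fs.tbr_index, fs.duration)
            if fs.replicate == 1:
                pending_frame1[key] = fs.volume
            else:
                frame1 = pending_frame1.pop(key)
                for morph in MORPHOLOGIES:
                    label = spec.tumor_label(morph, fs.tbr_index)
                    est = estimate_noise(frame1, fs.volume, fs.masks[label])
                    noise_rows.append(
                        {
                            "tumor_label": label,
                            "duration_s": fs.duration,
                            "protocol": fs.protocol,
                            "sd_diff": est[0],
                            "cov_diff": est[1],
                        }
                    )
    features = pd.DataFrame(rows)
    noise = pd.DataFrame(noise_rows)
    return features, noise


def estimate_noise(
    frame1: ImageVolume, frame2: ImageVolume, mask: VOIMask
) -> tuple[float, float]:
    """SD and COV of the difference image inside the VOI.

    ``sd_diff`` is the sample SD of (frame1 - frame2) voxels in the VOI;
    ``cov_diff`` divides it by the VOI mean of the replicate average. A
    non-positive mean leaves ``cov_diff`` as NaN.
    """
    diff = difference_image(frame1, frame2)
    vals = diff.grid[mask.grid]
    sd_diff = float(np.std(vals, ddof=1))
    mean_pair = float(np.mean(((frame1.grid + frame2.grid) / 2.0)[mask.grid]))
    cov_diff = sd_diff / mean_pair if mean_pair > 0 else float("nan")
    return sd_diff, cov_diff
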