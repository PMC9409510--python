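"""Synthetic digital phantom emulating replicate PET acquisitions of tumor inserts.

The generator reproduces the statistical structure of a NEMA-IQ-style phantom
study with three insert morphologies (homogeneous uptake, necrotic core, and a
two-compartment insert with only one compartment filled) scanned at three
tumor-to-background ratios — nine simulated tumors in total. Per tumor it
produces one long, nearly noise-free reference acquisition plus replicate short
frames whose noise variance scales inversely with frame duration, post-smoothed
with the reconstruction protocol's Gaussian PSF (6.5 mm FWHM for EARL1-like,
5.0 mm for EARL2-like harmonised reconstructions).

The noise model is an additive zero-mean Gaussian field: counting statistics in
reconstructed PET images are well approximated by Gaussian noise whose standard
deviation scales as 1/sqrt(acquisition time), and the downstream method consumes
only reconstructed-image noise statistics. Truth and noise are smoothed
together, so frames from different protocols generated from the same seed share
the pre-smoothing noise field and differ only through the PSF.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
from scipy import ndimage

from .errors import SizingError
from .volumetrics import ImageVolume, VOIMask

__all__ = [
    "ReconProtocol",
    "EARL1",
    "EARL2",
    "PROTOCOLS",
    "PhantomSpec",
    "FrameSet",
    "FrameRecord",
    "build_ground_truth",
    "to_suv",
    "simulate_frame",
    "iter_study",
    "generate_study",
]

MORPHOLOGIES = ("homogeneous", "necrotic_core", "half_filled")

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class ReconProtocol:
    """Reconstruction protocol emulated as Gaussian post-smoothing."""

    name: str
    smoothing_fwhm_mm: float

    def __post_init__(self) -> None:
        if self.smoothing_fwhm_mm < 0:
            raise ValueError("FWHM must be >= 0")


EARL1 = ReconProtocol("EARL1", 6.5)
EARL2 = ReconProtocol("EARL2", 5.0)
PROTOCOLS = {"EARL1": EARL1, "EARL2": EARL2}


@dataclass(frozen=True)
class PhantomSpec:
    """Study design of the synthetic phantom acquisitions.

    Defaults reproduce the acquisition design: fillings with tumor activities
    14.43/7.17/3.65 kBq/ml over backgrounds 1.6/1.61/1.22 kBq/ml (nominal TBR
    10:1, 5:1, 2.5:1), ten replicate frames at 5/10/30/120 s, and a 2400 s
    reference approximating a noise-free scan. ``noise_scale_sigma_ref`` is the
    pre-smoothing voxel noise SD (in SUV) at the reference duration; shorter
    frames scale it by sqrt(reference_duration / duration).

    ``insert_scale`` shrinks the insert geometry together with small test grids;
    at the default 1.0 every insert exceeds 10 cm^3, respecting the usual
    recommendation to restrict radiomic analysis to lesions larger than 10 cm^3.
    """

    tbr_list: tuple[float, ...] = (10.0, 5.0, 2.5)
    tumor_activities: tuple[float, ...] = (14.43, 7.17, 3.65)
    background_activities: tuple[float, ...] = (1.6, 1.61, 1.22)
    frame_durations: tuple[float, ...] = (5.0, 10.0, 30.0, 120.0)
    n_replicates: int = 10
    reference_duration: float = 2400.0
    voxel_size: tuple[float, float, float] = (3.1819, 3.1819, 2.0)
    grid_shape: tuple[int, int, int] = (96, 96, 64)
    noise_scale_sigma_ref: float = 0.12
    insert_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (len(self.tbr_list) == len(self.tumor_activities) == len(self.background_activities)):
            raise ValueError("tbr_list, tumor_activities and background_activities must align")
        for tumor, bg in zip(self.tumor_activities, self.background_activities):
            if not (tumor > bg > 0):
                raise ValueError("tumor activity must exceed background activity")
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates")
        if any(d <= 0 for d in self.frame_durations) or self.reference_duration <= 0:
            raise ValueError("all durations must be > 0")
        if self.noise_scale_sigma_ref < 0:
            raise ValueError("noise_scale_sigma_ref must be >= 0")

    @property
    def n_tumors(self) -> int:
        return len(self.tbr_list) * len(MORPHOLOGIES)

    def tumor_label(self, morphology: str, tbr_index: int) -> str:
        return f"{morphology}_tbr{self.tbr_list[tbr_index]:g}"


def _world_grids(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    axes = [
        (np.arange(n) - (n - 1) / 2.0) * s
        for n, s in zip(spec.grid_shape, spec.voxel_size)
    ]
    return np.meshgrid(*axes, indexing="ij", sparse=True)


def _ellipsoid(X, Y, Z, center, semiaxes) -> np.ndarray:
    return (
        ((X - center[0]) / semiaxes[0]) ** 2
        + ((Y - center[1]) / semiaxes[1]) ** 2
        + ((Z - center[2]) / semiaxes[2]) ** 2
    ) <= 1.0


def _insert_geometry(spec: PhantomSpec):
    """Insert centers and semiaxes in mm, scaled with the grid extent."""
    s = spec.insert_scale
    fov_x = spec.grid_shape[0] * spec.voxel_size[0]
    cx = 0.28 * fov_x
    return {
        "homogeneous": {"center": (-cx, 0.0, 0.0), "semiaxes": (16 * s, 14 * s, 12 * s)},
        "necrotic_core": {
            "center": (0.0, 0.0, 0.0),
            "semiaxes": (17 * s, 15 * s, 13 * s),
            "core_semiaxes": (8 * s, 7 * s, 6 * s),
        },
        "half_filled": {
            "center": (cx, 0.0, 0.0),
            "lobe_offset": 11 * s,
            "lobe_semiaxes": (12 * s, 13 * s, 11 * s),
        },
    }


def build_ground_truth(spec: PhantomSpec, tbr_index: int) -> tuple[ImageVolume, list[VOIMask]]:
    """Noise-free activity map (kBq/ml) with the three inserts, plus one VOI each.

    VOIs cover the full insert extent including cold regions (the necrotic core
    and the unfilled compartment), as a CT-based delineation would.
    """
    if tbr_index not in range(len(spec.tbr_list)):
        raise IndexError(f"tbr_index must be in 0..{len(spec.tbr_list) - 1}")
    tumor_act = spec.tumor_activities[tbr_index]
    bg_act = spec.background_activities[tbr_index]
    X, Y, Z = _world_grids(spec)
    geo = _insert_geometry(spec)
    grid = np.full(spec.grid_shape, bg_act, dtype=np.float64)
    masks: list[VOIMask] = []

    g = geo["homogeneous"]
    m1 = _ellipsoid(X, Y, Z, g["center"], g["semiaxes"])
    grid[m1] = tumor_act

    g = geo["necrotic_core"]
    m2 = _ellipsoid(X, Y, Z, g["center"], g["semiaxes"])
    core = _ellipsoid(X, Y, Z, g["center"], g["core_semiaxes"])
    grid[m2] = tumor_act
    grid[core] = 0.0

    g = geo["half_filled"]
    c = g["center"]
    off = g["lobe_offset"]
    hot = _ellipsoid(X, Y, Z, (c[0] - off, c[1], c[2]), g["lobe_semiaxes"])
    cold = _ellipsoid(X, Y, Z, (c[0] + off, c[1], c[2]), g["lobe_semiaxes"])
    grid[cold] = bg_act
    grid[hot] = tumor_act
    m3 = hot | cold

    for morph, m in zip(MORPHOLOGIES, (m1, m2, m3)):
        if m.sum() < 64:
            raise SizingError(
                f"grid {spec.grid_shape} too small for insert '{morph}' "
                f"({int(m.sum())} voxels); increase grid_shape or lower insert_scale"
            )
        # inserts must not touch the grid boundary
        idx = np.nonzero(m)
        for ax in range(3):
            if idx[ax].min() == 0 or idx[ax].max() == spec.grid_shape[ax] - 1:
                raise SizingError(f"insert '{morph}' touches the grid boundary")
        masks.append(
            VOIMask(grid=m, spacing=spec.voxel_size, tumor_label=spec.tumor_label(morph, tbr_index))
        )

    vol = ImageVolume(
        grid=grid, spacing=spec.voxel_size, units="kBq_per_ml", replicate="truth"
    )
    return vol, masks


def to_suv(volume: ImageVolume, background_activity: float) -> ImageVolume:
    """Convert activity concentration to SUV-like units with background == 1."""
    if volume.units != "kBq_per_ml":
        raise ValueError(f"expected kBq_per_ml input, got {volume.units}")
    if background_activity <= 0:
        raise ZeroDivisionError("background activity must be > 0")
    out = ImageVolume(
        grid=volume.grid / background_activity,
        spacing=volume.spacing,
        units="SUV",
        duration=volume.duration,
        replicate=volume.replicate,
        protocol=volume.protocol,
        tumor_label=volume.tumor_label,
    )
    return out


def noise_sigma(spec: PhantomSpec, duration: float) -> float:
    """Pre-smoothing voxel noise SD (SUV) at a given frame duration."""
    if duration <= 0:
        raise ValueError("duration must be > 0")
    return spec.noise_scale_sigma_ref * np.sqrt(spec.reference_duration / duration)


def simulate_frame(
    truth: ImageVolume,
    spec: PhantomSpec,
    duration: float,
    protocol: ReconProtocol,
    seed: int | np.random.SeedSequence,
) -> ImageVolume:
    """One noisy reconstructed frame: smooth(truth + Gaussian noise field).

    Deterministic given the seed; the noise field depends only on the seed and
    duration, not on the protocol, so EARL1/EARL2 frames with equal seeds share
    the pre-smoothing noise realisation.
    """
    if truth.units != "SUV":
        raise ValueError("simulate_frame expects a noise-free SUV truth map")
    sigma = noise_sigma(spec, duration)
    rng = np.random.default_rng(seed)
    noisy = truth.grid + rng.normal(0.0, 1.0, truth.grid.shape) * sigma
    if protocol.smoothing_fwhm_mm > 0:
        sig_vox = [
            protocol.smoothing_fwhm_mm * _FWHM_TO_SIGMA / s for s in truth.spacing
        ]
        noisy = ndimage.gaussian_filter(noisy, sig_vox, mode="nearest")
    return ImageVolume(
        grid=noisy,
        spacing=truth.spacing,
        units="SUV",
        duration=duration,
        protocol=protocol.name,
        tumor_label=truth.tumor_label,
    )


@dataclass
class FrameSet:
    """One simulated frame of a phantom filling, shared by its three tumors."""

    tbr_index: int
    tbr: float
    duration: float
    replicate: int | str
    protocol: str
    volume: ImageVolume
    masks: dict[str, VOIMask]


@dataclass
class FrameRecord:
    """A (volume, mask) study entry for a single tumor."""

    tumor_label: str
    tbr: float
    morphology: str
    duration: float
    replicate: int | str
    protocol: str
    volume: ImageVolume
    mask: VOIMask


def _frame_seed(master_seed: int, tbr_index: int, duration: float, replicate: int | str) -> np.random.SeedSequence:
    rep_code = -1 if replicate == "reference" else int(replicate)
    # duration encoded in ms to keep the entropy tuple integral
    return np.random.SeedSequence([int(master_seed), tbr_index, int(round(duration * 1000)), rep_code + 1])


def iter_study(
    spec: PhantomSpec, protocol: ReconProtocol, seed: int | None = None
) -> Iterator[FrameSet]:
    """Lazily generate all frames of a study: per filling, the reference frame
    followed by ``n_replicates`` frames at every frame duration."""
    master = spec.seed if seed is None else seed
    for tbr_index in range(len(spec.tbr_list)):
        truth_kbq, masks = build_ground_truth(spec, tbr_index)
        truth = to_suv(truth_kbq, spec.background_activities[tbr_index])
        mask_map = {m.tumor_label: m for m in masks}
        schedule: list[tuple[float, int | str]] = [(spec.reference_duration, "reference")]
        schedule += [
            (d, r) for d in spec.frame_durations for r in range(1, spec.n_replicates + 1)
        ]
        for duration, rep in schedule:
            frame = simulate_frame(
                truth, spec, duration, protocol, _frame_seed(master, tbr_index, duration, rep)
            )
            frame.replicate = rep
            if rep == "reference":
                frame.duration = spec.reference_duration
            yield FrameSet(
                tbr_index=tbr_index,
                tbr=spec.tbr_list[tbr_index],
                duration=duration,
                replicate=rep,
                protocol=protocol.name,
                volume=frame,
                masks=mask_map,
            )


def generate_study(
    spec: PhantomSpec, protocol: ReconProtocol, seed: int | None = None
) -> list[FrameRecord]:
    """Materialised study: one record per (tumor, frame); volumes are shared
    between the three tumors of a filling."""
    records: list[FrameRecord] = []
    for fs in iter_study(spec, protocol, seed):
        for morph in MORPHOLOGIES:
            label = spec.tumor_label(morph, fs.tbr_index)
            records.append(
                FrameRecord(
                    tumor_label=label,
                    tbr=fs.tbr,
                    morphology=morph,
                    duration=fs.duration,
                    replicate=fs.replicate,
                    protocol=fs.protocol,
                    volume=fs.volume,
                    mask=fs.masks[label],
                )
            )
    return records
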