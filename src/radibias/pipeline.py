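"""End-to-end orchestration: simulate, extract, score, gate, correct, report.

A :class:`RunConfig` bundles the phantom design, reconstruction protocols,
preprocessing and thresholds. :func:`run_pipeline` executes all stages per
protocol, optionally caching the expensive simulate+extract stage on disk
(keyed by a config hash) and, when both protocols are run, applies the first
protocol's fitted correction parameters to the second (parameter transfer).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .correctability import CorrectabilityThresholds, funnel_summary, screen_features
from .correction import correct_study, transfer_correct
from .features import ExtractionSettings, build_catalog, extract_study
from .features.catalog import ALL_FAMILIES, DEFAULT_EXCLUSIONS
from .phantom import PROTOCOLS, PhantomSpec
from .robustness import score_study, summarize_categories
from .volumetrics import DiscretizationSettings, ResampleSettings

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "summarize_improvement"]


@dataclass(frozen=True)
class RunConfig:
    spec: PhantomSpec = field(default_factory=PhantomSpec)
    protocols: tuple[str, ...] = ("EARL1", "EARL2")
    families: tuple[str, ...] = ALL_FAMILIES
    exclusions: tuple[str, ...] = DEFAULT_EXCLUSIONS
    bin_width: float = 0.25
    target_voxel_mm: float = 2.0
    mask_threshold: float = 0.5
    bands: tuple[float, float, float] = (0.5, 0.75, 0.9)
    thresholds: CorrectabilityThresholds = field(default_factory=CorrectabilityThresholds)
    sdm_ddof: int = 1
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        if not self.protocols:
            raise ValueError("need at least one protocol")
        for p in self.protocols:
            if p not in PROTOCOLS:
                raise KeyError(f"unknown protocol: {p}")
        if not (0 < self.bands[0] < self.bands[1] < self.bands[2] <= 1):
            raise ValueError("bands must be increasing and in (0, 1]")

    def extraction_settings(self) -> ExtractionSettings:
        return ExtractionSettings(
            discretization=DiscretizationSettings(bin_width=self.bin_width),
            resampling=ResampleSettings(
                target_voxel_mm=self.target_voxel_mm, mask_threshold=self.mask_threshold
            ),
            families=tuple(self.families),
            exclusions=tuple(self.exclusions),
        )

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "spec": asdict(self.spec),
                "protocols": self.protocols,
                "families": self.families,
                "exclusions": self.exclusions,
                "bin_width": self.bin_width,
                "target_voxel_mm": self.target_voxel_mm,
                "mask_threshold": self.mask_threshold,
                "seed": self.seed,
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        spec_kwargs = raw.get("phantom", {})
        for key in ("tbr_list", "tumor_activities", "background_activities",
                    "frame_durations", "voxel_size", "grid_shape"):
            if key in spec_kwargs:
                spec_kwargs[key] = tuple(spec_kwargs[key])
        pre = raw.get("preprocessing", {})
        gates = raw.get("gates", {})
        kwargs: dict = {}
        if spec_kwargs:
            kwargs["spec"] = PhantomSpec(**spec_kwargs)
        if "protocols" in raw:
            kwargs["protocols"] = tuple(raw["protocols"])
        if "families" in raw:
            kwargs["families"] = tuple(raw["families"])
        if "bands" in raw:
            kwargs["bands"] = tuple(raw["bands"])
        for k_yaml, k_cfg in (
            ("bin_width", "bin_width"),
            ("target_voxel_mm", "target_voxel_mm"),
            ("mask_threshold", "mask_threshold"),
        ):
            if k_yaml in pre:
                kwargs[k_cfg] = pre[k_yaml]
        if gates:
            kwargs["thresholds"] = CorrectabilityThresholds(**gates)
        for k in ("seed", "outdir", "sdm_ddof"):
            if k in raw:
                kwargs[k] = raw[k]
        return cls(**kwargs)


@dataclass
class ProtocolResult:
    features: pd.DataFrame
    noise: pd.DataFrame
    icc: pd.DataFrame
    sdm: pd.DataFrame
    icc_summary: pd.DataFrame
    sdm_summary: pd.DataFrame
    correctability: pd.DataFrame
    funnel: pd.DataFrame
    fits: pd.DataFrame
    before_after: pd.DataFrame
    improvement: pd.DataFrame
    correctors: dict


@dataclass
class PipelineResult:
    config: RunConfig
    protocols: dict[str, ProtocolResult]
    transfer: pd.DataFrame | None = None


def _family_map(config: RunConfig) -> dict[str, str]:
    return {e.feature_id: e.family for e in build_catalog(config.exclusions, config.families)}


def summarize_improvement(before_after: pd.DataFrame, worst_duration: float) -> pd.DataFrame:
    """Cross-tabulate features newly good/excellent at the noisiest duration.

    Rows: improvement level x correction technique (additive SD_diff only,
    multiplicative COV_diff only, or both), mirroring the structure of a
    before/after improvement table. A feature counts as improved to a level
    when correction moves it from a lower band into that band.
    """
    if before_after.empty:
        return pd.DataFrame(
            columns=["improvement", "technique", "n_features"]
        )
    at = before_after[before_after["duration_s"] == worst_duration]
    order = {"poor": 0, "moderate": 1, "good": 2, "excellent": 3}
    reach: dict[str, dict[str, str]] = {}
    for _, row in at.iterrows():
        gained = (
            row["category_after"]
            if order[row["category_after"]] > order[row["category_before"]]
            else None
        )
        reach.setdefault(row["feature_id"], {})[row["mode"]] = gained
    counts = {("excellent", t): 0 for t in ("sd_diff_only", "cov_diff_only", "both")}
    counts.update({("good", t): 0 for t in ("sd_diff_only", "cov_diff_only", "both")})
    for fid, modes in reach.items():
        add = modes.get("additive")
        mul = modes.get("multiplicative")
        for level in ("excellent", "good"):
            a = add == level
            m = mul == level
            if level == "excellent" and ("excellent" in (add, mul)):
                key = "both" if (a and m) else ("sd_diff_only" if a else "cov_diff_only")
                counts[("excellent", key)] += 1
                break
            if level == "good" and ("good" in (add, mul)):
                key = "both" if (a and m) else ("sd_diff_only" if a else "cov_diff_only")
                counts[("good", key)] += 1
                break
    rows = [
        {"improvement": lvl, "technique": tech, "n_features": n}
        for (lvl, tech), n in counts.items()
    ]
    return pd.DataFrame(rows)


def _load_or_extract(config: RunConfig, protocol_name: str):
    outdir = Path(config.outdir) if config.outdir else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        hash_file = outdir / "config_hash.json"
        feat_file = outdir / f"features_{protocol_name}.csv"
        noise_file = outdir / f"noise_{protocol_name}.csv"
        if hash_file.exists() and feat_file.exists() and noise_file.exists():
            stored = json.loads(hash_file.read_text()).get("hash")
            if stored == config.config_hash():
                feats = pd.read_csv(feat_file, dtype={"replicate": str})
                noise = pd.read_csv(noise_file)
                return feats, noise
    feats, noise = extract_study(
        config.spec,
        PROTOCOLS[protocol_name],
        config.extraction_settings(),
        seed=config.seed,
    )
    if outdir is not None:
        feats.to_csv(outdir / f"features_{protocol_name}.csv", index=False)
        noise.to_csv(outdir / f"noise_{protocol_name}.csv", index=False)
        (outdir / "config_hash.json").write_text(
            json.dumps({"hash": config.config_hash()})
        )
    return feats, noise


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full analysis for every configured protocol."""
    fam_map = _family_map(config)
    worst = min(config.spec.frame_durations)
    results: dict[str, ProtocolResult] = {}
    for prot in config.protocols:
        feats, noise = _load_or_extract(config, prot)
        icc, sdm = score_study(feats, config.bands, config.sdm_ddof)
        icc_summary = summarize_categories(icc, fam_map)
        sdm_summary = summarize_categories(sdm, fam_map)
        report = screen_features(feats, icc, sdm, config.thresholds, worst)
        funnel = funnel_summary(report)
        correctable = report.loc[report["correctable"], "feature_id"].tolist()
        fits, before_after, correctors = correct_study(
            feats, noise, correctable, config.sdm_ddof, config.seed
        )
        improvement = summarize_improvement(before_after, worst)
        results[prot] = ProtocolResult(
            feats, noise, icc, sdm, icc_summary, sdm_summary, report, funnel,
            fits, before_after, improvement, correctors,
        )
        if config.outdir:
            out = Path(config.outdir)
            icc.to_csv(out / f"icc_{prot}.csv", index=False)
            sdm.to_csv(out / f"sdm_{prot}.csv", index=False)
            icc_summary.to_csv(out / f"icc_summary_{prot}.csv", index=False)
            sdm_summary.to_csv(out / f"sdm_summary_{prot}.csv", index=False)
            report.to_csv(out / f"correctability_{prot}.csv", index=False)
            funnel.to_csv(out / f"funnel_{prot}.csv", index=False)
            fits.to_csv(out / f"fits_{prot}.csv", index=False)
            before_after.to_csv(out / f"sdm_before_after_{prot}.csv", index=False)
            improvement.to_csv(out / f"improvement_{prot}.csv", index=False)

    transfer = None
    if len(config.protocols) >= 2:
        src, dst = config.protocols[0], config.protocols[1]
        ids = sorted(
            {k[0] for k in results[src].correctors}
            & set(results[dst].correctability.loc[
                results[dst].correctability["correctable"], "feature_id"
            ])
        )
        transfer = transfer_correct(
            results[src].correctors,
            results[dst].features,
            results[dst].noise,
            ids,
            config.sdm_ddof,
        )
        if config.outdir and transfer is not None:
            transfer.to_csv(Path(config.outdir) / f"transfer_{src}_to_{dst}.csv", index=False)
    return PipelineResult(config=config, protocols=results, transfer=transfer)
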