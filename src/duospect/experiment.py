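"""Paired in-silico experiment: Ho-only vs dual-isotope dosimetry.

For each seed the pipeline builds the phantom, simulates a Ho-only
acquisition and a dual-isotope acquisition (Tc-colloid added, optional
small rigid motion), reconstructs the 166Ho activity with and without the
window-based downscatter correction, registers the DI frame back onto the
Ho-only frame via the attenuation maps, constructs the clinical VOIs
(ellipsoidal healthy-liver VOI, tumor, 2-cm-shrunk lungs; 25 ml minimum),
computes per-VOI mean absorbed doses from the administered activity, and
finally runs the agreement battery (Bland–Altman, Pearson r, paired t test)
over the seeds. Everything is deterministic given the config and seeds.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dosimetry import (
    DoseModel,
    DoseReport,
    dose_map,
    enforce_min_volume,
    lung_mask,
    mean_voi_dose,
    place_healthy_voi,
    rescale_to_administered,
)
from .geometry import RigidTransform, resample_into
from .phantom import Phantom, PhantomSpec, build_phantom, with_activities
from .recon import ReconConfig, reconstruct_ho
from .register import RegistrationConfig, register_rigid
from .simulate import (
    AcquisitionProtocol,
    CrosstalkModel,
    default_crosstalk,
    default_windows,
    simulate_acquisition,
)
from .stats import PairedSample, bland_altman, paired_t_test, pearson_r
from .volume import VoxelVolume

__all__ = ["ExperimentConfig", "ExperimentReport", "run_paired_experiment", "make_report"]


@dataclass
class ExperimentConfig:
    phantom_spec: PhantomSpec = field(default_factory=PhantomSpec)
    protocol: AcquisitionProtocol = field(default_factory=AcquisitionProtocol)
    crosstalk: CrosstalkModel = field(default_factory=default_crosstalk)
    recon: ReconConfig = field(default_factory=ReconConfig)
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    # administered therapeutic activity the dose maps are scaled to; the
    # scan-time activities live in the phantom spec (~250 + 50 MBq)
    administered_activity_mbq: float = 5757.0
    # small table motion between the two acquisitions (half a voxel)
    di_motion: RigidTransform = field(
        default_factory=lambda: RigidTransform(translation=(2.4, 0.0, 0.0))
    )
    min_voi_ml: float = 25.0
    lung_shrink_cm: float = 2.0
    healthy_voi_ml: float = 27.57
    seeds: tuple[int, ...] = tuple(range(10))
    register_arms: bool = True

    def __post_init__(self):
        if len(self.seeds) == 0:
            raise ValueError("seeds must be non-empty")

    def config_hash(self) -> str:
        blob = json.dumps(_jsonable(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str) -> "ExperimentConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        kwargs = {}
        if "phantom_spec" in d:
            kwargs["phantom_spec"] = PhantomSpec(**_tupled(d["phantom_spec"]))
        if "protocol" in d:
            kwargs["protocol"] = AcquisitionProtocol(**_tupled(d["protocol"]))
        if "recon" in d:
            kwargs["recon"] = ReconConfig(**d["recon"])
        if "di_motion" in d:
            kwargs["di_motion"] = RigidTransform.from_dict(d["di_motion"])
        for key in (
            "administered_activity_mbq",
            "min_voi_ml",
            "lung_shrink_cm",
            "healthy_voi_ml",
            "register_arms",
        ):
            if key in d:
                kwargs[key] = d[key]
        if "seeds" in d:
            kwargs["seeds"] = tuple(d["seeds"])
        return cls(**kwargs)


def _tupled(d: dict) -> dict:
    return {
        k: tuple(v) if isinstance(v, list) else v
        for k, v in d.items()
    }


def _jsonable(obj):
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


@dataclass
class ExperimentReport:
    """Per-seed per-VOI dose pairs plus the paired statistics per arm."""

    pairs: pd.DataFrame  # seed, voi, dose_ho_only, dose_di_corrected, dose_di_uncorrected, volume_ml
    statistics: dict
    rejected_vois: list[dict]
    provenance: dict


def _build_vois(phantom: Phantom, cfg: ExperimentConfig) -> dict:
    grid = phantom.labels
    vois = {
        "healthy": place_healthy_voi(
            phantom.healthy_liver_mask, phantom.mask("tumor"), grid, cfg.healthy_voi_ml
        ),
        "lungs": lung_mask(phantom.mu_81, shrink_cm=cfg.lung_shrink_cm),
    }
    # the tumor VOI stands in for the manually segmented tumor: ground truth
    from .dosimetry import VOIMask

    vois["tumor"] = VOIMask(
        VoxelVolume(phantom.mask("tumor"), grid.spacing, grid.origin), name="tumor"
    )
    return vois


def _voi_doses(recon_vol: VoxelVolume, density: VoxelVolume, vois: dict, administered: float):
    act = rescale_to_administered(recon_vol, administered)
    dm = dose_map(act, density, DoseModel())
    return {name: mean_voi_dose(dm, voi) for name, voi in vois.items()}


def run_paired_experiment(cfg: ExperimentConfig) -> ExperimentReport:
    """Run the full paired Ho-only vs DI dosimetry experiment."""
    rows: list[dict] = []
    rejected: list[dict] = []
    uncorrected = replace(cfg.recon, k_factor=0.0)
    for seed in cfg.seeds:
        spec = replace(cfg.phantom_spec, seed=int(seed))
        phantom = build_phantom(spec)

        # acquisition arms: Ho-only first, then Tc added (with optional motion)
        ho_only_phantom = with_activities(phantom, tc_scale=0.0)
        di_phantom = phantom
        moved = not cfg.di_motion.is_identity()
        if moved:
            from .phantom import apply_rigid_motion

            di_phantom = apply_rigid_motion(phantom, cfg.di_motion)

        proj_ho = simulate_acquisition(
            ho_only_phantom, cfg.protocol, cfg.crosstalk, seed=seed
        )
        proj_di = simulate_acquisition(di_phantom, cfg.protocol, cfg.crosstalk, seed=seed)

        recon_ho = reconstruct_ho(proj_ho, phantom.mu_81, cfg.protocol, cfg.recon)
        recon_di = reconstruct_ho(proj_di, di_phantom.mu_81, cfg.protocol, cfg.recon)
        recon_di_unc = reconstruct_ho(proj_di, di_phantom.mu_81, cfg.protocol, uncorrected)

        # register the DI frame onto the Ho-only frame via the mu-maps
        if cfg.register_arms and moved:
            reg = register_rigid(phantom.mu_81, di_phantom.mu_81, cfg.registration)
            di_vol = resample_into(recon_di.values, reg.transform, fixed_grid=phantom.mu_81)
            di_unc_vol = resample_into(
                recon_di_unc.values, reg.transform, fixed_grid=phantom.mu_81
            )
        else:
            di_vol, di_unc_vol = recon_di.values, recon_di_unc.values

        vois = _build_vois(phantom, cfg)
        kept = {}
        for name, voi in vois.items():
            decision = enforce_min_volume(voi, cfg.min_voi_ml)
            if decision.accepted:
                kept[name] = voi
            else:
                rejected.append({"seed": seed, "voi": name, "reason": decision.reason})
        doses_ho = _voi_doses(recon_ho.values, phantom.density, kept, cfg.administered_activity_mbq)
        doses_di = _voi_doses(di_vol, phantom.density, kept, cfg.administered_activity_mbq)
        doses_unc = _voi_doses(di_unc_vol, phantom.density, kept, cfg.administered_activity_mbq)
        for name in kept:
            rows.append(
                {
                    "seed": seed,
                    "voi": name,
                    "dose_ho_only_gy": doses_ho[name],
                    "dose_di_corrected_gy": doses_di[name],
                    "dose_di_uncorrected_gy": doses_unc[name],
                    "volume_ml": kept[name].volume_ml,
                }
            )

    pairs = pd.DataFrame(rows)
    statistics = _paired_statistics(pairs)
    provenance = {
        "config_hash": cfg.config_hash(),
        "seeds": list(cfg.seeds),
        "recon": asdict(cfg.recon),
        "administered_activity_mbq": cfg.administered_activity_mbq,
    }
    return ExperimentReport(pairs, statistics, rejected, provenance)


def _paired_statistics(pairs: pd.DataFrame) -> dict:
    stats: dict = {}
    if pairs.empty:
        return stats
    for voi, grp in pairs.groupby("voi"):
        stats[voi] = {}
        for arm, col in (
            ("corrected", "dose_di_corrected_gy"),
            ("uncorrected", "dose_di_uncorrected_gy"),
        ):
            s = PairedSample(grp["dose_ho_only_gy"].to_numpy(), grp[col].to_numpy())
            entry: dict = {"n": s.n}
            if s.n >= 2:
                ba = bland_altman(s)
                entry["bland_altman"] = {
                    "mean_diff_gy": ba.mean_diff,
                    "sd_diff_gy": ba.sd_diff,
                    "crp_gy": ba.crp,
                    "loa_gy": [ba.loa_lower, ba.loa_upper],
                }
                try:
                    entry["pearson_r"] = pearson_r(s)
                except ValueError:
                    entry["pearson_r"] = None
                try:
                    t, p = paired_t_test(s)
                    entry["paired_t"] = {"t": t, "p": p}
                except ValueError:
                    entry["paired_t"] = None
            stats[voi][arm] = entry
    return stats


def make_report(report: ExperimentReport, outdir: str, plots: bool = False) -> dict[str, str]:
    """Write the pair table (CSV), statistics (JSON) and optional
    Bland–Altman plots. Idempotent; returns the written paths."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    csv_path = out / "dose_pairs.csv"
    cols = [
        "seed",
        "voi",
        "dose_ho_only_gy",
        "dose_di_corrected_gy",
        "dose_di_uncorrected_gy",
        "volume_ml",
    ]
    df = report.pairs if not report.pairs.empty else pd.DataFrame(columns=cols)
    df.to_csv(csv_path, index=False)
    paths["pairs_csv"] = str(csv_path)
    json_path = out / "statistics.json"
    with open(json_path, "w") as fh:
        json.dump(
            {
                "statistics": report.statistics,
                "rejected_vois": report.rejected_vois,
                "provenance": report.provenance,
            },
            fh,
            indent=1,
        )
    paths["statistics_json"] = str(json_path)
    if plots and not report.pairs.empty:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        for voi, grp in report.pairs.groupby("voi"):
            x = grp["dose_ho_only_gy"].to_numpy()
            y = grp["dose_di_corrected_gy"].to_numpy()
            mean, diff = (x + y) / 2, y - x
            fig, ax = plt.subplots(figsize=(4, 3))
            ax.scatter(mean, diff, s=18)
            if len(diff) >= 2:
                ba = bland_altman(PairedSample(x, y))
                for v, ls in ((ba.mean_diff, "-"), (ba.loa_lower, "--"), (ba.loa_upper, "--")):
                    ax.axhline(v, color="k", ls=ls, lw=1)
            ax.set_xlabel("mean dose [Gy]")
            ax.set_ylabel("DI - Ho-only [Gy]")
            ax.set_title(f"VOI {voi}")
            fig.tight_layout()
            p = out / f"bland_altman_{voi}.png"
            fig.savefig(p, dpi=110)
            plt.close(fig)
            paths[f"plot_{voi}"] = str(p)
    return paths
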