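"""End-to-end orchestration: generate or load ensembles, analyse them, and
write curve/profile/summary outputs with a reproducibility manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import __version__
from .events import (
    EventRecord,
    analyze_trajectory,
    classification_counts,
    ensemble_curves,
)
from .io import read_gro_trajectory, read_xyz_trajectory, write_gro_trajectory
from .model import (
    AnalysisParams,
    ConfigurationError,
    Trajectory,
    assign_groups,
    subsample_frames,
)
from .residues import EmptyWindowError, ProfileAccumulator
from .synth import SimConfig, ensemble_configs, simulate_trajectory, write_ground_truth

log = logging.getLogger("memassoc")


@dataclass
class VariantSpec:
    """One experimental arm of the ensemble design."""

    name: str
    n_trajectories: int
    anchored: bool = True
    protein_model: str = "monomer"
    box: Optional[tuple] = None


#: The reference three-system design: 100 lipid-anchored monomer runs,
#: 10 non-anchored runs, and 16 disulfide-dimer runs (taller box).
DEFAULT_VARIANTS = [
    VariantSpec(name="anchored", n_trajectories=100, anchored=True),
    VariantSpec(name="non_anchored", n_trajectories=10, anchored=False),
    VariantSpec(
        name="dimer",
        n_trajectories=16,
        anchored=False,
        protein_model="dimer",
        box=(11.0, 11.0, 20.0),
    ),
]


@dataclass
class PipelineConfig:
    mode: str = "synthetic"  # or "files"
    params: AnalysisParams = field(default_factory=AnalysisParams)
    sim: SimConfig = field(default_factory=SimConfig)
    variants: list = field(default_factory=lambda: [dataclasses.replace(v) for v in DEFAULT_VARIANTS])
    input_files: dict = field(default_factory=dict)  # variant name -> list of paths
    lipid_residue_names: tuple = ("POPE",)
    solvent_residue_names: tuple = ("W", "WF")
    ion_residue_names: tuple = ("NA", "CL", "ION")
    outdir: str = "memassoc_out"
    seed: int = 0
    inserted_denominator: str = "inserted"
    write_trajectories: bool = False
    profile_cutoff: float = 0.5

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ConfigurationError("mode must be 'synthetic' or 'files'")
        if self.mode == "files":
            missing = [
                p
                for paths in self.input_files.values()
                for p in paths
                if not Path(p).exists()
            ]
            if missing:
                raise ConfigurationError(f"input files not found: {missing}")

    def config_hash(self) -> str:
        payload = {
            "mode": self.mode,
            "params": dataclasses.asdict(self.params) | {
                "head_group_bead_names": sorted(self.params.head_group_bead_names)
            },
            "sim": self.sim.to_dict(),
            "variants": [dataclasses.asdict(v) for v in self.variants],
            "input_files": {k: [str(p) for p in v] for k, v in self.input_files.items()},
            "seed": self.seed,
            "inserted_denominator": self.inserted_denominator,
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()


def summarize(records: list[EventRecord]) -> dict:
    """Ensemble-level statistics for one variant.

    Includes the irreversibility check: the fraction of inserted
    trajectories whose every post-insertion snapshot is a contact.
    """
    counts = classification_counts(records)
    fc_times = [
        float(r.times[r.first_contact_frame])
        for r in records
        if r.first_contact_frame is not None
    ]
    ins_times = [
        float(r.times[r.insertion_frame])
        for r in records
        if r.insertion_frame is not None
    ]
    inserted = [r for r in records if r.insertion_frame is not None]
    unbroken = sum(
        1 for r in inserted if bool(np.all(r.contact_mask[r.insertion_frame :]))
    )
    return {
        "n": len(records),
        "counts": counts,
        "inserted_fraction": counts["inserted"] / len(records) if records else 0.0,
        "median_first_contact_ns": float(np.median(fc_times)) if fc_times else None,
        "median_insertion_ns": float(np.median(ins_times)) if ins_times else None,
        "irreversibility_fraction": (unbroken / len(inserted)) if inserted else None,
    }


def _iter_variant_trajectories(config: PipelineConfig, variant: VariantSpec, base_seed: int):
    """Yield (trajectory, ground_truth_or_None, id) one at a time."""
    if config.mode == "synthetic":
        sim = _variant_sim(config, variant)
        for cfg, tid in ensemble_configs(sim, variant.n_trajectories, base_seed):
            traj, gt = simulate_trajectory(cfg, trajectory_id=tid)
            yield traj, gt, tid
        return
    paths = config.input_files.get(variant.name, [])
    if not paths:
        raise ConfigurationError(f"variant {variant.name!r} has no input files")
    for path in map(Path, paths):
        reader = read_xyz_trajectory if path.suffix == ".xyz" else read_gro_trajectory
        t = reader(path)
        t.topology = assign_groups(
            t.topology,
            config.lipid_residue_names,
            config.solvent_residue_names,
            config.ion_residue_names,
        )
        yield t, None, path.stem


def _variant_sim(config: PipelineConfig, variant: VariantSpec) -> SimConfig:
    overrides = {"anchored": variant.anchored, "protein_model": variant.protein_model}
    if variant.box is not None:
        overrides["box"] = tuple(variant.box)
    return dataclasses.replace(config.sim, **overrides)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full workflow; returns the report dict written to summary.json.

    Stages per variant: (1) generate or load trajectories, (2) subsample to
    the analysis interval, (3) contact/insertion analysis, (4) ensemble
    curves, (5) residue profiles (after/before insertion for anchored
    variants, after first contact otherwise).  Any stage failure raises,
    and partially written outputs are flagged in the manifest.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = config.params
    report: dict = {"variants": {}}
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "memassoc_version": __version__,
        "numpy_version": np.__version__,
        "outputs": [],
        "warnings": [],
    }

    def _emit(path: Path) -> None:
        manifest["outputs"].append(str(path.name))

    base_seed = config.seed
    for variant in config.variants:
        log.info("variant %s: preparing %s trajectories", variant.name, variant.n_trajectories)
        phases = (
            ("after_insertion", "before_insertion") if variant.anchored else ("after_first_contact",)
        )
        accumulators = {ph: ProfileAccumulator(params, ph) for ph in phases}
        records: list[EventRecord] = []
        ground_truth = []
        n_snap: set[int] = set()
        # trajectories are independent: stream them one at a time so large
        # ensembles never sit in memory together
        for i, (traj, gt, tid) in enumerate(
            _iter_variant_trajectories(config, variant, base_seed)
        ):
            if config.write_trajectories:
                p = outdir / f"{variant.name}_{i:04d}.gro"
                write_gro_trajectory(traj, p)
                _emit(p)
            sub = subsample_frames(traj, params.frame_interval)
            n_snap.add(sub.n_frames)
            rec = analyze_trajectory(sub, params, trajectory_id=f"{variant.name}_{tid}")
            records.append(rec)
            if gt is not None:
                ground_truth.append(gt)
            for acc in accumulators.values():
                acc.add(sub, rec)
        if config.mode == "synthetic":
            base_seed += variant.n_trajectories
            gt_path = outdir / f"{variant.name}_ground_truth.json"
            write_ground_truth(ground_truth, gt_path)
            _emit(gt_path)
        log.info("variant %s: %s snapshots per trajectory", variant.name, sorted(n_snap))

        curves = ensemble_curves(records, params, config.inserted_denominator)
        curves_path = outdir / f"{variant.name}_curves.csv"
        curves.to_frame().to_csv(curves_path, index=False)
        _emit(curves_path)

        profiles = {}
        for phase, acc in accumulators.items():
            try:
                prof = acc.finalize()
            except EmptyWindowError as exc:
                manifest["warnings"].append(f"{variant.name}/{phase}: {exc}")
                continue
            p = outdir / f"{variant.name}_profile_{phase}.csv"
            prof.to_csv(p)
            _emit(p)
            profiles[phase] = {
                "max_probability": float(prof.probabilities.max()),
                "denominator": prof.denominator,
                "high_contact_residues": [
                    int(r)
                    for r, pr in zip(prof.residue_ids, prof.probabilities)
                    if pr >= config.profile_cutoff
                ],
            }

        summary = summarize(records)
        summary["snapshots_per_trajectory"] = sorted(n_snap)
        summary["profiles"] = profiles
        if ground_truth:
            detected = [r.insertion_frame for r in records]
            truth = [g.true_insertion_frame for g in ground_truth]
            summary["ground_truth_insertion_match"] = sum(
                1 for d, t in zip(detected, truth) if d == t
            ) / len(records)
        report["variants"][variant.name] = summary

    summary_path = outdir / "summary.json"
    summary_path.write_text(json.dumps(report, indent=2, default=str) + "\n")
    _emit(summary_path)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return report
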