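"""End-to-end orchestration from a flat key-value configuration.

Stages: features -> clustering -> network -> cut-based profile -> kinetics ->
committor/TSE (-> LIE when energies are present).  Every stage writes its TSV
output into the output directory together with a machine-readable provenance
manifest (config values, config hash, seeds, package version, input
checksum), so a rerun with the same config and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clustering import leader_cluster
from .committor import node_committor, select_tse
from .cfep import cut_profile, detect_subbasins, solve_mfpt, write_profile_tsv
from .kinetics import cross_validated_tau, detect_events, fit_single_exponential
from .lie import lie_estimate, write_estimate_tsv
from .network import (
    build_network,
    restrict_nodes,
    symmetrize,
    write_edge_list,
    write_node_table,
)
from .synthetic import TrajectorySet

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Flat, diffable run configuration with field-level defaults matching
    the conventional operating point of the method."""

    input: str = ""  # feature TSV (synthetic dialect); empty = caller passes data
    out_dir: str = "unbindnet_out"
    drms_threshold: float = 1.0  # Å
    dt: float = 4.0  # ps, lag = saving interval
    temperature: float = 310.0  # K
    unbind_cut: float = 15.0  # Å
    rebind_cut: float = 10.0  # Å
    bound_restrict_cut: float = 15.0  # Å, node filter for the bound-state network
    commitment_time: float = 800.0  # ps
    tse_band: tuple[float, float] = (0.45, 0.55)
    tse_min_snapshots: int = 20
    tse_min_weight: float = 5.0
    lie_alpha: float = 0.56
    lie_beta: float = 0.5
    lie_blocks: int = 5
    cv_splits: int = 100
    seed: int = 0
    subbasin_min_drop_kT: float = 0.5

    def validate(self) -> None:
        for name in (
            "drms_threshold",
            "dt",
            "temperature",
            "unbind_cut",
            "rebind_cut",
            "commitment_time",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.tse_band[0] < self.tse_band[1] <= 1:
            raise ValueError("tse_band must be an increasing pair within [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "tse_band" in raw:
            raw["tse_band"] = tuple(raw["tse_band"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["tse_band"] = list(d["tse_band"])
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(
    config: PipelineConfig, trajectories: TrajectorySet | None = None
) -> dict:
    """Execute every stage and write the report bundle.

    Returns a summary dict (also written as ``summary.json``).  Input comes
    from ``config.input`` (feature TSV) unless a TrajectorySet is passed
    directly.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "version": __version__,
    }

    if trajectories is None:
        if not config.input:
            raise ValueError("config.input is empty and no trajectories were passed")
        trajectories = TrajectorySet.from_tsv(config.input, dt=config.dt)
        manifest["input_checksum"] = _checksum(Path(config.input))
    frames = trajectories.frames
    dcols = [c for c in frames.columns if c.startswith("d_")]
    summary: dict = {"n_runs": int(frames["run_id"].nunique()), "n_snapshots": len(frames)}

    def _stage(name):
        class _Ctx:
            def __enter__(self):
                return self

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc

        return _Ctx()

    # clustering
    with _stage("clustering"):
        if not dcols:
            raise ValueError("input carries no distance vector columns d_*")
        model = leader_cluster(frames[dcols].to_numpy(), config.drms_threshold)
        assignments = model.assignment_table(frames)
        assignments.to_csv(
            out / "assignments.tsv", sep="\t", index=False, float_format="%.10g"
        )
        summary["n_nodes"] = model.n_nodes

    # network
    with _stage("network"):
        net = symmetrize(build_network(assignments, dt=config.dt))
        write_edge_list(net, out / "edges.tsv")
        write_node_table(net, out / "nodes.tsv")
        summary["Z"] = net.Z

    # cut-based profile on the full network + subbasins on the bound part
    with _stage("cfep"):
        ref = int(np.argmax(net.Z_i))
        mfpt = solve_mfpt(net, ref)
        profile = cut_profile(net, mfpt, temperature=config.temperature)
        write_profile_tsv(profile, out / "profile.tsv")
        summary["main_barrier_kT"] = profile.barrier_height()
        bound_net = restrict_nodes(net, lambda com: com < config.bound_restrict_cut)
        sb = detect_subbasins(
            bound_net,
            temperature=config.temperature,
            min_drop_kT=config.subbasin_min_drop_kT,
        )
        sb.table().to_csv(out / "subbasins.tsv", sep="\t", index=False)
        summary["n_subbasins"] = sb.n_subbasins

    # kinetics
    with _stage("kinetics"):
        events = detect_events(
            frames, unbind_cut=config.unbind_cut, rebind_cut=config.rebind_cut
        )
        events.runs.to_csv(
            out / "events.tsv", sep="\t", index=False, float_format="%.10g"
        )
        summary["n_unbinding_events"] = events.n_events
        summary["n_rebinding_events"] = len(events.rebinds)
        if events.n_events >= 5:
            fit = fit_single_exponential(events)
            summary["tau_ps"] = fit.tau
            if events.n_runs >= 10:
                cv = cross_validated_tau(
                    events, n_splits=config.cv_splits, seed=config.seed
                )
                summary["tau_cv_ps"] = cv.tau
                summary["tau_cv_error_ps"] = cv.cv_error

    # committor / TSE
    with _stage("committor"):
        ctab = node_committor(
            assignments,
            commitment_time=config.commitment_time,
            dt=config.dt,
            unbind_cut=config.unbind_cut,
            rebind_cut=config.rebind_cut,
            net=net,
            fitted_tau=summary.get("tau_ps"),
        )
        ctab.nodes.to_csv(
            out / "committor.tsv", sep="\t", index=False, float_format="%.10g"
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            tse = select_tse(
                ctab,
                band=config.tse_band,
                min_snapshots=config.tse_min_snapshots,
                min_weight=config.tse_min_weight,
            )
        tse.nodes.to_csv(out / "tse.tsv", sep="\t", index=False, float_format="%.10g")
        summary["n_tse_nodes"] = len(tse.nodes)
        summary["tse_mean_com_A"] = tse.mean_com

    # LIE (optional)
    if {"e_elec", "e_vdw"} <= set(frames.columns):
        with _stage("lie"):
            est = lie_estimate(
                frames,
                alpha=config.lie_alpha,
                beta=config.lie_beta,
                bound_cut=config.unbind_cut,
                n_blocks=config.lie_blocks,
            )
            write_estimate_tsv(est, out / "lie.tsv")
            summary["lie_total_kcal_mol"] = est.total

    manifest["summary"] = summary
    with open(out / "provenance.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=float)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
    return summary
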