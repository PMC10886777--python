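"""End-to-end orchestration: descriptors -> fingerprint -> trajectory
statistics -> clustering, from one config, with a self-describing
manifest.

A config names one or two trajectories (two enables the side-by-side
contact-frequency comparison of two ligands against their targets),
the ligand residue name(s), the ligand annotation file(s), optional
criteria overrides and an optional species-energy table for the
reactivity descriptors.  Every output file is listed in
``manifest.json`` with its SHA-256 checksum; the active thresholds are
echoed there too, so a result directory is reproducible and
self-describing.  The manifest contains no timestamps: identical
config + seed gives byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import clustering as _clustering
from . import interactions as _inter
from . import traj_stats as _stats
from .pharmacophore import build_model
from .reactivity import descriptor_table, read_energy_table
from .structure_io import (
    DEFAULT_WATER_RESNAMES,
    read_ligand_annotation,
    read_multimodel_pdb,
    write_pdb,
)

__all__ = ["AnalysisConfig", "TrajectoryInput", "run", "load_config"]

log = logging.getLogger("pocketfp")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class TrajectoryInput:
    path: str
    annotation: str
    ligand_resname: str = "LIG"
    label: str = ""

    def __post_init__(self) -> None:
        if not self.label:
            self.label = Path(self.path).stem


@dataclass
class AnalysisConfig:
    trajectories: list[TrajectoryInput]
    output_dir: str = "pocketfp_out"
    criteria: dict = field(default_factory=dict)    # InteractionCriteria overrides
    stride: int = 10
    cluster_cutoff: float = 2.0
    dt_ns: float = 0.02
    descriptor_table: Optional[str] = None
    descriptors_from_orbitals: bool = False
    water_resnames: list[str] = field(
        default_factory=lambda: sorted(DEFAULT_WATER_RESNAMES)
    )
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if not self.trajectories:
            raise ValueError("config names no trajectories")
        for t in self.trajectories:
            for p in (t.path, t.annotation):
                if not Path(p).is_file():
                    raise FileNotFoundError(f"input file not found: {p}")
        if self.descriptor_table and not Path(self.descriptor_table).is_file():
            raise FileNotFoundError(
                f"descriptor table not found: {self.descriptor_table}"
            )
        _inter.InteractionCriteria(**self.criteria)  # raises on bad overrides


def load_config(path) -> AnalysisConfig:
    """Read a YAML or JSON config file."""
    raw = yaml.safe_load(Path(path).read_text())
    trajs = [TrajectoryInput(**t) for t in raw.pop("trajectories", [])]
    return AnalysisConfig(trajectories=trajs, **raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _analyze_one(
    tin: TrajectoryInput,
    cfg: AnalysisConfig,
    criteria: _inter.InteractionCriteria,
    outdir: Path,
) -> dict:
    label = tin.label
    t0 = time.perf_counter()
    traj = read_multimodel_pdb(
        tin.path, ligand_resnames={tin.ligand_resname},
        water_resnames=cfg.water_resnames, dt_ns=cfg.dt_ns,
    )
    annotation = read_ligand_annotation(tin.annotation)
    model = build_model(traj.topology, annotation)
    log.info("[%s] read %d frames, %d atoms (%.2fs)", label, traj.n_frames,
             traj.n_atoms, time.perf_counter() - t0)

    out: dict[str, str] = {}

    def _register(name: str, path: Path):
        out[name] = str(path)

    # fingerprint
    t0 = time.perf_counter()
    events = _inter.detect_trajectory(traj.frames, model, criteria)
    freq = _inter.aggregate(events, traj.n_frames)
    p = outdir / f"{label}_contact_frequencies.csv"
    freq.to_csv(p)
    _register("contact_frequencies", p)
    p = outdir / f"{label}_events.jsonl"
    with open(p, "w") as fh:
        for e in events:
            fh.write(json.dumps({
                "frame": e.frame, "kind": e.kind,
                "residue": list(e.residue),
                "ligand_site": list(e.ligand_site),
                "partner_site": list(e.partner_site),
                "water": list(e.water) if e.water else None,
            }) + "\n")
    _register("events", p)

    keys = sorted({(e.residue, e.kind) for e in events})
    tl_rows = []
    for key in keys:
        tl = _inter.timeline(events, key, traj.n_frames)
        tl_rows.append({
            "chain": key[0][0], "resseq": key[0][1], "resname": key[0][2],
            "kind": key[1], "longest_run": tl.longest_run,
            "frames_present": int((tl.counts > 0).sum()),
        })
    p = outdir / f"{label}_timelines.csv"
    pd.DataFrame(
        tl_rows, columns=["chain", "resseq", "resname", "kind",
                          "longest_run", "frames_present"],
    ).to_csv(p, index=False)
    _register("timelines", p)
    log.info("[%s] fingerprint: %d events, %d contact keys (%.2fs)",
             label, len(events), len(keys), time.perf_counter() - t0)

    # RMSD / RMSF
    t0 = time.perf_counter()
    ca = traj.topology.calpha_indices
    lig_heavy = traj.topology.indices_where(
        lambda a: a.is_ligand and a.element.upper() not in ("H", "D")
    )
    align = ca if ca.size else traj.topology.protein_indices
    series = {}
    if align.size >= 3:
        series["protein"] = _stats.rmsd_series(traj, align, align)
        if lig_heavy.size:
            series["ligand"] = _stats.rmsd_series(traj, lig_heavy, align)
    rows = {"frame": np.arange(traj.n_frames),
            "time_ns": traj.times_ns()}
    rows.update({f"rmsd_{k}": s.values for k, s in series.items()})
    p = outdir / f"{label}_rmsd.csv"
    pd.DataFrame(rows).to_csv(p, index=False)
    _register("rmsd", p)

    if traj.n_frames >= 2 and ca.size >= 3:
        prof = _stats.rmsf_profile(traj, ca)
        p = outdir / f"{label}_rmsf.csv"
        pd.DataFrame(
            [{"chain": c, "resseq": r, "rmsf": v}
             for (c, r), v in sorted(prof.per_residue.items())]
        ).to_csv(p, index=False)
        _register("rmsf", p)
    log.info("[%s] rmsd/rmsf done (%.2fs)", label, time.perf_counter() - t0)

    # clustering + representative complex
    if traj.n_frames > cfg.stride and lig_heavy.size:
        t0 = time.perf_counter()
        cres = _clustering.cluster_ligand_poses(
            traj, stride=cfg.stride, cutoff=cfg.cluster_cutoff,
            ligand_selection=lig_heavy,
            alignment_selection=align if align.size >= 3 else None,
        )
        p = outdir / f"{label}_clusters.csv"
        pd.DataFrame({
            "frame": cres.frame_indices_analyzed, "cluster": cres.labels,
        }).to_csv(p, index=False)
        _register("clusters", p)
        p = outdir / f"{label}_representative.pdb"
        write_pdb(traj, p, [cres.representative_frame])
        _register("representative", p)
        log.info("[%s] clustering: %d clusters, representative frame %d (%.2fs)",
                 label, cres.n_clusters, cres.representative_frame,
                 time.perf_counter() - t0)
    return {"label": label, "outputs": out, "n_frames": traj.n_frames,
            "frequency_table": freq}


def run(config: AnalysisConfig) -> dict:
    """Run the full analysis; returns the manifest dict (also written
    to ``<output_dir>/manifest.json``)."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    try:
        config.validate()
    except Exception as e:
        raise StageError(f"config validation: {e}") from e

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    criteria = _inter.InteractionCriteria(**config.criteria)

    results = []
    for tin in config.trajectories:
        try:
            results.append(_analyze_one(tin, config, criteria, outdir))
        except Exception as e:
            raise StageError(f"trajectory analysis [{tin.label}]: {e}") from e

    outputs: dict[str, dict[str, str]] = {
        r["label"]: r["outputs"] for r in results
    }

    if config.descriptor_table:
        try:
            df = read_energy_table(config.descriptor_table)
            dt = descriptor_table(df, from_orbitals=config.descriptors_from_orbitals)
            p = outdir / "reactivity_descriptors.csv"
            dt.to_csv(p, index=False)
            outputs.setdefault("_shared", {})["descriptors"] = str(p)
        except Exception as e:
            raise StageError(f"reactivity descriptors: {e}") from e

    if len(results) == 2:
        a, b = results
        ta = a["frequency_table"].table.set_index(
            ["chain", "resseq", "resname", "kind"])["value"]
        tb = b["frequency_table"].table.set_index(
            ["chain", "resseq", "resname", "kind"])["value"]
        cmp_df = pd.DataFrame({a["label"]: ta, b["label"]: tb}).fillna(0.0)
        cmp_df["difference"] = cmp_df[a["label"]] - cmp_df[b["label"]]
        p = outdir / "comparison.csv"
        cmp_df.reset_index().to_csv(p, index=False)
        outputs.setdefault("_shared", {})["comparison"] = str(p)

    manifest = {
        "seed": config.seed,
        "criteria": dataclasses.asdict(criteria),
        "stride": config.stride,
        "cluster_cutoff": config.cluster_cutoff,
        "dt_ns": config.dt_ns,
        "files": {
            f"{label}/{name}": {
                "path": path, "sha256": _sha256(Path(path)),
            }
            for label, files in outputs.items()
            for name, path in files.items()
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
    return manifest
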