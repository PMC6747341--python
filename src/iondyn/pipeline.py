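"""End-to-end orchestration: one config, all stages, one report bundle.

Stage order mirrors the analysis workflow: equilibration detection from the
configurational-entropy plateau, geometry observables, dihedral PCA /
free-energy landscape / conformational families, covariance / DCCM /
Cartesian PCA, ion hydration, and the interaction-energy / interaction-
entropy / outlier-residue stage.  Every output file carries the config hash
and seed, so a rerun with the archived config reproduces it byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import conformation, dynamics, energetics, geometry, solvation
from .constants import T_DEFAULT
from .model_io import (DomainConfig, MolecularSystem, Trajectory,
                       load_system, load_trajectory, select)

log = logging.getLogger("iondyn.pipeline")


@dataclass
class RunConfig:
    """Inputs, stage toggles and per-stage parameters for a full run."""

    structure: str | None = None
    trajectory: str | None = None
    parameter_table: str | None = None
    domain_config: str | None = None
    outdir: str = "iondyn_out"
    seed: int = 0
    temperature: float = T_DEFAULT
    equilibration_ns: float | None = None     # None -> entropy-plateau heuristic
    stages: dict = field(default_factory=lambda: {
        "geometry": True, "conformation": True, "dynamics": True,
        "solvation": True, "energetics": True,
    })
    params: dict = field(default_factory=lambda: {
        "fel_grid": 100, "k_families": 10, "k_populations": 5,
        "n_init": 50, "n_boot": 5000, "rdf_bin": 0.002,
        "protein_selection": "name CA",
        "geometry_cutoff": 0.35,
    })

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        import yaml
        data = yaml.safe_load(Path(path).read_text())
        cfg = cls()
        for key, val in data.items():
            if key in ("stages", "params"):
                getattr(cfg, key).update(val)
            elif hasattr(cfg, key):
                setattr(cfg, key, val)
            else:
                raise ValueError(f"unknown config key {key!r}")
        return cfg


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _write_tsv(path: Path, header: str, columns: dict, provenance: str) -> None:
    arrays = {k: np.asarray(v) for k, v in columns.items()}
    n = len(next(iter(arrays.values())))
    with open(path, "w") as fh:
        fh.write(f"# {provenance}\n# {header}\n")
        fh.write("\t".join(arrays.keys()) + "\n")
        for i in range(n):
            fh.write("\t".join(f"{arrays[k][i]:.6g}" if np.isreal(arrays[k][i])
                               else str(arrays[k][i]) for k in arrays) + "\n")


def run_all(
    config: RunConfig,
    system: MolecularSystem | None = None,
    traj: Trajectory | None = None,
) -> dict:
    """Execute every enabled stage; returns the structured report (also
    written as ``report.json``).  A stage failure aborts with the stage name.

    ``system``/``traj`` may be passed directly (e.g. from the synthetic
    generators) instead of file paths in the config.
    """
    if system is None:
        if config.structure is None:
            raise ValueError("no structure given")
        system, struct_traj = load_system(config.structure,
                                          config.parameter_table,
                                          config.domain_config)
        traj = (load_trajectory(config.trajectory, system)
                if config.trajectory else struct_traj)
    if traj is None:
        raise ValueError("no trajectory given")

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prov = f"iondyn config={config.config_hash()} seed={config.seed}"
    report: dict = {"config_hash": config.config_hash(), "seed": config.seed,
                    "stages": {}}

    p = config.params
    ca = select(system, p.get("protein_selection", "name CA"))
    if ca.size == 0:
        ca = np.arange(system.n_atoms)

    # --- equilibration window ------------------------------------------------
    t0 = time.time()
    try:
        cutoff = config.equilibration_ns
        if cutoff is None and traj.n_frames >= 20:
            ends = np.linspace(traj.times[0], traj.times[-1], 11)[1:]
            w_ends, entropies = conformation.configurational_entropy_series(
                traj, ca, system.masses[ca], ends, config.temperature)
            cutoff = conformation.detect_equilibration(w_ends, entropies)
            report["stages"]["entropy"] = {
                "window_ends_ns": w_ends.tolist(),
                "entropy_kj_mol_K": entropies.tolist(),
                "equilibration_ns": cutoff,
            }
        if cutoff is None:
            cutoff = 0.0
        analysis = traj.after(cutoff)
        if analysis.n_frames < 2:
            analysis = traj
        report["equilibration_ns"] = float(cutoff)
    except Exception as exc:  # noqa: BLE001
        raise StageError("equilibration", exc) from exc
    log.info("equilibration window: t >= %.3g ns (%.2fs)", cutoff, time.time() - t0)

    # --- geometry ------------------------------------------------------------
    if config.stages.get("geometry", True):
        t0 = time.time()
        try:
            rg = geometry.radius_of_gyration(analysis, ca, system.masses[ca])
            rmsd = geometry.rmsd_series(analysis, ca)
            resids, rmsf = geometry.rmsf_per_residue(analysis, system, ca)
            _write_tsv(outdir / "geometry_rg.tsv", "time_ns rg_nm",
                       {"time_ns": rg.times, "rg_nm": rg.values}, prov)
            _write_tsv(outdir / "geometry_rmsd.tsv", "time_ns rmsd_nm",
                       {"time_ns": rmsd.times, "rmsd_nm": rmsd.values}, prov)
            _write_tsv(outdir / "geometry_rmsf.tsv", "resid rmsf_nm",
                       {"resid": resids, "rmsf_nm": rmsf}, prov)
            stage = {"rg_mean_nm": rg.mean, "rg_sd_nm": rg.std,
                     "rmsd_mean_nm": rmsd.mean, "rmsd_sd_nm": rmsd.std}
            if analysis.box is not None:
                mind = geometry.min_periodic_distance(analysis, ca)
                stage["min_periodic_mean_nm"] = mind.mean
            report["stages"]["geometry"] = stage
        except Exception as exc:  # noqa: BLE001
            raise StageError("geometry", exc) from exc
        log.info("geometry done (%.2fs)", time.time() - t0)

    # --- conformation --------------------------------------------------------
    if config.stages.get("conformation", True):
        t0 = time.time()
        try:
            dih = conformation.extract_dihedrals(analysis, system)
            if dih.angles.shape[1] >= 2 and analysis.n_frames >= 4:
                pcm = conformation.dpca(dih)
                fel = conformation.free_energy_landscape(
                    pcm, grid=int(p.get("fel_grid", 100)),
                    temperature=config.temperature)
                k = min(int(p.get("k_families", 10)), analysis.n_frames)
                cm = conformation.kmeans_cluster(
                    pcm.projections[:, :2], k,
                    n_init=int(p.get("n_init", 50)), seed=config.seed)
                reps = conformation.extract_centroids(cm, fel, pcm)
                paths = conformation.write_centroids(reps, analysis, system,
                                                     outdir / "centroids")
                _write_tsv(outdir / "dpca_projections.tsv", "time_ns dpc1 dpc2",
                           {"time_ns": analysis.times,
                            "dpc1": pcm.projections[:, 0],
                            "dpc2": pcm.projections[:, 1]}, prov)
                report["stages"]["conformation"] = {
                    "n_dihedrals": dih.angles.shape[1],
                    "variance_fractions_first5":
                        pcm.variance_fractions[:5].tolist(),
                    "k": cm.k, "sse": cm.sse, "s_avg": cm.s_avg,
                    "n_centroids": len(paths),
                }
        except Exception as exc:  # noqa: BLE001
            raise StageError("conformation", exc) from exc
        log.info("conformation done (%.2fs)", time.time() - t0)

    # --- dynamics ------------------------------------------------------------
    if config.stages.get("dynamics", True):
        t0 = time.time()
        try:
            cov = dynamics.covariance_matrix(analysis, ca)
            if np.trace(cov) > 0:
                dm = dynamics.dccm(cov, resids=system.resids[ca])
                cpc = dynamics.cartesian_pca(cov, analysis, ca)
                np.savetxt(outdir / "dccm.tsv", dm.matrix, fmt="%.4f",
                           delimiter="\t", header=prov)
                report["stages"]["dynamics"] = {
                    "first5_variance_fraction_internal":
                        cpc.cumulative_fraction(5, internal=True),
                    "first5_variance_fraction_total":
                        cpc.cumulative_fraction(5, internal=False),
                }
        except Exception as exc:  # noqa: BLE001
            raise StageError("dynamics", exc) from exc
        log.info("dynamics done (%.2fs)", time.time() - t0)

    # --- solvation -----------------------------------------------------------
    ions = select(system, "domain ion")
    solvent_o = select(system, "domain solvent and element O")
    if config.stages.get("solvation", True) and ions.size and solvent_o.size \
            and analysis.box is not None:
        t0 = time.time()
        try:
            summaries = []
            for i in ions:
                s = solvation.solvation_summary(analysis, system, int(i),
                                                solvent_o,
                                                bin_width=float(p.get("rdf_bin", 0.002)))
                summaries.append(asdict(s))
            report["stages"]["solvation"] = summaries
        except Exception as exc:  # noqa: BLE001
            raise StageError("solvation", exc) from exc
        log.info("solvation done (%.2fs)", time.time() - t0)

    # --- energetics ----------------------------------------------------------
    prot = np.flatnonzero(~np.isin(system.domains, ["ion", "solvent"]))
    if config.stages.get("energetics", True) and ions.size and prot.size:
        t0 = time.time()
        try:
            groups = {f"{system.names[i]}_{system.resids[i]}": np.array([i])
                      for i in ions}
            rep = energetics.binding_report(
                analysis, system, groups, prot,
                temperature=config.temperature,
                n_boot=int(p.get("n_boot", 5000)), seed=config.seed)
            rep.table.to_csv(outdir / "binding_report.tsv", sep="\t")
            series = energetics.interaction_energy(analysis, system, ions, prot)
            sig = energetics.significant_residues(series) \
                if series.residue_ids is not None and series.residue_ids.size >= 4 \
                else None
            if sig is not None:
                sig.to_csv(outdir / "residue_contributions.tsv", sep="\t",
                           index=False)
            geo = energetics.assign_geometry(
                analysis.coords[-1], int(ions[0]), system,
                cutoff=float(p.get("geometry_cutoff", 0.35)))
            report["stages"]["energetics"] = {
                "ions": list(groups.keys()),
                "dG_binding": {k: float(rep.table.loc[k, "dG_binding"])
                               for k in rep.table.index},
                "minus_TdS": {k: float(rep.table.loc[k, "minus_TdS"])
                              for k in rep.table.index},
                "n_significant_residues":
                    int(sig["significant"].sum()) if sig is not None else 0,
                "last_frame_geometry": geo.label,
            }
        except Exception as exc:  # noqa: BLE001
            raise StageError("energetics", exc) from exc
        log.info("energetics done (%.2fs)", time.time() - t0)

    (outdir / "report.json").write_text(json.dumps(report, indent=1,
                                                   default=float))
    return report
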