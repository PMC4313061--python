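"""Full study orchestration: build the toy trimer, run the five
steering protocols, analyse every trajectory, and emit a comparison
report.

Protocol names follow the steering-selection design: ``freeDyn`` (no
steering), ``tmDom`` (all transmembrane groups), ``freeMon`` (the two
neighbouring monomers of the unsteered one), ``freePP`` (tmDom +
freeMon), ``fullTMD`` (every bead). Monomer B is the unsteered
"occupied" monomer in freeMon/freePP.
"""

from __future__ import annotations

import logging
import tomllib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import correlation as corr
from . import geometry as geom
from .model_io import (StructureModel, SubdomainPartition, Trajectory,
                       ValidationError, read_partition, write_partition,
                       write_structure, write_trajectory)
from .steering import ENMParameters, SteeringProtocol, build_enm, run_dynamics
from .synthetic import (PlantedMotion, TrimerSpec, build_trimer,
                        make_target_conformation)

logger = logging.getLogger(__name__)

__all__ = [
    "PROTOCOLS",
    "RunConfig",
    "protocol_selection",
    "run_study",
    "compare_protocols",
    "load_config",
    "default_config",
]

PROTOCOLS = ("freeDyn", "tmDom", "freeMon", "freePP", "fullTMD")

#: the monomer left unsteered by freeMon/freePP
UNSTEERED_MONOMER = 1


def protocol_selection(name: str, model: StructureModel,
                       partition: SubdomainPartition) -> np.ndarray:
    """Bead indices steered by a named protocol."""
    monomers = model.monomers
    if name == "freeDyn":
        return np.empty(0, dtype=int)
    if name == "fullTMD":
        return np.arange(model.n_atoms)
    if name == "tmDom":
        idx = [partition.indices(model, g) for g in partition.names if g.endswith("/TM")]
        return np.unique(np.concatenate(idx))
    if name == "freeMon":
        neighbours = [m for k, m in enumerate(monomers) if k != UNSTEERED_MONOMER]
        idx = [model.indices_for(m) for m in neighbours]
        return np.unique(np.concatenate(idx))
    if name == "freePP":
        return np.unique(np.concatenate([
            protocol_selection("tmDom", model, partition),
            protocol_selection("freeMon", model, partition),
        ]))
    raise ValidationError(f"unknown protocol {name!r}")


@dataclass(frozen=True)
class RunConfig:
    """Everything one study needs; no hidden defaults outside this."""

    trimer: TrimerSpec = field(default_factory=TrimerSpec)
    motion: PlantedMotion = field(default_factory=PlantedMotion)
    enm: ENMParameters = field(default_factory=ENMParameters)
    protocols: tuple[str, ...] = PROTOCOLS
    durations: dict = field(default_factory=dict)  # protocol -> n_steps override
    k_tmd: float = 3.0
    fit_mode: str = "selection"
    rmsf_threshold: float = 1.5
    corr_threshold: float = 0.5
    knn_k: int = 6
    window: int = 20
    correlation_groups: tuple[str, ...] = ()  # empty -> unsteered monomer's porter
    correlation_max_frames: int = 400
    analysis_seed: int = 0

    def __post_init__(self) -> None:
        for p in self.protocols:
            if p not in PROTOCOLS:
                raise ValidationError(f"unknown protocol {p!r}")

    def validate_selections(self, model: StructureModel,
                            partition: SubdomainPartition) -> None:
        """Set-algebra invariants of the protocol design."""
        sets = {p: set(protocol_selection(p, model, partition).tolist())
                for p in PROTOCOLS}
        if sets["freePP"] != sets["tmDom"] | sets["freeMon"]:
            raise ValidationError("freePP selection != tmDom union freeMon")
        for p in PROTOCOLS:
            if not sets[p] <= sets["fullTMD"]:
                raise ValidationError(f"fullTMD selection does not contain {p}")


def _series_table(traj: Trajectory, model: StructureModel,
                  partition: SubdomainPartition, target: StructureModel,
                  groups: list[str]) -> pd.DataFrame:
    """Per-frame, per-subdomain: RMSD to target, CoM displacement, angles.

    The RMSD-to-target fit uses the porter/docking beads: the membrane
    rods hang below the plane on a flexible neck and their slow wobble
    would otherwise leak into every subdomain series through the fit.
    """
    fit_sel = np.unique(np.concatenate(
        [partition.indices(model, g) for g in partition.names
         if not g.endswith("/TM")]))
    rmsd_series = geom.subdomain_rmsd_series(traj, model, partition, target,
                                            fit_selection=fit_sel,
                                            groups=groups)
    orient = geom.orientation_angles(traj, model, partition, groups=groups)
    rows = []
    for g in groups:
        vec = orient.com_vectors[g]
        for f in range(traj.n_frames):
            rows.append((f, g, rmsd_series[g][f], vec[f, 0], vec[f, 1], vec[f, 2],
                         orient.com_magnitude[g][f], orient.phi[g][f],
                         orient.theta[g][f]))
    return pd.DataFrame(rows, columns=["frame", "subdomain", "rmsd", "com_dx",
                                       "com_dy", "com_dz", "com_mag", "phi",
                                       "theta"])


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def run_study(config: RunConfig, outdir) -> Path:
    """Run the configured protocols and all analyses into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        model, partition = build_trimer(config.trimer)
        config.validate_selections(model, partition)
        target = make_target_conformation(model, config.motion, partition)
        write_structure(model, outdir / "start.pdb")
        write_structure(target, outdir / "target.pdb")
        write_partition(partition, outdir / "partition.cfg")

        disp, rods = geom.porcupine_vectors(model, target, partition)
        porc = pd.DataFrame({
            "bead": model.atom_index,
            "dx": disp[:, 0], "dy": disp[:, 1], "dz": disp[:, 2],
        })
        _write_tsv(porc, outdir / "porcupine.tsv")

        network = build_enm(model, config.enm)
        groups = list(partition.names)

        for proto in config.protocols:
            stage = f"protocol {proto}"
            pdir = outdir / proto
            pdir.mkdir(exist_ok=True)
            sel = protocol_selection(proto, model, partition)
            params = config.enm
            if proto in config.durations:
                params = replace(params, n_steps=int(config.durations[proto]))
            protocol = SteeringProtocol(
                target=target, steered_selection=sel,
                k_tmd=config.k_tmd if proto != "freeDyn" else 0.0,
                fit_mode=config.fit_mode, name=proto)
            traj, log = run_dynamics(model, params, protocol, network=network)
            write_trajectory(traj, model, pdir / "traj.pdb")
            if protocol.active:
                _write_tsv(log, pdir / "steering_log.tsv")
            stage = f"analysis {proto}"
            _write_tsv(_series_table(traj, model, partition, target, groups),
                       pdir / "series.tsv")

            if proto == "freeDyn":
                _correlation_outputs(config, model, partition, traj, pdir)

        stage = "comparison"
        summary = compare_protocols(outdir, protocols=config.protocols,
                                    window=config.window)
        _write_tsv(summary, outdir / "summary.tsv")
    except Exception as exc:
        raise RuntimeError(f"study failed at stage '{stage}': {exc}") from exc
    return outdir


def _correlation_outputs(config: RunConfig, model: StructureModel,
                         partition: SubdomainPartition, traj: Trajectory,
                         pdir: Path) -> None:
    groups = list(config.correlation_groups)
    if not groups:
        mon = model.monomers[UNSTEERED_MONOMER]
        groups = [f"{mon}/{s}" for s in ("PN1", "PN2", "PC1", "PC2")]
    sel = np.unique(np.concatenate([partition.indices(model, g) for g in groups]))
    coords = traj.coords
    if traj.n_frames > config.correlation_max_frames:
        stride = int(np.ceil(traj.n_frames / config.correlation_max_frames))
        coords = coords[::stride]
    sub = Trajectory(coords, dt=traj.dt, seed=traj.seed)

    pres = corr.pearson_matrix(sub, sel, rmsf_threshold=config.rmsf_threshold,
                               corr_threshold=config.corr_threshold)
    gres = corr.generalized_matrix(sub, sel, knn_k=config.knn_k,
                                   seed=config.analysis_seed,
                                   rmsf_threshold=config.rmsf_threshold,
                                   corr_threshold=config.corr_threshold)
    for res, tag in ((pres, "pearson"), (gres, "generalized")):
        dense = pd.DataFrame(res.matrix)
        dense.to_csv(pdir / f"{tag}_matrix.tsv", sep="\t", index=False,
                     header=False, float_format="%.6f")
        pairs = corr.apply_filters(res)
        _write_tsv(pairs, pdir / f"{tag}_pairs.tsv")
        summary = corr.block_summary(res, model, partition)
        _write_tsv(summary, pdir / f"{tag}_blocks.tsv")
        corr.map_to_structure(res, model, pdir / f"{tag}_annotated.pdb",
                              mode="count", pairs=pairs)
    rmsf = pd.DataFrame({"bead": sel, "rmsf": pres.rmsf})
    _write_tsv(rmsf, pdir / "rmsf.tsv")


def compare_protocols(report_dir, protocols=PROTOCOLS, window: int = 20) -> pd.DataFrame:
    """One row per protocol x subdomain: 20-frame-smoothed endpoint of the
    RMSD-to-target series plus net orientation change and CoM magnitude."""
    report_dir = Path(report_dir)
    rows = []
    for proto in protocols:
        path = report_dir / proto / "series.tsv"
        if not path.exists():
            raise FileNotFoundError(f"missing stage output for protocol {proto}: {path}")
        df = pd.read_csv(path, sep="\t")
        for g, sub in df.groupby("subdomain", sort=False):
            sub = sub.sort_values("frame")
            w = min(window, len(sub))
            final_rmsd = float(geom.running_average(sub["rmsd"].to_numpy(), w)[-1])
            phi = sub["phi"].to_numpy()
            phi_ok = phi[~np.isnan(phi)]
            dphi = float(geom.running_average(phi_ok, min(w, len(phi_ok)))[-1]) if len(phi_ok) else np.nan
            dtheta = float(geom.running_average(sub["theta"].to_numpy(), w)[-1])
            com = float(geom.running_average(sub["com_mag"].to_numpy(), w)[-1])
            rows.append((proto, g, final_rmsd, dphi, dtheta, com))
    return pd.DataFrame(rows, columns=["protocol", "subdomain", "final_rmsd",
                                       "delta_phi", "delta_theta", "com_mag"])


# --------------------------------------------------------------------------
# TOML config
# --------------------------------------------------------------------------


def default_config() -> RunConfig:
    """The default planted-motion toy study.

    Each monomer rotates about the membrane normal through the trimer
    axis: A by 40 degrees, C held, and B planted at the mechanical drag
    equilibrium (37.9 degrees) that steered neighbours impose through
    the (inequivalent) soft interfaces — so cooperative transmission
    through the network points toward B's own target, the effect the
    partial-steering comparison is designed to expose. Monomer-rigid
    rotations keep the intra-monomer network strain-free. Runs cold so
    thermal wander stays well below the planted amplitudes.
    """
    return RunConfig(
        trimer=TrimerSpec(seed=11),
        motion=PlantedMotion(rotations={
            "A": ((0.0, 0.0, 1.0), 40.0, "origin"),
            "B": ((0.0, 0.0, 1.0), 37.9, "origin"),
            "C": ((0.0, 0.0, 1.0), 0.0, "origin"),
        }, seed=11),
        enm=ENMParameters(cutoff=12.0, spring=0.5, inter_spring=0.003,
                          interface_springs={"AB": 0.009, "BC": 0.0015,
                                             "AC": 0.003},
                          temperature=20.0, friction=2.0, timestep=0.1,
                          n_steps=80000, stride=100,
                          equilibration_steps=100000, seed=11),
        # the unbiased control runs long so its stationarity is well
        # sampled; steered runs only need to cover the schedule
        durations={"freeDyn": 300000},
    )


def tracking_benchmark_config() -> RunConfig:
    """Schedule-tracking benchmark: the default planted motion with the
    soft interfaces turned nearly off, so the target is elastically
    almost free and the steering spring (3 kcal/(mol A^2) per atom) can
    follow its linear RMSD schedule; the finite spring still leaves a
    small nonzero final RMSD."""
    base = default_config()
    return replace(
        base,
        protocols=("fullTMD",),
        motion=PlantedMotion(rotations={
            "A": ((0.0, 0.0, 1.0), 50.0, "origin"),
            "B": ((0.0, 0.0, 1.0), 25.0, "origin"),
            "C": ((0.0, 0.0, 1.0), 0.0, "origin"),
        }, translations={"A": (0.0, 0.0, 3.0), "B": (0.0, 0.0, -3.0)},
            seed=11),
        enm=replace(base.enm, inter_spring=1e-4, interface_springs=None,
                    temperature=5.0, n_steps=60000, equilibration_steps=2000),
        durations={},
    )


def load_config(path) -> RunConfig:
    """Build a RunConfig from a TOML file; unspecified keys keep the
    package defaults."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    base = default_config()

    trimer = replace(base.trimer, **raw.get("trimer", {}))
    enm = replace(base.enm, **raw.get("enm", {}))

    mraw = raw.get("motion", {})
    rotations = dict(base.motion.rotations)
    translations = dict(base.motion.translations)
    if "rotations" in mraw or "translations" in mraw or "global_angle" in mraw:
        rotations, translations = {}, {}
    if "global_angle" in mraw:
        rotations["*"] = (tuple(mraw.get("global_axis", (0.0, 0.0, 1.0))),
                          float(mraw["global_angle"]))
    for item in mraw.get("rotations", []):
        spec = (tuple(item["axis"]), float(item["angle"]))
        if "center" in item:
            spec = spec + (item["center"],)
        rotations[item["group"]] = spec
    for item in mraw.get("translations", []):
        translations[item["group"]] = tuple(item["vector"])
    motion = replace(base.motion, rotations=rotations, translations=translations,
                     **{k: v for k, v in mraw.items()
                        if k in ("sigma", "rigid_noise", "n_frames", "seed")})

    sraw = raw.get("study", {})
    # the default per-protocol durations only make sense alongside the
    # default step count; an explicit n_steps clears them
    default_durations = {} if "n_steps" in raw.get("enm", {}) else base.durations
    return replace(
        base, trimer=trimer, enm=enm, motion=motion,
        protocols=tuple(sraw.get("protocols", base.protocols)),
        durations=dict(sraw.get("durations", default_durations)),
        k_tmd=float(sraw.get("k_tmd", base.k_tmd)),
        fit_mode=sraw.get("fit_mode", base.fit_mode),
        rmsf_threshold=float(sraw.get("rmsf_threshold", base.rmsf_threshold)),
        corr_threshold=float(sraw.get("corr_threshold", base.corr_threshold)),
        knn_k=int(sraw.get("knn_k", base.knn_k)),
        window=int(sraw.get("window", base.window)),
        correlation_groups=tuple(sraw.get("correlation_groups", ())),
        correlation_max_frames=int(sraw.get("correlation_max_frames",
                                            base.correlation_max_frames)),
        analysis_seed=int(sraw.get("analysis_seed", base.analysis_seed)),
    )
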