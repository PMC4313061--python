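"""Elastic-network toy dynamics with a targeted-steering bias.

The dynamical substrate is an elastic network on the bead model,
integrated with first-order overdamped (Euler-Maruyama) Langevin
dynamics in kcal/mol, Angstrom, ps units. Steering applies the
harmonic RMSD-tracking potential

    U(t) = 1/2 * k_tmd * [RMSD(t) - RMSD*(t)]^2

over a configurable bead selection, where RMSD is measured after
best-fit superposition of the target onto the current frame (fit over
the steered selection by default) and RMSD*(t) decreases linearly from
the initial RMSD to zero. k_tmd is the per-atom force constant
(default 3 kcal/(mol A^2)); beads outside the selection never receive
bias force.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .geometry import kabsch_superpose
from .model_io import StructureModel, Trajectory, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "ENMParameters",
    "SteeringProtocol",
    "ElasticNetwork",
    "build_enm",
    "tmd_rmsd",
    "tmd_force",
    "run_dynamics",
    "SimulationBlowupError",
    "BOLTZMANN_KCAL",
]

#: Boltzmann constant, kcal/(mol K)
BOLTZMANN_KCAL = 0.0019872041


class SimulationBlowupError(RuntimeError):
    """Numerical blow-up (NaN or runaway coordinate) during dynamics."""


@dataclass(frozen=True)
class ENMParameters:
    """Elastic network + integrator parameters (kcal/mol, Angstrom, ps)."""

    cutoff: float = 10.0         # bond cutoff, Angstrom
    spring: float = 1.0          # bond spring constant, kcal/(mol A^2)
    inter_spring: float | None = None  # softer constant for inter-monomer bonds
    # optional per-interface override, e.g. {"AB": 0.05, "BC": 0.01};
    # the asymmetric trimer has inequivalent interfaces
    interface_springs: dict | None = None
    temperature: float = 310.0   # K
    friction: float = 50.0       # ps^-1 (per unit bead mass)
    timestep: float = 0.5        # ps
    n_steps: int = 5000
    stride: int = 10             # record every stride-th step
    equilibration_steps: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValidationError(f"cutoff must be positive, got {self.cutoff}")
        if self.spring < 0:
            raise ValidationError(f"spring must be >= 0, got {self.spring}")
        if self.temperature <= 0:
            raise ValidationError(f"temperature must be positive, got {self.temperature}")
        if self.timestep <= 0:
            raise ValidationError(f"timestep must be positive, got {self.timestep}")
        if self.friction <= 0:
            raise ValidationError(f"friction must be positive, got {self.friction}")
        # Euler-Maruyama stability guard for the stiffest single bond
        if self.spring * self.timestep / self.friction >= 0.1:
            raise ValidationError(
                "unstable integrator settings: require spring*timestep/friction < 0.1"
            )


@dataclass(frozen=True)
class ElasticNetwork:
    """Bond list of an elastic network with per-bond rest lengths and
    spring constants."""

    i: np.ndarray
    j: np.ndarray
    rest: np.ndarray
    spring: np.ndarray  # per bond, kcal/(mol A^2)

    @property
    def n_bonds(self) -> int:
        return len(self.i)

    def forces(self, coords: np.ndarray) -> np.ndarray:
        f = np.zeros_like(coords)
        if self.n_bonds == 0:
            return f
        d = coords[self.i] - coords[self.j]
        lengths = np.linalg.norm(d, axis=1)
        # -k (L - L0) along the bond; lengths > 0 for any sane state
        fb = (-self.spring * (lengths - self.rest) / lengths)[:, None] * d
        np.add.at(f, self.i, fb)
        np.add.at(f, self.j, -fb)
        return f

    def energy(self, coords: np.ndarray) -> float:
        d = np.linalg.norm(coords[self.i] - coords[self.j], axis=1)
        return float(0.5 * np.sum(self.spring * (d - self.rest) ** 2))


def build_enm(model: StructureModel, params: ENMParameters) -> ElasticNetwork:
    """Bond (i, j) iff the reference distance is <= cutoff; rest length =
    reference distance. Bonds across monomers get ``inter_spring`` when
    set (softer interfaces let partial steering deform one monomer
    without fighting the full network). Isolated beads are logged."""
    pairs = cKDTree(model.coords).query_pairs(params.cutoff, output_type="ndarray")
    if len(pairs) == 0:
        i = np.empty(0, dtype=int)
        j = np.empty(0, dtype=int)
        rest = np.empty(0)
    else:
        i, j = pairs[:, 0], pairs[:, 1]
        rest = np.linalg.norm(model.coords[i] - model.coords[j], axis=1)
    spring = np.full(len(i), params.spring)
    inter = model.monomer_id[i] != model.monomer_id[j] if len(i) else np.empty(0, bool)
    if params.inter_spring is not None:
        spring[inter] = params.inter_spring
    if params.interface_springs:
        for idx in np.flatnonzero(inter):
            key = "".join(sorted((str(model.monomer_id[i[idx]]),
                                  str(model.monomer_id[j[idx]]))))
            if key in params.interface_springs:
                spring[idx] = params.interface_springs[key]
    bonded = np.zeros(model.n_atoms, dtype=bool)
    bonded[i] = True
    bonded[j] = True
    n_isolated = int((~bonded).sum())
    if n_isolated:
        logger.warning("%d isolated beads (no ENM bonds within %.1f A cutoff)",
                       n_isolated, params.cutoff)
    return ElasticNetwork(i, j, rest, spring)


@dataclass(frozen=True)
class SteeringProtocol:
    """Which beads are steered, how hard, and toward what."""

    target: StructureModel
    steered_selection: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    k_tmd: float = 3.0  # per-atom force constant, kcal/(mol A^2)
    schedule: Callable[[int], float] | None = None  # step -> target RMSD
    fit_mode: str = "selection"  # "selection" | "all"
    name: str = "custom"

    def __post_init__(self) -> None:
        object.__setattr__(self, "steered_selection",
                           np.asarray(self.steered_selection, dtype=int))
        if self.k_tmd < 0:
            raise ValidationError(f"k_tmd must be >= 0, got {self.k_tmd}")
        if self.fit_mode not in ("selection", "all"):
            raise ValidationError(f"fit_mode must be 'selection' or 'all'")

    @property
    def active(self) -> bool:
        return self.k_tmd > 0 and len(self.steered_selection) > 0


def _fit_target(current: np.ndarray, target: np.ndarray,
                selection: np.ndarray, fit_mode: str) -> np.ndarray:
    """Target coordinates superposed onto the current frame."""
    fit_sel = None if fit_mode == "all" else selection
    rot, trans, _ = kabsch_superpose(target, current, fit_sel)
    return target @ rot.T + trans


def tmd_rmsd(current: np.ndarray, target: StructureModel | np.ndarray,
             selection: np.ndarray, fit_mode: str = "selection") -> float:
    """RMSD over the selection after best-fit superposition of target
    onto current."""
    tcoords = target.coords if isinstance(target, StructureModel) else np.asarray(target)
    selection = np.asarray(selection, int)
    if len(selection) < 3:
        raise ValidationError(
            f"steering selection needs >= 3 beads for superposition, got {len(selection)}"
        )
    fitted = _fit_target(np.asarray(current, float), tcoords, selection, fit_mode)
    dev = current[selection] - fitted[selection]
    return float(np.sqrt(np.mean(np.sum(dev * dev, axis=1))))


def tmd_force(current: np.ndarray, protocol: SteeringProtocol,
              rmsd_star: float) -> tuple[np.ndarray, float, float]:
    """Analytic steering forces for one frame.

    Returns ``(forces, rmsd, bias_energy)``. Because the superposition
    is optimal, holding the fitted target fixed gives the exact
    gradient of U; beads outside the steered selection carry exactly
    zero force.
    """
    current = np.asarray(current, float)
    forces = np.zeros_like(current)
    sel = protocol.steered_selection
    if not protocol.active:
        return forces, np.nan, 0.0
    fitted = _fit_target(current, protocol.target.coords, sel, protocol.fit_mode)
    dev = current[sel] - fitted[sel]
    nsel = len(sel)
    d = float(np.sqrt(np.mean(np.sum(dev * dev, axis=1))))
    energy = 0.5 * protocol.k_tmd * (d - rmsd_star) ** 2
    if d > 1e-12:
        # dU/dx_i = k (D - D*) * dev_i / (N D)
        forces[sel] = -(protocol.k_tmd * (d - rmsd_star) / (nsel * d)) * dev
    return forces, d, float(energy)


def linear_schedule(initial_rmsd: float, n_steps: int) -> Callable[[int], float]:
    """Target RMSD decreasing linearly from the initial value to 0."""
    def schedule(step: int) -> float:
        if n_steps <= 0:
            return 0.0
        return max(initial_rmsd * (1.0 - step / n_steps), 0.0)
    return schedule


def run_dynamics(model: StructureModel, params: ENMParameters,
                 protocol: SteeringProtocol | None = None,
                 network: ElasticNetwork | None = None,
                 ) -> tuple[Trajectory, pd.DataFrame]:
    """Overdamped Langevin dynamics of the ENM plus optional steering.

    Returns the recorded trajectory (every ``stride`` steps, frame 0 =
    state after equilibration) and a log table with per-recorded-step
    RMSD to target, scheduled RMSD*, and bias energy. Deterministic for
    a fixed seed; the noise stream does not depend on the protocol, so a
    zero-bias protocol reproduces the free run exactly.
    """
    net = network if network is not None else build_enm(model, params)
    rng = np.random.default_rng(params.seed)
    dt, gamma = params.timestep, params.friction
    noise_amp = np.sqrt(2.0 * BOLTZMANN_KCAL * params.temperature * dt / gamma)
    x = model.coords.copy()

    for _ in range(params.equilibration_steps):
        x = x + (dt / gamma) * net.forces(x) + noise_amp * rng.normal(size=x.shape)

    active = protocol is not None and protocol.active
    if active:
        d0 = tmd_rmsd(x, protocol.target, protocol.steered_selection, protocol.fit_mode)
        schedule = protocol.schedule or linear_schedule(d0, params.n_steps)

    frames = [x.copy()]
    log_rows = []
    if active:
        _, d, e = tmd_force(x, protocol, schedule(0))
        log_rows.append((0, d, schedule(0), e))
    for step in range(1, params.n_steps + 1):
        f = net.forces(x)
        if active:
            fb, d, e = tmd_force(x, protocol, schedule(step))
            f = f + fb
        x = x + (dt / gamma) * f + noise_amp * rng.normal(size=x.shape)
        if step % params.stride == 0:
            if not np.all(np.isfinite(x)) or np.any(np.abs(x) > 1e6):
                raise SimulationBlowupError(f"numerical blow-up at step {step}")
            frames.append(x.copy())
            if active:
                _, d, e = tmd_force(x, protocol, schedule(step))
                log_rows.append((step, d, schedule(step), e))
    traj = Trajectory(np.asarray(frames), dt=dt * params.stride, seed=params.seed)
    log = pd.DataFrame(log_rows, columns=["step", "rmsd", "rmsd_star", "bias_energy"])
    return traj, log
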