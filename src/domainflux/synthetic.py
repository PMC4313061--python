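"""Synthetic trimeric multi-domain toy systems with planted motion.

Every generator is deterministic under its seed so downstream analyses
can be validated by parameter recovery: rigid-body subdomain rotations
and translations of known magnitude, block-structured linear
correlations of known strength, and phase-coupled pairs that carry high
mutual information but near-zero linear correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_io import StructureModel, SubdomainPartition, Trajectory, ValidationError

__all__ = [
    "TrimerSpec",
    "CorrelationBlock",
    "PlantedMotion",
    "SUBDOMAIN_NAMES",
    "build_trimer",
    "make_target_conformation",
    "generate_rigid_body_trajectory",
    "generate_fluctuation_trajectory",
    "rotation_matrix",
    "plant_orientation_change",
]

#: the seven groups per monomer: one transmembrane, four porter
#: subdomains, two docking subdomains
SUBDOMAIN_NAMES = ("TM", "PN1", "PN2", "PC1", "PC2", "DN", "DC")

# monomer-0 layout: (center, unit-ish axis direction). TM sits below
# z = 0 (membrane), porter in the middle, docking on top. Axes are
# tilted so both their xy-projection and z-component are nonzero,
# keeping Phi and Theta well-defined.
_LAYOUT = {
    "TM": ((13.0, 1.0, -7.0), (0.15, 0.1, 1.0)),
    "PN1": ((9.0, 4.0, 7.0), (0.9, 0.25, 0.45)),
    "PN2": ((14.0, -4.0, 8.0), (0.4, -0.85, 0.5)),
    "PC1": ((10.0, 8.0, 12.0), (-0.5, 0.8, 0.55)),
    "PC2": ((16.0, 3.0, 13.0), (0.85, 0.45, 0.5)),
    "DN": ((7.0, 1.0, 19.0), (0.7, -0.4, 0.7)),
    "DC": ((11.0, -4.0, 20.0), (-0.35, 0.75, 0.7)),
}


def rotation_matrix(axis, angle_deg: float) -> np.ndarray:
    """Proper rotation about ``axis`` by ``angle_deg`` (Rodrigues)."""
    axis = np.asarray(axis, float)
    n = np.linalg.norm(axis)
    if n == 0:
        raise ValidationError("rotation axis must be nonzero")
    x, y, z = axis / n
    t = np.radians(angle_deg)
    c, s = np.cos(t), np.sin(t)
    k = np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])
    return np.eye(3) + s * k + (1.0 - c) * (k @ k)


@dataclass(frozen=True)
class TrimerSpec:
    """Geometry spec for a three-fold symmetric toy trimer."""

    monomers: tuple[str, str, str] = ("A", "B", "C")
    beads_per_subdomain: int = 12
    elongation: float = 3.0  # length/width ratio of each subdomain
    subdomain_length: float = 12.0  # Angstrom along the group axis
    seed: int = 0

    def __post_init__(self) -> None:
        if self.beads_per_subdomain < 10:
            raise ValidationError(
                f"beads_per_subdomain must be >= 10 (got {self.beads_per_subdomain}); "
                "inertia tensor ill-conditioned below that"
            )
        if self.elongation < 2:
            raise ValidationError(
                f"elongation must be >= 2 for principal-axis identifiability "
                f"(got {self.elongation})"
            )
        if len(self.monomers) != 3:
            raise ValidationError("exactly three monomer labels required")


def build_trimer(spec: TrimerSpec) -> tuple[StructureModel, SubdomainPartition]:
    """Build the trimer and its partition.

    Monomer k is monomer 0 rotated by 120k degrees about z (exact, same
    pseudo-random jitter). Partition group names are ``{monomer}/{sub}``,
    e.g. ``"B/PC2"``. Residues are numbered 1.. within each monomer,
    contiguously over the subdomains in :data:`SUBDOMAIN_NAMES` order.
    """
    rng = np.random.default_rng(spec.seed)
    bps = spec.beads_per_subdomain
    width = spec.subdomain_length / (2.0 * spec.elongation)

    mono_coords = np.empty((7 * bps, 3))
    for g, name in enumerate(SUBDOMAIN_NAMES):
        center, axis = _LAYOUT[name]
        axis = np.asarray(axis) / np.linalg.norm(axis)
        t = np.linspace(-0.5, 0.5, bps) * spec.subdomain_length
        # two unit vectors perpendicular to the axis
        ref = np.array([0.0, 0.0, 1.0]) if abs(axis[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
        p1 = np.cross(axis, ref)
        p1 /= np.linalg.norm(p1)
        p2 = np.cross(axis, p1)
        jitter = rng.normal(0.0, width, size=(bps, 2))
        pts = (np.asarray(center)
               + t[:, None] * axis
               + jitter[:, :1] * p1
               + jitter[:, 1:] * p2)
        mono_coords[g * bps:(g + 1) * bps] = pts

    # TM strictly below the membrane plane (z = 0), rest above; shift the
    # whole rod rather than clamping so its shape is preserved
    tm = mono_coords[:bps]
    if tm[:, 2].max() > -1.0:
        tm[:, 2] += -1.0 - tm[:, 2].max()

    n_mono = 7 * bps
    coords = np.empty((3 * n_mono, 3))
    chains = np.empty(3 * n_mono, dtype="U4")
    resseq = np.empty(3 * n_mono, dtype=int)
    for k, label in enumerate(spec.monomers):
        rot = rotation_matrix([0, 0, 1], 120.0 * k)
        coords[k * n_mono:(k + 1) * n_mono] = mono_coords @ rot.T
        chains[k * n_mono:(k + 1) * n_mono] = label
        resseq[k * n_mono:(k + 1) * n_mono] = np.arange(1, n_mono + 1)

    model = StructureModel(np.arange(1, 3 * n_mono + 1), resseq, chains, coords)
    groups = {}
    for label in spec.monomers:
        for g, name in enumerate(SUBDOMAIN_NAMES):
            groups[f"{label}/{name}"] = ((label, g * bps + 1, (g + 1) * bps),)
    partition = SubdomainPartition(groups)
    partition.validate_against(model)
    return model, partition


# --------------------------------------------------------------------------
# planted motion
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CorrelationBlock:
    """Planted linear correlation r between (and within) two bead sets."""

    set_a: tuple[int, ...]  # 0-based bead indices
    set_b: tuple[int, ...]
    r: float
    name: str = "block"

    def __post_init__(self) -> None:
        if not -1.0 <= self.r <= 1.0:
            raise ValidationError(
                f"block {self.name}: correlation {self.r} outside [-1, 1] "
                "(planted covariance not PSD)"
            )


@dataclass(frozen=True)
class PlantedMotion:
    """Exactly known motion parameters for a synthetic trajectory.

    ``rotations`` maps group name -> (axis 3-vector, angle in degrees)
    or (axis, angle, center) with center in {"centroid", "origin"}
    (default centroid). Keys are partition groups or monomer labels;
    the special key ``"*"`` rotates the whole model about the origin
    (z axis = trimer axis). ``translations`` maps group name -> CoM
    translation vector.
    """

    translations: dict = field(default_factory=dict)
    rotations: dict = field(default_factory=dict)
    correlation_blocks: tuple = ()
    nonlinear_pairs: tuple = ()  # ((i, j), ...) 0-based bead indices
    sigma: float = 0.3           # per-axis fluctuation, Angstrom
    rigid_noise: float = 0.05    # noise on rigid-body frames, <= 0.1
    n_frames: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValidationError(f"sigma must be positive, got {self.sigma}")
        if self.rigid_noise > 0.1:
            raise ValidationError("rigid_noise must be <= 0.1 Angstrom")
        blocks = tuple(self.correlation_blocks)
        object.__setattr__(self, "correlation_blocks", blocks)
        claimed: dict[int, str] = {}
        for blk in blocks:
            for i in (*blk.set_a, *blk.set_b):
                if i in claimed:
                    raise ValidationError(
                        f"blocks {claimed[i]} and {blk.name} overlap at bead {i}; "
                        "planted covariance would not be PSD by construction"
                    )
                claimed[i] = blk.name


def plant_orientation_change(model: StructureModel, partition: SubdomainPartition,
                             group: str, phi: float = 0.0, theta: float = 0.0,
                             axis_mode: str = "long") -> np.ndarray:
    """Rotation matrix that changes a group's axis azimuth by ``phi``
    degrees and its polar angle by ``theta`` degrees.

    The tilt (about the in-plane direction perpendicular to the current
    axis azimuth) is applied first, then the azimuthal rotation about z,
    so both planted angles are recovered independently by the
    orientation analysis.
    """
    from .geometry import principal_axis

    sel = partition.indices(model, group)
    axis = principal_axis(model.coords[sel], mode=axis_mode)
    rot = np.eye(3)
    if theta:
        az = np.arctan2(axis[1], axis[0])
        # unit vector perpendicular to the axis azimuth, in the xy plane;
        # rotating about it by +theta increases the polar angle by theta
        perp = np.array([-np.sin(az), np.cos(az), 0.0])
        rot = rotation_matrix(perp, theta) @ rot
    if phi:
        rot = rotation_matrix([0, 0, 1], phi) @ rot
    return rot


def _apply_motion(model: StructureModel, partition: SubdomainPartition | None,
                  motion: PlantedMotion, fraction: float) -> np.ndarray:
    """Coordinates after ``fraction`` of the planted rigid motion."""
    coords = model.coords.copy()
    rot_global = motion.rotations.get("*")
    if rot_global is not None:
        axis, angle = rot_global[0], rot_global[1]
        coords = coords @ rotation_matrix(axis, fraction * angle).T
    groups = set(motion.rotations) | set(motion.translations)
    groups.discard("*")
    for g in sorted(groups):
        # a partition group, or a whole monomer by its label
        if partition is not None and g in partition.groups:
            sel = partition.indices(model, g)
        elif g in model.monomers:
            sel = model.indices_for(g)
        else:
            raise ValidationError(f"motion references unknown group {g!r}")
        if len(sel) == 0:
            raise ValidationError(f"motion references empty group {g!r}")
        if g in motion.rotations:
            spec = motion.rotations[g]
            axis, angle = spec[0], spec[1]
            center = spec[2] if len(spec) > 2 else "centroid"
            r = rotation_matrix(axis, fraction * angle)
            if center == "origin":
                coords[sel] = coords[sel] @ r.T
            elif center == "centroid":
                centroid = coords[sel].mean(axis=0)
                coords[sel] = (coords[sel] - centroid) @ r.T + centroid
            else:
                raise ValidationError(f"unknown rotation center {center!r}")
        if g in motion.translations:
            coords[sel] = coords[sel] + fraction * np.asarray(motion.translations[g], float)
    return coords


def make_target_conformation(model: StructureModel, motion: PlantedMotion,
                             partition: SubdomainPartition | None = None) -> StructureModel:
    """Deterministic steering target: the model after the full planted
    rigid motion (no noise)."""
    return model.with_coords(_apply_motion(model, partition, motion, 1.0))


def generate_rigid_body_trajectory(model: StructureModel,
                                   partition: SubdomainPartition,
                                   motion: PlantedMotion,
                                   dt: float = 1.0) -> Trajectory:
    """Linear interpolation from the start to the planted endpoint.

    Frame f applies fraction f/(n_frames-1) of every planted rotation and
    translation, plus isotropic Gaussian noise of scale ``rigid_noise``.
    Frame 0 is noise-free so displacement-from-frame-0 analyses see the
    exact planted motion.
    """
    rng = np.random.default_rng(motion.seed)
    nf = motion.n_frames
    frames = np.empty((nf, model.n_atoms, 3))
    fractions = np.linspace(0.0, 1.0, nf) if nf > 1 else np.array([1.0])
    for k, s in enumerate(fractions):
        frames[k] = _apply_motion(model, partition, motion, s)
        if k > 0 and motion.rigid_noise > 0:
            frames[k] += rng.normal(0.0, motion.rigid_noise, size=(model.n_atoms, 3))
    return Trajectory(frames, dt=dt, seed=motion.seed)


def generate_fluctuation_trajectory(model: StructureModel,
                                    partition: SubdomainPartition,
                                    motion: PlantedMotion,
                                    dt: float = 1.0) -> Trajectory:
    """Zero-mean Gaussian fluctuations with planted cross-correlations.

    Correlated blocks use a one-factor construction per axis: every bead
    in a block has per-axis displacement sqrt(|r|)*g + sqrt(1-|r|)*e
    (scaled to total variance sigma^2), with the factor sign flipped for
    set_b when r < 0; any pair spanning the block then has correlation r.
    Nonlinear pairs move on a common circle in the xy plane with shared
    uniform phase and independent radius jitter, which yields ~zero
    linear correlation but high mutual information.
    """
    rng = np.random.default_rng(motion.seed)
    nf, n = motion.n_frames, model.n_atoms
    sigma = motion.sigma
    disp = rng.normal(0.0, sigma, size=(nf, n, 3))

    for blk in motion.correlation_blocks:
        idx = np.array([*blk.set_a, *blk.set_b], dtype=int)
        if idx.size and (idx.min() < 0 or idx.max() >= n):
            raise ValidationError(f"block {blk.name}: bead index out of range")
        signs = np.concatenate([np.ones(len(blk.set_a)),
                                np.full(len(blk.set_b), np.sign(blk.r) or 1.0)])
        a = np.sqrt(abs(blk.r))
        b = np.sqrt(1.0 - abs(blk.r))
        for ax in range(3):
            g = rng.normal(0.0, 1.0, size=nf)
            eps = rng.normal(0.0, 1.0, size=(nf, len(idx)))
            disp[:, idx, ax] = sigma * (a * g[:, None] * signs[None, :] + b * eps)

    radius = 3.0 * sigma
    for (i, j) in motion.nonlinear_pairs:
        phase = rng.uniform(0.0, 2.0 * np.pi, size=nf)
        # the partner runs 90 degrees ahead on the same circle, so the
        # same-axis products average to cos(pi/2) = 0 over a uniform phase
        for bead, offset in ((i, 0.0), (j, 0.5 * np.pi)):
            rad = radius * (1.0 + 0.15 * rng.normal(size=nf))
            disp[:, bead, 0] = rad * np.cos(phase + offset)
            disp[:, bead, 1] = rad * np.sin(phase + offset)
            # z keeps its independent Gaussian component

    return Trajectory(model.coords[None, :, :] + disp, dt=dt, seed=motion.seed)
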