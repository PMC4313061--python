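"""Subdomain geometry: superposition, RMSD series, centre-of-mass
displacement, principal-axis orientation angles, and porcupine vectors.

Conventions: the membrane normal is +z; all beads carry equal mass; the
"major" axis of an elongated group defaults to its long geometric axis
(smallest principal moment of inertia). Angles are degrees; Phi is the
signed in-plane (xy) rotation of the axis relative to frame 0 and Theta
the signed change of its polar angle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .model_io import StructureModel, SubdomainPartition, Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "kabsch_superpose",
    "superpose_frames",
    "subdomain_rmsd_series",
    "com_displacement_series",
    "principal_axis",
    "orientation_angles",
    "OrientationSeries",
    "running_average",
    "porcupine_vectors",
    "rmsd",
]

PHI_UNDEFINED = np.nan
_DEGENERATE_TOL = 1e-6


class DegenerateGeometryError(ValueError):
    """Selection is collinear/degenerate for the requested operation."""


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain coordinate RMSD without superposition."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray,
                     selection: np.ndarray | None = None):
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best fits ``reference`` in the
    least-squares sense over ``selection`` (all beads if None). The
    rotation is proper (det = +1).
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if selection is None:
        selection = np.arange(len(mobile))
    selection = np.asarray(selection)
    if len(selection) < 3:
        raise DegenerateGeometryError(
            f"superposition needs >= 3 beads, got {len(selection)}"
        )
    x = mobile[selection]
    y = reference[selection]
    xc = x.mean(axis=0)
    yc = y.mean(axis=0)
    x0 = x - xc
    y0 = y - yc
    # guard against a fully collinear selection (rank < 2 covariance)
    h = x0.T @ y0
    u, s, vt = np.linalg.svd(h)
    if s[1] <= _DEGENERATE_TOL * max(s[0], 1.0):
        raise DegenerateGeometryError("selection is collinear; superposition underdetermined")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    trans = yc - rot @ xc
    fitted = x @ rot.T + trans
    return rot, trans, rmsd(fitted, y)


def superpose_frames(traj_coords: np.ndarray, reference: np.ndarray,
                     fit_selection: np.ndarray | None = None) -> np.ndarray:
    """Superpose every frame onto ``reference`` using ``fit_selection``."""
    out = np.empty_like(traj_coords)
    for k in range(len(traj_coords)):
        rot, trans, _ = kabsch_superpose(traj_coords[k], reference, fit_selection)
        out[k] = traj_coords[k] @ rot.T + trans
    return out


def subdomain_rmsd_series(traj: Trajectory, model: StructureModel,
                          partition: SubdomainPartition,
                          target: StructureModel,
                          fit_selection: np.ndarray | None = None,
                          groups: list[str] | None = None,
                          per_group_fit: bool = False) -> dict[str, np.ndarray]:
    """Per-subdomain RMSD to ``target`` per frame.

    Each frame is superposed onto the target over ``fit_selection``
    (default: all beads), then the per-group RMSD is measured without
    refitting. With ``per_group_fit`` each group is instead superposed
    independently before its RMSD is taken.
    """
    traj.check_congruent(model)
    if target.n_atoms != model.n_atoms:
        raise ValueError("target not congruent with model")
    names = groups if groups is not None else partition.names
    idx = {g: partition.indices(model, g) for g in names}
    out = {g: np.empty(traj.n_frames) for g in names}
    for k in range(traj.n_frames):
        frame = traj.coords[k]
        if not per_group_fit:
            rot, trans, _ = kabsch_superpose(frame, target.coords, fit_selection)
            fitted = frame @ rot.T + trans
            for g in names:
                out[g][k] = rmsd(fitted[idx[g]], target.coords[idx[g]])
        else:
            for g in names:
                _, _, r = kabsch_superpose(frame, target.coords, idx[g])
                out[g][k] = r
    return out


def com_displacement_series(traj: Trajectory, model: StructureModel,
                            partition: SubdomainPartition,
                            groups: list[str] | None = None):
    """Subdomain CoM displacement (vector and magnitude) from frame 0.

    Every frame is globally superposed onto frame 0 over all beads first,
    so whole-body rigid motion does not register as subdomain motion.
    Beads have uniform mass.
    """
    traj.check_congruent(model)
    names = groups if groups is not None else partition.names
    idx = {g: partition.indices(model, g) for g in names}
    ref = traj.coords[0]
    aligned = superpose_frames(traj.coords, ref)
    vectors = {g: np.empty((traj.n_frames, 3)) for g in names}
    for g in names:
        com0 = ref[idx[g]].mean(axis=0)
        vectors[g] = aligned[:, idx[g], :].mean(axis=1) - com0
    magnitudes = {g: np.linalg.norm(v, axis=1) for g, v in vectors.items()}
    return vectors, magnitudes


def principal_axis(coords: np.ndarray, mode: str = "long",
                   previous: np.ndarray | None = None) -> np.ndarray:
    """Unit principal axis of a bead group (uniform masses).

    ``mode='long'`` returns the long geometric axis (eigenvector of the
    SMALLEST moment of inertia); ``mode='major_moment'`` the eigenvector
    of the largest moment. Sign convention: positive dot product with
    ``previous`` if given, else positive z (tie: positive x).
    """
    coords = np.asarray(coords, float)
    if len(coords) < 3:
        raise DegenerateGeometryError("principal axis needs >= 3 beads")
    c = coords - coords.mean(axis=0)
    r2 = np.sum(c * c, axis=1)
    inertia = np.eye(3) * r2.sum() - c.T @ c
    evals, evecs = np.linalg.eigh(inertia)  # ascending
    gaps = np.diff(evals)
    scale = max(abs(evals[-1]), 1.0)
    if mode == "long":
        if gaps[0] < _DEGENERATE_TOL * scale:
            raise DegenerateGeometryError(
                f"degenerate smallest principal moments (gap {gaps[0]:.3g})"
            )
        axis = evecs[:, 0]
    elif mode == "major_moment":
        if gaps[1] < _DEGENERATE_TOL * scale:
            raise DegenerateGeometryError(
                f"degenerate largest principal moments (gap {gaps[1]:.3g})"
            )
        axis = evecs[:, 2]
    else:
        raise ValueError(f"unknown principal-axis mode {mode!r}")
    if previous is not None:
        if np.dot(axis, previous) < 0:
            axis = -axis
    else:
        if axis[2] < -1e-10 or (abs(axis[2]) <= 1e-10 and axis[0] < 0):
            axis = -axis
    return axis


def _wrap_angle(deg: float) -> float:
    """Wrap into (-180, 180]."""
    out = (deg + 180.0) % 360.0 - 180.0
    return 180.0 if out == -180.0 else out


@dataclass
class OrientationSeries:
    """Per-frame, per-subdomain orientation relative to frame 0."""

    groups: list[str]
    com_vectors: dict[str, np.ndarray]      # (F, 3)
    com_magnitude: dict[str, np.ndarray]    # (F,)
    phi: dict[str, np.ndarray]              # degrees, signed, NaN if undefined
    theta: dict[str, np.ndarray]            # degrees, signed
    axes: dict[str, np.ndarray]             # (F, 3) unit axes
    window: int = 20

    def smoothed(self, series: np.ndarray) -> np.ndarray:
        return running_average(series, self.window)


def orientation_angles(traj: Trajectory, model: StructureModel,
                       partition: SubdomainPartition,
                       groups: list[str] | None = None,
                       axis_mode: str = "long",
                       window: int = 20) -> OrientationSeries:
    """Phi/Theta principal-axis angles and CoM displacement per subdomain.

    Phi(t): signed angle from the xy-projection of axis(0) to that of
    axis(t) (positive = counterclockwise viewed from +z). Theta(t):
    polar angle of axis(t) minus polar angle of axis(0). Frames are
    globally superposed onto frame 0 first.
    """
    traj.check_congruent(model)
    names = groups if groups is not None else partition.names
    idx = {g: partition.indices(model, g) for g in names}
    aligned = superpose_frames(traj.coords, traj.coords[0])
    nf = traj.n_frames

    com_vectors, com_magnitude = {}, {}
    phi: dict[str, np.ndarray] = {}
    theta: dict[str, np.ndarray] = {}
    axes: dict[str, np.ndarray] = {}
    for g in names:
        sel = idx[g]
        com0 = aligned[0, sel].mean(axis=0)
        vec = aligned[:, sel, :].mean(axis=1) - com0
        com_vectors[g] = vec
        com_magnitude[g] = np.linalg.norm(vec, axis=1)

        ax = np.empty((nf, 3))
        prev = None
        for k in range(nf):
            ax[k] = principal_axis(aligned[k, sel], mode=axis_mode, previous=prev)
            prev = ax[k]
        axes[g] = ax

        az = np.degrees(np.arctan2(ax[:, 1], ax[:, 0]))
        pol = np.degrees(np.arccos(np.clip(ax[:, 2], -1.0, 1.0)))
        proj = np.hypot(ax[:, 0], ax[:, 1])
        ph = np.array([_wrap_angle(a - az[0]) for a in az])
        undef = proj < 1e-8
        if undef.any():
            logger.warning("group %s: axis parallel to z in %d frames; Phi undefined",
                           g, int(undef.sum()))
            ph[undef] = PHI_UNDEFINED
        if proj[0] < 1e-8:
            ph[:] = PHI_UNDEFINED
        phi[g] = ph
        theta[g] = pol - pol[0]
    return OrientationSeries(names, com_vectors, com_magnitude, phi, theta, axes,
                             window=window)


def running_average(series: np.ndarray, window: int = 20) -> np.ndarray:
    """Trailing mean over ``window`` frames; prefix entries average over
    whatever is available."""
    series = np.asarray(series, float)
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    if window > len(series):
        raise ValueError(f"window {window} exceeds series length {len(series)}")
    csum = np.cumsum(series)
    out = np.empty_like(csum, dtype=float)
    out[:window] = csum[:window] / np.arange(1, window + 1)
    out[window:] = (csum[window:] - csum[:-window]) / window
    return out


def porcupine_vectors(initial: StructureModel, final: StructureModel,
                      partition: SubdomainPartition | None = None,
                      axis_mode: str = "long"):
    """Per-bead displacement vectors final - initial after global
    superposition, plus per-subdomain initial/final principal axes.

    Returns ``(displacements, axis_rods)`` where ``axis_rods`` maps
    group -> (initial_axis, final_axis) unit vectors.
    """
    if initial.n_atoms != final.n_atoms:
        raise ValueError("structures not congruent")
    rot, trans, _ = kabsch_superpose(final.coords, initial.coords)
    fitted = final.coords @ rot.T + trans
    disp = fitted - initial.coords
    rods: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    if partition is not None:
        for g in partition.names:
            sel = partition.indices(initial, g)
            a0 = principal_axis(initial.coords[sel], mode=axis_mode)
            a1 = principal_axis(fitted[sel], mode=axis_mode, previous=a0)
            rods[g] = (a0, a1)
    return disp, rods
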