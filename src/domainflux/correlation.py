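"""Residue-residue correlation analysis of bead trajectories.

Implements both the standard Pearson cross-correlation of displacement
vectors and the mutual-information-based generalized correlation
coefficient rho_gen = sqrt(1 - exp(-2 I / 3)) for 3-dimensional
per-residue displacement variables, with I estimated by the
Kraskov-Stoegbauer-Grassberger k-nearest-neighbour method (first
variant, max-norm metric).

Filtering follows the convention of discarding pairs whose correlation
magnitude falls below a cutoff (default 0.5) or whose residues
fluctuate less than an RMSF threshold (default 1.5 Angstrom).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.special import digamma

from .geometry import superpose_frames
from .model_io import StructureModel, SubdomainPartition, Trajectory, write_bfactor_annotation

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationResult",
    "compute_rmsf",
    "pearson_matrix",
    "generalized_matrix",
    "generalized_pair",
    "knn_mutual_information",
    "apply_filters",
    "block_summary",
    "map_to_structure",
]


@dataclass
class CorrelationResult:
    """Symmetric residue x residue correlation matrix plus metadata."""

    matrix: np.ndarray
    method: str  # "pearson" | "generalized"
    rmsf: np.ndarray
    selection: np.ndarray  # bead indices (into the model) of matrix rows
    rmsf_threshold: float = 1.5
    corr_threshold: float = 0.5
    knn_k: int | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError(f"matrix shape {m.shape} not square")
        if self.method not in ("pearson", "generalized"):
            raise ValueError(f"unknown method {self.method!r}")
        self.matrix = m
        self.rmsf = np.asarray(self.rmsf, float)
        self.selection = np.asarray(self.selection, int)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def _displacements(traj: Trajectory, selection: np.ndarray | None,
                   align: bool) -> np.ndarray:
    """(F, n_sel, 3) displacements about the trajectory mean.

    With ``align`` the frames are first superposed (over the selection)
    onto the mean structure, iterated once, removing global rigid drift.
    """
    coords = traj.coords
    sel = np.arange(traj.n_atoms) if selection is None else np.asarray(selection, int)
    if align:
        aligned = superpose_frames(coords, coords.mean(axis=0), sel)
        aligned = superpose_frames(aligned, aligned.mean(axis=0), sel)
    else:
        aligned = coords
    x = aligned[:, sel, :]
    return x - x.mean(axis=0)


def compute_rmsf(traj: Trajectory, selection: np.ndarray | None = None,
                 align: bool = True) -> np.ndarray:
    """Root-mean-square fluctuation of each bead about its mean position."""
    if traj.n_frames < 2:
        raise ValueError(f"RMSF needs >= 2 frames, got {traj.n_frames}")
    d = _displacements(traj, selection, align)
    return np.sqrt(np.mean(np.sum(d * d, axis=2), axis=0))


def pearson_matrix(traj: Trajectory, selection: np.ndarray | None = None,
                   align: bool = True, rmsf_threshold: float = 1.5,
                   corr_threshold: float = 0.5) -> CorrelationResult:
    """Pearson cross-correlation of displacement vectors.

    rho_P(i, j) = <dr_i . dr_j> / sqrt(<dr_i^2><dr_j^2>). Beads with
    zero variance get NaN rows/columns (logged), diagonal 1 elsewhere.
    """
    if traj.n_frames < 2:
        raise ValueError("Pearson matrix needs >= 2 frames")
    d = _displacements(traj, selection, align)
    nf = d.shape[0]
    # <dr_i . dr_j> averaged over frames, all pairs at once
    num = np.tensordot(d, d, axes=([0, 2], [0, 2])) / nf
    var = np.diag(num).copy()
    dead = var <= 0
    if dead.any():
        logger.warning("%d zero-variance beads: correlation undefined", int(dead.sum()))
        var[dead] = np.nan
    denom = np.sqrt(np.outer(var, var))
    mat = num / denom
    np.fill_diagonal(mat, np.where(dead, np.nan, 1.0))
    mat = np.clip(mat, -1.0, 1.0, out=mat)
    sel = np.arange(traj.n_atoms) if selection is None else np.asarray(selection, int)
    rmsf = np.sqrt(np.mean(np.sum(d * d, axis=2), axis=0))
    return CorrelationResult(mat, "pearson", rmsf, sel,
                             rmsf_threshold=rmsf_threshold,
                             corr_threshold=corr_threshold)


# --------------------------------------------------------------------------
# KSG mutual information and the generalized correlation coefficient
# --------------------------------------------------------------------------


def knn_mutual_information(x: np.ndarray, y: np.ndarray, k: int = 6) -> float:
    """KSG (first variant) mutual information estimate in nats.

    ``x`` and ``y`` are (n, d) samples of two continuous variables. Uses
    the Chebyshev (max-norm) metric throughout. The caller is
    responsible for tie-breaking jitter. Estimates may be slightly
    negative for independent variables; clamp as appropriate.
    """
    x = np.atleast_2d(np.asarray(x, float))
    y = np.atleast_2d(np.asarray(y, float))
    n = x.shape[0]
    if y.shape[0] != n:
        raise ValueError("x and y must have the same number of samples")
    if k >= n:
        raise ValueError(f"k = {k} must be smaller than the sample count {n}")
    joint = np.hstack([x, y])
    tree_joint = cKDTree(joint)
    # distance to the k-th neighbour (excluding self) in the joint space
    dist, _ = tree_joint.query(joint, k=k + 1, p=np.inf)
    eps = dist[:, -1]
    # strictly-within-eps marginal counts (self excluded)
    tree_x = cKDTree(x)
    tree_y = cKDTree(y)
    r = np.nextafter(eps, 0.0)
    nx = tree_x.query_ball_point(x, r, p=np.inf, return_length=True) - 1
    ny = tree_y.query_ball_point(y, r, p=np.inf, return_length=True) - 1
    return float(digamma(k) + digamma(n)
                 - np.mean(digamma(nx + 1) + digamma(ny + 1)))


def _mi_to_rho(mi: float, d: int = 3) -> float:
    mi = max(mi, 0.0)  # estimator noise can go slightly negative
    return float(np.sqrt(1.0 - np.exp(-2.0 * mi / d)))


def generalized_pair(xi: np.ndarray, xj: np.ndarray, k: int = 6,
                     rng: np.random.Generator | None = None) -> float:
    """Generalized correlation coefficient of two (n, 3) displacement
    samples."""
    if rng is not None:
        xi = xi + rng.normal(0.0, 1e-10, size=xi.shape)
        xj = xj + rng.normal(0.0, 1e-10, size=xj.shape)
    return _mi_to_rho(knn_mutual_information(xi, xj, k=k), d=xi.shape[1])


def generalized_matrix(traj: Trajectory, selection: np.ndarray | None = None,
                       knn_k: int = 6, seed: int = 0, align: bool = True,
                       rmsf_threshold: float = 1.5,
                       corr_threshold: float = 0.5) -> CorrelationResult:
    """Generalized correlation matrix rho_gen in [0, 1].

    Each entry transforms a KSG mutual-information estimate between the
    two beads' 3D displacement variables. A tiny seeded jitter
    (1e-10 Angstrom) breaks exact distance ties, so the result is
    deterministic given ``seed``.
    """
    if traj.n_frames < knn_k + 2:
        raise ValueError(
            f"generalized matrix needs >= knn_k + 2 = {knn_k + 2} frames, "
            f"got {traj.n_frames}"
        )
    d = _displacements(traj, selection, align)
    rng = np.random.default_rng(seed)
    d = d + rng.normal(0.0, 1e-10, size=d.shape)
    n = d.shape[1]
    mat = np.zeros((n, n))
    np.fill_diagonal(mat, 1.0)
    trees = [cKDTree(d[:, i, :]) for i in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            joint = np.concatenate([d[:, i, :], d[:, j, :]], axis=1)
            dist, _ = cKDTree(joint).query(joint, k=knn_k + 1, p=np.inf)
            r = np.nextafter(dist[:, -1], 0.0)
            nx = trees[i].query_ball_point(d[:, i, :], r, p=np.inf, return_length=True) - 1
            ny = trees[j].query_ball_point(d[:, j, :], r, p=np.inf, return_length=True) - 1
            mi = (digamma(knn_k) + digamma(d.shape[0])
                  - np.mean(digamma(nx + 1) + digamma(ny + 1)))
            mat[i, j] = mat[j, i] = _mi_to_rho(float(mi), d=3)
    sel = np.arange(traj.n_atoms) if selection is None else np.asarray(selection, int)
    rmsf = np.sqrt(np.mean(np.sum(_displacements(traj, selection, align) ** 2, axis=2), axis=0))
    return CorrelationResult(mat, "generalized", rmsf, sel,
                             rmsf_threshold=rmsf_threshold,
                             corr_threshold=corr_threshold, knn_k=knn_k)


# --------------------------------------------------------------------------
# filters, block summaries, structure mapping
# --------------------------------------------------------------------------


def apply_filters(result: CorrelationResult,
                  rmsf_threshold: float | None = None,
                  corr_threshold: float | None = None,
                  rmsf_rule: str = "both") -> pd.DataFrame:
    """Significant correlated pairs as a tidy table.

    A pair (i, j), i < j, survives when |value| >= ``corr_threshold``
    and the RMSF condition holds: with ``rmsf_rule='both'`` (default)
    both residues' RMSF must exceed ``rmsf_threshold``; with
    ``'either'`` one suffices. Indices refer to positions within the
    result's selection; the ``bead`` columns give model bead indices.
    """
    rt = result.rmsf_threshold if rmsf_threshold is None else rmsf_threshold
    ct = result.corr_threshold if corr_threshold is None else corr_threshold
    if rmsf_rule not in ("both", "either"):
        raise ValueError(f"rmsf_rule must be 'both' or 'either', got {rmsf_rule!r}")
    n = result.n
    iu, ju = np.triu_indices(n, k=1)
    vals = result.matrix[iu, ju]
    ok = np.abs(vals) >= ct
    ok &= ~np.isnan(vals)
    moving = result.rmsf > rt
    if rmsf_rule == "both":
        ok &= moving[iu] & moving[ju]
    else:
        ok &= moving[iu] | moving[ju]
    return pd.DataFrame({
        "i": iu[ok],
        "j": ju[ok],
        "bead_i": result.selection[iu[ok]],
        "bead_j": result.selection[ju[ok]],
        "value": vals[ok],
    })


def block_summary(result: CorrelationResult, model: StructureModel,
                  partition: SubdomainPartition,
                  groups: list[str] | None = None,
                  include_monomers: bool = True,
                  count_threshold: float | None = None) -> pd.DataFrame:
    """(mean, max, count-above-threshold) of |value| per group x group block.

    Covers every ordered pair of partition groups (default: those that
    intersect the analysed selection), plus monomer-level groups when
    requested. The diagonal of same-group blocks is excluded from the
    statistics. An explicitly requested group with no beads in the
    selection is an error.
    """
    ct = result.corr_threshold if count_threshold is None else count_threshold
    sel_pos = {b: p for p, b in enumerate(result.selection)}

    group_pos: dict[str, np.ndarray] = {}
    explicit = groups is not None
    names = list(groups) if explicit else list(partition.names)
    for g in names:
        beads = partition.indices(model, g)
        pos = np.array([sel_pos[b] for b in beads if b in sel_pos], dtype=int)
        group_pos[g] = pos
    if not explicit:
        names = [g for g in names if group_pos[g].size > 0]
        if not names:
            raise ValueError("no partition group intersects the analysed selection")
    if include_monomers:
        for mon, beads in partition.monomer_groups(model).items():
            pos = np.array([sel_pos[b] for b in beads if b in sel_pos], dtype=int)
            if pos.size == 0 and not explicit:
                continue
            group_pos[mon] = pos
            names.append(mon)

    rows = []
    for ga in names:
        pa = group_pos[ga]
        if pa.size == 0:
            raise ValueError(f"group {ga!r} is empty within the analysed selection")
        for gb in names:
            pb = group_pos[gb]
            block = np.abs(result.matrix[np.ix_(pa, pb)]).astype(float)
            if ga == gb:
                mask = ~np.eye(len(pa), dtype=bool)
                vals = block[mask]
            else:
                vals = block.ravel()
            vals = vals[~np.isnan(vals)]
            if vals.size == 0:
                rows.append((ga, gb, np.nan, np.nan, 0))
            else:
                rows.append((ga, gb, float(vals.mean()), float(vals.max()),
                             int(np.sum(vals >= ct))))
    return pd.DataFrame(rows, columns=["group_a", "group_b", "mean", "max",
                                       "count_above_threshold"])


def map_to_structure(result: CorrelationResult, model: StructureModel,
                     path, mode: str = "count",
                     pairs: pd.DataFrame | None = None,
                     **filter_kwargs) -> np.ndarray:
    """Write per-residue correlation involvement as a B-factor annotation.

    ``mode='count'``: number of surviving correlation partners per
    residue; ``mode='max'``: largest surviving |value|. Residues outside
    the analysed selection get 0. Returns the per-bead values written.
    """
    if mode not in ("count", "max"):
        raise ValueError(f"mode must be 'count' or 'max', got {mode!r}")
    if pairs is None:
        pairs = apply_filters(result, **filter_kwargs)
    values = np.zeros(model.n_atoms)
    for _, row in pairs.iterrows():
        for bead in (int(row["bead_i"]), int(row["bead_j"])):
            if mode == "count":
                values[bead] += 1.0
            else:
                values[bead] = max(values[bead], abs(float(row["value"])))
    write_bfactor_annotation(model, values, path)
    return values
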