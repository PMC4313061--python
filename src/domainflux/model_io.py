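"""Structure and trajectory I/O for bead (one bead per residue) models.

Supports single- and multi-model PDB plus XYZ block format. Coordinates
are in Angstrom throughout; residue indices are 1-based and ranges are
inclusive on both ends.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "StructureModel",
    "SubdomainPartition",
    "Trajectory",
    "ParseError",
    "ValidationError",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
    "write_bfactor_annotation",
    "read_partition",
    "write_partition",
]


class ParseError(ValueError):
    """A file failed to parse in the declared dialect."""


class ValidationError(ValueError):
    """Parsed content violates a model invariant."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class StructureModel:
    """A bead model: one bead per residue, grouped into monomers.

    Parameters
    ----------
    atom_index : (N,) int array, 1-based, strictly increasing.
    residue_index : (N,) int array, 1-based, unique within a monomer.
    monomer_id : (N,) array of single-character labels (e.g. A, B, C).
    coords : (N, 3) float array in Angstrom.
    box : optional length-3 box vector in Angstrom (unused by analyses).
    """

    atom_index: np.ndarray
    residue_index: np.ndarray
    monomer_id: np.ndarray
    coords: np.ndarray
    box: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "atom_index", np.asarray(self.atom_index, dtype=int))
        object.__setattr__(self, "residue_index", np.asarray(self.residue_index, dtype=int))
        object.__setattr__(self, "monomer_id", np.asarray(self.monomer_id, dtype="U4"))
        object.__setattr__(self, "coords", np.asarray(self.coords, dtype=float))
        self._validate()

    def _validate(self) -> None:
        n = self.n_atoms
        if self.coords.shape != (n, 3):
            raise ValidationError(
                f"coords shape {self.coords.shape} does not match {n} atoms"
            )
        if n and np.any(np.diff(self.atom_index) <= 0):
            bad = int(np.flatnonzero(np.diff(self.atom_index) <= 0)[0])
            raise ValidationError(
                f"atom_index not strictly increasing at position {bad + 1} "
                f"(index {self.atom_index[bad + 1]})"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("non-finite coordinate in structure")
        for mon in np.unique(self.monomer_id):
            res = self.residue_index[self.monomer_id == mon]
            if len(np.unique(res)) != len(res):
                raise ValidationError(f"duplicate residue index in monomer {mon}")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_index)

    @property
    def monomers(self) -> list[str]:
        seen: dict[str, None] = {}
        for m in self.monomer_id:
            seen.setdefault(str(m))
        return list(seen)

    def residue_keys(self) -> list[tuple[str, int]]:
        """(monomer_id, residue_index) per bead, in atom order."""
        return [(str(m), int(r)) for m, r in zip(self.monomer_id, self.residue_index)]

    def with_coords(self, coords: np.ndarray) -> "StructureModel":
        return replace(self, coords=np.asarray(coords, dtype=float))

    def indices_for(self, monomer: str, residues: Iterable[int] | None = None) -> np.ndarray:
        mask = self.monomer_id == monomer
        if residues is not None:
            mask &= np.isin(self.residue_index, np.fromiter(residues, dtype=int))
        return np.flatnonzero(mask)


@dataclass(frozen=True)
class SubdomainPartition:
    """Named residue groups: group name -> list of (monomer, first, last) ranges."""

    groups: Mapping[str, tuple[tuple[str, int, int], ...]]

    def __post_init__(self) -> None:
        norm = {
            str(name): tuple((str(m), int(a), int(b)) for m, a, b in ranges)
            for name, ranges in self.groups.items()
        }
        object.__setattr__(self, "groups", norm)
        for name, ranges in norm.items():
            for mon, a, b in ranges:
                if a > b:
                    raise ValidationError(f"group {name}: empty range {a}-{b}")

    @property
    def names(self) -> list[str]:
        return list(self.groups)

    def residues(self, name: str) -> set[tuple[str, int]]:
        out: set[tuple[str, int]] = set()
        for mon, a, b in self.groups[name]:
            out.update((mon, r) for r in range(a, b + 1))
        return out

    def validate_against(self, model: StructureModel) -> None:
        """Check disjointness within a monomer and existence of every residue."""
        existing = set(model.residue_keys())
        claimed: dict[tuple[str, int], str] = {}
        for name in self.groups:
            for key in self.residues(name):
                if key not in existing:
                    raise ValidationError(
                        f"group {name} references missing residue {key[1]} in monomer {key[0]}"
                    )
                if key in claimed and claimed[key] != name:
                    raise ValidationError(
                        f"groups {claimed[key]} and {name} overlap at residue "
                        f"{key[1]} of monomer {key[0]}"
                    )
                claimed[key] = name

    def indices(self, model: StructureModel, name: str) -> np.ndarray:
        """Bead indices (0-based, atom order) of a group."""
        keys = self.residues(name)
        mask = np.fromiter(
            (k in keys for k in model.residue_keys()), dtype=bool, count=model.n_atoms
        )
        return np.flatnonzero(mask)

    def monomer_groups(self, model: StructureModel) -> dict[str, np.ndarray]:
        return {m: model.indices_for(m) for m in model.monomers}


@dataclass(frozen=True)
class Trajectory:
    """Ordered frames congruent with a StructureModel."""

    coords: np.ndarray  # (n_frames, n_atoms, 3)
    dt: float = 1.0  # frame interval, ps
    seed: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "coords", np.asarray(self.coords, dtype=float))
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValidationError(f"trajectory coords shape {self.coords.shape} invalid")
        if self.dt <= 0:
            raise ValidationError(f"dt must be positive, got {self.dt}")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def check_congruent(self, model: StructureModel) -> None:
        if self.n_atoms != model.n_atoms:
            raise ValidationError(
                f"trajectory has {self.n_atoms} atoms, model has {model.n_atoms}"
            )


# --------------------------------------------------------------------------
# PDB
# --------------------------------------------------------------------------

_PDB_ATOM_FMT = (
    "ATOM  {serial:>5d}  CA  ALA {chain:1s}{resseq:>4d}    "
    "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{bf:6.2f}           C\n"
)


def _parse_pdb_atom(line: str, lineno: int):
    try:
        serial = int(line[6:11])
        chain = line[21].strip() or "A"
        resseq = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise ParseError(f"line {lineno}: malformed ATOM record: {exc}") from exc
    bf = 0.0
    if len(line) >= 66 and line[60:66].strip():
        try:
            bf = float(line[60:66])
        except ValueError as exc:
            raise ParseError(f"line {lineno}: malformed B-factor field") from exc
    return serial, chain, resseq, (x, y, z), bf


def _read_pdb_models(path: Path):
    """Yield (serials, chains, resseqs, coords, bfactors) per model."""
    models = []
    cur: list | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                if cur:
                    models.append(cur)
                cur = []
            elif rec in ("ATOM", "HETATM"):
                if cur is None:
                    cur = []
                cur.append(_parse_pdb_atom(line, lineno))
            elif rec == "ENDMDL":
                if cur is not None:
                    models.append(cur)
                    cur = None
    if cur:
        models.append(cur)
    if not models:
        raise ParseError(f"{path}: no ATOM records found")
    return models


def _model_from_records(records) -> StructureModel:
    serials = np.array([r[0] for r in records], dtype=int)
    if len(np.unique(serials)) != len(serials):
        dupes = serials[np.flatnonzero(np.diff(np.sort(serials)) == 0)]
        raise ValidationError(f"duplicate atom index {int(dupes[0])}")
    chains = np.array([r[1] for r in records])
    resseqs = np.array([r[2] for r in records], dtype=int)
    coords = np.array([r[3] for r in records], dtype=float)
    return StructureModel(serials, resseqs, chains, coords)


def read_structure(path, format: str = "pdb", monomer_map: Sequence[str] | None = None) -> StructureModel:
    """Read a bead structure.

    For XYZ input monomer labels are not part of the format; supply
    ``monomer_map`` (one label per atom) or all beads land in monomer A.
    """
    path = Path(path)
    if format == "pdb":
        models = _read_pdb_models(path)
        return _model_from_records(models[0])
    if format == "xyz":
        frames = _read_xyz_frames(path)
        coords = frames[0]
        n = len(coords)
        if monomer_map is None:
            chains = np.full(n, "A")
            resseqs = np.arange(1, n + 1)
        else:
            if len(monomer_map) != n:
                raise ValidationError(
                    f"monomer_map has {len(monomer_map)} entries for {n} atoms"
                )
            chains = np.asarray(monomer_map)
            resseqs = np.zeros(n, dtype=int)
            counter: dict[str, int] = {}
            for i, c in enumerate(chains):
                counter[c] = counter.get(c, 0) + 1
                resseqs[i] = counter[c]
        return StructureModel(np.arange(1, n + 1), resseqs, chains, coords)
    raise ValueError(f"unknown structure format {format!r}")


def write_structure(model: StructureModel, path, format: str = "pdb",
                    bfactors: np.ndarray | None = None) -> None:
    path = Path(path)
    if format == "pdb":
        with open(path, "w") as fh:
            _write_pdb_model(fh, model, bfactors)
            fh.write("END\n")
    elif format == "xyz":
        with open(path, "w") as fh:
            _write_xyz_frame(fh, model.coords, comment="structure")
    else:
        raise ValueError(f"unknown structure format {format!r}")


def _write_pdb_model(fh, model: StructureModel, bfactors=None) -> None:
    bfs = np.zeros(model.n_atoms) if bfactors is None else np.asarray(bfactors, float)
    for i in range(model.n_atoms):
        x, y, z = model.coords[i]
        fh.write(
            _PDB_ATOM_FMT.format(
                serial=int(model.atom_index[i]) % 100000,
                chain=str(model.monomer_id[i])[:1],
                resseq=int(model.residue_index[i]) % 10000,
                x=x, y=y, z=z, occ=1.0, bf=bfs[i],
            )
        )


# --------------------------------------------------------------------------
# XYZ
# --------------------------------------------------------------------------


def _read_xyz_frames(path: Path) -> list[np.ndarray]:
    frames: list[np.ndarray] = []
    with open(path) as fh:
        lines = fh.readlines()
    i, lineno = 0, 0
    nframe = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        nframe += 1
        try:
            natoms = int(lines[i].strip())
        except ValueError as exc:
            raise ParseError(f"line {i + 1}: expected atom count, got {lines[i]!r}") from exc
        if i + 1 + natoms + 1 > len(lines) + 1:
            raise ParseError(f"frame {nframe}: truncated (expected {natoms} atoms)")
        block = lines[i + 2: i + 2 + natoms]
        if len(block) < natoms:
            raise ParseError(f"frame {nframe}: truncated (expected {natoms} atoms, got {len(block)})")
        coords = np.empty((natoms, 3))
        for k, line in enumerate(block):
            parts = line.split()
            if len(parts) < 4:
                raise ParseError(f"line {i + 3 + k}: expected 'name x y z', got {line!r}")
            try:
                coords[k] = [float(parts[1]), float(parts[2]), float(parts[3])]
            except ValueError as exc:
                raise ParseError(f"line {i + 3 + k}: non-numeric coordinate") from exc
        frames.append(coords)
        i += 2 + natoms
    if not frames:
        raise ParseError(f"{path}: no XYZ frames found")
    return frames


def _write_xyz_frame(fh, coords: np.ndarray, comment: str = "") -> None:
    fh.write(f"{len(coords)}\n{comment}\n")
    for x, y, z in coords:
        fh.write(f"CA {x:12.6f} {y:12.6f} {z:12.6f}\n")


# --------------------------------------------------------------------------
# trajectories
# --------------------------------------------------------------------------


def read_trajectory(path, format: str = "pdb", dt: float = 1.0,
                    seed: int | None = None) -> Trajectory:
    """Read a multi-frame trajectory (multi-model PDB or XYZ blocks)."""
    path = Path(path)
    if format == "pdb":
        models = _read_pdb_models(path)
        n0 = len(models[0])
        for k, m in enumerate(models):
            if len(m) != n0:
                raise ValidationError(
                    f"frame {k + 1} has {len(m)} atoms, frame 1 has {n0}"
                )
        coords = np.array([[r[3] for r in m] for m in models], dtype=float)
    elif format == "xyz":
        frames = _read_xyz_frames(path)
        n0 = len(frames[0])
        for k, f in enumerate(frames):
            if len(f) != n0:
                raise ValidationError(
                    f"frame {k + 1} has {len(f)} atoms, frame 1 has {n0}"
                )
        coords = np.asarray(frames)
    else:
        raise ValueError(f"unknown trajectory format {format!r}")
    return Trajectory(coords, dt=dt, seed=seed)


def write_trajectory(traj: Trajectory, model: StructureModel, path,
                     format: str = "pdb") -> None:
    traj.check_congruent(model)
    path = Path(path)
    if format == "pdb":
        with open(path, "w") as fh:
            for k in range(traj.n_frames):
                fh.write(f"MODEL     {k + 1:>4d}\n")
                _write_pdb_model(fh, model.with_coords(traj.coords[k]))
                fh.write("ENDMDL\n")
            fh.write("END\n")
    elif format == "xyz":
        with open(path, "w") as fh:
            for k in range(traj.n_frames):
                _write_xyz_frame(fh, traj.coords[k], comment=f"frame {k + 1}")
    else:
        raise ValueError(f"unknown trajectory format {format!r}")


# --------------------------------------------------------------------------
# annotation
# --------------------------------------------------------------------------


def write_bfactor_annotation(model: StructureModel, values, path) -> None:
    """Write the model as PDB with per-residue scalars in the B-factor column.

    One value per residue (= per bead); values must fit the 6.2f column.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != (model.n_atoms,):
        raise ValidationError(
            f"got {values.size} values for {model.n_atoms} residues"
        )
    if np.any(values > 9999.99) or np.any(values < -999.99):
        raise ValidationError("value out of B-factor column range [-999.99, 9999.99]")
    write_structure(model, path, format="pdb", bfactors=values)


def read_bfactors(path) -> np.ndarray:
    """Per-atom B-factors from the first model of a PDB file."""
    models = _read_pdb_models(Path(path))
    return np.array([r[4] for r in models[0]], dtype=float)


# --------------------------------------------------------------------------
# partition config: "name: monomer start-end[, monomer start-end ...]"
# --------------------------------------------------------------------------


def read_partition(path) -> SubdomainPartition:
    groups: dict[str, tuple] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if ":" not in line:
                raise ParseError(f"line {lineno}: expected 'name: monomer start-end'")
            name, rhs = line.split(":", 1)
            ranges = []
            for chunk in rhs.split(","):
                parts = chunk.split()
                if len(parts) != 2 or "-" not in parts[1]:
                    raise ParseError(
                        f"line {lineno}: bad range spec {chunk.strip()!r}"
                    )
                mon = parts[0]
                try:
                    a, b = (int(v) for v in parts[1].split("-", 1))
                except ValueError as exc:
                    raise ParseError(f"line {lineno}: non-integer residue bound") from exc
                ranges.append((mon, a, b))
            name = name.strip()
            if name in groups:
                raise ParseError(f"line {lineno}: duplicate group {name!r}")
            groups[name] = tuple(ranges)
    return SubdomainPartition(groups)


def write_partition(partition: SubdomainPartition, path) -> None:
    with open(path, "w") as fh:
        for name, ranges in partition.groups.items():
            spec = ", ".join(f"{m} {a}-{b}" for m, a, b in ranges)
            fh.write(f"{name}: {spec}\n")
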