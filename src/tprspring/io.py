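"""Structures, trajectories, repeat annotations and observable series.

This module defines the coordinate and numbering conventions used by the
rest of the package:

* residue numbering is 1-based author numbering, ranges inclusive on both
  ends (matching PDB convention and residue labels like L254, R284);
* coordinates are in Å, frame times in ps;
* trajectory frame times come from configuration (a frame spacing), not
  from the file — multi-model PDB carries no time information.

PDB parsing and writing is delegated to :mod:`biotite`; the classes here
are light containers shared by the analysis operators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
import biotite.structure as struc
import biotite.structure.io.pdb as biotite_pdb
from biotite.structure.info import mass as element_mass


class FormatError(ValueError):
    """A file did not contain what its format promises."""


class AnnotationError(ValueError):
    """A repeat annotation failed validation."""


# ---------------------------------------------------------------------------
# structures and trajectories
# ---------------------------------------------------------------------------

@dataclass
class StructureModel:
    """A molecular model: per-atom names, residue info, coordinates, masses.

    Parameters
    ----------
    atom_names, elements, res_ids, res_names, chain_ids : arrays of length n
    coords : (n, 3) float array, Å
    masses : (n,) float array, Da
    metadata : free-form dict (generators record ground truth here)
    """

    atom_names: np.ndarray
    elements: np.ndarray
    res_ids: np.ndarray
    res_names: np.ndarray
    chain_ids: np.ndarray
    coords: np.ndarray
    masses: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.atom_names)
        for name in ("elements", "res_ids", "res_names", "chain_ids", "masses"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} has length {len(getattr(self, name))}, expected {n}")
        if self.coords.shape != (n, 3):
            raise ValueError(f"coords shape {self.coords.shape}, expected ({n}, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        self.masses = np.asarray(self.masses, dtype=float)
        if np.any(self.masses <= 0):
            raise ValueError("masses must be positive")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    def select(self, res_id_range: tuple[int, int] | None = None,
               atom_name: str | None = None,
               res_id: int | None = None) -> np.ndarray:
        """Boolean mask over atoms; range is inclusive on both ends."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if res_id_range is not None:
            lo, hi = res_id_range
            mask &= (self.res_ids >= lo) & (self.res_ids <= hi)
        if res_id is not None:
            mask &= self.res_ids == res_id
        if atom_name is not None:
            mask &= self.atom_names == atom_name
        return mask

    def center_of_mass(self, mask: np.ndarray | None = None) -> np.ndarray:
        m = self.masses if mask is None else self.masses[mask]
        x = self.coords if mask is None else self.coords[mask]
        if len(m) == 0:
            raise ValueError("empty selection has no centre of mass")
        return (m[:, None] * x).sum(axis=0) / m.sum()

    def to_biotite(self) -> struc.AtomArray:
        arr = struc.AtomArray(self.n_atoms)
        arr.coord = self.coords.astype(np.float32)
        arr.atom_name = np.asarray(self.atom_names, dtype="U6")
        arr.element = np.asarray(self.elements, dtype="U2")
        arr.res_id = np.asarray(self.res_ids, dtype=int)
        arr.res_name = np.asarray(self.res_names, dtype="U5")
        arr.chain_id = np.asarray(self.chain_ids, dtype="U4")
        arr.hetero = np.zeros(self.n_atoms, dtype=bool)
        return arr

    @classmethod
    def from_biotite(cls, arr: struc.AtomArray) -> "StructureModel":
        elements = np.asarray(arr.element, dtype="U2")
        blank = np.array([e.strip() == "" for e in elements])
        if blank.any():
            inferred = struc.infer_elements(arr.atom_name)
            elements = np.where(blank, inferred, elements)
        masses = np.array([element_mass(e.capitalize() if len(e) > 1 else e)
                           for e in elements], dtype=float)
        return cls(
            atom_names=np.asarray(arr.atom_name, dtype="U6"),
            elements=elements,
            res_ids=np.asarray(arr.res_id, dtype=int),
            res_names=np.asarray(arr.res_name, dtype="U5"),
            chain_ids=np.asarray(arr.chain_id, dtype="U4"),
            coords=np.asarray(arr.coord, dtype=float),
            masses=masses,
        )


@dataclass
class CoordinateTrajectory:
    """Frames of coordinates over a fixed atom set.

    ``frames`` has shape (n_frames, n_atoms, 3) in Å; ``times`` is one
    strictly increasing time (ps) per frame.  ``reference`` carries the
    atom identities shared by every frame.
    """

    reference: StructureModel
    frames: np.ndarray
    times: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1] != self.reference.n_atoms:
            raise ValueError(
                f"frames shape {self.frames.shape} incompatible with "
                f"{self.reference.n_atoms} reference atoms")
        if len(self.times) != len(self.frames):
            raise ValueError("one time per frame required")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def frame(self, i: int) -> StructureModel:
        return replace(self.reference, coords=self.frames[i])

    @classmethod
    def from_structure(cls, structure: StructureModel) -> "CoordinateTrajectory":
        """Single-frame trajectory view of a static structure."""
        return cls(structure, structure.coords[None, :, :], np.array([0.0]))


# ---------------------------------------------------------------------------
# observable series
# ---------------------------------------------------------------------------

@dataclass
class DistanceSeries:
    """A scalar distance observable per frame (Å)."""

    times: np.ndarray
    values: np.ndarray
    label: str = "distance"
    states: np.ndarray | None = None
    replicate: int | None = None

    unit = "A"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times) != len(self.values):
            raise ValueError("times and values must have equal length")
        if self.states is not None:
            self.states = np.asarray(self.states)
            if len(self.states) != len(self.values):
                raise ValueError("states must match values length")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def std(self) -> float:
        return float(np.std(self.values, ddof=1))

    def to_tsv(self, path: str | Path) -> None:
        write_series_tsv(self, path)

    @classmethod
    def from_tsv(cls, path: str | Path, label: str | None = None):
        return read_series_tsv(path, kind=cls, label=label)


def wrap_degrees(values: np.ndarray) -> np.ndarray:
    """Wrap angles (degrees) to the interval (−180, 180]."""
    wrapped = np.mod(np.asarray(values, dtype=float), 360.0)
    wrapped = np.where(wrapped > 180.0, wrapped - 360.0, wrapped)
    # np.mod maps -180 to 180-eps territory fine; ensure exactly +180 kept
    return wrapped


@dataclass
class AngleSeries(DistanceSeries):
    """A scalar angle observable per frame, degrees wrapped to (−180, 180].

    Mean and SD are circular (scipy), so values straddling ±180° behave.
    """

    label: str = "angle"
    unit = "deg"

    def __post_init__(self) -> None:
        super().__post_init__()
        self.values = wrap_degrees(self.values)

    @property
    def mean(self) -> float:
        from scipy.stats import circmean
        return float(circmean(self.values, low=-180.0, high=180.0))

    @property
    def std(self) -> float:
        from scipy.stats import circstd
        return float(circstd(self.values, low=-180.0, high=180.0))


SERIES_TSV_COLUMNS = ["time_ps", "value", "state", "replicate"]


def write_series_tsv(series: DistanceSeries, path: str | Path) -> None:
    """Write a series as TSV with header time_ps, value, state, replicate."""
    df = pd.DataFrame({
        "time_ps": series.times,
        "value": series.values,
        "state": series.states if series.states is not None
        else np.full(len(series), ""),
        "replicate": np.full(
            len(series),
            series.replicate if series.replicate is not None else ""),
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_series_tsv(path: str | Path, kind=DistanceSeries,
                    label: str | None = None) -> DistanceSeries:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("time_ps", "value") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    states = None
    if "state" in df.columns and df["state"].notna().any():
        states = df["state"].to_numpy()
    replicate = None
    if "replicate" in df.columns and df["replicate"].notna().any():
        uniq = pd.unique(df["replicate"].dropna())
        if len(uniq) == 1:
            try:
                replicate = int(uniq[0])
            except (TypeError, ValueError):
                replicate = None
    return kind(times=df["time_ps"].to_numpy(), values=df["value"].to_numpy(),
                label=label or Path(path).stem, states=states,
                replicate=replicate)


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def read_structure(path: str | Path) -> StructureModel:
    """Read a PDB file into a :class:`StructureModel`.

    Multi-model files yield the first model with a warning.  Elements are
    inferred from atom names when the element column is blank; masses come
    from the standard element table.  A duplicate atom name within a
    residue keeps the first occurrence with a warning.
    """
    pdb_file = biotite_pdb.PDBFile.read(str(path))
    n_models = pdb_file.get_model_count()
    if n_models == 0:
        raise FormatError(f"{path}: no ATOM records")
    if n_models > 1:
        warnings.warn(
            f"{path}: {n_models} MODELs present; using the first "
            "(use read_trajectory for all frames)")
    arr = pdb_file.get_structure(model=1)
    arr = arr[~arr.hetero] if arr.hetero.any() else arr
    if arr.array_length() == 0:
        raise FormatError(f"{path}: no ATOM records")
    model = StructureModel.from_biotite(arr)
    model = _drop_duplicate_atoms(model, str(path))
    return model


def _drop_duplicate_atoms(model: StructureModel, origin: str) -> StructureModel:
    key = list(zip(model.chain_ids, model.res_ids, model.atom_names))
    seen: set = set()
    keep = np.ones(model.n_atoms, dtype=bool)
    for i, k in enumerate(key):
        if k in seen:
            keep[i] = False
        seen.add(k)
    if keep.all():
        return model
    warnings.warn(f"{origin}: duplicate atom(s) within residue; keeping first")
    return StructureModel(
        atom_names=model.atom_names[keep], elements=model.elements[keep],
        res_ids=model.res_ids[keep], res_names=model.res_names[keep],
        chain_ids=model.chain_ids[keep], coords=model.coords[keep],
        masses=model.masses[keep], metadata=dict(model.metadata))


def write_structure(model: StructureModel, path: str | Path) -> None:
    pdb_file = biotite_pdb.PDBFile()
    pdb_file.set_structure(model.to_biotite())
    pdb_file.write(str(path))


def read_trajectory(paths: str | Path | Sequence[str | Path],
                    frame_spacing_ps: float = 1.0) -> CoordinateTrajectory:
    """Read a multi-model PDB (or a sequence of PDB files) as a trajectory.

    Frames appear in MODEL (or file) order; times are
    ``0, spacing, 2·spacing, …`` ps because the format carries no time.
    All frames must share atom count and order.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    frames: list[np.ndarray] = []
    reference: StructureModel | None = None
    for path in paths:
        pdb_file = biotite_pdb.PDBFile.read(str(path))
        n_models = pdb_file.get_model_count()
        if n_models == 0:
            raise FormatError(f"{path}: no ATOM records")
        stack = pdb_file.get_structure()
        if isinstance(stack, struc.AtomArray):
            stack = struc.stack([stack])
        if reference is None:
            reference = StructureModel.from_biotite(stack[0])
        if stack.array_length() != reference.n_atoms:
            raise FormatError(
                f"{path} (frame {len(frames)}): atom count "
                f"{stack.array_length()} != reference {reference.n_atoms}")
        frames.append(np.asarray(stack.coord, dtype=float))
    coords = np.concatenate(frames, axis=0)
    times = frame_spacing_ps * np.arange(len(coords))
    assert reference is not None
    return CoordinateTrajectory(reference, coords, times)


def write_trajectory(traj: CoordinateTrajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB (MODEL/ENDMDL records)."""
    arr = traj.reference.to_biotite()
    stack = struc.AtomArrayStack(traj.n_frames, traj.reference.n_atoms)
    for cat in arr.get_annotation_categories():
        stack.set_annotation(cat, arr.get_annotation(cat))
    stack.coord = traj.frames.astype(np.float32)
    pdb_file = biotite_pdb.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))


def read_trajectory_mdanalysis(topology: str | Path, trajectory: str | Path,
                               frame_spacing_ps: float | None = None
                               ) -> CoordinateTrajectory:
    """Optional adapter for native MD trajectory formats (XTC/DCD/…).

    Delegates parsing to MDAnalysis (imported lazily; the core pipeline
    does not require it).  ``frame_spacing_ps`` overrides the file's
    frame times; when None the reader trusts the trajectory timestamps.
    """
    import MDAnalysis as mda
    u = mda.Universe(str(topology), str(trajectory))
    masses = None
    try:
        masses = np.asarray(u.atoms.masses, dtype=float)
        if np.any(masses <= 0):
            masses = None
    except mda.exceptions.NoDataError:
        masses = None
    elements = struc.infer_elements(u.atoms.names)
    if masses is None:
        masses = np.array([element_mass(e) for e in elements], dtype=float)
    reference = StructureModel(
        atom_names=np.asarray(u.atoms.names, dtype="U6"),
        elements=np.asarray(elements, dtype="U2"),
        res_ids=np.asarray(u.atoms.resids, dtype=int),
        res_names=np.asarray(u.atoms.resnames, dtype="U5"),
        chain_ids=np.asarray(getattr(u.atoms, "chainIDs",
                                     np.full(len(u.atoms), "A")), dtype="U4"),
        coords=u.atoms.positions.astype(float),
        masses=masses)
    frames, times = [], []
    for i, ts in enumerate(u.trajectory):
        frames.append(u.atoms.positions.astype(float))
        times.append(ts.time if frame_spacing_ps is None
                     else frame_spacing_ps * i)
    return CoordinateTrajectory(reference, np.asarray(frames),
                                np.asarray(times, dtype=float))


def as_trajectory(obj) -> CoordinateTrajectory:
    """Accept a trajectory or a single structure (promoted to one frame)."""
    if isinstance(obj, CoordinateTrajectory):
        return obj
    if isinstance(obj, StructureModel):
        return CoordinateTrajectory(obj, obj.coords[None], np.array([0.0]))
    raise TypeError(f"expected StructureModel or CoordinateTrajectory, got {type(obj)}")


# ---------------------------------------------------------------------------
# repeat annotations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RepeatUnit:
    unit_id: str
    start: int
    end: int
    helix_a: tuple[int, int]
    helix_b: tuple[int, int]
    consensus: dict[int, int]  # consensus position Ψp -> residue number

    def contains(self, res_id: int) -> bool:
        return self.start <= res_id <= self.end


@dataclass
class RepeatAnnotation:
    """Ordered repeat units with helix spans and consensus-position maps."""

    units: list[RepeatUnit]

    def __post_init__(self) -> None:
        errors: list[str] = []
        ids = [u.unit_id for u in self.units]
        if len(set(ids)) != len(ids):
            errors.append("duplicate unit ids")
        prev_end = None
        for u in self.units:
            if u.start > u.end:
                errors.append(f"{u.unit_id}: start > end")
            if prev_end is not None and u.start <= prev_end:
                errors.append(f"{u.unit_id}: overlaps/disorders previous unit")
            prev_end = u.end
            for psi in (1, 30):
                if psi not in u.consensus:
                    errors.append(f"{u.unit_id}: consensus map missing Ψ{psi}")
            for psi, res in u.consensus.items():
                if not u.contains(res):
                    errors.append(
                        f"{u.unit_id}: Ψ{psi}->{res} outside range "
                        f"[{u.start}, {u.end}]")
            for hname, (lo, hi) in (("helix A", u.helix_a), ("helix B", u.helix_b)):
                if not (u.contains(lo) and u.contains(hi) and lo <= hi):
                    errors.append(f"{u.unit_id}: {hname} span [{lo},{hi}] invalid")
        if errors:
            raise AnnotationError("; ".join(errors))

    @property
    def unit_ids(self) -> list[str]:
        return [u.unit_id for u in self.units]

    def unit(self, unit_id: str) -> RepeatUnit:
        for u in self.units:
            if u.unit_id == unit_id:
                return u
        raise KeyError(
            f"unit {unit_id!r} not in annotation; available: {self.unit_ids}")

    def predecessor(self, unit_id: str) -> RepeatUnit:
        idx = self.unit_ids.index(self.unit(unit_id).unit_id)
        if idx == 0:
            raise ValueError(f"{unit_id} is the first unit; no predecessor")
        return self.units[idx - 1]

    def unit_of_residue(self, res_id: int) -> str | None:
        for u in self.units:
            if u.contains(res_id):
                return u.unit_id
        return None

    def consensus_position(self, res_id: int) -> int | None:
        uid = self.unit_of_residue(res_id)
        if uid is None:
            return None
        for psi, res in self.unit(uid).consensus.items():
            if res == res_id:
                return psi
        return None


def load_annotation(path: str | Path) -> RepeatAnnotation:
    """Load a repeat annotation from YAML.

    Schema: top-level key ``units``, a list of mappings with keys
    ``id``, ``range`` ([start, end] inclusive), ``helix_a``, ``helix_b``
    (two-element ranges) and ``consensus`` (Ψposition -> residue number).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "units" not in raw:
        raise AnnotationError(f"{path}: expected a top-level 'units' list")
    units = []
    for entry in raw["units"]:
        try:
            units.append(RepeatUnit(
                unit_id=str(entry["id"]),
                start=int(entry["range"][0]), end=int(entry["range"][1]),
                helix_a=(int(entry["helix_a"][0]), int(entry["helix_a"][1])),
                helix_b=(int(entry["helix_b"][0]), int(entry["helix_b"][1])),
                consensus={int(k): int(v)
                           for k, v in dict(entry["consensus"]).items()},
            ))
        except (KeyError, TypeError, IndexError) as exc:
            raise AnnotationError(f"{path}: malformed unit entry {entry!r}: {exc}")
    return RepeatAnnotation(units)


# The OGT TPR domain annotation shipped by default.  The repeat boundaries
# are a documented approximation built from 34-residue periodicity: the
# disease variant R284P sits at repeat position 26 of TPR8, anchoring the
# TPR8 start at residue 259 and hence the TPR2 start at residue 55.  This
# places A319 at consensus position 27 (the consensus alanine) and the
# disease sites L254/R284/A319 in TPR7/TPR8/TPR9.  Override with a custom
# YAML file where exact boundaries are known.
DEFAULT_OGT_TPR2_START = 55
TPR_PERIOD = 34


def default_ogt_annotation(offset: int = DEFAULT_OGT_TPR2_START,
                           first_unit: int = 2,
                           n_units: int = 10) -> RepeatAnnotation:
    """Build the default OGT TPR2–TPR11 annotation (34-residue periodicity).

    ``offset`` is the first residue of the first unit and is configurable
    because the exact boundaries are an approximation.
    """
    units = []
    for i in range(n_units):
        start = offset + TPR_PERIOD * i
        end = start + TPR_PERIOD - 1
        units.append(RepeatUnit(
            unit_id=f"TPR{first_unit + i}",
            start=start, end=end,
            helix_a=(start, start + 11),
            helix_b=(start + 16, start + 28),
            consensus={p: start + p - 1 for p in range(1, TPR_PERIOD + 1)},
        ))
    return RepeatAnnotation(units)


def default_annotation_path() -> Path:
    """Path of the shipped OGT annotation YAML."""
    return Path(__file__).parent / "data" / "ogt_tpr_annotation.yaml"
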