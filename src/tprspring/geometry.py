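"""Per-frame structural descriptors of repeat-protein geometry.

Local determinants of individual repeat units — intra-repeat Cα
distances, inter-repeat centre-of-mass distances, the B-A'-B' angle that
quantifies the turn between consecutive repeats, side-chain dihedral
series with rotamer-state assignment, helix kink angles and atom-pair
(hydrogen-bond proxy) distances — plus global measures: the domain
end-to-end distance and RMSD.

Every operator accepts either a :class:`CoordinateTrajectory` or a single
:class:`StructureModel` (treated as a one-frame trajectory), and every
descriptor is invariant under global rotation and translation of the
coordinates.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation
from scipy.stats import circmean, circstd

from .io import (AngleSeries, CoordinateTrajectory, DistanceSeries,
                 RepeatAnnotation, StructureModel, as_trajectory)


@dataclass
class DescriptorResult:
    """A descriptor series with its summary statistics and provenance.

    ``definition`` records the atoms/residues used, sufficient to
    recompute the value.
    """

    series: DistanceSeries
    mean: float
    sd: float
    unit_ids: tuple[str, ...]
    definition: dict

    @classmethod
    def from_series(cls, series: DistanceSeries, unit_ids=(),
                    definition: dict | None = None) -> "DescriptorResult":
        return cls(series=series, mean=series.mean, sd=series.std,
                   unit_ids=tuple(unit_ids), definition=definition or {})


@dataclass
class RotamerPopulations:
    """Occupancies and circular statistics of rotamer states.

    ``boundaries`` are the angular cut points (degrees) partitioning
    (−180, 180] into states; state i covers [boundaries[i-1], boundaries[i])
    cyclically.
    """

    state_names: tuple[str, ...]
    boundaries: tuple[float, ...]
    occupancies: np.ndarray
    means: np.ndarray       # circular mean per state, NaN if empty
    sds: np.ndarray         # circular SD per state, NaN if empty
    counts: np.ndarray


# default χ1 partition: gauche− / trans / gauche+ boundaries
CHI1_BOUNDARIES = (-120.0, 0.0, 120.0)
CHI1_STATE_NAMES = ("gauche-", "gauche+", "trans")


# ---------------------------------------------------------------------------
# selections and per-frame primitives
# ---------------------------------------------------------------------------

def _com_series(traj: CoordinateTrajectory, mask: np.ndarray,
                ca_only: bool = False) -> np.ndarray:
    """(n_frames, 3) mass-weighted centre of mass of the selection."""
    ref = traj.reference
    if ca_only:
        mask = mask & (ref.atom_names == "CA")
    if not mask.any():
        raise ValueError("empty selection has no centre of mass")
    m = ref.masses[mask]
    return np.einsum("a,fax->fx", m, traj.frames[:, mask]) / m.sum()


def _ca_coord(traj: CoordinateTrajectory, res_id: int) -> np.ndarray:
    mask = traj.reference.select(res_id=res_id, atom_name="CA")
    if mask.sum() == 0:
        raise ValueError(f"residue {res_id} has no Cα atom")
    return traj.frames[:, np.flatnonzero(mask)[0]]


def _vector_angle(v1: np.ndarray, v2: np.ndarray) -> np.ndarray:
    """Angle (degrees) between vectors, rowwise; range [0, 180]."""
    n1 = np.linalg.norm(v1, axis=-1)
    n2 = np.linalg.norm(v2, axis=-1)
    cosang = np.einsum("...x,...x->...", v1, v2) / (n1 * n2)
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def end_to_end_distance(traj, ann: RepeatAnnotation, unit_a: str, unit_b: str,
                        ca_only: bool = False) -> DistanceSeries:
    """Distance between the centres of mass of two repeat units, per frame.

    With ``unit_a`` and ``unit_b`` the first and last repeats of the
    domain this is the global end-to-end distance.  COM is mass-weighted
    over all atoms of each unit's residue range (``ca_only`` restricts to
    Cα for sensitivity checks).
    """
    traj = as_trajectory(traj)
    ua, ub = ann.unit(unit_a), ann.unit(unit_b)
    com_a = _com_series(traj, traj.reference.select(res_id_range=(ua.start, ua.end)), ca_only)
    com_b = _com_series(traj, traj.reference.select(res_id_range=(ub.start, ub.end)), ca_only)
    values = np.linalg.norm(com_b - com_a, axis=-1)
    return DistanceSeries(times=traj.times, values=values,
                          label=f"end_to_end[{unit_a}-{unit_b}]")


def inter_tpr_distance(traj, ann: RepeatAnnotation, unit_i: str, unit_j: str,
                       ca_only: bool = False) -> DistanceSeries:
    """COM–COM distance between two repeat units (consecutive expected)."""
    ids = ann.unit_ids
    if abs(ids.index(unit_i) - ids.index(unit_j)) != 1:
        warnings.warn(f"{unit_i} and {unit_j} are not consecutive repeats")
    series = end_to_end_distance(traj, ann, unit_i, unit_j, ca_only=ca_only)
    series.label = f"inter_tpr[{unit_i}-{unit_j}]"
    return series


def intra_tpr_distance(traj, ann: RepeatAnnotation, unit: str) -> DistanceSeries:
    """Cα(Ψ1)–Cα(Ψ30) distance within one repeat unit, per frame."""
    traj = as_trajectory(traj)
    u = ann.unit(unit)
    ca1 = _ca_coord(traj, u.consensus[1])
    ca30 = _ca_coord(traj, u.consensus[30])
    values = np.linalg.norm(ca30 - ca1, axis=-1)
    return DistanceSeries(times=traj.times, values=values,
                          label=f"intra_tpr[{unit}]")


_ATOM_SPEC_RE = re.compile(r"^[A-Za-z]*(\d+):([A-Za-z0-9']+)$")


def _resolve_atom(ref: StructureModel, spec) -> int:
    """Resolve an atom spec — (res_id, atom_name) or 'E280:O' — to an index."""
    if isinstance(spec, str):
        m = _ATOM_SPEC_RE.match(spec)
        if not m:
            raise ValueError(f"cannot parse atom spec {spec!r} (expected 'E280:O')")
        res_id, atom_name = int(m.group(1)), m.group(2)
    else:
        res_id, atom_name = int(spec[0]), str(spec[1])
    idx = np.flatnonzero(ref.select(res_id=res_id, atom_name=atom_name))
    if len(idx) == 0:
        raise ValueError(f"atom spec {spec!r}: no atom {atom_name} in residue {res_id}")
    if len(idx) > 1:
        raise ValueError(f"atom spec {spec!r} is ambiguous ({len(idx)} matches)")
    return int(idx[0])


def atom_pair_distance(traj, spec_a, spec_b) -> DistanceSeries:
    """Euclidean distance between two uniquely resolved atoms, per frame."""
    traj = as_trajectory(traj)
    ia = _resolve_atom(traj.reference, spec_a)
    ib = _resolve_atom(traj.reference, spec_b)
    values = np.linalg.norm(traj.frames[:, ib] - traj.frames[:, ia], axis=-1)
    return DistanceSeries(times=traj.times, values=values,
                          label=f"pair[{spec_a}-{spec_b}]")


# ---------------------------------------------------------------------------
# angles and dihedrals
# ---------------------------------------------------------------------------

def bab_angle(traj, ann: RepeatAnnotation, unit: str,
              vertex_position: int = 1) -> AngleSeries:
    """B-A'-B' angle quantifying the turn between consecutive repeats.

    Per frame, the angle at the Cα of ``vertex_position`` (consensus Ψ1
    by default; the alternative convention uses position 2) of ``unit``
    between the Cα of Ψ30 of the previous repeat and the Cα of Ψ30 of
    ``unit``.  Degrees in [0, 180].
    """
    traj = as_trajectory(traj)
    cur = ann.unit(unit)
    prev = ann.predecessor(unit)
    if vertex_position not in cur.consensus:
        raise ValueError(f"{unit}: consensus map has no Ψ{vertex_position}")
    b_prev = _ca_coord(traj, prev.consensus[30])
    vertex = _ca_coord(traj, cur.consensus[vertex_position])
    b_cur = _ca_coord(traj, cur.consensus[30])
    values = _vector_angle(b_prev - vertex, b_cur - vertex)
    return AngleSeries(times=traj.times, values=values,
                       label=f"bab[{prev.unit_id}-{unit}]")


# χ1 fourth atom by residue type (N–CA–CB–X); ALA/GLY have no χ1
_CHI1_FOURTH_ATOM = {
    "SER": "OG", "THR": "OG1", "CYS": "SG", "VAL": "CG1", "ILE": "CG1",
}


def _dihedral_values(p0, p1, p2, p3) -> np.ndarray:
    """Signed dihedral (degrees) in (−180, 180], IUPAC sign convention."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1, axis=-1, keepdims=True))
    x = np.einsum("...x,...x->...", n1, n2)
    y = np.einsum("...x,...x->...", m1, n2)
    ang = np.degrees(np.arctan2(-y, x))
    return np.where(ang <= -180.0, ang + 360.0, ang)


def dihedral_series(traj, residue: int, which: str = "chi1") -> AngleSeries:
    """Per-frame signed dihedral of one residue: ``chi1``, ``phi`` or ``psi``.

    χ1 is the N–CA–CB–CG-class dihedral (fourth atom depends on the side
    chain; Gly/Ala have none and raise).  φ uses C of the preceding
    residue, ψ the N of the following one.  Values are wrapped to
    (−180, 180]; circular statistics apply downstream.
    """
    traj = as_trajectory(traj)
    ref = traj.reference
    which = which.lower().replace("χ", "chi").replace("ψ", "psi").replace("φ", "phi")

    def atom(res_id: int, name: str) -> np.ndarray:
        idx = np.flatnonzero(ref.select(res_id=res_id, atom_name=name))
        if len(idx) == 0:
            raise ValueError(
                f"residue {res_id}: missing atom {name} for dihedral {which}")
        return traj.frames[:, idx[0]]

    if which == "chi1":
        res_mask = ref.res_ids == residue
        if not res_mask.any():
            raise ValueError(f"residue {residue} not found")
        res_name = str(ref.res_names[res_mask][0])
        if res_name in ("GLY", "ALA"):
            raise ValueError(f"residue {residue} ({res_name}) has no χ1 dihedral")
        fourth = _CHI1_FOURTH_ATOM.get(res_name, "CG")
        quad = [atom(residue, "N"), atom(residue, "CA"),
                atom(residue, "CB"), atom(residue, fourth)]
    elif which == "phi":
        quad = [atom(residue - 1, "C"), atom(residue, "N"),
                atom(residue, "CA"), atom(residue, "C")]
    elif which == "psi":
        quad = [atom(residue, "N"), atom(residue, "CA"),
                atom(residue, "C"), atom(residue + 1, "N")]
    else:
        raise ValueError(f"unknown dihedral {which!r} (use chi1, phi or psi)")
    values = _dihedral_values(*quad)
    return AngleSeries(times=traj.times, values=values,
                       label=f"{which}[{residue}]")


def assign_rotamers(series: AngleSeries,
                    boundaries: tuple[float, ...] = CHI1_BOUNDARIES,
                    state_names: tuple[str, ...] | None = None
                    ) -> RotamerPopulations:
    """Partition an angle series into rotamer states and summarise each.

    ``boundaries`` are sorted cut points in (−180, 180] partitioning the
    circle into ``len(boundaries)`` cyclic sectors; the sector from the
    last boundary through ±180 back to the first is one state.  Empty
    states get occupancy 0 and NaN statistics.  Occupancies always sum
    to 1.
    """
    cuts = np.sort(np.asarray(boundaries, dtype=float))
    if len(cuts) < 1:
        raise ValueError("at least one boundary required")
    n_states = len(cuts)
    values = np.asarray(series.values, dtype=float)
    # state i: [cuts[i], cuts[i+1]); wrap-around sector gets index n-1
    idx = np.searchsorted(cuts, values, side="right") - 1
    idx = np.where(idx < 0, n_states - 1, idx)

    if state_names is None:
        if tuple(cuts) == CHI1_BOUNDARIES:
            state_names = CHI1_STATE_NAMES
        else:
            state_names = tuple(f"state{i}" for i in range(n_states))
    occ = np.zeros(n_states)
    means = np.full(n_states, np.nan)
    sds = np.full(n_states, np.nan)
    counts = np.zeros(n_states, dtype=int)
    for s in range(n_states):
        sel = values[idx == s]
        counts[s] = len(sel)
        occ[s] = len(sel) / len(values)
        if len(sel):
            means[s] = circmean(sel, low=-180.0, high=180.0)
            sds[s] = circstd(sel, low=-180.0, high=180.0)
    return RotamerPopulations(state_names=tuple(state_names),
                              boundaries=tuple(cuts), occupancies=occ,
                              means=means, sds=sds, counts=counts)


# ---------------------------------------------------------------------------
# helix kink
# ---------------------------------------------------------------------------

def _axis_direction(points: np.ndarray) -> np.ndarray:
    """Local helix axis of Cα windows, per frame.

    For an ideal helix the second differences of consecutive Cα
    positions are purely radial (they point at the axis), so the cross
    product of successive second differences lies exactly along the
    axis, whatever the twist per residue.  Averaging the normalised
    cross products cancels the helical wobble without tuning a smoothing
    width; the result is oriented along increasing residue index.
    ``points`` has shape (n_frames, n_res, 3) and needs n_res ≥ 4.
    """
    d2 = np.diff(points, n=2, axis=1)            # (F, n-2, 3), radial
    cross = np.cross(d2[:, :-1], d2[:, 1:])      # (F, n-3, 3), axial
    norm = np.linalg.norm(cross, axis=-1, keepdims=True)
    cross = cross / np.where(norm == 0, 1.0, norm)
    axis = cross.mean(axis=1)
    chain = points[:, -1] - points[:, 0]
    sign = np.sign(np.einsum("fx,fx->f", axis, chain))
    axis = axis * np.where(sign == 0, 1.0, sign)[:, None]
    return axis


def helix_kink_angle(traj, helix_residues: tuple[int, int], kink_position: int,
                     min_window: int = 4) -> AngleSeries:
    """Angle between the two local helix axes on either side of a kink.

    ``helix_residues`` is the inclusive residue range of the helix;
    ``kink_position`` splits it into an upstream window (residues ≤ kink)
    and a downstream window (residues > kink).  Each window's axis comes
    from the second-difference cross-product estimator (exact for ideal
    helix geometry).  Degrees; ~0 for a straight helix.
    """
    traj = as_trajectory(traj)
    lo, hi = helix_residues
    ref = traj.reference
    ca_mask = (ref.atom_names == "CA") & (ref.res_ids >= lo) & (ref.res_ids <= hi)
    res = ref.res_ids[ca_mask]
    order = np.argsort(res)
    res = res[order]
    pts = traj.frames[:, np.flatnonzero(ca_mask)[order]]
    up = res <= kink_position
    down = res > kink_position
    if up.sum() < min_window or down.sum() < min_window:
        raise ValueError(
            f"kink window too short: need ≥ {min_window} Cα on each side of "
            f"residue {kink_position} (got {int(up.sum())}/{int(down.sum())})")
    d1 = _axis_direction(pts[:, up])
    d2 = _axis_direction(pts[:, down])
    values = _vector_angle(d1, d2)
    return AngleSeries(times=traj.times, values=values,
                       label=f"kink[{lo}-{hi}@{kink_position}]")


def kink_angle_profile(traj, helix_residues: tuple[int, int],
                       smooth: int = 4) -> np.ndarray:
    """Per-residue-step bend profile along a helix (secondary output).

    Returns an (n_frames, n_steps) array of angles between consecutive
    smoothed axis segments — a per-step view of where a helix bends.
    """
    traj = as_trajectory(traj)
    lo, hi = helix_residues
    ref = traj.reference
    ca_mask = (ref.atom_names == "CA") & (ref.res_ids >= lo) & (ref.res_ids <= hi)
    res = ref.res_ids[ca_mask]
    order = np.argsort(res)
    pts = traj.frames[:, np.flatnonzero(ca_mask)[order]]
    n_res = pts.shape[1]
    w = min(smooth, n_res - 1)
    kernel = np.ones(w) / w
    sm = np.stack([np.apply_along_axis(
        lambda v: np.convolve(v, kernel, mode="valid"), 1, pts[..., d])
        for d in range(3)], axis=-1)
    seg = np.diff(sm, axis=1)
    return _vector_angle(seg[:, :-1], seg[:, 1:])


# ---------------------------------------------------------------------------
# RMSD
# ---------------------------------------------------------------------------

def rmsd(traj, reference: StructureModel, selection: np.ndarray | None = None,
         superpose: bool = True) -> DistanceSeries:
    """Per-frame RMSD (Å) to a reference structure.

    ``selection`` is a boolean atom mask resolved identically in both;
    with ``superpose`` the optimal least-squares rigid superposition
    (Kabsch) is applied before the deviation is computed.
    """
    traj = as_trajectory(traj)
    if selection is None:
        selection = np.ones(reference.n_atoms, dtype=bool)
    if len(selection) != traj.reference.n_atoms or len(selection) != reference.n_atoms:
        raise ValueError("selection/atom count mismatch between trajectory and reference")
    ref_xyz = reference.coords[selection]
    ref_centred = ref_xyz - ref_xyz.mean(axis=0)
    values = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        mob = traj.frames[f, selection]
        if superpose:
            mob_centred = mob - mob.mean(axis=0)
            rot, _ = Rotation.align_vectors(ref_centred, mob_centred)
            mob = rot.apply(mob_centred)
            diff = mob - ref_centred
        else:
            diff = mob - ref_xyz
        values[f] = np.sqrt((diff ** 2).sum() / selection.sum())
    return DistanceSeries(times=traj.times, values=values, label="rmsd")
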