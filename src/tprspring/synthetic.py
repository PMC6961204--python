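"""Synthetic generators for nanospring and repeat-geometry analyses.

Two families of generators are provided:

* **Fluctuation series** — stationary Ornstein–Uhlenbeck (OU) processes
  model the thermal end-to-end distance fluctuations of a harmonic
  protein nanospring; mixtures of OU components with Markov state
  switching model ensembles that partition into conformational
  populations of different mean extension and stiffness.
* **Idealised α-solenoid coordinates** — helix-hairpin repeat units
  placed on a regular superhelix, with controllable intra-repeat
  distance, superhelical rise/twist, and optionally an injected helix
  kink.  The generator records the exact ground-truth value of every
  descriptor it was built with, so the geometry operators can be
  validated by round trip.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import brentq
from scipy.signal import lfilter
from scipy.spatial.transform import Rotation

from .io import (AngleSeries, CoordinateTrajectory, DistanceSeries,
                 RepeatAnnotation, RepeatUnit, StructureModel)
from .units import DEFAULT_TEMPERATURE_K, thermal_variance_A2


class ParameterError(ValueError):
    """A generator was given invalid parameters."""


# ---------------------------------------------------------------------------
# Ornstein–Uhlenbeck fluctuation series
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OUParams:
    """Parameters of a stationary OU end-to-end distance process.

    k : stiffness in pN/nm; sets the stationary variance via k_B·T/k.
    mean : equilibrium length in Å.
    temperature : bath temperature in K.
    tau : relaxation (autocorrelation) time in ps.
    dt : frame spacing in ps.
    n_frames : number of frames.
    seed : RNG seed (mandatory; generators are reproducible).
    """

    k: float
    mean: float
    tau: float
    dt: float
    n_frames: int
    temperature: float = DEFAULT_TEMPERATURE_K
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("k", "mean", "tau", "dt", "temperature"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ParameterError(f"{name} must be finite, got {v}")
        for name in ("k", "tau", "dt", "temperature"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive, got {getattr(self, name)}")
        if self.n_frames < 2:
            raise ParameterError(f"n_frames must be >= 2, got {self.n_frames}")

    @property
    def stationary_sd_A(self) -> float:
        """Stationary standard deviation in Å (equipartition)."""
        return float(np.sqrt(thermal_variance_A2(self.k, self.temperature)))


def _ou_path(rng: np.random.Generator, n: int, mean: float, sd: float,
             phi: float, x0: float | None = None) -> np.ndarray:
    """Exact discrete-time OU path: AR(1) with decay factor ``phi``.

    The update x_{t+1} = mean + phi (x_t - mean) + sd·sqrt(1-phi²)·ξ is the
    exact transition density of the OU process at lag dt, so stationarity
    holds at any dt (no Euler discretisation bias).  ``x0`` defaults to a
    draw from the stationary distribution.
    """
    innov = rng.standard_normal(n)
    innov[1:] *= sd * np.sqrt(1.0 - phi * phi)
    if x0 is None:
        innov[0] *= sd
    else:
        innov[0] = x0 - mean
    centred = lfilter([1.0], [1.0, -phi], innov)
    return mean + centred


def simulate_ou_series(params: OUParams,
                       x0: float | None = None,
                       replicate: int | None = None) -> DistanceSeries:
    """Simulate a stationary OU end-to-end distance series.

    The series has mean ``params.mean``, stationary variance k_B·T/k
    (in Å²) and autocorrelation time ``params.tau``.  ``x0`` overrides
    the stationary initial draw (used for relaxation traces).
    """
    rng = np.random.default_rng(params.seed)
    phi = float(np.exp(-params.dt / params.tau))
    values = _ou_path(rng, params.n_frames, params.mean,
                      params.stationary_sd_A, phi, x0=x0)
    times = params.dt * np.arange(params.n_frames)
    return DistanceSeries(times=times, values=values,
                          label="end_to_end", replicate=replicate)


@dataclass(frozen=True)
class MixtureSimSpec:
    """A mixture of OU components with Markov state switching.

    components : list of (OUParams, weight); weights sum to 1 and set the
        stationary occupancy of each latent state.  All components must
        share temperature, dt and n_frames.
    switch_rate : per-ps probability of a latent-state change attempt; on
        a switch the coordinate re-equilibrates from the new component's
        stationary distribution.
    """

    components: tuple
    switch_rate: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.components) == 0:
            raise ParameterError("at least one component required")
        weights = np.array([w for _, w in self.components], dtype=float)
        if np.any(weights <= 0):
            raise ParameterError("component weights must be positive")
        if abs(weights.sum() - 1.0) > 1e-9:
            raise ParameterError(
                f"weights must sum to 1 (got {weights.sum():.12f})")
        ref = self.components[0][0]
        for p, _ in self.components[1:]:
            if (p.temperature, p.dt, p.n_frames) != (ref.temperature, ref.dt, ref.n_frames):
                raise ParameterError(
                    "all components must share temperature, dt and n_frames")
        if self.switch_rate < 0:
            raise ParameterError("switch_rate must be non-negative")

    @property
    def weights(self) -> np.ndarray:
        return np.array([w for _, w in self.components], dtype=float)


def simulate_mixture_series(spec: MixtureSimSpec,
                            replicate: int | None = None) -> DistanceSeries:
    """Simulate a state-switching OU mixture with latent-state labels.

    The latent state is a discrete-time Markov chain: at each step a
    switch event occurs with probability ``switch_rate·dt``; on an event
    the new state is drawn from the component weights (possibly the same
    state), which makes the weights the exact stationary occupancies.
    Within a state the coordinate follows that component's OU dynamics,
    re-equilibrated from the component's stationary distribution at each
    entry.
    """
    rng = np.random.default_rng(spec.seed)
    ref = spec.components[0][0]
    n, dt = ref.n_frames, ref.dt
    p_switch = min(1.0, spec.switch_rate * dt)
    weights = spec.weights

    states = np.empty(n, dtype=int)
    states[0] = rng.choice(len(weights), p=weights)
    if p_switch > 0 and len(weights) > 1:
        events = rng.random(n) < p_switch
        events[0] = False
        idx = np.flatnonzero(events)
        draws = rng.choice(len(weights), size=len(idx), p=weights)
        # piecewise-constant fill between events
        states[:] = states[0]
        for start, s in zip(idx, draws):
            states[start:] = s
    else:
        states[:] = states[0]

    values = np.empty(n, dtype=float)
    # contiguous same-state segments; re-equilibrate at each entry
    boundaries = np.flatnonzero(np.diff(states)) + 1
    seg_starts = np.concatenate([[0], boundaries])
    seg_ends = np.concatenate([boundaries, [n]])
    for lo, hi in zip(seg_starts, seg_ends):
        params = spec.components[states[lo]][0]
        phi = float(np.exp(-dt / params.tau))
        values[lo:hi] = _ou_path(rng, hi - lo, params.mean,
                                 params.stationary_sd_A, phi)
    times = dt * np.arange(n)
    return DistanceSeries(times=times, values=values, label="end_to_end",
                          states=states, replicate=replicate)


# ---------------------------------------------------------------------------
# idealised helix / solenoid coordinates
# ---------------------------------------------------------------------------

# textbook α-helix: 1.5 Å rise and 100° turn per residue, Cα radius 2.3 Å
HELIX_RISE_PER_RES = 1.5
HELIX_TWIST_PER_RES = 100.0
HELIX_CA_RADIUS = 2.3

# internal superhelix radius for solenoid placement (Å)
_SUPERHELIX_RADIUS = 15.0

_BACKBONE_ATOMS = (
    # name, element, radius (Å), phase offset (deg), z offset (Å)
    ("N", "N", 1.75, -28.0, -0.85),
    ("CA", "C", HELIX_CA_RADIUS, 0.0, 0.0),
    ("C", "C", 1.70, 27.0, 0.95),
    ("O", "O", 2.00, 25.0, 2.00),
)


def _ideal_helix_atoms(n_res: int) -> tuple[list[tuple[str, str, int]], np.ndarray]:
    """Backbone atoms of an ideal α-helix along +z starting at residue 1."""
    names: list[tuple[str, str, int]] = []
    coords = []
    for i in range(n_res):
        theta0 = np.deg2rad(HELIX_TWIST_PER_RES * i)
        z0 = HELIX_RISE_PER_RES * i
        for name, elem, radius, phase, dz in _BACKBONE_ATOMS:
            theta = theta0 + np.deg2rad(phase)
            coords.append([radius * np.cos(theta), radius * np.sin(theta), z0 + dz])
            names.append((name, elem, i + 1))
        # placeholder side-chain anchor so χ1-style fixtures have a CB
        theta = theta0 + np.deg2rad(-120.0)
        coords.append([3.3 * np.cos(theta), 3.3 * np.sin(theta), z0 + 0.5])
        names.append(("CB", "C", i + 1))
    return names, np.asarray(coords, dtype=float)


def _make_structure(names: list[tuple[str, str, int]], coords: np.ndarray,
                    res_name: str = "ALA", chain: str = "A",
                    metadata: dict | None = None) -> StructureModel:
    from biotite.structure.info import mass as element_mass
    atom_names = np.array([n for n, _, _ in names], dtype="U6")
    elements = np.array([e for _, e, _ in names], dtype="U2")
    res_ids = np.array([r for _, _, r in names], dtype=int)
    masses = np.array([element_mass(e) for e in elements], dtype=float)
    return StructureModel(
        atom_names=atom_names, elements=elements, res_ids=res_ids,
        res_names=np.full(len(names), res_name, dtype="U5"),
        chain_ids=np.full(len(names), chain, dtype="U4"),
        coords=coords, masses=masses, metadata=metadata or {})


def build_kinked_helix(n_res: int, kink_position: int,
                       kink_angle: float) -> StructureModel:
    """Ideal α-helix whose axis direction changes by ``kink_angle`` degrees.

    Residues are numbered 1..n_res; residues with number > ``kink_position``
    are rotated about an axis perpendicular to the helix axis through the
    Cα of the kink residue, so the downstream local helix axis is tilted
    by exactly ``kink_angle``.  ``kink_angle = 0`` gives a straight helix.
    """
    if not (0 < kink_position < n_res):
        raise ParameterError(
            f"kink_position must be in (0, {n_res}), got {kink_position}")
    if not (0 <= kink_angle < 90):
        raise ParameterError(f"kink_angle must be in [0, 90), got {kink_angle}")
    names, coords = _ideal_helix_atoms(n_res)
    res_ids = np.array([r for _, _, r in names])
    if kink_angle > 0:
        pivot = coords[(res_ids == kink_position)
                       & (np.array([n for n, _, _ in names]) == "CA")][0]
        rot = Rotation.from_rotvec(np.deg2rad(kink_angle) * np.array([1.0, 0, 0]))
        move = res_ids > kink_position
        coords[move] = rot.apply(coords[move] - pivot) + pivot
    meta = {"kink_angle": float(kink_angle), "kink_position": int(kink_position),
            "n_res": int(n_res)}
    return _make_structure(names, coords, metadata=meta)


@dataclass(frozen=True)
class KinkSpec:
    """A helix kink to inject into one repeat unit of a solenoid."""
    unit: int          # 0-based repeat index
    helix: str         # "A" or "B"
    residue: int       # 1-based position within that helix
    angle: float       # degrees

    def __post_init__(self) -> None:
        if self.helix not in ("A", "B"):
            raise ParameterError("kink helix must be 'A' or 'B'")
        if not (0 <= self.angle < 90):
            raise ParameterError(f"kink angle must be in [0, 90), got {self.angle}")


@dataclass(frozen=True)
class SolenoidSpec:
    """An idealised α-solenoid: helix-hairpin units on a regular superhelix.

    Each repeat unit is a pair of antiparallel ideal α-helices
    (``residues_per_helix`` residues each, contiguously numbered); units
    are placed at superhelix radius with ``superhelical_rise`` Å and
    ``superhelical_twist`` degrees between consecutive units.
    ``intra_repeat_distance`` is the target Cα(Ψ1)–Cα(Ψ30) distance,
    realised by adjusting the helix-pair separation.
    """

    n_repeats: int
    residues_per_helix: int = 12
    superhelical_rise: float = 8.0
    superhelical_twist: float = 15.0
    intra_repeat_distance: float = 10.0
    kink: Optional[KinkSpec] = None

    def __post_init__(self) -> None:
        if self.n_repeats < 2:
            raise ParameterError(f"n_repeats must be >= 2, got {self.n_repeats}")
        if self.residues_per_helix < 5:
            raise ParameterError("residues_per_helix must be >= 5")
        if self.superhelical_rise <= 0:
            raise ParameterError("superhelical_rise must be positive")
        if self.intra_repeat_distance <= 0:
            raise ParameterError("intra_repeat_distance must be positive")
        if self.kink is not None:
            if not (0 <= self.kink.unit < self.n_repeats):
                raise ParameterError("kink unit index out of range")
            if not (0 < self.kink.residue <= self.residues_per_helix):
                raise ParameterError("kink residue out of range")

    @property
    def unit_length(self) -> int:
        return 2 * self.residues_per_helix


def _build_unit(spec: SolenoidSpec) -> tuple[list[tuple[str, str, int]], np.ndarray]:
    """One helix-hairpin unit in its local frame (residues 1..2·rph)."""
    rph = spec.residues_per_helix

    def assemble(sep: float) -> tuple[list, np.ndarray]:
        names_a, coords_a = _ideal_helix_atoms(rph)
        names_b, coords_b = _ideal_helix_atoms(rph)
        # helix B: antiparallel (180° about x), displaced by sep in x,
        # aligned so its top meets helix A's top (hairpin)
        flip = np.diag([1.0, -1.0, -1.0])
        coords_b = coords_b @ flip.T
        coords_b[:, 0] += sep
        coords_b[:, 2] += HELIX_RISE_PER_RES * (rph - 1)
        names_b = [(n, e, r + rph) for n, e, r in names_b]
        return names_a + names_b, np.vstack([coords_a, coords_b])

    def intra_distance(sep: float) -> float:
        names, coords = assemble(sep)
        ca1 = _atom(names, coords, 1, "CA")
        ca30 = _atom(names, coords, 2 * rph, "CA")
        return float(np.linalg.norm(ca30 - ca1))

    lo, hi = 0.05, 80.0
    f_lo = intra_distance(lo) - spec.intra_repeat_distance
    f_hi = intra_distance(hi) - spec.intra_repeat_distance
    if f_lo * f_hi > 0:
        raise ParameterError(
            f"intra_repeat_distance {spec.intra_repeat_distance} Å is not "
            "achievable for this helix geometry")
    sep = brentq(lambda s: intra_distance(s) - spec.intra_repeat_distance, lo, hi,
                 xtol=1e-9)
    names, coords = assemble(sep)

    if spec.kink is not None:
        k = spec.kink
        # local residue number of the kink residue within the unit
        res = k.residue if k.helix == "A" else rph + k.residue
        res_ids = np.array([r for _, _, r in names])
        atom_names = np.array([n for n, _, _ in names])
        pivot = coords[(res_ids == res) & (atom_names == "CA")][0]
        # helix axis is ±z in the local frame for both helices; rotate the
        # part of the kinked helix downstream of the kink residue
        helix_lo = 1 if k.helix == "A" else rph + 1
        helix_hi = rph if k.helix == "A" else 2 * rph
        move = (res_ids > res) & (res_ids >= helix_lo) & (res_ids <= helix_hi)
        rot = Rotation.from_rotvec(np.deg2rad(k.angle) * np.array([1.0, 0, 0]))
        coords = coords.copy()
        coords[move] = rot.apply(coords[move] - pivot) + pivot
    return names, coords


def _atom(names: list, coords: np.ndarray, res_id: int, atom: str) -> np.ndarray:
    for (n, _, r), xyz in zip(names, coords):
        if r == res_id and n == atom:
            return xyz
    raise KeyError(f"atom {atom} of residue {res_id} not found")


def build_solenoid(spec: SolenoidSpec) -> StructureModel:
    """Build an idealised α-solenoid and record descriptor ground truth.

    The returned model's ``metadata`` holds the exact values of every
    descriptor the structure was built with: per-unit intra-repeat
    distances, consecutive inter-repeat centre-of-mass distances,
    inter-repeat (B-A'-B') angles, the end-to-end distance between the
    first and last unit's centres of mass, and the injected kink angle.
    Raises on geometrically impossible specs (steric self-intersection).
    """
    unit_names, unit_coords = _build_unit(spec)
    # orient helix axes tangentially (local z -> y), as in a real solenoid
    # where repeat helices run roughly perpendicular to the superhelix axis;
    # this keeps consecutive units from interpenetrating at realistic rises
    unit_coords = unit_coords[:, [0, 2, 1]] * np.array([1.0, 1.0, -1.0])
    unit_len = spec.unit_length
    names: list[tuple[str, str, int]] = []
    coords_list = []
    for u in range(spec.n_repeats):
        theta = np.deg2rad(spec.superhelical_twist * u)
        rot = np.array([[np.cos(theta), -np.sin(theta), 0.0],
                        [np.sin(theta), np.cos(theta), 0.0],
                        [0.0, 0.0, 1.0]])
        placed = (unit_coords + np.array([_SUPERHELIX_RADIUS, 0.0, 0.0])) @ rot.T
        placed[:, 2] += spec.superhelical_rise * u
        coords_list.append(placed)
        names.extend((n, e, r + u * unit_len) for n, e, r in unit_names)
    coords = np.vstack(coords_list)

    model = _make_structure(names, coords)
    _check_no_self_intersection(model, spec)

    ann = solenoid_annotation(spec)
    masses = model.masses
    truth: dict = {
        "intra_repeat_distance": {},
        "inter_repeat_distance": {},
        "inter_repeat_angle": {},
    }
    coms = []
    for unit in ann.units:
        mask = model.select(res_id_range=(unit.start, unit.end))
        com = (masses[mask, None] * coords[mask]).sum(0) / masses[mask].sum()
        coms.append(com)
        ca1 = coords[model.select(res_id=unit.consensus[1], atom_name="CA")][0]
        ca30 = coords[model.select(res_id=unit.consensus[30], atom_name="CA")][0]
        truth["intra_repeat_distance"][unit.unit_id] = float(
            np.linalg.norm(ca30 - ca1))
    for prev, cur, com_p, com_c in zip(ann.units, ann.units[1:], coms, coms[1:]):
        pair = f"{prev.unit_id}-{cur.unit_id}"
        truth["inter_repeat_distance"][pair] = float(np.linalg.norm(com_c - com_p))
        b_prev = coords[model.select(res_id=prev.consensus[30], atom_name="CA")][0]
        a_cur = coords[model.select(res_id=cur.consensus[1], atom_name="CA")][0]
        b_cur = coords[model.select(res_id=cur.consensus[30], atom_name="CA")][0]
        v1, v2 = b_prev - a_cur, b_cur - a_cur
        cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        truth["inter_repeat_angle"][cur.unit_id] = float(
            np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    truth["end_to_end_distance"] = float(np.linalg.norm(coms[-1] - coms[0]))
    if spec.kink is not None:
        truth["kink_angle"] = float(spec.kink.angle)
        truth["kink"] = {"unit": spec.kink.unit, "helix": spec.kink.helix,
                         "residue": spec.kink.residue}
    truth["spec"] = {
        "n_repeats": spec.n_repeats,
        "residues_per_helix": spec.residues_per_helix,
        "superhelical_rise": spec.superhelical_rise,
        "superhelical_twist": spec.superhelical_twist,
        "intra_repeat_distance": spec.intra_repeat_distance,
    }
    model.metadata.update(truth)
    return model


def _check_no_self_intersection(model: StructureModel, spec: SolenoidSpec,
                                cutoff: float = 1.2) -> None:
    """Reject structures whose non-bonded Cα atoms come closer than cutoff."""
    ca = model.coords[model.atom_names == "CA"]
    res = model.res_ids[model.atom_names == "CA"]
    d = np.linalg.norm(ca[:, None, :] - ca[None, :, :], axis=-1)
    sep = np.abs(res[:, None] - res[None, :])
    bad = (d < cutoff) & (sep > 1)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ParameterError(
            f"solenoid spec is geometrically impossible: residues {res[i]} and "
            f"{res[j]} clash ({d[i, j]:.2f} Å apart)")


def solenoid_annotation(spec: SolenoidSpec) -> RepeatAnnotation:
    """Repeat annotation matching :func:`build_solenoid` numbering.

    Units are named R1..Rn; Ψ1 maps to the first residue of helix A and
    Ψ30 to the last residue of helix B.
    """
    rph = spec.residues_per_helix
    units = []
    for u in range(spec.n_repeats):
        start = u * spec.unit_length + 1
        end = start + spec.unit_length - 1
        units.append(RepeatUnit(
            unit_id=f"R{u + 1}", start=start, end=end,
            helix_a=(start, start + rph - 1),
            helix_b=(start + rph, end),
            consensus={1: start, 30: end},
        ))
    return RepeatAnnotation(units)


def perturb_to_trajectory(structure: StructureModel, amplitude: float,
                          n_frames: int, seed: int,
                          frame_spacing_ps: float = 1.0) -> CoordinateTrajectory:
    """Add i.i.d. Gaussian coordinate noise of SD ``amplitude`` per frame.

    Amplitude 0 reproduces the input structure in every frame; a fixed
    seed gives a bit-identical trajectory on rerun.
    """
    if amplitude < 0:
        raise ParameterError(f"amplitude must be >= 0, got {amplitude}")
    if n_frames < 1:
        raise ParameterError(f"n_frames must be >= 1, got {n_frames}")
    rng = np.random.default_rng(seed)
    base = structure.coords[None, :, :]
    if amplitude == 0:
        frames = np.repeat(base, n_frames, axis=0)
    else:
        frames = base + rng.normal(0.0, amplitude,
                                   size=(n_frames,) + structure.coords.shape)
    times = frame_spacing_ps * np.arange(n_frames)
    return CoordinateTrajectory(structure, frames, times)
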