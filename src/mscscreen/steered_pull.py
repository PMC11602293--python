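"""Desk-scale steered-pulling simulator with adaptive acceleration control.

A ligand is pulled out of a receptor pocket by a constant external
acceleration applied to every ligand atom along the continuously updated
receptor→ligand centre-of-mass direction. The controller adapts the
acceleration with three rules:

* **stagnation** — if the maximum receptor–ligand COM separation has not
  increased for ``stagnation_window`` steps (default 400), raise the
  acceleration by ``a_increment`` (default 500 pm/ps²);
* **speed throttle** — every ``scale_check_interval`` steps (default 20),
  if the maximum separation grew faster than ``speed_cap`` (default
  4000 m/s), scale the acceleration by ``1 − (1 − cap/v)²``;
* **floor** — the acceleration never drops below ``a_min``
  (default 2000 pm/ps²).

The run terminates once the ligand COM has moved ``stop_displacement``
(default 15 Å) from its position at the start of the pull. Pulling force is
reported in pN via ``F = m·a`` with the conversion constant 0.00166 pN per
(Da·pm/ps²); work is the path integral of that force along the pull
direction, in pN·Å.

Internal unit system: Å, ps, Da (hence energies in Da·Å²/ps²); the
controller's acceleration is kept in pm/ps² (1 pm/ps² = 0.01 Å/ps²) and
COM-separation growth speeds in m/s (1 Å/ps = 100 m/s), matching the
protocol constants.

The force field is deliberately minimal: 12-6 Lennard-Jones pairs between
receptor and ligand atoms (Lorentz–Berthelot combination, 10 Å cutoff),
harmonic intra-ligand bonds, a rigid receptor, and no electrostatics. The
controller — the part worth testing — is agnostic to these choices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from mscscreen.errors import ClashError, NonTerminationError
from mscscreen.structure_io import Structure

__all__ = [
    "PullProtocol",
    "PullSystem",
    "PullState",
    "PullResult",
    "build_system",
    "update_acceleration",
    "force_from_acceleration",
    "run_pull",
    "prolonged_contacts",
    "APOLAR_RESIDUES",
]

#: 1 pm/ps² in Å/ps²
PM_PS2_TO_A_PS2 = 0.01
#: 1 Å/ps in m/s
A_PER_PS_TO_M_PER_S = 100.0
#: Boltzmann constant in Da·Å²/ps²/K
KB = 0.83144626

#: residues treated as apolar for hydrophobic-contact detection
APOLAR_RESIDUES = {"ALA", "VAL", "LEU", "ILE", "PHE", "MET", "PRO", "TRP", "GLY"}


@dataclass
class PullProtocol:
    """Controller constants and run parameters (defaults as used for the
    AprY–substrate pulls)."""

    a_min: float = 2000.0  # pm/ps²
    a_increment: float = 500.0  # pm/ps²
    stagnation_window: int = 400  # steps
    speed_cap: float = 4000.0  # m/s
    scale_check_interval: int = 20  # steps
    stop_displacement: float = 15.0  # Å
    equilibration_time: float = 3.0  # ps
    timestep: float = 0.00125  # ps (1.25 fs)
    force_conversion: float = 0.00166  # pN per (Da·pm/ps²)
    temperature: float = 298.0  # K, for initial Maxwell-Boltzmann velocities
    contact_cutoff: float = 5.0  # Å, apolar-pair recording cutoff
    max_steps: int = 2_000_000  # hard non-termination guard

    def __post_init__(self) -> None:
        positive = {
            "a_min": self.a_min, "a_increment": self.a_increment,
            "stagnation_window": self.stagnation_window,
            "speed_cap": self.speed_cap,
            "scale_check_interval": self.scale_check_interval,
            "stop_displacement": self.stop_displacement,
            "timestep": self.timestep,
            "force_conversion": self.force_conversion,
            "contact_cutoff": self.contact_cutoff,
            "max_steps": self.max_steps,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if self.a_increment > self.a_min:
            raise ValueError("a_increment must not exceed a_min")
        if self.equilibration_time < 0 or self.temperature < 0:
            raise ValueError("equilibration_time and temperature must be >= 0")


@dataclass
class PullSystem:
    """A rigid receptor plus a mobile ligand with toy LJ interactions."""

    receptor_positions: np.ndarray  # (R, 3) Å, fixed
    receptor_residue_ids: np.ndarray  # (R,)
    receptor_apolar: np.ndarray  # (R,) bool
    receptor_sigma: np.ndarray  # (R,) Å
    receptor_epsilon: np.ndarray  # (R,) Da·Å²/ps²
    ligand_positions: np.ndarray  # (L, 3) Å
    ligand_masses: np.ndarray  # (L,) Da
    ligand_apolar: np.ndarray  # (L,) bool
    ligand_sigma: np.ndarray  # (L,) Å
    ligand_epsilon: np.ndarray  # (L,) Da·Å²/ps²
    bonds: list = field(default_factory=list)  # (i, j, r0 Å, k Da/ps²)
    nonbonded_cutoff: float = 10.0  # Å

    def __post_init__(self) -> None:
        for name in ("receptor_positions", "ligand_positions"):
            arr = np.asarray(getattr(self, name), dtype=float).reshape(-1, 3)
            setattr(self, name, arr)
        for name in ("receptor_residue_ids", "receptor_apolar", "receptor_sigma",
                     "receptor_epsilon", "ligand_masses", "ligand_apolar",
                     "ligand_sigma", "ligand_epsilon"):
            setattr(self, name, np.asarray(getattr(self, name)))
        if self.nonbonded_cutoff <= 0:
            raise ValueError("nonbonded_cutoff must be positive")
        if self.ligand_masses.sum() <= 0:
            raise ValueError("ligand total mass must be positive")

    @property
    def n_receptor(self) -> int:
        return len(self.receptor_positions)

    @property
    def n_ligand(self) -> int:
        return len(self.ligand_positions)

    @property
    def ligand_mass(self) -> float:
        return float(self.ligand_masses.sum())

    def receptor_com(self) -> np.ndarray:
        """Receptor centre (unweighted); the origin for an empty receptor."""
        if self.n_receptor == 0:
            return np.zeros(3)
        return self.receptor_positions.mean(axis=0)


@dataclass
class PullState:
    """Mutable integrator/controller state during a pull."""

    positions: np.ndarray  # ligand positions (L, 3)
    velocities: np.ndarray  # (L, 3) Å/ps
    current_acceleration: float  # pm/ps²
    max_com_distance: float  # Å, non-decreasing
    steps_since_max_increase: int = 0
    step_index: int = 0
    pull_direction: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    max_distance_at_last_check: float = 0.0


@dataclass
class PullResult:
    """Outcome of one pull run."""

    peak_force: float  # pN
    total_work: float  # pN·Å
    displacement_series: np.ndarray  # Å per pull step
    acceleration_series: np.ndarray  # pm/ps² per pull step
    contact_timeline: list  # per step: list of (receptor_residue, ligand_atom, distance)
    termination_time: float  # ps of pull phase
    n_steps: int
    ligand_mass: float  # Da


def build_system(receptor: Structure | None, ligand_spec: dict, params: dict | None = None) -> PullSystem:
    """Assemble a :class:`PullSystem` from a receptor structure and a ligand
    specification.

    ``ligand_spec`` keys: ``positions`` (required), ``masses``, ``apolar``,
    ``sigma``, ``epsilon``, ``bonds``. Receptor atoms get apolar flags from
    their residue names (:data:`APOLAR_RESIDUES`); ``params`` may override
    per-class LJ parameters (``sigma``, ``epsilon``, ``nonbonded_cutoff``)
    or supply explicit receptor arrays (``receptor_apolar``,
    ``receptor_epsilon``).

    Raises :class:`~mscscreen.errors.ClashError` when any receptor–ligand
    pair sits closer than half its combined LJ sigma.
    """
    params = dict(params or {})
    sigma0 = float(params.get("sigma", 3.5))
    epsilon0 = float(params.get("epsilon", 10.0))

    lig_pos = np.asarray(ligand_spec["positions"], dtype=float).reshape(-1, 3)
    n_lig = len(lig_pos)
    lig_masses = np.asarray(ligand_spec.get("masses", np.full(n_lig, 100.0)), dtype=float)
    lig_apolar = np.asarray(ligand_spec.get("apolar", np.ones(n_lig, bool)), dtype=bool)
    lig_sigma = np.asarray(ligand_spec.get("sigma", np.full(n_lig, sigma0)), dtype=float)
    lig_eps = np.asarray(ligand_spec.get("epsilon", np.full(n_lig, epsilon0)), dtype=float)
    bonds = list(ligand_spec.get("bonds", []))

    if receptor is None or (hasattr(receptor, "n_atoms") and receptor.n_atoms == 0):
        rec_pos = np.empty((0, 3))
        rec_res = np.empty(0, dtype=int)
        rec_apolar = np.empty(0, dtype=bool)
    else:
        rec_pos = receptor.coordinates
        rec_res = receptor.atom_residue_ids
        name_by_id = dict(zip(receptor.residue_ids, receptor.residue_names))
        rec_apolar = np.array(
            [name_by_id[int(r)] in APOLAR_RESIDUES for r in rec_res], dtype=bool)
    if "receptor_apolar" in params:
        rec_apolar = np.asarray(params["receptor_apolar"], dtype=bool)
    rec_sigma = np.asarray(params.get("receptor_sigma", np.full(len(rec_pos), sigma0)), dtype=float)
    rec_eps = np.asarray(params.get("receptor_epsilon", np.full(len(rec_pos), epsilon0)), dtype=float)

    system = PullSystem(
        receptor_positions=rec_pos,
        receptor_residue_ids=rec_res,
        receptor_apolar=rec_apolar,
        receptor_sigma=rec_sigma,
        receptor_epsilon=rec_eps,
        ligand_positions=lig_pos,
        ligand_masses=lig_masses,
        ligand_apolar=lig_apolar,
        ligand_sigma=lig_sigma,
        ligand_epsilon=lig_eps,
        bonds=bonds,
        nonbonded_cutoff=float(params.get("nonbonded_cutoff", 10.0)),
    )
    _check_clashes(system)
    return system


def _check_clashes(system: PullSystem) -> None:
    if system.n_receptor == 0:
        return
    diff = system.ligand_positions[:, None, :] - system.receptor_positions[None, :, :]
    dist = np.linalg.norm(diff, axis=2)
    sigma = 0.5 * (system.ligand_sigma[:, None] + system.receptor_sigma[None, :])
    clashes = np.argwhere(dist < 0.5 * sigma)
    if len(clashes):
        raise ClashError([(int(i), int(j)) for i, j in clashes])


def update_acceleration(state: PullState, protocol: PullProtocol) -> float:
    """Apply the controller rules and return the new acceleration (pm/ps²).

    Mutates ``state``: resets the stagnation counter after an increment and
    records the max separation seen at a scale-check step.
    """
    acceleration = state.current_acceleration
    if state.steps_since_max_increase >= protocol.stagnation_window:
        acceleration += protocol.a_increment
        state.steps_since_max_increase = 0
    if state.step_index > 0 and state.step_index % protocol.scale_check_interval == 0:
        window = protocol.scale_check_interval * protocol.timestep  # ps
        growth = state.max_com_distance - state.max_distance_at_last_check  # Å
        speed = growth / window * A_PER_PS_TO_M_PER_S  # m/s
        state.max_distance_at_last_check = state.max_com_distance
        if speed > protocol.speed_cap:
            acceleration *= 1.0 - (1.0 - protocol.speed_cap / speed) ** 2
    return max(acceleration, protocol.a_min)


def force_from_acceleration(mass: float, acceleration: float,
                            conversion: float = 0.00166) -> float:
    """Pulling force in pN from F = m·a (mass in Da, a in pm/ps²)."""
    if mass <= 0:
        raise ValueError("mass must be positive")
    return mass * acceleration * conversion


def _internal_forces(system: PullSystem, positions: np.ndarray) -> np.ndarray:
    """LJ receptor→ligand forces plus harmonic intra-ligand bond forces,
    in Da·Å/ps²."""
    forces = np.zeros_like(positions)
    if system.n_receptor:
        diff = positions[:, None, :] - system.receptor_positions[None, :, :]  # (L,R,3)
        dist = np.linalg.norm(diff, axis=2)
        sigma = 0.5 * (system.ligand_sigma[:, None] + system.receptor_sigma[None, :])
        eps = np.sqrt(system.ligand_epsilon[:, None] * system.receptor_epsilon[None, :])
        within = dist <= system.nonbonded_cutoff
        safe = np.where(dist > 1e-9, dist, 1e-9)
        sr6 = (sigma / safe) ** 6
        # dU/dr of 4ε[(σ/r)^12 − (σ/r)^6]; force on ligand atom points along +diff
        magnitude = 24.0 * eps * (2.0 * sr6**2 - sr6) / safe
        magnitude = np.where(within, magnitude, 0.0)
        forces += np.sum(magnitude[:, :, None] * diff / safe[:, :, None], axis=1)
    for i, j, r0, k in system.bonds:
        rij = positions[j] - positions[i]
        r = np.linalg.norm(rij)
        if r < 1e-12:
            continue
        f = k * (r - r0) * rij / r
        forces[i] += f
        forces[j] -= f
    return forces


def run_pull(system: PullSystem, protocol: PullProtocol | None = None,
             seed: int | None = 0) -> PullResult:
    """Velocity-Verlet pull run under the adaptive controller.

    ``seed`` feeds the Maxwell–Boltzmann initial velocities (zero when
    ``protocol.temperature`` is 0, making the run fully deterministic).
    After ``equilibration_time`` without external force, the external
    acceleration is applied to every ligand atom along the receptor→ligand
    COM unit vector (updated every step) until the ligand COM has moved
    ``stop_displacement`` from its pull-start position.
    """
    protocol = protocol or PullProtocol()
    rng = np.random.default_rng(seed)
    positions = system.ligand_positions.copy()
    masses = system.ligand_masses.astype(float)
    if protocol.temperature > 0:
        sd = np.sqrt(KB * protocol.temperature / masses)
        velocities = rng.normal(size=positions.shape) * sd[:, None]
    else:
        velocities = np.zeros_like(positions)

    dt = protocol.timestep
    rec_com = system.receptor_com()

    def com(pos: np.ndarray) -> np.ndarray:
        return np.average(pos, axis=0, weights=masses)

    # equilibration: internal forces only
    forces = _internal_forces(system, positions)
    for _ in range(int(round(protocol.equilibration_time / dt))):
        accel = forces / masses[:, None]
        positions = positions + velocities * dt + 0.5 * accel * dt**2
        new_forces = _internal_forces(system, positions)
        velocities = velocities + 0.5 * (accel + new_forces / masses[:, None]) * dt
        forces = new_forces

    start_com = com(positions)
    direction = start_com - rec_com
    norm = np.linalg.norm(direction)
    direction = direction / norm if norm > 1e-9 else np.array([1.0, 0.0, 0.0])

    state = PullState(
        positions=positions,
        velocities=velocities,
        current_acceleration=protocol.a_min,
        max_com_distance=float(np.linalg.norm(start_com - rec_com)),
        pull_direction=direction,
        max_distance_at_last_check=float(np.linalg.norm(start_com - rec_com)),
    )

    apolar_pairs = None
    if system.n_receptor:
        apolar_pairs = np.outer(system.ligand_apolar, system.receptor_apolar)

    displacement_series: list[float] = []
    acceleration_series: list[float] = []
    contact_timeline: list[list] = []
    peak_force = 0.0
    total_work = 0.0
    previous_com = start_com
    displacement = 0.0

    while displacement < protocol.stop_displacement:
        if state.step_index >= protocol.max_steps:
            raise NonTerminationError(
                f"pull exceeded {protocol.max_steps} steps at displacement "
                f"{displacement:.2f} Å (stop at {protocol.stop_displacement} Å)")
        state.current_acceleration = update_acceleration(state, protocol)
        external = (state.current_acceleration * PM_PS2_TO_A_PS2) * state.pull_direction
        force = force_from_acceleration(
            system.ligand_mass, state.current_acceleration, protocol.force_conversion)
        peak_force = max(peak_force, force)

        accel = forces / masses[:, None] + external
        positions = positions + velocities * dt + 0.5 * accel * dt**2
        new_forces = _internal_forces(system, positions)
        velocities = velocities + 0.5 * (accel + (new_forces / masses[:, None] + external)) * dt
        forces = new_forces
        state.positions = positions
        state.velocities = velocities

        current_com = com(positions)
        total_work += force * float(np.dot(current_com - previous_com, state.pull_direction))
        previous_com = current_com

        com_distance = float(np.linalg.norm(current_com - rec_com))
        if com_distance > state.max_com_distance:
            state.max_com_distance = com_distance
            state.steps_since_max_increase = 0
        else:
            state.steps_since_max_increase += 1

        new_direction = current_com - rec_com
        norm = np.linalg.norm(new_direction)
        if norm > 1e-9:
            state.pull_direction = new_direction / norm

        displacement = float(np.linalg.norm(current_com - start_com))
        displacement_series.append(displacement)
        acceleration_series.append(state.current_acceleration)
        if apolar_pairs is not None:
            diff = positions[:, None, :] - system.receptor_positions[None, :, :]
            dist = np.linalg.norm(diff, axis=2)
            hits = np.argwhere(apolar_pairs & (dist <= protocol.contact_cutoff))
            contact_timeline.append([
                (int(system.receptor_residue_ids[j]), int(i), float(dist[i, j]))
                for i, j in hits
            ])
        else:
            contact_timeline.append([])
        state.step_index += 1

    return PullResult(
        peak_force=peak_force,
        total_work=total_work,
        displacement_series=np.array(displacement_series),
        acceleration_series=np.array(acceleration_series),
        contact_timeline=contact_timeline,
        termination_time=state.step_index * dt,
        n_steps=state.step_index,
        ligand_mass=system.ligand_mass,
    )


def prolonged_contacts(result: PullResult, contact_cutoff: float = 5.0,
                       persistence_fraction: float = 0.5) -> set[int]:
    """Receptor residues whose apolar contact with any ligand atom persists
    in at least ``persistence_fraction`` of the pull steps.

    ``contact_cutoff`` may tighten (not widen) the cutoff the timeline was
    recorded with, since recorded pairs carry their distances.
    """
    n_steps = len(result.contact_timeline)
    if n_steps == 0:
        return set()
    step_counts: dict[int, int] = {}
    for step in result.contact_timeline:
        seen = {res for res, _atom, dist in step if dist <= contact_cutoff}
        for res in seen:
            step_counts[res] = step_counts.get(res, 0) + 1
    return {res for res, count in step_counts.items()
            if count / n_steps >= persistence_fraction}
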