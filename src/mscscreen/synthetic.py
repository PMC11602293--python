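"""Synthetic inputs with known ground truth for every pipeline stage.

Generators are pure functions of (spec, seed):

* two-temperature trajectories where residue *i* jitters isotropically
  about a fixed backbone with per-coordinate Gaussian sd σᵢ (scaled at the
  high temperature), so the expected RMSF is exactly σᵢ·√3;
* alignments with a prescribed modal residue and modal frequency per
  column (modal frequency 1.0 → a strictly conserved column, grade 9);
* receptor–ligand pull systems with planted "sticky" apolar residues laid
  along the ligand exit path, so prolonged-contact detection has a known
  answer;
* noisy Michaelis–Menten and thermal-inactivation measurement series from
  the characterized variant presets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mscscreen.errors import GenerationError
from mscscreen.kinetics import VARIANT_PRESETS, michaelis_menten
from mscscreen.steered_pull import PullSystem, _check_clashes
from mscscreen.structure_io import MSA, TrajectoryEnsemble

__all__ = [
    "FlexibilitySpec",
    "KineticsSpec",
    "gen_trajectory",
    "gen_trajectory_pair",
    "gen_msa",
    "gen_pull_system",
    "gen_kinetic_series",
    "helical_backbone",
]


@dataclass
class FlexibilitySpec:
    """Ground truth for a two-temperature trajectory pair.

    ``sigma`` is the per-residue, per-coordinate positional sd (Å) at the
    low temperature; ``high_scale`` multiplies it at the high temperature.
    A scale > 1 plants a positive ΔRMSF of σ·√3·(scale − 1).
    """

    sigma: np.ndarray  # (n_residues,) Å
    high_scale: np.ndarray  # (n_residues,) dimensionless
    n_frames: int = 2000
    seed: int = 0
    temperatures: tuple[float, float] = (298.0, 328.0)
    residue_ids: list[int] | None = None

    def __post_init__(self) -> None:
        self.sigma = np.atleast_1d(np.asarray(self.sigma, dtype=float))
        self.high_scale = np.atleast_1d(np.asarray(self.high_scale, dtype=float))
        if len(self.high_scale) == 1 and len(self.sigma) > 1:
            self.high_scale = np.full_like(self.sigma, self.high_scale[0])
        if np.any(self.sigma <= 0) or np.any(self.high_scale <= 0):
            raise ValueError("sigma and high_scale must be positive")
        if len(self.sigma) != len(self.high_scale):
            raise ValueError("sigma and high_scale must have equal length")
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        if self.residue_ids is None:
            self.residue_ids = list(range(1, len(self.sigma) + 1))


@dataclass
class KineticsSpec:
    """Ground truth for synthetic kinetic measurement series.

    Default design points follow the assay layout: substrate levels
    log-spaced over 0.05–5 (concentration units of Km) and inactivation
    times of 10–100 min in 10-min steps.
    """

    Km: float = VARIANT_PRESETS["rAprY"]["Km"]
    kcat: float = VARIANT_PRESETS["rAprY"]["kcat"]
    enzyme_conc: float = 1.0  # amount units; Vmax = kcat * enzyme_conc
    half_life: float = VARIANT_PRESETS["rAprY"]["half_life"]  # min
    noise_sd: float = 0.0  # multiplicative Gaussian sd
    substrate_points: np.ndarray = field(
        default_factory=lambda: np.geomspace(0.05, 5.0, 8))
    decay_times: np.ndarray = field(
        default_factory=lambda: np.arange(10.0, 101.0, 10.0))
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.Km, self.kcat, self.enzyme_conc, self.half_life) <= 0:
            raise ValueError("kinetic parameters must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        self.substrate_points = np.asarray(self.substrate_points, dtype=float)
        self.decay_times = np.asarray(self.decay_times, dtype=float)

    @classmethod
    def from_preset(cls, variant: str, noise_sd: float = 0.0, seed: int = 0) -> "KineticsSpec":
        preset = VARIANT_PRESETS[variant]
        return cls(Km=preset["Km"], kcat=preset["kcat"],
                   half_life=preset["half_life"], noise_sd=noise_sd, seed=seed)

    @property
    def Vmax(self) -> float:
        return self.kcat * self.enzyme_conc


def helical_backbone(n_residues: int, radius: float = 8.0, rise: float = 1.5,
                     turn_deg: float = 100.0) -> np.ndarray:
    """Non-collinear Cα backbone (coarse helix) for synthetic trajectories."""
    angles = np.deg2rad(turn_deg) * np.arange(n_residues)
    return np.column_stack([
        radius * np.cos(angles),
        radius * np.sin(angles),
        rise * np.arange(n_residues),
    ])


def gen_trajectory(spec: FlexibilitySpec, temperature: str = "low") -> TrajectoryEnsemble:
    """One Cα trajectory with iid per-coordinate Gaussian jitter.

    ``temperature`` is "low" or "high"; the high-temperature run scales
    each residue's sd by ``spec.high_scale`` and draws from an independent
    stream of the same seed.
    """
    if temperature not in {"low", "high"}:
        raise ValueError("temperature must be 'low' or 'high'")
    sigma = spec.sigma if temperature == "low" else spec.sigma * spec.high_scale
    stream = 0 if temperature == "low" else 1
    rng = np.random.default_rng([spec.seed, stream])
    backbone = helical_backbone(len(sigma))
    jitter = rng.normal(size=(spec.n_frames, len(sigma), 3)) * sigma[None, :, None]
    return TrajectoryEnsemble(
        frames=backbone[None, :, :] + jitter,
        timestep=1.0,
        temperature=spec.temperatures[0 if temperature == "low" else 1],
        residue_ids=list(spec.residue_ids),
    )


def gen_trajectory_pair(spec: FlexibilitySpec) -> tuple[TrajectoryEnsemble, TrajectoryEnsemble]:
    """(low-T, high-T) trajectory pair from one spec."""
    return gen_trajectory(spec, "low"), gen_trajectory(spec, "high")


def gen_msa(n_sequences: int, column_specs, seed: int = 0,
            reference_id: str | None = None) -> MSA:
    """Alignment with prescribed per-column modal residue and frequency.

    ``column_specs`` is a sequence of ``(modal_residue, modal_frequency)``
    with frequencies in [1/20, 1]; the remaining mass is spread uniformly
    over the other 19 amino acids. When ``reference_id`` is given, the
    first row is replaced by the all-modal consensus under that id, so it
    can serve as an ungapped structure reference.
    """
    from mscscreen.conservation import AMINO_ACIDS

    if n_sequences < 2:
        raise ValueError("need at least 2 sequences")
    rng = np.random.default_rng(seed)
    alphabet = list(AMINO_ACIDS)
    columns = []
    for modal, freq in column_specs:
        modal = modal.upper()
        if modal not in AMINO_ACIDS:
            raise ValueError(f"unknown amino acid {modal!r}")
        if not (1.0 / 20.0 - 1e-12 <= freq <= 1.0 + 1e-12):
            raise ValueError(f"modal frequency {freq} outside [1/20, 1]")
        probs = np.full(20, (1.0 - freq) / 19.0)
        probs[alphabet.index(modal)] = freq
        probs /= probs.sum()
        columns.append(rng.choice(alphabet, size=n_sequences, p=probs))
    rows = ["".join(col[i] for col in columns) for i in range(n_sequences)]
    ids = [f"seq{i + 1:04d}" for i in range(n_sequences)]
    if reference_id is not None:
        rows[0] = "".join(modal.upper() for modal, _ in column_specs)
        ids[0] = reference_id
    return MSA(sequence_ids=ids, aligned_rows=rows)


def gen_pull_system(
    n_receptor: int = 30,
    n_ligand: int = 5,
    sticky_residues=(),
    seed: int = 0,
    ligand_mass: float = 624.24,
    sticky_epsilon: float = 4000.0,
    base_epsilon: float = 10.0,
    sigma: float = 3.5,
    max_attempts: int = 50,
) -> PullSystem:
    """Receptor–ligand system with planted sticky apolar residues.

    The receptor body is a clash-free blob of polar atoms near the origin;
    the ligand (total mass ``ligand_mass`` Da, all atoms apolar) sits 8 Å
    out along +x, which is therefore the pull exit direction. Each sticky
    residue contributes a three-atom apolar rail laid parallel to the exit
    path at ~4 Å lateral offset.

    Atom classes set the Lennard-Jones well depths: apolar atoms (the
    ligand and sticky rails) carry ``sticky_epsilon`` (Da·Å²/ps²; the
    default is ~16 kBT at 298 K, so the pairwise well survives thermal
    equilibration and the maximum LJ restoring force exceeds the pull
    force at the minimum acceleration — the stagnation rule must escalate
    before the ligand escapes), polar body atoms carry ``base_epsilon``.
    Pair depths combine geometrically, so polar–apolar pairs stay weak.
    """
    sticky_residues = sorted(set(int(r) for r in sticky_residues))
    if any(r < 1 or r > n_receptor for r in sticky_residues):
        raise GenerationError(
            f"sticky residues {sticky_residues} outside receptor 1..{n_receptor}")
    lanes = [np.array(v, dtype=float) for v in
             [(0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]]
    ligand_centre = np.array([8.0, 0.0, 0.0])

    for attempt in range(max_attempts):
        rng = np.random.default_rng([seed, attempt])
        rec_pos, rec_res, rec_apolar, rec_eps = [], [], [], []
        lane_cursor = 0
        for residue in range(1, n_receptor + 1):
            if residue in sticky_residues:
                lane = lanes[lane_cursor % len(lanes)]
                lane_cursor += 1
                for along in (0.0, 3.0, 6.0):
                    rec_pos.append(ligand_centre + np.array([along, 0.0, 0.0]) + 4.0 * lane)
                    rec_res.append(residue)
                    rec_apolar.append(True)
                    rec_eps.append(sticky_epsilon)
            else:
                # polar body atom in a ball of radius 4 behind the pocket mouth
                point = rng.normal(size=3)
                point *= rng.uniform(0.0, 4.0) / np.linalg.norm(point)
                rec_pos.append(point - np.array([2.0, 0.0, 0.0]))
                rec_res.append(residue)
                rec_apolar.append(False)
                rec_eps.append(base_epsilon)

        lig_pos = ligand_centre + 0.9 * _ligand_offsets(n_ligand)
        masses = np.full(n_ligand, ligand_mass / n_ligand)
        bonds = []
        for i in range(n_ligand - 1):
            r0 = float(np.linalg.norm(lig_pos[i + 1] - lig_pos[i]))
            bonds.append((i, i + 1, r0, 10000.0))

        system = PullSystem(
            receptor_positions=np.array(rec_pos) if rec_pos else np.empty((0, 3)),
            receptor_residue_ids=np.array(rec_res, dtype=int),
            receptor_apolar=np.array(rec_apolar, dtype=bool),
            receptor_sigma=np.full(len(rec_pos), sigma),
            receptor_epsilon=np.array(rec_eps, dtype=float),
            ligand_positions=lig_pos,
            ligand_masses=masses,
            ligand_apolar=np.ones(n_ligand, dtype=bool),
            ligand_sigma=np.full(n_ligand, sigma),
            ligand_epsilon=np.full(n_ligand, sticky_epsilon),
            bonds=bonds,
        )
        try:
            _check_clashes(system)
        except Exception:
            continue
        return system
    raise GenerationError(
        f"could not place a clash-free system in {max_attempts} attempts")


def _ligand_offsets(n: int) -> np.ndarray:
    """Small non-collinear cluster offsets for the ligand atoms."""
    base = np.array([
        [0.0, 0.0, 0.0],
        [1.0, 0.0, 0.0],
        [0.0, 1.0, 0.0],
        [0.0, 0.0, 1.0],
        [1.0, 1.0, 0.0],
        [1.0, 0.0, 1.0],
        [0.0, 1.0, 1.0],
        [1.0, 1.0, 1.0],
    ])
    if n > len(base):
        raise GenerationError(f"at most {len(base)} ligand atoms supported, got {n}")
    offsets = base[:n]
    return offsets - offsets.mean(axis=0)


def gen_kinetic_series(spec: KineticsSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Michaelis–Menten and thermal-inactivation measurement tables.

    Returns ``(mm_table, decay_table)`` with columns ``substrate``/``rate``
    and ``time``/``activity``. Noise is multiplicative Gaussian
    (value·(1 + N(0, sd))); the tables are exact when ``noise_sd`` is 0.
    """
    rng = np.random.default_rng(spec.seed)
    rates = michaelis_menten(spec.substrate_points, spec.Vmax, spec.Km)
    k = np.log(2.0) / spec.half_life
    activities = 100.0 * np.exp(-k * spec.decay_times)
    if spec.noise_sd > 0:
        rates = rates * (1.0 + rng.normal(scale=spec.noise_sd, size=rates.shape))
        activities = activities * (1.0 + rng.normal(scale=spec.noise_sd, size=activities.shape))
        rates = np.clip(rates, 1e-12, None)
        activities = np.clip(activities, 1e-12, 100.0)
    mm_table = pd.DataFrame({"substrate": spec.substrate_points, "rate": rates})
    decay_table = pd.DataFrame({"time": spec.decay_times, "activity": activities})
    return mm_table, decay_table
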