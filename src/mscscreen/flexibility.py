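"""Per-residue flexibility and trajectory summaries.

The central quantity is the root-mean-square fluctuation (RMSF) of each
residue's Cα about its time-mean position, computed separately at a low and
a high simulation temperature; their difference ΔRMSF (high − low) marks
heat-labile sites. The module also provides the auxiliary per-frame
summaries typically reported alongside (RMSD vs a reference, radius of
gyration, hydrogen-bond counts, solvent-accessible surface area).

The first half of every trajectory is discarded as equilibration by
default (``equilibration_fraction = 0.5``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from mscscreen.errors import (
    DegenerateSuperpositionError,
    InsufficientFramesError,
    ResidueAlignmentError,
)
from mscscreen.structure_io import TrajectoryEnsemble

__all__ = [
    "RMSFProfile",
    "FlexibilityComparison",
    "TrajectorySummary",
    "kabsch_superpose",
    "compute_rmsf",
    "delta_rmsf",
    "radius_of_gyration",
    "count_hydrogen_bonds",
    "shrake_rupley_sasa",
    "summarize_trajectory",
]


@dataclass
class RMSFProfile:
    """Per-residue RMSF (Å) at one temperature."""

    residue_ids: list[int]
    rmsf_values: np.ndarray
    temperature: float | None = None
    equilibration_fraction: float = 0.5

    def __post_init__(self) -> None:
        self.rmsf_values = np.asarray(self.rmsf_values, dtype=float)
        if len(self.residue_ids) != len(self.rmsf_values):
            raise ValueError("one RMSF value per residue required")
        if np.any(self.rmsf_values < 0):
            raise ValueError("RMSF values must be non-negative")
        if not 0 <= self.equilibration_fraction < 1:
            raise ValueError("equilibration_fraction must lie in [0, 1)")


@dataclass
class FlexibilityComparison:
    """Per-residue ΔRMSF = RMSF(high T) − RMSF(low T); may be negative."""

    residue_ids: list[int]
    delta_rmsf: np.ndarray
    temperatures: tuple[float | None, float | None] = (None, None)  # (low, high)

    def __post_init__(self) -> None:
        self.delta_rmsf = np.asarray(self.delta_rmsf, dtype=float)
        if len(self.residue_ids) != len(self.delta_rmsf):
            raise ValueError("one ΔRMSF value per residue required")

    def as_dict(self) -> dict[int, float]:
        return dict(zip(self.residue_ids, self.delta_rmsf.tolist()))


@dataclass
class TrajectorySummary:
    """Per-frame scalar series over a trajectory."""

    rmsd_series: np.ndarray  # Å vs reference frame
    rg_series: np.ndarray  # Å
    hbond_count_series: np.ndarray | None = None
    sasa_series: np.ndarray | None = None


def kabsch_superpose(mobile_frame, reference_frame, atom_mask=None):
    """Least-squares rigid superposition of ``mobile_frame`` onto
    ``reference_frame``.

    The optimal proper rotation (det = +1) is found on the masked atoms;
    the transform is applied to the whole frame. Returns
    ``(aligned_frame, rmsd)`` with the RMSD evaluated over the mask.
    """
    mobile = np.asarray(mobile_frame, dtype=float)
    reference = np.asarray(reference_frame, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError("frames must share shape")
    if atom_mask is None:
        atom_mask = np.ones(len(mobile), dtype=bool)
    atom_mask = np.asarray(atom_mask, dtype=bool)
    sel_mob = mobile[atom_mask]
    sel_ref = reference[atom_mask]
    if len(sel_mob) < 3:
        raise DegenerateSuperpositionError(
            f"superposition needs >=3 atoms, got {len(sel_mob)}")
    centroid_mob = sel_mob.mean(axis=0)
    centroid_ref = sel_ref.mean(axis=0)
    centered = sel_mob - centroid_mob
    if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
        raise DegenerateSuperpositionError("masked atoms are collinear")
    rotation, _ = Rotation.align_vectors(sel_ref - centroid_ref, centered)
    aligned = rotation.apply(mobile - centroid_mob) + centroid_ref
    rmsd = float(np.sqrt(np.mean(np.sum((aligned[atom_mask] - sel_ref) ** 2, axis=1))))
    return aligned, rmsd


def compute_rmsf(
    traj: TrajectoryEnsemble,
    equilibration_fraction: float = 0.5,
    superpose: bool = True,
) -> RMSFProfile:
    """Per-residue RMSF over the post-equilibration portion of a trajectory.

    RMSF_i = sqrt( <|x_i(t) − <x_i>|²> ) over retained frames. When
    ``superpose`` is true each retained frame is first rigid-body aligned;
    the reference is the time-mean structure obtained iteratively (align to
    the first frame, take the mean, realign to that mean, re-take the mean).
    """
    if not 0 <= equilibration_fraction < 1:
        raise ValueError("equilibration_fraction must lie in [0, 1)")
    start = int(np.floor(traj.n_frames * equilibration_fraction))
    frames = traj.frames[start:]
    if len(frames) < 2:
        raise InsufficientFramesError(
            f"{len(frames)} post-equilibration frame(s); need >=2 "
            f"(equilibration_fraction={equilibration_fraction}, "
            f"n_frames={traj.n_frames})")
    if superpose:
        frames = _align_ensemble(frames)
    mean = frames.mean(axis=0)
    sq = np.sum((frames - mean) ** 2, axis=2)  # (n_frames, n_atoms)
    rmsf = np.sqrt(sq.mean(axis=0))
    return RMSFProfile(
        residue_ids=list(traj.residue_ids),
        rmsf_values=rmsf,
        temperature=traj.temperature,
        equilibration_fraction=equilibration_fraction,
    )


def _align_ensemble(frames: np.ndarray) -> np.ndarray:
    """Two-pass iterative superposition onto the evolving mean structure."""
    reference = frames[0]
    for _ in range(2):
        aligned = np.empty_like(frames)
        for k, frame in enumerate(frames):
            aligned[k], _ = kabsch_superpose(frame, reference)
        reference = aligned.mean(axis=0)
        frames = aligned
    return frames


def delta_rmsf(profile_high: RMSFProfile, profile_low: RMSFProfile) -> FlexibilityComparison:
    """ΔRMSF = high-temperature RMSF minus low-temperature RMSF, per residue."""
    high_ids, low_ids = set(profile_high.residue_ids), set(profile_low.residue_ids)
    if high_ids != low_ids:
        diff = sorted(high_ids.symmetric_difference(low_ids))
        raise ResidueAlignmentError(
            f"profiles cover different residues; symmetric difference: {diff}")
    low_lookup = dict(zip(profile_low.residue_ids, profile_low.rmsf_values))
    deltas = np.array([
        h - low_lookup[rid]
        for rid, h in zip(profile_high.residue_ids, profile_high.rmsf_values)
    ])
    return FlexibilityComparison(
        residue_ids=list(profile_high.residue_ids),
        delta_rmsf=deltas,
        temperatures=(profile_low.temperature, profile_high.temperature),
    )


def radius_of_gyration(frame, masses=None) -> float:
    """Mass-weighted RMS distance (Å) of the atoms from their centre of mass."""
    coords = np.atleast_2d(np.asarray(frame, dtype=float))
    if coords.size == 0:
        raise ValueError("radius of gyration needs at least one atom")
    if masses is None:
        masses = np.ones(len(coords))
    masses = np.asarray(masses, dtype=float)
    if np.any(masses <= 0):
        raise ValueError("masses must be positive")
    com = np.average(coords, axis=0, weights=masses)
    sq = np.sum((coords - com) ** 2, axis=1)
    return float(np.sqrt(np.average(sq, weights=masses)))


def count_hydrogen_bonds(
    donor_positions,
    acceptor_positions,
    donor_hydrogen_positions=None,
    distance_cutoff: float = 3.5,
    angle_cutoff: float = 120.0,
) -> int:
    """Count donor–acceptor pairs that satisfy a geometric hydrogen-bond
    criterion.

    Heavy-atom mode (no hydrogens supplied): D···A distance ≤
    ``distance_cutoff`` (Å). With hydrogens, the D–H···A angle must also be
    ≥ ``angle_cutoff`` (degrees).
    """
    donors = np.atleast_2d(np.asarray(donor_positions, dtype=float)) \
        if len(donor_positions) else np.empty((0, 3))
    acceptors = np.atleast_2d(np.asarray(acceptor_positions, dtype=float)) \
        if len(acceptor_positions) else np.empty((0, 3))
    if donors.size == 0 or acceptors.size == 0:
        return 0
    diff = donors[:, None, :] - acceptors[None, :, :]
    dist = np.linalg.norm(diff, axis=2)
    within = dist <= distance_cutoff
    if donor_hydrogen_positions is None:
        return int(within.sum())
    hydrogens = np.atleast_2d(np.asarray(donor_hydrogen_positions, dtype=float))
    count = 0
    for i, j in np.argwhere(within):
        dh = donors[i] - hydrogens[i]
        ah = acceptors[j] - hydrogens[i]
        denom = np.linalg.norm(dh) * np.linalg.norm(ah)
        if denom == 0:
            continue
        angle = np.degrees(np.arccos(np.clip(np.dot(dh, ah) / denom, -1.0, 1.0)))
        if angle >= angle_cutoff:
            count += 1
    return count


def shrake_rupley_sasa(
    frame,
    radii,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
    per_atom: bool = False,
) -> float | np.ndarray:
    """Solvent-accessible surface area (Å²) by sphere-point sampling.

    Each atom is expanded by the probe radius and covered with an
    approximately uniform spherical point set (golden-spiral lattice); a
    point is exposed when it lies outside every other atom's expanded
    sphere. The SASA is the sum over atoms of the exposed point fraction
    times the expanded-sphere area; ``per_atom=True`` returns the per-atom
    contributions instead of their sum.
    """
    coords = np.atleast_2d(np.asarray(frame, dtype=float))
    radii = np.asarray(radii, dtype=float)
    if np.any(radii <= 0):
        raise ValueError("atomic radii must be positive")
    if n_sphere_points < 32:
        raise ValueError("n_sphere_points must be >= 32")
    expanded = radii + probe_radius
    sphere = _golden_spiral_points(n_sphere_points)
    areas = np.zeros(len(coords))
    for i, (centre, radius) in enumerate(zip(coords, expanded)):
        points = centre + radius * sphere
        exposed = np.ones(n_sphere_points, dtype=bool)
        for j, (other, other_radius) in enumerate(zip(coords, expanded)):
            if i == j or np.linalg.norm(centre - other) > radius + other_radius:
                continue
            buried = np.linalg.norm(points - other, axis=1) < other_radius
            exposed &= ~buried
            if not exposed.any():
                break
        areas[i] = exposed.mean() * 4.0 * np.pi * radius**2
    return areas if per_atom else float(areas.sum())


def _golden_spiral_points(n: int) -> np.ndarray:
    """~Uniform points on the unit sphere (Fibonacci lattice)."""
    indices = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * indices / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * indices
    return np.column_stack([
        np.sin(phi) * np.cos(theta),
        np.sin(phi) * np.sin(theta),
        np.cos(phi),
    ])


def summarize_trajectory(
    traj: TrajectoryEnsemble,
    reference_frame=None,
    masses=None,
    sasa_radii=None,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
) -> TrajectorySummary:
    """Per-frame RMSD (vs the first frame by default) and radius of
    gyration; SASA per frame when radii are supplied."""
    reference = traj.frames[0] if reference_frame is None else np.asarray(reference_frame)
    rmsd = np.empty(traj.n_frames)
    rg = np.empty(traj.n_frames)
    for k, frame in enumerate(traj.frames):
        _, rmsd[k] = kabsch_superpose(frame, reference)
        rg[k] = radius_of_gyration(frame, masses)
    sasa = None
    if sasa_radii is not None:
        sasa = np.array([
            shrake_rupley_sasa(frame, sasa_radii, probe_radius, n_sphere_points)
            for frame in traj.frames
        ])
    return TrajectorySummary(rmsd_series=rmsd, rg_series=rg, sasa_series=sasa)
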