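"""Readers/writers and shared containers for the formats the pipeline touches.

Conventions fixed here and respected everywhere downstream:

* coordinates are in Å;
* residue ids are 1-based author numbering as printed in the source file —
  they are never renumbered (positions like 216 or 221 are meaningful);
* trajectories are Cα-level by default, one atom per residue.

Supported formats: PDB (single- and multi-model, via Biopython), aligned
multi-FASTA, a TSV residue-annotation table, and a plain-text frames table
for trajectories (header line ``natoms nframes timestep_ps`` followed by one
``x y z`` triple per atom per frame, frames concatenated).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException, PDBConstructionWarning
from Bio import SeqIO

from mscscreen.errors import (
    AlignmentLengthError,
    EmptySelectionError,
    StructuralMismatchError,
    StructureFormatError,
)

__all__ = [
    "Structure",
    "TrajectoryEnsemble",
    "MSA",
    "ResidueTable",
    "read_structure",
    "read_trajectory",
    "write_trajectory",
    "read_msa",
    "write_msa",
    "read_residue_table",
    "write_residue_table",
    "load_apry_sites",
]


@dataclass
class Structure:
    """A single conformation with author residue numbering.

    ``residue_ids``/``residue_names`` are per residue (ordered as in the
    file); ``atom_names``/``atom_residue_ids``/``coordinates`` are per atom.
    """

    residue_ids: list[int]
    residue_names: list[str]
    atom_names: list[str]
    atom_residue_ids: np.ndarray
    coordinates: np.ndarray  # (n_atoms, 3) Å
    chain_id: str = "A"

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.atom_residue_ids = np.asarray(self.atom_residue_ids, dtype=int)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates must be finite")
        if len(self.atom_names) != len(self.coordinates):
            raise ValueError("one atom name per coordinate row required")
        if len(self.atom_residue_ids) != len(self.coordinates):
            raise ValueError("every atom must map to exactly one residue")
        ids = np.asarray(self.residue_ids)
        if ids.size and np.any(np.diff(ids) <= 0):
            raise ValueError("residue_ids must be strictly increasing within a chain")

    @property
    def n_atoms(self) -> int:
        return len(self.coordinates)

    @property
    def n_residues(self) -> int:
        return len(self.residue_ids)

    def select_atoms(self, atom_name: str = "CA") -> "Structure":
        """Subset to atoms with a given name (default Cα)."""
        mask = np.array([a == atom_name for a in self.atom_names], dtype=bool)
        if not mask.any():
            raise EmptySelectionError(f"no atoms named {atom_name!r}")
        kept_res = [int(r) for r in np.unique(self.atom_residue_ids[mask])]
        res_names = [self.residue_names[self.residue_ids.index(r)] for r in kept_res]
        return Structure(
            residue_ids=kept_res,
            residue_names=res_names,
            atom_names=[a for a, m in zip(self.atom_names, mask) if m],
            atom_residue_ids=self.atom_residue_ids[mask],
            coordinates=self.coordinates[mask],
            chain_id=self.chain_id,
        )


@dataclass
class TrajectoryEnsemble:
    """An ordered stack of coordinate snapshots over a fixed atom set."""

    frames: np.ndarray  # (n_frames, n_atoms, 3) Å
    timestep: float = 1.0  # ps per frame
    temperature: float | None = None  # K label
    atom_selection: str = "CA"
    residue_ids: list[int] | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[0] < 1:
            raise ValueError("a trajectory needs at least one frame")
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if self.residue_ids is None:
            self.residue_ids = list(range(1, self.frames.shape[1] + 1))
        elif len(self.residue_ids) != self.frames.shape[1]:
            raise ValueError("residue_ids length must equal the atom count")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]


@dataclass
class MSA:
    """An aligned set of protein sequences (rows over the 20 AAs plus '-')."""

    sequence_ids: list[str]
    aligned_rows: list[str]

    def __post_init__(self) -> None:
        if len(self.sequence_ids) != len(self.aligned_rows):
            raise ValueError("one id per aligned row required")
        lengths = {len(r) for r in self.aligned_rows}
        if len(lengths) > 1:
            bad = [i for i, r in zip(self.sequence_ids, self.aligned_rows)
                   if len(r) != len(self.aligned_rows[0])]
            raise AlignmentLengthError(f"rows have unequal lengths; offending ids: {bad}")
        self.aligned_rows = [r.upper() for r in self.aligned_rows]

    @property
    def n_sequences(self) -> int:
        return len(self.aligned_rows)

    @property
    def n_columns(self) -> int:
        return len(self.aligned_rows[0]) if self.aligned_rows else 0

    def row(self, sequence_id: str) -> str:
        try:
            return self.aligned_rows[self.sequence_ids.index(sequence_id)]
        except ValueError:
            raise KeyError(f"sequence id {sequence_id!r} not in alignment") from None


#: column order of the residue-annotation TSV
RESIDUE_TABLE_COLUMNS = ["residue", "rmsf_low", "rmsf_high", "delta", "conservation", "contact"]


@dataclass
class ResidueTable:
    """Per-residue annotations: two-temperature RMSF, ΔRMSF, conservation
    grade (1–9 or missing) and substrate-contact flag.

    Backed by a DataFrame with columns ``residue`` (int), ``rmsf_low``,
    ``rmsf_high``, ``delta`` (Å), ``conservation`` (nullable Int64) and
    ``contact`` (bool).
    """

    frame: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=RESIDUE_TABLE_COLUMNS))

    def __post_init__(self) -> None:
        df = self.frame.copy()
        for col in RESIDUE_TABLE_COLUMNS:
            if col not in df.columns:
                df[col] = pd.Series(dtype=float)
        df = df[RESIDUE_TABLE_COLUMNS]
        if len(df):
            df["residue"] = df["residue"].astype(int)
            if df["residue"].duplicated().any():
                dupes = df.loc[df["residue"].duplicated(), "residue"].tolist()
                raise ValueError(f"duplicate residue ids: {dupes}")
            df["conservation"] = _to_grade_series(df["conservation"])
            bad = df["conservation"].dropna()
            if len(bad) and not bad.between(1, 9).all():
                raise ValueError("conservation grades must lie in 1..9")
            df["contact"] = df["contact"].map(_to_bool).astype(bool)
        self.frame = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def residue_ids(self) -> list[int]:
        return self.frame["residue"].tolist()

    def contacts(self) -> set[int]:
        """Residue ids flagged as substrate contacts."""
        return set(self.frame.loc[self.frame["contact"], "residue"])

    def grades(self) -> dict[int, int | None]:
        """residue id -> conservation grade (None when missing)."""
        out: dict[int, int | None] = {}
        for _, row in self.frame.iterrows():
            g = row["conservation"]
            out[int(row["residue"])] = None if pd.isna(g) else int(g)
        return out

    def deltas(self) -> dict[int, float]:
        return dict(zip(self.frame["residue"].astype(int), self.frame["delta"].astype(float)))


def _to_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return False
    text = str(value).strip().lower()
    return text in {"1", "true", "yes", "y", "contact", "hydrophobic"}


def _to_grade_series(series: pd.Series) -> pd.Series:
    def convert(v):
        if v is None or (isinstance(v, float) and np.isnan(v)) or str(v).strip() == "":
            return pd.NA
        f = float(v)
        if f != int(f):
            raise StructureFormatError(f"non-integer conservation grade: {v!r}")
        return int(f)

    return series.map(convert).astype("Int64")


# ---------------------------------------------------------------------------
# PDB structures
# ---------------------------------------------------------------------------

def read_structure(path: str | Path, chain_filter: str | None = None) -> Structure:
    """Read a single-model PDB file, preserving author residue numbering.

    Parameters
    ----------
    path
        A parseable PDB file.
    chain_filter
        If given, keep only atoms from this chain id.
    """
    path = Path(path)
    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PDBConstructionWarning)
            pdb = parser.get_structure("structure", str(path))
    except (PDBConstructionException, ValueError) as exc:
        raise StructureFormatError(
            f"{path.name}: not a parseable PDB file ({_first_bad_pdb_line(path)})"
        ) from exc
    model = next(iter(pdb), None)
    if model is None:
        raise StructureFormatError(f"{path.name}: no models found")
    return _model_to_structure(model, chain_filter, path.name)


def _first_bad_pdb_line(path: Path) -> str:
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        rec = line[:6].strip()
        if rec in {"ATOM", "HETATM"}:
            try:
                float(line[30:38]); float(line[38:46]); float(line[46:54])
                int(line[22:26])
            except (ValueError, IndexError):
                return f"first bad line {lineno}: {line!r}"
    return "no well-formed ATOM records"


def _model_to_structure(model, chain_filter: str | None, name: str) -> Structure:
    residue_ids: list[int] = []
    residue_names: list[str] = []
    atom_names: list[str] = []
    atom_res: list[int] = []
    coords: list[np.ndarray] = []
    chain_seen = ""
    for chain in model:
        if chain_filter is not None and chain.id != chain_filter:
            continue
        chain_seen = chain.id
        for residue in chain:
            if residue.id[0].strip():  # skip waters/heteroatoms
                continue
            rid = residue.id[1]
            residue_ids.append(rid)
            residue_names.append(residue.get_resname())
            for atom in residue:
                atom_names.append(atom.get_name())
                atom_res.append(rid)
                coords.append(atom.coord.astype(float))
    if not coords:
        raise EmptySelectionError(
            f"{name}: selection empty"
            + (f" for chain {chain_filter!r}" if chain_filter else ""))
    return Structure(
        residue_ids=residue_ids,
        residue_names=residue_names,
        atom_names=atom_names,
        atom_residue_ids=np.array(atom_res),
        coordinates=np.array(coords),
        chain_id=chain_filter or chain_seen,
    )


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

def read_trajectory(
    path: str | Path,
    format_hint: str | None = None,
    timestep: float = 1.0,
    temperature: float | None = None,
    atom_selection: str = "CA",
) -> TrajectoryEnsemble:
    """Read a multi-model PDB or plain-text frames table as a trajectory.

    The format is taken from ``format_hint`` ("pdb" or "frames") or guessed
    from the file suffix (``.pdb`` → PDB, anything else → frames table).
    """
    path = Path(path)
    fmt = format_hint or ("pdb" if path.suffix.lower() in {".pdb", ".ent"} else "frames")
    if fmt == "pdb":
        frames, residue_ids = _read_multimodel_pdb(path, atom_selection)
    elif fmt == "frames":
        frames, timestep = _read_frames_table(path)
        residue_ids = None
    else:
        raise ValueError(f"unknown trajectory format {fmt!r}")
    return TrajectoryEnsemble(
        frames=frames,
        timestep=timestep,
        temperature=temperature,
        atom_selection=atom_selection,
        residue_ids=residue_ids,
    )


def _read_multimodel_pdb(path: Path, atom_selection: str):
    parser = PDBParser(PERMISSIVE=True, QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        pdb = parser.get_structure("traj", str(path))
    frames = []
    residue_ids = None
    for index, model in enumerate(pdb):
        structure = _model_to_structure(model, None, path.name)
        if atom_selection:
            structure = structure.select_atoms(atom_selection)
        if residue_ids is None:
            residue_ids = [int(r) for r in structure.atom_residue_ids]
        elif structure.n_atoms != len(residue_ids):
            raise StructuralMismatchError(
                f"{path.name}: frame {index} has {structure.n_atoms} atoms, "
                f"expected {len(residue_ids)}")
        frames.append(structure.coordinates)
    if not frames:
        raise StructureFormatError(f"{path.name}: no models found")
    return np.stack(frames), residue_ids


def _read_frames_table(path: Path):
    tokens = path.read_text().split("\n", 1)
    header = tokens[0].split()
    if len(header) != 3:
        raise StructureFormatError(
            f"{path.name}: frames header must be 'natoms nframes timestep_ps', "
            f"got {tokens[0]!r}")
    natoms, nframes = int(header[0]), int(header[1])
    timestep = float(header[2])
    body = np.loadtxt(io.StringIO(tokens[1]), dtype=float, ndmin=2)
    if body.shape != (natoms * nframes, 3):
        # report the first frame at which the atom count breaks
        bad_frame = body.shape[0] // max(natoms, 1)
        raise StructuralMismatchError(
            f"{path.name}: expected {natoms * nframes} coordinate rows "
            f"({natoms} atoms x {nframes} frames), got {body.shape[0]} "
            f"(inconsistency at or before frame {bad_frame})")
    return body.reshape(nframes, natoms, 3), timestep


def write_trajectory(traj: TrajectoryEnsemble, path: str | Path) -> None:
    """Write the plain-text frames table (lossless round-trip)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"{traj.n_atoms} {traj.n_frames} {float(traj.timestep)!r}\n")
        for frame in traj.frames:
            for x, y, z in frame:
                fh.write(f"{float(x)!r} {float(y)!r} {float(z)!r}\n")


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

def read_msa(path: str | Path) -> MSA:
    """Read an aligned multi-FASTA; rows are uppercased on read."""
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise StructureFormatError(f"{path.name}: no FASTA records found")
    return MSA(
        sequence_ids=[r.id for r in records],
        aligned_rows=[str(r.seq) for r in records],
    )


def write_msa(msa: MSA, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for sid, row in zip(msa.sequence_ids, msa.aligned_rows):
            fh.write(f">{sid}\n{row}\n")


# ---------------------------------------------------------------------------
# Residue tables
# ---------------------------------------------------------------------------

DELTA_WARN_TOL = 1e-3  # Å; stored-vs-recomputed ΔRMSF mismatch above this warns


def read_residue_table(path: str | Path) -> ResidueTable:
    """Read the TSV residue-annotation table.

    ΔRMSF is recomputed from the two RMSF columns; a stored delta differing
    by more than 1 mÅ triggers a consistency warning (not fatal). Missing
    cells are allowed for the grade and contact columns.
    """
    df = pd.read_csv(path, sep="\t", dtype={"residue": int})
    missing = [c for c in RESIDUE_TABLE_COLUMNS[:3] if c not in df.columns]
    if missing:
        raise StructureFormatError(f"residue table missing columns: {missing}")
    recomputed = df["rmsf_high"].astype(float) - df["rmsf_low"].astype(float)
    if "delta" in df.columns and df["delta"].notna().any():
        gap = (df["delta"].astype(float) - recomputed).abs()
        if (gap > DELTA_WARN_TOL).any():
            bad = df.loc[gap > DELTA_WARN_TOL, "residue"].tolist()
            warnings.warn(
                f"stored ΔRMSF differs from rmsf_high - rmsf_low by more than "
                f"{DELTA_WARN_TOL} Å at residues {bad}; using the recomputed values",
                stacklevel=2)
    df["delta"] = recomputed
    return ResidueTable(df)


def write_residue_table(table: ResidueTable, path: str | Path) -> None:
    df = table.frame.copy()
    df["contact"] = df["contact"].astype(int)
    df.to_csv(path, sep="\t", index=False, na_rep="")


def load_apry_sites() -> ResidueTable:
    """The packaged AprY active-centre residue table.

    32 residues around the catalytic triad (Asp32/His64/Ser221) with their
    RMSF at 298 K and 328 K, ΔRMSF, conservation grade (1–9, 9 = strictly
    conserved) and the steered-pull substrate-contact flag (hydrophobic
    interactions persisting along the substrate exit path at residues
    96, 126, 154 and 222).
    """
    source = resources.files("mscscreen").joinpath("data/apry_active_centre_sites.tsv")
    with resources.as_file(source) as fh:
        return read_residue_table(fh)
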