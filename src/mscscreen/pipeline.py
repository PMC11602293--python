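"""End-to-end orchestration of the MSC screen from a configuration.

Each of the three stages can be fed either from raw inputs (trajectory
pair, pull system, alignment) or from a precomputed residue table — the
latter is how a published annotation table is replayed. Exactly one source
must be configured per stage. ``run_screen`` executes flexibility →
contacts → conservation → selection, writes a deterministic report (JSON +
per-stage TSVs + a parameter log, no timestamps) and returns the
:class:`~mscscreen.selection.SelectionReport`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from mscscreen.conservation import map_columns_to_residues, score_msa
from mscscreen.errors import ConfigError, StageError
from mscscreen.flexibility import compute_rmsf, delta_rmsf
from mscscreen.selection import SelectionReport, select_candidates
from mscscreen.steered_pull import PullProtocol, prolonged_contacts, run_pull
from mscscreen.structure_io import read_msa, read_residue_table, read_trajectory
from mscscreen import synthetic

__all__ = ["ScreenConfig", "run_screen"]


@dataclass
class ScreenConfig:
    """Configuration for one screen run.

    Stage sources (exactly one per stage):

    * flexibility — ``residue_table`` or ``trajectory_low`` + ``trajectory_high``;
    * contacts — ``contacts`` (explicit residue list), ``pull_system``
      (generator keyword dict; the pull is run and prolonged contacts
      extracted), or ``residue_table`` contact flags;
    * conservation — ``msa`` + ``msa_reference`` or ``residue_table`` grades.
    """

    residue_table: str | None = None
    trajectory_low: str | None = None
    trajectory_high: str | None = None
    contacts: list[int] | None = None
    pull_system: dict | None = None
    msa: str | None = None
    msa_reference: str | None = None
    threshold: float = 0.05
    excluded_grade: int = 9
    persistence_fraction: float = 0.5
    contact_cutoff: float = 5.0
    missing_grade: str = "keep"
    equilibration_fraction: float = 0.5
    seed: int = 0
    output_dir: str | None = None
    pull_protocol: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.threshold < 0:
            raise ConfigError("threshold must be >= 0")
        have_traj = self.trajectory_low is not None or self.trajectory_high is not None
        if have_traj and (self.trajectory_low is None or self.trajectory_high is None):
            raise ConfigError("both trajectory_low and trajectory_high are required")
        if not have_traj and self.residue_table is None:
            raise ConfigError("no flexibility source: give a residue_table or a "
                              "trajectory pair")
        if have_traj and self.residue_table is not None:
            raise ConfigError("flexibility source ambiguous: residue_table and "
                              "trajectories both given")
        contact_sources = sum([
            self.contacts is not None,
            self.pull_system is not None,
        ])
        if contact_sources > 1:
            raise ConfigError("contacts source ambiguous")
        if contact_sources == 0 and self.residue_table is None:
            raise ConfigError("no contacts source: give contacts, pull_system, "
                              "or a residue_table")
        if (self.msa is None) != (self.msa_reference is None):
            raise ConfigError("msa and msa_reference must be given together")
        if self.msa is None and self.residue_table is None:
            raise ConfigError("no conservation source: give an msa or a residue_table")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScreenConfig":
        with Path(path).open() as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)


def run_screen(config: ScreenConfig) -> SelectionReport:
    """Execute the three-stage screen described by ``config``."""
    table = None
    if config.residue_table is not None:
        table = _stage("inputs", read_residue_table, config.residue_table)

    # stage: flexibility
    if config.trajectory_low is not None:
        comparison = _stage("flexibility", _compare_trajectories, config)
    else:
        comparison = table.deltas()

    # stage: contacts
    if config.contacts is not None:
        contacts = set(int(r) for r in config.contacts)
    elif config.pull_system is not None:
        contacts = _stage("contacts", _contacts_from_pull, config)
    else:
        contacts = table.contacts()

    # stage: conservation
    if config.msa is not None:
        grades = _stage("conservation", _grades_from_msa, config, comparison)
    else:
        grades = table.grades()

    report = _stage(
        "selection", select_candidates,
        comparison, contacts, grades,
        config.threshold, config.excluded_grade, config.missing_grade)

    if config.output_dir is not None:
        _write_outputs(config, comparison, contacts, grades, report)
    return report


def _stage(name: str, func, *args):
    try:
        return func(*args)
    except StageError:
        raise
    except Exception as exc:
        raise StageError(name, exc) from exc


def _compare_trajectories(config: ScreenConfig) -> dict[int, float]:
    low = read_trajectory(config.trajectory_low)
    high = read_trajectory(config.trajectory_high)
    profile_low = compute_rmsf(low, config.equilibration_fraction)
    profile_high = compute_rmsf(high, config.equilibration_fraction)
    return delta_rmsf(profile_high, profile_low).as_dict()


def _contacts_from_pull(config: ScreenConfig) -> set[int]:
    system = synthetic.gen_pull_system(seed=config.seed, **config.pull_system)
    protocol = PullProtocol(**config.pull_protocol)
    result = run_pull(system, protocol, seed=config.seed)
    return prolonged_contacts(result, config.contact_cutoff, config.persistence_fraction)


def _grades_from_msa(config: ScreenConfig, comparison: dict[int, float]) -> dict[int, int | None]:
    msa = read_msa(config.msa)
    profile = score_msa(msa)
    mapped = map_columns_to_residues(profile, msa, config.msa_reference,
                                     sorted(comparison))
    return mapped.grade_by_residue()


def _write_outputs(config, comparison, contacts, grades, report: SelectionReport) -> None:
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "report.json").write_text(report.to_json() + "\n")
    residues = sorted(comparison)
    pd.DataFrame({
        "residue": residues,
        "delta_rmsf": [comparison[r] for r in residues],
        "stage1_pass": [r in set(report.stage1_pass) for r in residues],
    }).to_csv(outdir / "stage1_flexibility.tsv", sep="\t", index=False)
    pd.DataFrame({"residue": sorted(contacts)}).to_csv(
        outdir / "stage2_contacts.tsv", sep="\t", index=False)
    pd.DataFrame({
        "residue": residues,
        "grade": [grades.get(r) if grades.get(r) is not None else "" for r in residues],
    }).to_csv(outdir / "stage3_conservation.tsv", sep="\t", index=False)
    pd.DataFrame({"residue": report.final_candidates}).to_csv(
        outdir / "final_candidates.tsv", sep="\t", index=False)
    log_lines = [
        f"threshold_A={config.threshold}",
        f"excluded_grade={config.excluded_grade}",
        f"missing_grade_policy={config.missing_grade}",
        f"persistence_fraction={config.persistence_fraction}",
        f"contact_cutoff_A={config.contact_cutoff}",
        f"equilibration_fraction={config.equilibration_fraction}",
        f"seed={config.seed}",
        f"n_input={len(report.input_residues)}",
        f"n_stage1={len(report.stage1_pass)}",
        f"n_stage2_removed={len(report.stage2_removed)}",
        f"n_stage3_removed={len(report.stage3_removed)}",
        f"n_final={len(report.final_candidates)}",
    ] + [f"note: {n}" for n in report.notes]
    (outdir / "screen.log").write_text("\n".join(log_lines) + "\n")
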