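"""Three-stage MSC candidate selection with per-stage provenance.

Stage 1 keeps residues whose ΔRMSF (high T − low T) is strictly greater
than a threshold (default 0.05 Å). Stage 2 removes residues with prolonged
substrate contact during the steered pull. Stage 3 removes strictly
conserved residues (grade 9 by default). The report records every input
residue exactly once — kept, or removed with the stage and reason.

For the AprY active-centre table this yields 20 stage-1 survivors and 13
final candidates; one flagged contact residue (222) never passes stage 1
and is logged rather than double-counted, which is why the naive
"20 − 4 contacts" intermediate bookkeeping does not add up.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from mscscreen.errors import ConfigError
from mscscreen.flexibility import FlexibilityComparison
from mscscreen.structure_io import ResidueTable

__all__ = [
    "SelectionReport",
    "flexibility_filter",
    "select_candidates",
    "select_from_table",
]


@dataclass
class SelectionReport:
    """Outcome of the three-stage selection.

    Invariant: ``final_candidates = stage1_pass − stage2_removed −
    stage3_removed`` and ``final ⊆ stage1 ⊆ input``.
    """

    input_residues: list[int]
    stage1_pass: list[int]
    stage2_removed: list[int]
    stage3_removed: list[int]
    final_candidates: list[int]
    threshold: float
    excluded_grade: int
    missing_grade_policy: str
    removal_log: dict[int, str] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        expected = sorted(set(self.stage1_pass)
                          - set(self.stage2_removed)
                          - set(self.stage3_removed))
        if sorted(self.final_candidates) != expected:
            raise ValueError("final candidates inconsistent with stage sets")

    def to_dict(self) -> dict:
        return {
            "parameters": {
                "threshold": self.threshold,
                "excluded_grade": self.excluded_grade,
                "missing_grade_policy": self.missing_grade_policy,
            },
            "input_residues": sorted(self.input_residues),
            "stage1_pass": sorted(self.stage1_pass),
            "stage2_removed": sorted(self.stage2_removed),
            "stage3_removed": sorted(self.stage3_removed),
            "final_candidates": sorted(self.final_candidates),
            "removal_log": {str(k): v for k, v in sorted(self.removal_log.items())},
            "notes": self.notes,
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        kwargs.setdefault("sort_keys", True)
        return json.dumps(self.to_dict(), **kwargs)


def flexibility_filter(comparison: FlexibilityComparison | dict,
                       threshold: float = 0.05) -> set[int]:
    """Residues with ΔRMSF strictly greater than ``threshold`` (Å)."""
    deltas = comparison.as_dict() if isinstance(comparison, FlexibilityComparison) \
        else dict(comparison)
    return {rid for rid, d in deltas.items() if d > threshold}


def select_candidates(
    comparison: FlexibilityComparison | dict,
    contacts: set[int],
    grades: dict[int, int | None],
    threshold: float = 0.05,
    excluded_grade: int = 9,
    missing_grade: str = "keep",
) -> SelectionReport:
    """Run the full three-stage selection.

    Parameters
    ----------
    comparison
        ΔRMSF per residue (Å), high minus low temperature.
    contacts
        Residues with prolonged substrate contact (stage-2 removal).
    grades
        Conservation grade per residue (1–9), ``None`` for unknown.
    threshold
        Stage-1 ΔRMSF cut (strict inequality), Å.
    excluded_grade
        Grade treated as strictly conserved (stage-3 removal).
    missing_grade
        "keep" (default: exclusion requires positive evidence of strict
        conservation) or "drop" (conservative: unknown grades removed).
    """
    if missing_grade not in {"keep", "drop"}:
        raise ConfigError(f"missing_grade must be 'keep' or 'drop', got {missing_grade!r}")
    deltas = comparison.as_dict() if isinstance(comparison, FlexibilityComparison) \
        else dict(comparison)
    input_residues = sorted(deltas)
    removal_log: dict[int, str] = {}
    notes: list[str] = []

    stage1 = flexibility_filter(deltas, threshold)
    for rid in input_residues:
        if rid not in stage1:
            removal_log[rid] = (f"stage1: ΔRMSF {deltas[rid]:.3f} Å "
                                f"<= threshold {threshold} Å")

    stage2_removed = sorted(stage1 & set(contacts))
    for rid in stage2_removed:
        removal_log[rid] = "stage2: prolonged substrate contact"
    orphan_contacts = sorted(set(contacts) - stage1)
    for rid in orphan_contacts:
        notes.append(f"contact residue {rid} not in stage-1 set "
                     f"(ΔRMSF {deltas.get(rid, float('nan')):.3f} Å); no removal recorded")

    survivors = stage1 - set(stage2_removed)
    stage3_removed = []
    for rid in sorted(survivors):
        grade = grades.get(rid)
        if grade is None:
            if missing_grade == "drop":
                stage3_removed.append(rid)
                removal_log[rid] = "stage3: conservation grade unknown (policy=drop)"
            else:
                notes.append(f"residue {rid} has no conservation grade; kept (policy=keep)")
        elif grade == excluded_grade:
            stage3_removed.append(rid)
            removal_log[rid] = f"stage3: strictly conserved (grade {grade})"

    final = sorted(survivors - set(stage3_removed))
    return SelectionReport(
        input_residues=input_residues,
        stage1_pass=sorted(stage1),
        stage2_removed=stage2_removed,
        stage3_removed=stage3_removed,
        final_candidates=final,
        threshold=threshold,
        excluded_grade=excluded_grade,
        missing_grade_policy=missing_grade,
        removal_log=removal_log,
        notes=notes,
    )


def select_from_table(
    table: ResidueTable,
    threshold: float = 0.05,
    excluded_grade: int = 9,
    missing_grade: str = "keep",
) -> SelectionReport:
    """Run the selection using a residue table's own ΔRMSF, contact flags
    and grades (the worked-example path)."""
    return select_candidates(
        comparison=table.deltas(),
        contacts=table.contacts(),
        grades=table.grades(),
        threshold=threshold,
        excluded_grade=excluded_grade,
        missing_grade=missing_grade,
    )
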