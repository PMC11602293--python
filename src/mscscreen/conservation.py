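"""Per-column conservation scoring on the 1–9 grade scale.

The screening pipeline excludes strictly conserved residues (grade 9) from
mutagenesis. Phylogenetic rate estimation (the ConSurf/Rate4Site approach)
is out of scope here; this module uses an entropy-based stand-in with
absolute anchoring: a perfectly conserved column scores 1.0 (grade 9) and a
uniformly distributed column scores 0.0 (grade 1). Absolute anchoring —
rather than percentile binning — keeps the grade-9 exclusion rule
meaningful on any alignment. Published grade tables are therefore consumed
as data where available, never recomputed.

Grade convention: 9 = most conserved (the exclusion criterion), 1 = most
variable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from mscscreen.errors import MappingError
from mscscreen.structure_io import MSA

__all__ = [
    "ConservationProfile",
    "column_conservation",
    "grade_conservation",
    "map_columns_to_residues",
    "score_msa",
    "AMINO_ACIDS",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: columns with a gap fraction above this are flagged low-confidence
GAP_FLAG_FRACTION = 0.5


@dataclass
class ConservationProfile:
    """Per-column raw conservation scores in [0, 1] and 1–9 grades.

    ``raw_scores`` is NaN and ``grades`` is 0 for undefined (all-gap)
    columns; ``low_confidence`` flags columns with >50% gaps.
    ``residue_ids`` is populated by :func:`map_columns_to_residues`.
    """

    column_indices: list[int]
    raw_scores: np.ndarray
    grades: np.ndarray
    low_confidence: np.ndarray
    residue_ids: list[int] | None = None

    def grade_by_residue(self) -> dict[int, int | None]:
        if self.residue_ids is None:
            raise MappingError("profile has no residue mapping; call "
                               "map_columns_to_residues first")
        return {rid: (int(g) if g > 0 else None)
                for rid, g in zip(self.residue_ids, self.grades)}


def column_conservation(msa: MSA) -> tuple[np.ndarray, np.ndarray]:
    """Raw per-column conservation scores.

    For each column, s = 1 − H/ln(20) with H the Shannon entropy of the
    amino-acid frequency distribution (gaps excluded). All-gap columns get
    NaN. Returns ``(scores, gap_fractions)``.
    """
    if msa.n_sequences < 2:
        raise ValueError("conservation scoring needs >=2 sequences")
    n_cols = msa.n_columns
    scores = np.full(n_cols, np.nan)
    gap_fractions = np.zeros(n_cols)
    max_entropy = np.log(len(AMINO_ACIDS))
    for col in range(n_cols):
        letters = [row[col] for row in msa.aligned_rows]
        residues = [c for c in letters if c != "-"]
        gap_fractions[col] = 1.0 - len(residues) / len(letters)
        if not residues:
            continue
        _, counts = np.unique(residues, return_counts=True)
        freqs = counts / counts.sum()
        entropy = float(-np.sum(freqs * np.log(freqs)))
        scores[col] = 1.0 - entropy / max_entropy
    return scores, gap_fractions


def grade_conservation(raw_scores) -> np.ndarray:
    """Bin raw scores onto integer grades: grade = 1 + round(8·s).

    Missing (NaN) scores map to 0, meaning "no grade".
    """
    scores = np.asarray(raw_scores, dtype=float)
    grades = np.zeros(scores.shape, dtype=int)
    defined = ~np.isnan(scores)
    if np.any((scores[defined] < -1e-9) | (scores[defined] > 1 + 1e-9)):
        raise ValueError("raw scores must lie in [0, 1]")
    grades[defined] = 1 + np.rint(8.0 * np.clip(scores[defined], 0.0, 1.0)).astype(int)
    return grades


def score_msa(msa: MSA) -> ConservationProfile:
    """Score every column and grade it; convenience wrapper."""
    scores, gap_fractions = column_conservation(msa)
    return ConservationProfile(
        column_indices=list(range(msa.n_columns)),
        raw_scores=scores,
        grades=grade_conservation(scores),
        low_confidence=gap_fractions > GAP_FLAG_FRACTION,
    )


def map_columns_to_residues(
    profile: ConservationProfile,
    msa: MSA,
    reference_id: str,
    structure_residue_ids,
) -> ConservationProfile:
    """Attach structure residue ids to alignment columns via a reference row.

    The i-th non-gap position of the reference row corresponds to the i-th
    structure residue id. Columns where the reference is gapped are dropped
    from the returned profile.
    """
    reference = msa.row(reference_id)
    ungapped_cols = [c for c, letter in enumerate(reference) if letter != "-"]
    structure_residue_ids = list(structure_residue_ids)
    if len(ungapped_cols) != len(structure_residue_ids):
        raise MappingError(
            f"reference {reference_id!r} has {len(ungapped_cols)} residues "
            f"but the structure has {len(structure_residue_ids)}")
    keep = np.array(ungapped_cols, dtype=int)
    return ConservationProfile(
        column_indices=[profile.column_indices[c] for c in keep],
        raw_scores=profile.raw_scores[keep],
        grades=profile.grades[keep],
        low_confidence=profile.low_confidence[keep],
        residue_ids=structure_residue_ids,
    )
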