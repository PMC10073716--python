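"""Sequence-context analysis of citrullination sites.

Each Cit site contributes a ±10-residue window anchored on the modified Arg.
Windows are stacked with no gaps (they are fixed-length and pre-anchored by
construction; a general aligner would add nothing but nondeterminism), padded
at protein termini with ``-`` which scores 0 and is excluded from consensus
denominators.  Column scoring uses the BLOSUM62 substitution matrix
(sum-of-pairs); column conservation uses a Jalview/AMAS-style 0-11 score
counting physicochemical property classes uniformly present or absent down
the column, with 11 reserved for full identity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

import pandas as pd
from Bio.Align import substitution_matrices

from .io_formats import DomainAnnotation

FLANK = 10
GAP = "-"

BLOSUM62 = substitution_matrices.load("BLOSUM62")

#: Physicochemical property classes (Livingstone & Barton style) used by the
#: 0-11 conservation score.  A column scores one point per class whose
#: membership is uniform (all residues in, or all out); an identical column
#: scores the full 11.
PROPERTY_CLASSES: Dict[str, frozenset] = {
    "hydrophobic": frozenset("ACFGHIKLMTVWY"),
    "polar": frozenset("CDEHKNQRSTWY"),
    "small": frozenset("ACDGNPSTV"),
    "proline": frozenset("P"),
    "aliphatic": frozenset("ILV"),
    "aromatic": frozenset("FHWY"),
    "positive": frozenset("HKR"),
    "negative": frozenset("DE"),
    "charged": frozenset("DEHKR"),
    "tiny": frozenset("AGS"),
    "buried": frozenset("ACFILMVW"),
}

MAX_CONSERVATION = 11

#: Consensus shading thresholds (strict), as percent agreement.
SHADE_MID_THRESHOLD = 60.0
SHADE_LIGHT_THRESHOLD = 40.0


@dataclass(frozen=True)
class SequenceWindow:
    """±flank residue context of a Cit site; center residue is always R."""

    protein_accession: str
    center: int  # 1-based position of the Cit Arg in the protein
    window: str  # verbatim substring, truncated at protein termini
    flank_left: int  # number of residues left of the center in `window`

    @property
    def flank_right(self) -> int:
        return len(self.window) - self.flank_left - 1

    @property
    def truncated(self) -> bool:
        return len(self.window) < 2 * FLANK + 1


@dataclass(frozen=True)
class ConsensusColumn:
    offset: int  # -flank .. +flank relative to the center
    modal_residue: str | None  # None on an all-gap column
    agreement: float  # % of non-gap rows sharing the modal residue (NaN if all-gap)
    conservation_score: int  # 0-11
    shade: str  # "mid" | "light" | "none"
    mark: str  # consensus logo character; "+" marks non-conserved columns


def extract_window(sequence: str, center: int, flank: int = FLANK,
                   accession: str = "") -> SequenceWindow:
    """Extract the ±flank window around a Cit Arg (1-based *center*)."""
    if not 1 <= center <= len(sequence):
        raise ValueError(f"center {center} outside sequence of length {len(sequence)}")
    if sequence[center - 1] != "R":
        raise ValueError(
            f"center residue is {sequence[center - 1]!r}, not R: Cit windows only")
    lo = max(1, center - flank)
    hi = min(len(sequence), center + flank)
    return SequenceWindow(
        protein_accession=accession,
        center=center,
        window=sequence[lo - 1:hi],
        flank_left=center - lo,
    )


def _pad(window: SequenceWindow, flank: int = FLANK) -> str:
    return (GAP * (flank - window.flank_left) + window.window
            + GAP * (flank - window.flank_right))


@dataclass(frozen=True)
class WindowAlignment:
    """Center-anchored, gap-free stack of padded windows."""

    rows: Tuple[str, ...]  # each of length 2*flank + 1
    column_scores: Tuple[float, ...]  # BLOSUM62 sum-of-pairs per column
    flank: int = FLANK

    @property
    def total_score(self) -> float:
        return sum(self.column_scores)


def _column_sum_of_pairs(chars: Sequence[str]) -> float:
    score = 0.0
    for i in range(len(chars)):
        if chars[i] == GAP:
            continue
        for j in range(i + 1, len(chars)):
            if chars[j] == GAP:
                continue
            score += BLOSUM62[chars[i], chars[j]]
    return score


def align_windows(windows: Sequence[SequenceWindow],
                  flank: int = FLANK) -> WindowAlignment:
    """Anchor windows on the center residue and score columns with BLOSUM62.

    Gap (terminal padding) positions score 0 and never pair.
    """
    if len(windows) < 2:
        raise ValueError("need at least 2 windows to align")
    for w in windows:
        if w.flank_left > flank or w.flank_right > flank:
            raise ValueError(f"window at {w.protein_accession}:{w.center} exceeds "
                             f"flank {flank}")
    rows = tuple(_pad(w, flank) for w in windows)
    width = 2 * flank + 1
    column_scores = tuple(
        _column_sum_of_pairs([row[i] for row in rows]) for i in range(width))
    return WindowAlignment(rows=rows, column_scores=column_scores, flank=flank)


def conservation_score(residues: Sequence[str]) -> int:
    """Jalview/AMAS-style 0-11 physicochemical conservation of one column."""
    residues = [r for r in residues if r != GAP]
    if not residues:
        return 0
    if len(set(residues)) == 1:
        return MAX_CONSERVATION
    score = sum(
        1 for members in PROPERTY_CLASSES.values()
        if len({r in members for r in residues}) == 1)
    return min(score, MAX_CONSERVATION - 1)


def consensus(alignment: WindowAlignment) -> List[ConsensusColumn]:
    """Per-column modal residue, % agreement, shading and conservation.

    Terminal-padding gaps are excluded from agreement denominators so
    truncated windows do not dilute the consensus.
    """
    out: List[ConsensusColumn] = []
    width = 2 * alignment.flank + 1
    for i in range(width):
        offset = i - alignment.flank
        chars = [row[i] for row in alignment.rows]
        residues = [c for c in chars if c != GAP]
        if not residues:
            out.append(ConsensusColumn(offset, None, math.nan, 0, "none", " "))
            continue
        counts: Dict[str, int] = {}
        for r in residues:
            counts[r] = counts.get(r, 0) + 1
        modal = min(counts, key=lambda r: (-counts[r], r))  # ties: lexicographic
        agreement = 100.0 * counts[modal] / len(residues)
        if agreement > SHADE_MID_THRESHOLD:
            shade = "mid"
        elif agreement > SHADE_LIGHT_THRESHOLD:
            shade = "light"
        else:
            shade = "none"
        mark = modal if shade != "none" else "+"
        out.append(ConsensusColumn(
            offset=offset, modal_residue=modal, agreement=agreement,
            conservation_score=conservation_score(chars), shade=shade, mark=mark))
    return out


def consensus_table(columns: Sequence[ConsensusColumn]) -> pd.DataFrame:
    return pd.DataFrame([{
        "offset": c.offset, "modal_residue": c.modal_residue or "",
        "agreement": c.agreement, "conservation": c.conservation_score,
        "shade": c.shade, "mark": c.mark,
    } for c in columns])


def has_consensus(columns: Sequence[ConsensusColumn]) -> bool:
    """True iff any non-center column exceeds the light-shade threshold.

    This is the package's reading of "no consensus at all": no flanking
    position reaches even >40% agreement.
    """
    return any(c.offset != 0 and not math.isnan(c.agreement)
               and c.agreement > SHADE_LIGHT_THRESHOLD for c in columns)


def domain_overlap(accession: str, position: int,
                   domains: Sequence[DomainAnnotation]) -> List[Tuple[str, bool]]:
    """For each domain annotated on the protein: (name, site inside interval)."""
    return [(d.domain_name, d.contains(position))
            for d in domains if d.protein_accession == accession]


def category_summary(categories: Mapping[str, str]) -> pd.DataFrame:
    """Per-category protein count and integer percentage.

    Every protein must carry exactly one non-empty category.  Percentages are
    rounded to the nearest integer, halves away from zero; the unrounded
    percentages sum to 100 exactly.
    """
    missing = sorted(acc for acc, cat in categories.items() if not cat)
    if missing:
        raise ValueError(f"proteins without a category: {missing}")
    if not categories:
        raise ValueError("empty category map")
    counts: Dict[str, int] = {}
    for cat in categories.values():
        counts[cat] = counts.get(cat, 0) + 1
    total = sum(counts.values())
    rows = []
    for cat in sorted(counts, key=lambda c: (-counts[c], c)):
        pct = 100.0 * counts[cat] / total
        rows.append({"category": cat, "count": counts[cat],
                     "percent": int(math.floor(pct + 0.5)),
                     "percent_exact": pct})
    return pd.DataFrame(rows, columns=["category", "count", "percent",
                                       "percent_exact"])
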