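"""Classification of mass shifts into ureido-modification classes.

Citrulline (Cit) and deamidation share the same monoisotopic delta
(+0.98402 Da: O replaces NH); they are separated here purely by residue
identity — Cit occurs on Arg, deamidation on Asn/Gln.  Homocitrulline (hCit,
Lys carbamylation) and peptide N-terminal carbamylation share +43.00581 Da
(+HNCO) and are separated by position: offset -1 means the peptide
N-terminus.  Anything else is ``Other``.  Classification is a pure function
of (residue, offset, delta, tolerance); no spectrum re-scoring is attempted.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from enum import Enum
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

from .io_formats import PSMRecord

logger = logging.getLogger(__name__)

#: Monoisotopic reference deltas (Da).
#: Cit / deamidation: O - N - H = 15.994915 - 14.003074 - 1.007825
DELTA_CIT = 0.98402
#: hCit / N-terminal carbamylation: H + C + N + O = 43.005814
DELTA_CARBAMYL = 43.00581

#: Absolute tolerance (Da) for assigning a delta to a reference class.  This
#: governs class assignment on already-searched PSMs, not the precursor-level
#: search tolerance; 0.01 Da cleanly separates the two reference deltas while
#: tolerating rounding in exported tables.
DEFAULT_TOL_DA = 0.01

DEFAULT_Q_MAX = 0.01  # identification filter: keep q < 1% FDR


class ModClass(str, Enum):
    CIT = "Cit"
    HCIT = "hCit"
    DEAMIDATION = "Deamidation"
    NTERM_CARBAMYL = "NtermCarbamyl"
    OTHER = "Other"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: The two ureido modifications proper.
UREIDO_CLASSES = (ModClass.CIT, ModClass.HCIT)


@dataclass(frozen=True)
class ModSite:
    """A classified modification site on a protein (1-based position)."""

    protein_accession: str
    position: int
    residue: str
    mod_class: ModClass
    supporting_psm_ids: Tuple[str, ...]
    flagged: bool = False  # cleavage-inconsistency flag (Cit sites only)

    @property
    def n_psms(self) -> int:
        return len(self.supporting_psm_ids)


def classify_mass_shift(residue: str, offset: int, delta_mass: float,
                        tol_da: float = DEFAULT_TOL_DA) -> ModClass:
    """Classify one mass shift.  Unmatched shifts are ``Other``, never an error."""
    if tol_da <= 0:
        raise ValueError("tol_da must be positive")
    if abs(delta_mass - DELTA_CIT) <= tol_da:
        if offset == -1:
            return ModClass.OTHER
        if residue == "R":
            return ModClass.CIT
        if residue in ("N", "Q"):
            return ModClass.DEAMIDATION
        return ModClass.OTHER
    if abs(delta_mass - DELTA_CARBAMYL) <= tol_da:
        if offset == -1:
            return ModClass.NTERM_CARBAMYL
        if residue == "K":
            return ModClass.HCIT
        return ModClass.OTHER
    return ModClass.OTHER


def classify_psm_mods(psm: PSMRecord,
                      tol_da: float = DEFAULT_TOL_DA) -> List[Tuple[int, ModClass]]:
    """Classify every mod on a PSM; returns ``[(offset, class), ...]``."""
    out = []
    for offset, delta in psm.mods:
        residue = "" if offset == -1 else psm.peptide[offset]
        out.append((offset, classify_mass_shift(residue, offset, delta, tol_da)))
    return out


def psm_has_class(psm: PSMRecord, mod_class: ModClass,
                  tol_da: float = DEFAULT_TOL_DA) -> bool:
    return any(c == mod_class for _, c in classify_psm_mods(psm, tol_da))


def map_site(psm: PSMRecord, offset: int) -> Tuple[str, int]:
    """Map a peptide-internal mod offset to (accession, 1-based protein position)."""
    if offset < 0:
        raise ValueError("peptide N-terminal mods (offset -1) have no residue position")
    if offset >= len(psm.peptide):
        raise ValueError(f"offset {offset} beyond peptide of length {len(psm.peptide)}")
    return psm.protein_accession, psm.peptide_start + offset


def filter_psms(psms: Sequence[PSMRecord],
                q_max: float = DEFAULT_Q_MAX) -> List[PSMRecord]:
    """Identification filter: keep PSMs with q-value strictly below *q_max*."""
    kept = [p for p in psms if p.q_value < q_max]
    removed = len(psms) - len(kept)
    if removed:
        logger.info("filter_psms: removed %d of %d PSMs at q >= %g",
                    removed, len(psms), q_max)
    return kept


def flag_cleavage_inconsistency(psm: PSMRecord, position: int,
                                protein_length: int | None) -> bool:
    """True iff a Cit site sits at the peptide C-terminus mid-protein.

    Trypsin does not cleave after citrullinated Arg, so a Cit call on a
    peptide's C-terminal Arg is suspect — unless the peptide ends at the
    protein C-terminus (no cleavage was needed there).  With an unknown
    protein length the site cannot be exonerated and is flagged.
    """
    peptide_end = psm.peptide_start + len(psm.peptide) - 1
    if position != peptide_end:
        return False
    if protein_length is not None and peptide_end == protein_length:
        return False
    return True


def annotate_sites(psms: Sequence[PSMRecord],
                   sequences: Mapping[str, str] | None = None,
                   tol_da: float = DEFAULT_TOL_DA) -> List[ModSite]:
    """Aggregate PSM-level mods into protein sites.

    A site's class is the modal class over its supporting PSMs; ties are
    broken by higher total supporting reporter intensity, then by
    lexicographic class name.  N-terminal carbamylation, which has no residue
    position, is anchored at the peptide's first residue.  Cit sites are
    checked for the tryptic cleavage inconsistency (flag, not removal).
    """
    votes: Dict[Tuple[str, int], Dict[ModClass, List[PSMRecord]]] = defaultdict(
        lambda: defaultdict(list))
    residues: Dict[Tuple[str, int], str] = {}
    for psm in psms:
        for offset, mod_class in classify_psm_mods(psm, tol_da):
            if mod_class is ModClass.OTHER:
                continue
            if offset == -1:
                key = (psm.protein_accession, psm.peptide_start)
                residue = psm.peptide[0]
            else:
                key = map_site(psm, offset)
                residue = psm.peptide[offset]
            if sequences is not None:
                seq = sequences.get(key[0])
                if seq is not None and seq[key[1] - 1] != residue:
                    raise ValueError(
                        f"PSM {psm.spectrum_id}: residue {residue} at "
                        f"{key[0]}:{key[1]} disagrees with sequence {seq[key[1] - 1]}")
            residues[key] = residue
            votes[key][mod_class].append(psm)

    sites: List[ModSite] = []
    for key in sorted(votes):
        by_class = votes[key]

        def rank(mc: ModClass):
            supporters = by_class[mc]
            total_intensity = sum(p.intensity() for p in supporters)
            # maximize count, then intensity; minimize class name
            return (-len(supporters), -total_intensity, mc.value)

        winner = min(by_class, key=rank)
        supporters = by_class[winner]
        accession, position = key
        flagged = False
        if winner is ModClass.CIT:
            length = None
            if sequences is not None and accession in sequences:
                length = len(sequences[accession])
            flagged = any(
                flag_cleavage_inconsistency(p, position, length) for p in supporters)
        sites.append(ModSite(
            protein_accession=accession,
            position=position,
            residue=residues[key],
            mod_class=winner,
            supporting_psm_ids=tuple(p.spectrum_id for p in supporters),
            flagged=flagged,
        ))
    return sites
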