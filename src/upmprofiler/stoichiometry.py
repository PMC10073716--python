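"""Site-level modification stoichiometry and its between-group chi-squared
comparison.

A site's stoichiometry in a group is

    percent = 100 * I_mod / (I_mod + I_unmod)

where ``I_mod`` (``I_unmod``) is the summed reporter intensity, over that
group's channels, of PSMs whose peptide covers the site position with (resp.
without) a ureido modification at that position.  The two-group comparison is
a Pearson chi-squared test with 1 df, no continuity correction, on the 2x2
table of intensities rounded to integer pseudo-counts.

The pseudo-count convention matters: intensities are treated as if they were
counts, so the chi-squared p-value is calibrated only when the intensity
scale is about one unit per PSM (as in this package's simulator).  An
alternative estimator using raw spectral counts, for which the test is
exactly count-based, is available via ``estimator="counts"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .io_formats import PSMRecord, ReporterDesign
from .upm_annotation import (DEFAULT_TOL_DA, ModClass, ModSite,
                             UREIDO_CLASSES, classify_psm_mods)

logger = logging.getLogger(__name__)

UP, DOWN, EQUAL = "↑", "↓", "="


@dataclass(frozen=True)
class ComparisonResult:
    chi2: float
    p: float
    direction: str  # direction of group B (patients) vs group A (controls)


def site_stoichiometry(i_mod: float, i_unmod: float) -> float:
    """Percent modified, ``100*I_mod/(I_mod+I_unmod)``, to 2 decimals."""
    if i_mod < 0 or i_unmod < 0:
        raise ValueError("intensities must be non-negative")
    total = i_mod + i_unmod
    if total == 0:
        raise ValueError("both intensities zero: stoichiometry undefined")
    return round(100.0 * i_mod / total, 2)


def _covering_psms(psms: Sequence[PSMRecord], accession: str,
                   position: int) -> List[Tuple[PSMRecord, bool]]:
    """PSMs whose peptide covers *position*, with a modified-at-site flag."""
    out = []
    for psm in psms:
        if psm.protein_accession != accession:
            continue
        offset = position - psm.peptide_start
        if not 0 <= offset < len(psm.peptide):
            continue
        modified = any(
            off == offset and cls in UREIDO_CLASSES
            for off, cls in classify_psm_mods(psm))
        out.append((psm, modified))
    return out


def site_group_intensities(psms: Sequence[PSMRecord], accession: str, position: int,
                           design: ReporterDesign | None = None
                           ) -> Dict[str, Tuple[float, float]]:
    """Per-group ``(I_mod, I_unmod)`` summed over the group's channels."""
    if design is None:
        design = ReporterDesign()
    covering = _covering_psms(psms, accession, position)
    out: Dict[str, Tuple[float, float]] = {}
    for group in design.groups:
        channels = design.channels_for(group)
        i_mod = sum(p.intensity(channels) for p, m in covering if m)
        i_unmod = sum(p.intensity(channels) for p, m in covering if not m)
        out[group] = (i_mod, i_unmod)
    return out


def site_group_counts(psms: Sequence[PSMRecord], accession: str, position: int,
                      design: ReporterDesign | None = None
                      ) -> Dict[str, Tuple[int, int]]:
    """Per-group ``(n_mod, n_unmod)`` spectral counts (PSMs assigned by pool)."""
    if design is None:
        design = ReporterDesign()
    covering = _covering_psms(psms, accession, position)
    out: Dict[str, Tuple[int, int]] = {}
    for group in design.groups:
        in_group = [(p, m) for p, m in covering
                    if design.pool_group(p.pool_id) == group]
        out[group] = (sum(1 for _, m in in_group if m),
                      sum(1 for _, m in in_group if not m))
    return out


def compare_stoichiometry(group_a: Tuple[float, float],
                          group_b: Tuple[float, float]) -> ComparisonResult:
    """Pearson chi-squared (1 df, no continuity correction) on the 2x2 table
    of rounded pseudo-counts ``[[A_mod, A_unmod], [B_mod, B_unmod]]``.

    The direction compares group B's 2-decimal percent against group A's:
    up-arrow iff percent(B) > percent(A), ``=`` only on an exact tie.  A zero
    margin skips the test (NaN statistic) but the direction is still
    reported.
    """
    a_mod, a_unmod = group_a
    b_mod, b_unmod = group_b
    if min(a_mod, a_unmod, b_mod, b_unmod) < 0:
        raise ValueError("intensities must be non-negative")
    pct_a = site_stoichiometry(a_mod, a_unmod)
    pct_b = site_stoichiometry(b_mod, b_unmod)
    if pct_b > pct_a:
        direction = UP
    elif pct_b < pct_a:
        direction = DOWN
    else:
        direction = EQUAL

    table = np.rint([[a_mod, a_unmod], [b_mod, b_unmod]]).astype(np.int64)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        logger.warning("compare_stoichiometry: zero margin, test skipped")
        return ComparisonResult(np.nan, np.nan, direction)
    chi2, p, _, _ = chi2_contingency(table, correction=False)
    return ComparisonResult(float(chi2), float(p), direction)


def stoichiometry_table(psms: Sequence[PSMRecord],
                        sites: Sequence[ModSite],
                        design: ReporterDesign | None = None,
                        estimator: str = "intensity",
                        control_group: str = "NZ",
                        patient_group: str = "nonNZ") -> pd.DataFrame:
    """Per-site stoichiometry by group with the chi-squared comparison.

    Only ureido sites (Cit/hCit) are analyzed; sites with no signal in a
    group are dropped with a warning.  ``estimator`` selects intensity
    pseudo-counts (default) or raw spectral counts.
    """
    if design is None:
        design = ReporterDesign()
    if estimator not in ("intensity", "counts"):
        raise ValueError("estimator must be 'intensity' or 'counts'")
    by_accession: Dict[str, List[PSMRecord]] = {}
    for psm in psms:
        by_accession.setdefault(psm.protein_accession, []).append(psm)
    rows = []
    for site in sites:
        if site.mod_class not in UREIDO_CLASSES:
            continue
        subset = by_accession.get(site.protein_accession, [])
        if estimator == "intensity":
            per_group = site_group_intensities(
                subset, site.protein_accession, site.position, design)
        else:
            per_group = site_group_counts(
                subset, site.protein_accession, site.position, design)
        ctrl = per_group[control_group]
        pat = per_group[patient_group]
        if sum(ctrl) == 0 or sum(pat) == 0:
            logger.warning("site %s:%d dropped: no signal in a group",
                           site.protein_accession, site.position)
            continue
        cmp = compare_stoichiometry(ctrl, pat)
        rows.append({
            "protein": site.protein_accession,
            "residue_position": f"{site.residue}{site.position}",
            "mod_class": site.mod_class.value,
            "pct_control": site_stoichiometry(*ctrl),
            "pct_patient": site_stoichiometry(*pat),
            "chi2": cmp.chi2,
            "p": cmp.p,
            "direction": cmp.direction,
        })
    return pd.DataFrame(
        rows, columns=["protein", "residue_position", "mod_class", "pct_control",
                       "pct_patient", "chi2", "p", "direction"])
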