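"""Group comparisons of sperm parameters, correlation of modification burden
with clinical signs, and confound screening.

All tests are two-sided.  Missing clinical values are removed pairwise (small
cohorts make listwise deletion too destructive), and the number of pairs
actually used is always reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import pooled_ttest
from .io_formats import ClinicalRecord, GROUPS

logger = logging.getLogger(__name__)

#: Continuous clinical variables, in reporting order.
CLINICAL_VARIABLES = ("vitality", "morphology", "progressive_motility", "count")
LIFESTYLE_FLAGS = ("smoking", "alcohol", "toxicology")


@dataclass(frozen=True)
class GroupComparison:
    variable: str
    mean_nz: float
    sd_nz: float
    n_nz: int
    mean_nonnz: float
    sd_nonnz: float
    n_nonnz: int
    t: float
    p: float


@dataclass(frozen=True)
class CorrelationResult:
    pair: str
    method: str  # "Pearson" or "Spearman"
    r: float
    p: float
    n: int


def clinical_frame(records: Sequence[ClinicalRecord]) -> pd.DataFrame:
    """Tidy DataFrame view of clinical records (index: subject_id)."""
    df = pd.DataFrame([{
        "subject_id": r.subject_id, "group": r.group, "vitality": r.vitality,
        "morphology": r.morphology, "progressive_motility": r.progressive_motility,
        "count": r.count, "age": r.age, "smoking": r.smoking,
        "alcohol": r.alcohol, "toxicology": r.toxicology,
    } for r in records])
    return df.set_index("subject_id")


def group_compare(clinical: pd.DataFrame, variable: str) -> GroupComparison | None:
    """Pooled-variance Student t-test of one variable, NZ vs nonNZ.

    Missing values are dropped per group; a group left with fewer than two
    subjects skips the comparison (returns None with a warning).
    """
    a = clinical.loc[clinical["group"] == "NZ", variable].dropna().to_numpy(float)
    b = clinical.loc[clinical["group"] == "nonNZ", variable].dropna().to_numpy(float)
    if len(a) < 2 or len(b) < 2:
        logger.warning("group_compare(%s): fewer than 2 subjects in a group, skipped",
                       variable)
        return None
    t, p, _ = pooled_ttest(a, b)
    return GroupComparison(
        variable=variable,
        mean_nz=float(a.mean()), sd_nz=float(a.std(ddof=1)), n_nz=len(a),
        mean_nonnz=float(b.mean()), sd_nonnz=float(b.std(ddof=1)), n_nonnz=len(b),
        t=t, p=p)


def correlate(x: Sequence[float], y: Sequence[float], method: str = "Pearson",
              pair: str = "") -> CorrelationResult:
    """Correlation with two-sided p; Spearman uses average ranks for ties.

    NaN pairs are removed; at least 3 complete pairs are required.  Zero
    variance in either argument leaves r undefined (NaN).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    method_norm = method.capitalize()
    if method_norm not in ("Pearson", "Spearman"):
        raise ValueError("method must be 'Pearson' or 'Spearman'")
    if x.std() == 0 or y.std() == 0:
        logger.warning("correlate(%s): zero variance, r undefined", pair or method)
        return CorrelationResult(pair, method_norm, np.nan, np.nan, n)
    if method_norm == "Pearson":
        r, p = stats.pearsonr(x, y)
    else:
        r, p = stats.spearmanr(x, y)
    return CorrelationResult(pair, method_norm, float(r), float(p), n)


def confound_screen(clinical: pd.DataFrame,
                    burden: Mapping[str, float] | None = None,
                    alpha: float = 0.05) -> pd.DataFrame:
    """Screen lifestyle flags and age as potential confounds.

    Boolean lifestyle flags: each flag is tested (pooled t) against every
    continuous clinical variable; a degenerate flag (all subjects identical)
    is skipped.  Age: Pearson correlation against each clinical variable that
    differs significantly between groups, and against the modification burden
    when one is supplied (*burden* maps subject_id -> value).  Everything is
    screened at ``p < alpha``.
    """
    rows: List[dict] = []

    for flag in LIFESTYLE_FLAGS:
        values = clinical[flag].astype(bool)
        if values.nunique() < 2:
            rows.append({"covariate": flag, "variable": "", "kind": "flag",
                         "effect": np.nan, "p": np.nan, "n": len(values),
                         "significant": False, "skipped": True})
            continue
        for var in CLINICAL_VARIABLES:
            sub = clinical[[flag, var]].dropna()
            a = sub.loc[sub[flag].astype(bool), var].to_numpy(float)
            b = sub.loc[~sub[flag].astype(bool), var].to_numpy(float)
            if len(a) < 2 or len(b) < 2:
                rows.append({"covariate": flag, "variable": var, "kind": "flag",
                             "effect": np.nan, "p": np.nan, "n": len(sub),
                             "significant": False, "skipped": True})
                continue
            t, p, _ = pooled_ttest(a, b)
            rows.append({"covariate": flag, "variable": var, "kind": "flag",
                         "effect": t, "p": p, "n": len(sub),
                         "significant": p < alpha, "skipped": False})

    significant_vars = [
        var for var in CLINICAL_VARIABLES
        if (gc := group_compare(clinical, var)) is not None and gc.p < alpha]
    for var in significant_vars:
        res = correlate(clinical["age"], clinical[var], "Pearson",
                        pair=f"age~{var}")
        rows.append({"covariate": "age", "variable": var, "kind": "pearson",
                     "effect": res.r, "p": res.p, "n": res.n,
                     "significant": bool(res.p < alpha) if np.isfinite(res.p) else False,
                     "skipped": False})
    if burden is not None:
        sub = clinical.loc[clinical.index.intersection(list(burden))]
        b = np.array([burden[s] for s in sub.index], dtype=float)
        if len(sub) >= 3:
            res = correlate(sub["age"].to_numpy(float), b, "Pearson",
                            pair="age~burden")
            rows.append({"covariate": "age", "variable": "burden", "kind": "pearson",
                         "effect": res.r, "p": res.p, "n": res.n,
                         "significant": bool(res.p < alpha) if np.isfinite(res.p) else False,
                         "skipped": False})
    return pd.DataFrame(
        rows, columns=["covariate", "variable", "kind", "effect", "p", "n",
                       "significant", "skipped"])


def burden_correlations(clinical: pd.DataFrame,
                        burden: Mapping[str, float],
                        variables: Sequence[str] = ("morphology",
                                                    "progressive_motility", "age"),
                        method: str = "Pearson") -> pd.DataFrame:
    """Correlate per-subject modification burden with clinical variables."""
    sub = clinical.loc[clinical.index.intersection(list(burden))]
    b = np.array([burden[s] for s in sub.index], dtype=float)
    rows = []
    for var in variables:
        res = correlate(b, sub[var].to_numpy(float), method, pair=f"burden~{var}")
        rows.append({"pair": res.pair, "method": res.method, "r": res.r,
                     "p": res.p, "n": res.n})
    return pd.DataFrame(rows, columns=["pair", "method", "r", "p", "n"])
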