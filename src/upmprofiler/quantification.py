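"""Cumulative modification burden, reporter-based protein quantification,
and EV-marker summaries.

Two burden estimators are carried side by side: spectral counting (each PSM
contributes one count to the pool it was acquired in, the default) and
summed reporter intensity over a group's channels.  Protein-level relative
quantification normalizes channel totals, averages channels per group, and
tests NZ vs nonNZ with a pooled-variance Student t-test at p <= 0.05; no
multiple-testing correction is applied by default (a Benjamini-Hochberg
column can be requested).
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from ._stats import pooled_ttest
from .io_formats import CHANNELS, PSMRecord, ReporterDesign
from .upm_annotation import DEFAULT_TOL_DA, ModClass, psm_has_class

logger = logging.getLogger(__name__)

#: Label of the nonNZ-minus-NZ difference row in group-level cumulative tables.
DIFFERENCE_LABEL = "nonNZ-NZ"

NORMALIZATIONS = ("total", "median-ratio", "none")


def cumulative_signal(psms: Sequence[PSMRecord], mod_class: ModClass | str,
                      design: ReporterDesign | None = None, by: str = "group",
                      tol_da: float = DEFAULT_TOL_DA) -> pd.DataFrame:
    """Cumulative burden of one modification class, by group or by pool.

    Each PSM carrying the class contributes one spectral count to its pool
    (and thereby to its pool's group) and its summed reporter intensity over
    the key's channels.  For ``by="group"`` with the standard two groups a
    ``nonNZ-NZ`` difference row is appended.
    """
    mod_class = ModClass(mod_class)
    if design is None:
        design = ReporterDesign()
    if by not in ("group", "pool"):
        raise ValueError("by must be 'group' or 'pool'")

    if by == "pool":
        keys = list(design.pools)
        channels = {p: (design.pool_to_channel[p],) for p in keys}
        key_of = {p: p for p in keys}
    else:
        keys = list(design.groups)
        channels = {g: design.channels_for(g) for g in keys}
        key_of = {p: design.pool_group(p) for p in design.pools}

    counts = {k: 0 for k in keys}
    intensity = {k: 0.0 for k in keys}
    for psm in psms:
        if not psm_has_class(psm, mod_class, tol_da):
            continue
        key = key_of[psm.pool_id]
        counts[key] += 1
        intensity[key] += psm.intensity(channels[key])

    df = pd.DataFrame(
        {"spectral_counts": [counts[k] for k in keys],
         "intensity": [intensity[k] for k in keys]},
        index=pd.Index(keys, name=by))
    if by == "group" and set(keys) == {"NZ", "nonNZ"}:
        diff = df.loc["nonNZ"] - df.loc["NZ"]
        df.loc[DIFFERENCE_LABEL] = diff
    return df


# ---------------------------------------------------------------------------
# protein quantification
# ---------------------------------------------------------------------------

def protein_channel_table(psms: Sequence[PSMRecord]) -> pd.DataFrame:
    """Protein x channel table of summed reporter intensities."""
    totals: Dict[str, np.ndarray] = {}
    for psm in psms:
        row = totals.get(psm.protein_accession)
        if row is None:
            row = totals[psm.protein_accession] = np.zeros(len(CHANNELS))
        for i, ch in enumerate(CHANNELS):
            row[i] += psm.reporter_intensities.get(ch, 0.0)
    table = pd.DataFrame.from_dict(totals, orient="index", columns=list(CHANNELS))
    table.index.name = "protein"
    return table.sort_index()


def normalize_channels(table: pd.DataFrame, method: str = "total") -> pd.DataFrame:
    """Normalize channel columns so downstream results are per-channel
    scale-invariant.

    ``total``: scale each channel to unit total, i.e. per-channel relative
    intensities (the minimal standard for reporter data; the unit target
    makes the result strictly invariant to rescaling any single channel).
    ``median-ratio``: scale by the median of each channel's ratios to the
    per-protein geometric mean reference.  ``none``: pass through.
    """
    if method == "none":
        return table.copy()
    if method == "total":
        col_sums = table.sum(axis=0)
        if (col_sums == 0).any():
            logger.warning("normalize_channels: empty channel(s) %s left unscaled",
                           list(col_sums.index[col_sums == 0]))
        factors = pd.Series(
            np.where(col_sums > 0, 1.0 / col_sums.replace(0, np.nan), 1.0),
            index=col_sums.index)
        return table * factors
    if method == "median-ratio":
        positive = table[(table > 0).all(axis=1)]
        if positive.empty:
            raise ValueError("median-ratio normalization needs at least one "
                             "protein quantified in all channels")
        reference = np.exp(np.log(positive).mean(axis=1))
        factors = 1.0 / (positive.div(reference, axis=0)).median(axis=0)
        return table * factors
    raise ValueError(f"unknown normalization {method!r}; choose from {NORMALIZATIONS}")


def quantify_channel_table(table: pd.DataFrame,
                           design: ReporterDesign | None = None,
                           normalization: str = "total",
                           alpha: float = 0.05,
                           bh_correction: bool = False) -> pd.DataFrame:
    """Group comparison on a protein x channel intensity table."""
    if design is None:
        design = ReporterDesign()
    norm = normalize_channels(table, normalization)
    groups = design.groups
    if len(groups) != 2:
        raise ValueError("protein quantification expects exactly two groups")
    g_ref, g_alt = groups  # NZ, nonNZ in the default design
    ch_ref = list(design.channels_for(g_ref))
    ch_alt = list(design.channels_for(g_alt))
    testable = len(ch_ref) >= 2 and len(ch_alt) >= 2
    if not testable:
        logger.warning("quantify: a group has < 2 channels; t-tests skipped")

    out = norm.copy()
    out.columns = [f"norm_{c}" for c in norm.columns]
    out[f"mean_{g_ref}"] = norm[ch_ref].mean(axis=1)
    out[f"mean_{g_alt}"] = norm[ch_alt].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out["ratio"] = out[f"mean_{g_alt}"] / out[f"mean_{g_ref}"]
    tvals, pvals = [], []
    for _, row in norm.iterrows():
        if testable:
            t, p, _ = pooled_ttest(row[ch_ref].to_numpy(), row[ch_alt].to_numpy())
        else:
            t, p = np.nan, np.nan
        tvals.append(t)
        pvals.append(p)
    out["t"] = tvals
    out["p"] = pvals
    if bh_correction:
        out["p_adj"] = _benjamini_hochberg(np.asarray(pvals, dtype=float))
        out["significant"] = out["p_adj"] <= alpha
    else:
        out["significant"] = out["p"] <= alpha
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


def quantify_proteins(psms: Sequence[PSMRecord],
                      design: ReporterDesign | None = None,
                      normalization: str = "total",
                      alpha: float = 0.05,
                      bh_correction: bool = False) -> pd.DataFrame:
    """Protein-level relative quantification from reporter intensities."""
    table = protein_channel_table(psms)
    return quantify_channel_table(table, design, normalization, alpha, bh_correction)


# ---------------------------------------------------------------------------
# EV markers
# ---------------------------------------------------------------------------

def marker_summary(protein_quants: pd.DataFrame,
                   marker_list: Sequence[str],
                   exosome_list: Sequence[str] = (),
                   microvesicle_list: Sequence[str] = ()) -> Tuple[pd.DataFrame, dict]:
    """Per-marker relative intensity and exosome-vs-microvesicle comparison.

    Relative intensity is a protein's mean normalized channel intensity as a
    fraction of the summed mean over all quantified proteins.  Markers absent
    from the data are listed as not detected.  The class comparison is a
    pooled t-test of detected exosome-marker vs microvesicle-marker relative
    intensities.
    """
    norm_cols = [c for c in protein_quants.columns if c.startswith("norm_")]
    mean_intensity = protein_quants[norm_cols].mean(axis=1)
    total = mean_intensity.sum()
    relative = mean_intensity / total if total > 0 else mean_intensity

    exo, micro = set(exosome_list), set(microvesicle_list)
    rows = []
    for marker in marker_list:
        detected = marker in relative.index
        if marker in exo and marker in micro:
            klass = "both"
        elif marker in exo:
            klass = "exosome"
        elif marker in micro:
            klass = "microvesicle"
        else:
            klass = "unclassified"
        rows.append({
            "marker": marker,
            "detected": detected,
            "relative_intensity": float(relative[marker]) if detected else np.nan,
            "marker_class": klass,
        })
    markers_df = pd.DataFrame(rows)
    if markers_df.empty or not markers_df["detected"].any():
        logger.warning("marker_summary: no marker overlaps the quantified proteins")

    detected = markers_df[markers_df["detected"]]
    exo_vals = detected.loc[detected["marker_class"].isin(["exosome", "both"]),
                            "relative_intensity"].to_numpy()
    micro_vals = detected.loc[detected["marker_class"].isin(["microvesicle", "both"]),
                              "relative_intensity"].to_numpy()
    comparison = {
        "n_detected": int(detected.shape[0]),
        "n_not_detected": int((~markers_df["detected"]).sum()),
        "exosome_mean": float(exo_vals.mean()) if len(exo_vals) else np.nan,
        "microvesicle_mean": float(micro_vals.mean()) if len(micro_vals) else np.nan,
        "t": np.nan,
        "p": np.nan,
    }
    if len(exo_vals) >= 2 and len(micro_vals) >= 2:
        t, p, _ = pooled_ttest(exo_vals, micro_vals)
        comparison["t"], comparison["p"] = t, p
    return markers_df, comparison
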