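"""Shared low-level statistics helpers."""

from __future__ import annotations

import logging
from typing import Sequence, Tuple

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)


def pooled_ttest(a: Sequence[float], b: Sequence[float]) -> Tuple[float, float, int]:
    """Equal-variance (pooled) two-sample Student t-test, two-sided.

    Returns ``(t, p, df)`` with ``t`` computed as ``mean(a) - mean(b)`` over
    the pooled standard error.  A zero pooled variance (both samples
    constant) is floored at machine epsilon times the squared grand mean so
    that a genuine mean difference yields a finite, extreme t rather than a
    division by zero; an exact tie returns ``t = 0, p = 1``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("each sample needs at least 2 observations")
    df = na + nb - 2
    mean_a, mean_b = a.mean(), b.mean()
    s2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    if s2 == 0.0:
        if mean_a == mean_b:
            return 0.0, 1.0, df
        grand = np.concatenate([a, b]).mean()
        s2 = np.finfo(float).eps * max(grand * grand, np.finfo(float).tiny)
        logger.warning("pooled_ttest: zero pooled variance floored at %g", s2)
    t = (mean_a - mean_b) / np.sqrt(s2 * (1.0 / na + 1.0 / nb))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(p), df
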