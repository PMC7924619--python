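"""Position-wise residue enrichment/depletion between window sets.

This is the statistic behind two-sample sequence-logo displays: for each
window offset (excluding the fixed central lysine) and each standard
residue, the positive-set frequency is compared with the negative-set
frequency by a pooled two-proportion z-test. Residues with p < alpha are
called enriched or depleted according to the sign of the difference. Pad
and ambiguity characters are excluded from the denominators. No
multiple-testing correction is applied by default (the logo-tool
convention); a Bonferroni option is available.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .alphabet import AA_ORDER, AA_TO_COL
from .seq_io import PeptideWindow


def _position_counts(windows: Sequence[PeptideWindow], w: int):
    """counts[t, a] of standard residue a at window index t, and valid totals."""
    counts = np.zeros((w, 20), dtype=int)
    for win in windows:
        for t, res in enumerate(win.residues):
            col = AA_TO_COL.get(res)
            if col is not None:
                counts[t, col] += 1
    return counts, counts.sum(axis=1)


def two_proportion_z(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float]:
    """Pooled two-proportion z statistic and two-sided p-value."""
    if n1 == 0 or n2 == 0:
        return 0.0, 1.0
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    var = pooled * (1 - pooled) * (1 / n1 + 1 / n2)
    if var == 0:
        return 0.0, 1.0
    z = (p1 - p2) / np.sqrt(var)
    return float(z), float(2 * stats.norm.sf(abs(z)))


def position_enrichment(positives: Sequence[PeptideWindow],
                        negatives: Sequence[PeptideWindow],
                        alpha: float = 0.05,
                        bonferroni: bool = False) -> pd.DataFrame:
    """Enrichment table over (offset, residue) cells.

    Columns: offset, residue, pos_freq, neg_freq, diff, z, p, call
    (enriched / depleted / none). The central position (always 'K') is
    excluded from testing; swapping the inputs flips every call.
    """
    if not positives or not negatives:
        raise ValueError("both window sets must be non-empty")
    w = len(positives[0])
    if any(len(x) != w for x in positives) or any(len(x) != w for x in negatives):
        raise ValueError("all windows must share one window size")
    half = (w - 1) // 2
    pos_counts, pos_tot = _position_counts(positives, w)
    neg_counts, neg_tot = _position_counts(negatives, w)
    n_tests = (w - 1) * 20
    level = alpha / n_tests if bonferroni else alpha

    rows = []
    for t in range(w):
        offset = t - half
        if offset == 0:
            continue
        for a_idx, a in enumerate(AA_ORDER):
            x1, n1 = int(pos_counts[t, a_idx]), int(pos_tot[t])
            x2, n2 = int(neg_counts[t, a_idx]), int(neg_tot[t])
            p1 = x1 / n1 if n1 else np.nan
            p2 = x2 / n2 if n2 else np.nan
            z, p = two_proportion_z(x1, n1, x2, n2)
            diff = (p1 - p2) if n1 and n2 else 0.0
            if p < level and diff > 0:
                call = "enriched"
            elif p < level and diff < 0:
                call = "depleted"
            else:
                call = "none"
            rows.append((offset, a, p1, p2, diff, z, p, call))
    return pd.DataFrame(
        rows, columns=["offset", "residue", "pos_freq", "neg_freq",
                       "diff", "z", "p", "call"]
    )


def render_text_logo(table: pd.DataFrame, max_letters: int = 5) -> str:
    """Crude text-mode two-sample logo: per offset, significant residues
    stacked by |difference| (uppercase = enriched, lowercase = depleted)."""
    lines = []
    for offset, grp in table.groupby("offset"):
        sig = grp[grp["call"] != "none"].copy()
        if sig.empty:
            continue
        sig["absdiff"] = sig["diff"].abs()
        sig = sig.sort_values("absdiff", ascending=False).head(max_letters)
        letters = "".join(
            r.residue if r.call == "enriched" else r.residue.lower()
            for r in sig.itertuples()
        )
        lines.append(f"{int(offset):+3d}: {letters}")
    return "\n".join(lines)
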