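"""Redundancy removal: greedy elimination of highly correlated feature columns.

Before any model is fit, features whose pairwise Pearson |r| exceeds a
threshold (default 0.50) are pruned.  Elimination is greedy and deterministic:
while any pair exceeds the threshold, the member of the worst pair with the
larger mean absolute correlation to all remaining features is dropped (ties
drop the later column in canonical order).  Absolute r governs removal — a
perfectly anti-correlated duplicate is just as redundant as a correlated one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateInputError


@dataclass
class ReductionReport:
    """Audit trail of the correlation filter."""

    kept: list[str]
    dropped: list[dict]  # {"feature", "partner", "r_value"}
    threshold: float

    def to_dict(self) -> dict:
        return {"kept": self.kept, "dropped": self.dropped, "threshold": self.threshold}


def correlation_filter(
    table: pd.DataFrame, threshold: float = 0.50
) -> tuple[pd.DataFrame, ReductionReport]:
    """Drop features until no kept pair has pairwise |r| > ``threshold``.

    Constant columns (zero variance) are dropped first with a warning, since
    their correlation is undefined.  Returns the reduced table (columns keep
    their input order) and the full report.
    """
    if len(table) < 3:
        raise DegenerateInputError(
            f"correlation filter needs >= 3 subjects, got {len(table)}"
        )
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    cols = list(table.columns)
    dropped: list[dict] = []

    X = table.to_numpy(dtype=np.float64)
    sd = X.std(axis=0)
    const = [c for c, s in zip(cols, sd) if s == 0.0]
    if const:
        warnings.warn(f"dropping {len(const)} constant column(s) before correlation filter")
        for c in const:
            dropped.append({"feature": c, "partner": None, "r_value": None})
        cols = [c for c in cols if c not in const]

    keep_idx = list(range(len(cols)))
    sub = table[cols].to_numpy(dtype=np.float64)
    corr = np.abs(np.corrcoef(sub, rowvar=False))
    np.fill_diagonal(corr, 0.0)

    active = np.ones(len(cols), dtype=bool)
    while True:
        masked = np.where(np.outer(active, active), corr, 0.0)
        i, j = np.unravel_index(int(np.argmax(masked)), masked.shape)
        if masked[i, j] <= threshold:
            break
        # victim: larger mean |r| to the other remaining features; tie -> later column
        others = active.copy()
        others[[i, j]] = False
        mean_i = corr[i, others].mean() if others.any() else 0.0
        mean_j = corr[j, others].mean() if others.any() else 0.0
        if mean_i > mean_j:
            victim, partner = i, j
        elif mean_j > mean_i:
            victim, partner = j, i
        else:
            victim, partner = (max(i, j), min(i, j))
        active[victim] = False
        dropped.append(
            {"feature": cols[victim], "partner": cols[partner], "r_value": float(corr[i, j])}
        )

    kept = [c for c, a in zip(cols, active) if a]
    report = ReductionReport(kept=kept, dropped=dropped, threshold=threshold)
    return table[kept], report
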