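"""Patient-specific PEFR risk zoning.

Each patient's critical peak-expiratory-flow value (PEFR_C) is an empirical
lower quantile (default the 20th percentile) of their own historical morning
PEFR distribution.  Days whose morning PEFR falls strictly below PEFR_C are
risk-zone days; all others are no-risk days.  Using the patient's own
history instead of population norms makes the zoning robust to the large
between-patient variability of PEFR.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["RiskZoning", "InsufficientHistoryError", "critical_pefr", "label_days"]

#: default minimum number of historical PEFR values to estimate a quantile
MIN_HISTORY = 10


class InsufficientHistoryError(ValueError):
    pass


@dataclass(frozen=True)
class RiskZoning:
    """A fitted zoning rule: risk iff morning PEFR < ``pefr_critical``."""

    pefr_critical: float
    cutoff_quantile: float = 0.20
    history_n: int = 0


def critical_pefr(
    history: Sequence[float], q: float = 0.20, *, min_history: int = MIN_HISTORY
) -> RiskZoning:
    """Estimate PEFR_C as the empirical q-quantile of a PEFR history.

    Uses linear interpolation between order statistics (the common
    ``h = (n - 1) q + 1`` convention), so PEFR_C is continuous and
    non-decreasing in ``q``.
    """
    if not 0 < q < 1:
        raise ValueError(f"cutoff quantile must be in (0, 1), got {q}")
    values = np.asarray(history, dtype=float)
    values = values[~np.isnan(values)]
    if values.size < min_history:
        raise InsufficientHistoryError(
            f"need >= {min_history} PEFR values to estimate PEFR_C, got {values.size}"
        )
    pefr_c = float(np.quantile(values, q, method="linear"))
    return RiskZoning(pefr_critical=pefr_c, cutoff_quantile=q, history_n=values.size)


def label_days(rows: pd.DataFrame, zoning: RiskZoning) -> pd.DataFrame:
    """Attach binary risk labels to a daily feature table.

    A day is labelled risk (1) iff its observed morning PEFR is strictly
    below ``zoning.pefr_critical``; a PEFR exactly at the critical value is
    no-risk.  Rows with a missing ``am_pefr`` are dropped.  Adds ``label``
    and ``pefr_critical`` columns; the input frame is not modified.
    """
    if "am_pefr" not in rows.columns:
        raise KeyError("feature table must carry an 'am_pefr' column")
    out = rows.loc[rows["am_pefr"].notna()].copy()
    out["label"] = (out["am_pefr"] < zoning.pefr_critical).astype(int)
    out["pefr_critical"] = zoning.pefr_critical
    return out
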