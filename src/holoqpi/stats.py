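"""Treatment-effect summaries and flow-cytometry-style gating.

Volume effects are summarised at field level: for each paired field the
percent decrease is 100·(1 − V_post/V_pre) on the field's total segmented
volume, and the condition summary is the mean ± sd of those per-field
decreases — matching how population volume loss is usually reported for
monolayer treatments. Condition contrasts use Welch's unequal-variance
two-sample t-test. Uptake gating thresholds treated events at a quantile
(default 99th percentile) of the negative-control intensity distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
from scipy import stats as sp_stats

from .morphometry import MorphometryReport
from .scene import FlowEventTable

__all__ = [
    "ConditionSummary",
    "UptakeResult",
    "volume_change",
    "compare_conditions",
    "gate_positive",
]


@dataclass(frozen=True)
class ConditionSummary:
    label: str
    n_fields: int
    mean_volume_decrease_pct: float
    sd_volume_decrease_pct: float
    mean_count_change: float
    sd_count_change: float
    per_field_decrease_pct: Tuple[float, ...] = ()


@dataclass(frozen=True)
class UptakeResult:
    label: str
    percent_positive: float
    gate_threshold: float
    control_false_positive_pct: float


def volume_change(pre: Sequence[MorphometryReport],
                  post: Sequence[MorphometryReport],
                  label: str = "") -> ConditionSummary:
    """Paired pre/post field summaries → percent volume decrease ± sd.

    Pairs with zero pre-treatment volume are excluded with a warning.
    Count change is pre.cell_count − post.cell_count (positive = loss).
    """
    if len(pre) != len(post) or len(pre) == 0:
        raise ValueError("pre and post must be non-empty lists of equal length")
    decreases, count_changes = [], []
    for i, (a, b) in enumerate(zip(pre, post)):
        if a.total_volume_um3 <= 0:
            warnings.warn(f"pair {i}: zero pre-treatment volume, excluded")
            continue
        decreases.append(100.0 * (1.0 - b.total_volume_um3 / a.total_volume_um3))
        count_changes.append(a.cell_count - b.cell_count)
    if not decreases:
        raise ValueError("no valid pairs (all pre-treatment volumes were zero)")
    d = np.asarray(decreases)
    c = np.asarray(count_changes, dtype=float)
    return ConditionSummary(
        label=label,
        n_fields=len(d),
        mean_volume_decrease_pct=float(d.mean()),
        sd_volume_decrease_pct=float(d.std(ddof=1)) if len(d) > 1 else 0.0,
        mean_count_change=float(c.mean()),
        sd_count_change=float(c.std(ddof=1)) if len(c) > 1 else 0.0,
        per_field_decrease_pct=tuple(float(x) for x in d),
    )


def compare_conditions(a: Sequence[float], b: Sequence[float],
                       ) -> Tuple[float, float]:
    """Welch two-sample t-test on per-field decreases.

    Returns (mean(a) − mean(b), two-sided p). Degenerate zero-variance
    inputs with equal means yield p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 fields")
    diff = float(a.mean() - b.mean())
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        return diff, 1.0 if diff == 0 else 0.0
    res = sp_stats.ttest_ind(a, b, equal_var=False)
    return diff, float(res.pvalue)


def gate_positive(events: FlowEventTable, control: FlowEventTable,
                  control_quantile: float = 0.99,
                  label: str = "") -> UptakeResult:
    """Percent of treated events above the control-quantile gate."""
    if not (0.5 < control_quantile < 1.0):
        raise ValueError("control_quantile must lie in (0.5, 1)")
    ctrl = control.events["intensity"].to_numpy()
    treated = events.events["intensity"].to_numpy()
    if ctrl.size == 0 or treated.size == 0:
        raise ValueError("event tables must be non-empty")
    gate = float(np.quantile(ctrl, control_quantile))
    pct = float(100.0 * np.mean(treated > gate))
    fp = float(100.0 * np.mean(ctrl > gate))
    return UptakeResult(label=label, percent_positive=pct, gate_threshold=gate,
                        control_false_positive_pct=fp)
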