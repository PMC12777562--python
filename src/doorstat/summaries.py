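"""Standardized distribution and expected gain/loss summaries.

These are the absolute-risk tabular companions to the rank-based analysis:
the per-arm category distribution with cumulative percentages, and the
expected number of patients gained or lost per category if ``standard_n``
patients received the experimental instead of the control intervention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import DoorTable

__all__ = [
    "GainLossSummary",
    "distribution_table",
    "gain_loss",
    "component_gain_loss",
    "round_half_away",
]


def round_half_away(x) -> np.ndarray:
    """Round to the nearest integer, halves away from zero (−85.5 → −86)."""
    x = np.asarray(x, dtype=float)
    return (np.sign(x) * np.floor(np.abs(x) + 0.5)).astype(np.int64)


@dataclass(frozen=True)
class GainLossSummary:
    """Expected patients gained (+) or lost (−) per category, per ``standard_n``.

    Sign convention: experimental − control.  Pre-rounding per-category
    values sum to zero when both arms are fully classified; the cumulative
    value at the last category is zero.
    """

    per_category: tuple[int, ...]
    cumulative: tuple[int, ...]
    standard_n: int
    raw_per_category: tuple[float, ...]
    raw_cumulative: tuple[float, ...]


def distribution_table(table: DoorTable) -> pd.DataFrame:
    """Per-arm category counts, percentages and cumulative counts/percentages.

    Percentages are reported to one decimal; cumulation runs from the most
    desirable category downward.
    """
    rows = []
    for arm_idx, arm in enumerate(table.arms):
        c = table.counts[arm_idx].astype(float)
        n = c.sum()
        cum = np.cumsum(c)
        for k in range(table.K):
            rows.append(
                {
                    "arm": arm,
                    "category": table.scheme.labels[k],
                    "n": int(c[k]),
                    "pct": round(100.0 * c[k] / n, 1),
                    "cum_n": int(cum[k]),
                    "cum_pct": round(100.0 * cum[k] / n, 1),
                }
            )
    return pd.DataFrame(rows)


def gain_loss(table: DoorTable, standard_n: int = 1000) -> GainLossSummary:
    """Expected gain/loss per category, standardized per ``standard_n`` patients.

    Per-category value = (a_k/n1 − b_k/n2) · standard_n, rounded half away
    from zero to whole patients; cumulative values are computed the same way
    on cumulative proportions.  Raw counts are used throughout — never the
    rounded percentages.
    """
    if standard_n < 1:
        raise ValueError("standard_n must be ≥ 1")
    a = table.counts[0].astype(float)
    b = table.counts[1].astype(float)
    diff = (a / a.sum() - b / b.sum()) * standard_n
    cum = (np.cumsum(a) / a.sum() - np.cumsum(b) / b.sum()) * standard_n
    return GainLossSummary(
        per_category=tuple(int(v) for v in round_half_away(diff)),
        cumulative=tuple(int(v) for v in round_half_away(cum)),
        standard_n=int(standard_n),
        raw_per_category=tuple(float(v) for v in diff),
        raw_cumulative=tuple(float(v) for v in cum),
    )


def component_gain_loss(
    components: dict[str, DoorTable], standard_n: int = 1000
) -> dict[str, int]:
    """Expected extra events per component (event = the less desirable level).

    value = (event_rate_exp − event_rate_ctl) · standard_n, rounded half away
    from zero.  Negative values mean fewer events on the experimental arm.
    """
    out = {}
    for name, tab in components.items():
        if tab.K != 2:
            raise ValueError(f"component {name!r} must be a 2-level table")
        a = tab.counts[0].astype(float)
        b = tab.counts[1].astype(float)
        diff = (a[1] / a.sum() - b[1] / b.sum()) * standard_n
        out[name] = int(round_half_away(diff))
    return out


def render_markdown(table: DoorTable, summary: GainLossSummary) -> str:
    """Markdown rendering of the distribution + gain/loss table for reports."""
    dist = distribution_table(table)
    exp, ctl = table.arms
    lines = [
        f"| Category | {exp} N (%) | Cum. | {ctl} N (%) | Cum. | Gain/loss | Cum. |",
        "|---|---|---|---|---|---|---|",
    ]
    de = dist[dist["arm"] == exp].reset_index(drop=True)
    dc = dist[dist["arm"] == ctl].reset_index(drop=True)
    for k in range(table.K):
        lines.append(
            f"| {table.scheme.labels[k]} "
            f"| {de.n[k]} ({de.pct[k]}) | {de.cum_n[k]} ({de.cum_pct[k]}) "
            f"| {dc.n[k]} ({dc.pct[k]}) | {dc.cum_n[k]} ({dc.cum_pct[k]}) "
            f"| {summary.per_category[k]} | {summary.cumulative[k]} |"
        )
    return "\n".join(lines)
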