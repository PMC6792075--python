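"""Display formatting for estimate tables.

Rounding is for display only (written CSVs carry full precision):
means of 100 or more print as integers with SEs to one decimal; smaller
means print to one decimal with SEs to two decimals.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["format_mean_se", "format_ci", "format_table"]


def format_mean_se(mean: float, se: float) -> str:
    if abs(mean) >= 100:
        return f"{mean:.0f} ± {se:.1f}"
    return f"{mean:.1f} ± {se:.2f}"


def format_ci(mean: float, lcl: float, ucl: float) -> str:
    if abs(mean) >= 100:
        return f"{lcl:.0f}, {ucl:.0f}"
    return f"{lcl:.1f}, {ucl:.1f}"


def format_table(estimates: pd.DataFrame) -> str:
    """Render an estimates table (quantity, scenario, mean, se, lcl99,
    ucl99) as fixed-width text with Mean ± SE and LCL99, UCL99 columns."""
    if estimates is None or len(estimates) == 0:
        return ""
    rows = []
    for _, r in estimates.iterrows():
        rows.append(
            {
                "Quantity": r["quantity"],
                "Scenario": r["scenario"],
                "Mean ± SE": format_mean_se(r["mean"], r["se"]),
                "LCL99, UCL99": format_ci(r["mean"], r["lcl99"], r["ucl99"]),
            }
        )
    out = pd.DataFrame(rows)
    return out.to_string(index=False)
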