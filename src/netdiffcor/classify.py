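"""Eight-way classification of significant edges for visualization.

A significant edge is driven by the group whose correlation passed the
permutation criterion.  The label encodes the driver group, the sign of the
driver correlation, and whether the other group's correlation agrees in
sign: agreeing signs get the ``_significance`` suffix and a dashed line,
opposing signs get the plain label and a solid line.  Colors follow the
Cytoscape convention of the original visualization: HA-driven positive
edges red, HA-driven negative light green, LA-driven positive green,
LA-driven negative orange.

"LA" and "HA" here name the first and second group of the analysis
orientation (low/high phenotype in the motivating study); the pipeline maps
arbitrary group labels onto these positions.
"""

from __future__ import annotations

import logging
import math

import pandas as pd

logger = logging.getLogger(__name__)

CORR_TYPES = (
    "HA_positive",
    "HA_positive_significance",
    "HA_negative",
    "HA_negative_significance",
    "LA_positive",
    "LA_positive_significance",
    "LA_negative",
    "LA_negative_significance",
)

_STYLE = {
    "HA_positive": ("red", "solid"),
    "HA_positive_significance": ("red", "dashed"),
    "HA_negative": ("light green", "solid"),
    "HA_negative_significance": ("light green", "dashed"),
    "LA_positive": ("green", "solid"),
    "LA_positive_significance": ("green", "dashed"),
    "LA_negative": ("orange", "solid"),
    "LA_negative_significance": ("orange", "dashed"),
}

#: LA<->HA swap sends each type to its mirror
MIRROR = {t: ("LA" + t[2:] if t.startswith("HA") else "HA" + t[2:]) for t in CORR_TYPES}


def classify_edge(
    r_la: float,
    r_ha: float,
    sig_la: bool,
    sig_ha: bool,
    p_la: float | None = None,
    p_ha: float | None = None,
) -> str:
    """Assign one of the 8 correlation types to a significant edge.

    ``sig_*`` flags mark which group's correlation passed the permutation
    criterion; at least one must be set.  When both are significant the
    driver is the group with the smaller correlation p-value (ties: larger
    |r|, then HA).  A driver correlation of exactly zero is degenerate and
    treated as positive; a zero in the non-driver group counts as
    sign-agreeing (dashed).
    """
    if not (sig_la or sig_ha):
        raise ValueError("classify_edge requires at least one significant correlation")

    if sig_la and sig_ha:
        if p_la is not None and p_ha is not None and not math.isclose(p_la, p_ha):
            driver = "LA" if p_la < p_ha else "HA"
        elif abs(r_la) != abs(r_ha):
            driver = "LA" if abs(r_la) > abs(r_ha) else "HA"
        else:
            driver = "HA"
        logger.debug("both correlations significant; driver=%s", driver)
    else:
        driver = "LA" if sig_la else "HA"

    r_driver, r_other = (r_la, r_ha) if driver == "LA" else (r_ha, r_la)
    if r_driver == 0.0:
        logger.debug("driver correlation exactly zero; treating as positive")
    sign = "positive" if r_driver >= 0 else "negative"
    same_sign = (r_other >= 0) == (r_driver >= 0) or r_other == 0.0
    suffix = "_significance" if same_sign else ""
    return f"{driver}_{sign}{suffix}"


def style_for_type(corr_type: str) -> tuple[str, str]:
    """(color, line_style) for a correlation type."""
    try:
        return _STYLE[corr_type]
    except KeyError:
        raise ValueError(f"unknown correlation type: {corr_type!r}") from None


def classify_significant(
    sig_table: pd.DataFrame, group_order: tuple[str, str], alpha: float = 0.05
) -> pd.DataFrame:
    """Classify every significant edge of a significance table.

    ``group_order`` = (first, second) maps onto (LA, HA) positions.  Returns
    the significant rows with corr_type, color and line_style columns added;
    corr_type labels carry the actual group names.
    """
    first, second = group_order
    rows = sig_table[sig_table["significant"]].copy()
    types, colors, styles = [], [], []
    for _, row in rows.iterrows():
        t = classify_edge(
            r_la=row[f"r_{first}"],
            r_ha=row[f"r_{second}"],
            sig_la=bool(row[f"p_r_{first}"] < alpha),
            sig_ha=bool(row[f"p_r_{second}"] < alpha),
            p_la=row[f"p_r_{first}"],
            p_ha=row[f"p_r_{second}"],
        )
        color, style = style_for_type(t)
        types.append(t.replace("LA", first).replace("HA", second))
        colors.append(color)
        styles.append(style)
    rows["corr_type"] = types
    rows["color"] = colors
    rows["line_style"] = styles
    return rows


def type_counts(classified: pd.DataFrame, group_order: tuple[str, str]) -> dict[str, int]:
    """Per-type summary counts (the network-statistics table categories)."""
    first, second = group_order
    labels = [t.replace("LA", first).replace("HA", second) for t in CORR_TYPES]
    counts = classified["corr_type"].value_counts() if len(classified) else {}
    return {lab: int(counts.get(lab, 0)) for lab in labels}
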