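"""Rule-based assignment of cells to six functional groups and tabulation
of group counts per projection target.

Decision order (first match wins):

1. ON_OFF polarity with NVSL above the direction-selectivity threshold
   → On-Off DS.
2. OFF polarity → sustained vs. transient Off by response duration.
3. ON polarity → small-transient On when the response is transient *and*
   the size tuning width is narrow; otherwise sustained vs. transient On
   by duration.

Cells that match no rule (no polarity, missing duration, or ON_OFF without
direction selectivity) are UNCLASSIFIED. The best-size ≤ 200 μm property of
small-transient On cells is advisory in the source data ("generally,
although not always") and is therefore reported but never enforced.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .types import CellMetrics, ClassLabel, ClassifierThresholds, ContingencyTable, Polarity


def classify(
    metrics: CellMetrics,
    thresholds: Optional[ClassifierThresholds] = None,
) -> ClassLabel:
    """Assign one functional group label; total over any metrics record."""
    thr = thresholds or ClassifierThresholds()
    pol = metrics.polarity
    if isinstance(pol, str):
        pol = Polarity(pol)
    dur = metrics.response_duration
    if pol is None:
        return ClassLabel.UNCLASSIFIED
    if pol is Polarity.ON_OFF:
        if metrics.nvsl is not None and metrics.nvsl > thr.nvsl_ds:
            return ClassLabel.ON_OFF_DS
        return ClassLabel.UNCLASSIFIED
    if dur is None:
        return ClassLabel.UNCLASSIFIED
    if pol is Polarity.OFF:
        return (ClassLabel.OFF_SUSTAINED if dur >= thr.duration_sustained
                else ClassLabel.OFF_TRANSIENT)
    # ON branch
    width = metrics.size_tuning_width
    if (dur < thr.duration_sustained and width is not None
            and width < thr.small_width_max):
        return ClassLabel.ON_SMALL_TRANSIENT
    return (ClassLabel.ON_SUSTAINED if dur >= thr.duration_sustained
            else ClassLabel.ON_TRANSIENT)


def classify_table(
    metrics: pd.DataFrame,
    thresholds: Optional[ClassifierThresholds] = None,
) -> pd.DataFrame:
    """Label every row of a metrics table; returns cell_id + class_label."""
    labels = []
    for row in metrics.itertuples(index=False):
        m = CellMetrics(
            cell_id=row.cell_id,
            response_duration=_nan_none(getattr(row, "response_duration", None)),
            nvsl=_nan_none(getattr(row, "nvsl", None)),
            size_tuning_width=_nan_none(getattr(row, "size_tuning_width", None)),
            best_size=_nan_none(getattr(row, "best_size", None)),
            polarity=_pol(getattr(row, "polarity", None)),
        )
        labels.append(classify(m, thresholds).value)
    return pd.DataFrame({"cell_id": metrics.cell_id.to_numpy(),
                         "class_label": labels})


def _nan_none(v):
    if v is None:
        return None
    try:
        return None if np.isnan(v) else float(v)
    except TypeError:
        return v


def _pol(v):
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return None
    return Polarity(v)


def tabulate(labels: pd.DataFrame) -> pd.DataFrame:
    """Class-by-projection-group count table.

    ``labels`` needs ``class_label`` and ``group`` columns; output rows are
    class labels, columns are groups, entries are cell counts (every known
    class appears even at zero so downstream tables align).
    """
    if "group" not in labels.columns:
        raise ValueError("labels table requires a 'group' column")
    if labels.group.isna().any():
        raise ValueError("unknown (missing) projection group")
    counts = pd.crosstab(labels.class_label, labels.group)
    counts = counts.reindex([c.value for c in ClassLabel], fill_value=0)
    counts.index.name = "class_label"
    return counts


def contingency_2x2(
    counts: pd.DataFrame,
    classes: str | list[str],
    groups: tuple[str, str],
    versus: str | list[str] = "rest",
) -> ContingencyTable:
    """Build a 2x2 class-vs-rest (or class-vs-class) table from counts.

    Rows are the two projection groups, columns are (in-class, comparison).
    """
    if isinstance(classes, str):
        classes = [classes]
    g0, g1 = groups
    in0 = int(counts.loc[counts.index.isin(classes), g0].sum())
    in1 = int(counts.loc[counts.index.isin(classes), g1].sum())
    if versus == "rest":
        out0 = int(counts[g0].sum()) - in0
        out1 = int(counts[g1].sum()) - in1
        col2 = "rest"
    else:
        if isinstance(versus, str):
            versus = [versus]
        out0 = int(counts.loc[counts.index.isin(versus), g0].sum())
        out1 = int(counts.loc[counts.index.isin(versus), g1].sum())
        col2 = "+".join(versus)
    return ContingencyTable(
        counts=np.array([[in0, out0], [in1, out1]]),
        row_labels=(g0, g1),
        col_labels=("+".join(classes), col2),
    )


def paper_composition() -> pd.DataFrame:
    """Published coarse composition of the two characterised populations.

    Counts per projection group at the polarity level (On-Off DS, Off, On,
    other/unclassified), with column sums 89 (dLGN) and 103 (SC) — the 192
    functionally characterised cells.
    """
    df = pd.DataFrame(
        {
            "dLGN": [10, 19, 45, 15],
            "SC": [20, 27, 36, 20],
        },
        index=pd.Index(["ON_OFF_DS", "OFF", "ON", "OTHER"], name="class_label"),
    )
    return df
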