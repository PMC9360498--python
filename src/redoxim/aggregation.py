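"""Hierarchical averaging and group summaries.

Two replication models are supported, mirroring how adherent-culture imaging
studies are commonly analysed:

* **dish-based** — cell values are averaged within each FOV (equal cell
  weight), FOV means are averaged within each dish (equal FOV weight,
  regardless of how many cells survived thresholding), and the dish means
  are the replicates.
* **cell-based** — every cell is a replicate.

Pooling schemes map cells to groups by cell line, receptor-status group, or
mitotic status.  Pooling concatenates the replicate lists of the member
units, so e.g. two 3-dish cell lines pooled dish-based give N = 6.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field as dc_field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import AggregationError, ContractError, ParameterError
from .redox_core import COMPARTMENTS, CellRedoxRecord

logger = logging.getLogger(__name__)

Mode = Literal["dish_based", "cell_based"]
Pooling = Literal["per_cell_line", "receptor_group", "mitotic_status"]

#: Indices aggregated by default: the three redox indices per compartment
#: plus the per-cell N:C area ratio.
DEFAULT_INDICES: tuple[tuple[str, str], ...] = tuple(
    (idx, comp) for comp in COMPARTMENTS for idx in ("mean_fp", "mean_nadh", "mean_orr")
) + (("nc_ratio", ""),)

_POOLING_COLUMN = {
    "per_cell_line": "cell_line",
    "receptor_group": "receptor_group",
    "mitotic_status": "mitotic",
}


@dataclass(frozen=True)
class AnalysisMode:
    """Replication model (dish- or cell-based) plus a pooling scheme."""

    mode: Mode = "dish_based"
    pooling: Pooling = "per_cell_line"

    def __post_init__(self) -> None:
        if self.mode not in ("dish_based", "cell_based"):
            raise ParameterError(f"unknown mode {self.mode!r}")
        if self.pooling not in _POOLING_COLUMN:
            raise ParameterError(f"unknown pooling {self.pooling!r}")


@dataclass
class GroupSummary:
    """Mean ± SD of one index for one group under one analysis mode."""

    group: str
    index: str
    compartment: str
    mode: Mode
    values: tuple[float, ...] = dc_field(default_factory=tuple)

    @property
    def n_replicates(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values)) if self.values else float("nan")

    @property
    def sd(self) -> float:
        # n-1 denominator; an SD needs at least two replicates.
        if self.n_replicates < 2:
            return float("nan")
        return float(np.std(self.values, ddof=1))

    def to_row(self) -> dict:
        return {
            "group": self.group,
            "index": self.index,
            "compartment": self.compartment,
            "mode": self.mode,
            "n": self.n_replicates,
            "mean": self.mean,
            "sd": self.sd,
        }


def records_to_dataframe(records: Iterable[CellRedoxRecord] | pd.DataFrame) -> pd.DataFrame:
    """Flatten CellRedoxRecord objects into the per-cell table."""
    if isinstance(records, pd.DataFrame):
        return records.copy()
    rows = [r.to_row() for r in records]
    if not rows:
        raise ContractError("no records to aggregate")
    return pd.DataFrame(rows)


def _index_column(index: str, compartment: str) -> str:
    return f"{compartment}_{index}" if compartment else index


def aggregate(
    records: Iterable[CellRedoxRecord] | pd.DataFrame,
    mode: AnalysisMode,
    indices: Sequence[tuple[str, str]] = DEFAULT_INDICES,
) -> list[GroupSummary]:
    """Aggregate per-cell records into group summaries.

    Cells flagged ``excluded`` or carrying NaN for an index are dropped for
    that index with a logged count.  Dish-based replicates are two-stage
    means (cell -> FOV -> dish, equal weights at each stage); the output is
    deterministic and independent of input record order.
    """
    df = records_to_dataframe(records)
    group_col = _POOLING_COLUMN[mode.pooling]
    if group_col not in df.columns:
        raise ContractError(f"records lack grouping column {group_col!r}")
    if "excluded" in df.columns:
        n_excl = int(df["excluded"].sum())
        if n_excl:
            logger.info("aggregation: dropping %d excluded cells", n_excl)
        df = df[~df["excluded"].astype(bool)]

    summaries: list[GroupSummary] = []
    for index, compartment in indices:
        col = _index_column(index, compartment)
        if col not in df.columns:
            continue
        usable = df[np.isfinite(df[col].astype(float))]
        n_dropped = len(df) - len(usable)
        if n_dropped:
            logger.info("aggregation: %s: dropped %d cells with missing values", col, n_dropped)
        # A dish that appears in the input but contributes no usable cell is
        # an integrity problem, not a silent omission.
        empty_dishes = sorted(set(df["dish_id"]) - set(usable["dish_id"]))
        if empty_dishes:
            raise AggregationError(
                f"index {col}: dish(es) {empty_dishes} have zero usable cells"
            )
        for group_label, sub in sorted(usable.groupby(group_col), key=lambda kv: str(kv[0])):
            if mode.mode == "dish_based":
                fov_means = sub.groupby(["dish_id", "field_id"], sort=True)[col].mean()
                dish_means = fov_means.groupby(level="dish_id").mean()
                values = tuple(float(v) for v in dish_means.sort_index())
            else:
                values = tuple(float(v) for v in sub.sort_values("cell_id")[col])
            label = {True: "mitotic", False: "nonmitotic"}.get(group_label, str(group_label))
            summaries.append(
                GroupSummary(
                    group=label,
                    index=index,
                    compartment=compartment,
                    mode=mode.mode,
                    values=values,
                )
            )
    return summaries


def pool(summaries: Sequence[GroupSummary], members: Sequence[str], label: str) -> list[GroupSummary]:
    """Pool member groups' replicate lists into one group per index.

    The pooled replicate count is the sum of the members' counts (e.g. two
    dish-based cell lines with N = 3 each pool to N = 6).
    """
    pooled: dict[tuple[str, str, str], list[float]] = {}
    for s in summaries:
        if s.group in members:
            pooled.setdefault((s.index, s.compartment, s.mode), []).extend(s.values)
    return [
        GroupSummary(group=label, index=idx, compartment=comp, mode=mode, values=tuple(vals))
        for (idx, comp, mode), vals in pooled.items()
    ]


def percent_difference(summary_a: GroupSummary | float, summary_b: GroupSummary | float) -> float:
    """Signed percent change of A relative to reference B.

    ``100 * (mean_a - mean_b) / mean_b`` — "A compared to B".  The reference
    (denominator) is the second argument.
    """
    mean_a = summary_a.mean if isinstance(summary_a, GroupSummary) else float(summary_a)
    mean_b = summary_b.mean if isinstance(summary_b, GroupSummary) else float(summary_b)
    if isinstance(summary_a, GroupSummary) and isinstance(summary_b, GroupSummary):
        # compartments may differ (nucleus compared to cytoplasm), the index not
        if summary_a.index != summary_b.index:
            raise ContractError(
                f"percent_difference across different indices: "
                f"{summary_a.index} vs {summary_b.index}"
            )
    if not (math.isfinite(mean_a) and math.isfinite(mean_b)):
        raise ContractError("percent_difference requires finite means")
    if mean_b == 0:
        raise ContractError("percent difference undefined for a zero reference mean")
    return 100.0 * (mean_a - mean_b) / mean_b


#: Verdicts of the reliability gate.
RELIABLE = "reliable"
SIGNIFICANT_BUT_BELOW_THRESHOLD = "significant_but_below_threshold"
NOT_SIGNIFICANT = "not_significant"

#: Minimum percent change a statistically significant difference must exceed
#: to be called reliable, guarding against residual instrument variation.
DEFAULT_RELIABILITY_THRESHOLD_PCT = 15.0


def reliability_gate(
    p_value: float,
    pct: float,
    threshold_pct: float = DEFAULT_RELIABILITY_THRESHOLD_PCT,
    alpha: float = 0.05,
) -> str:
    """Classify a comparison as reliable / significant-but-small / not significant.

    A change is *reliable* only if it is statistically significant (p <
    ``alpha``) **and** its magnitude exceeds ``threshold_pct`` percent; a
    significant change at or below the threshold is reported but flagged as
    below the reliability threshold.
    """
    if not threshold_pct > 0:
        raise ParameterError(f"threshold_pct must be > 0, got {threshold_pct}")
    if hasattr(p_value, "p_value"):  # accept a StatResult
        p_value = p_value.p_value
    if not math.isfinite(pct):
        raise ContractError("percent difference must be finite")
    if p_value < alpha:
        return RELIABLE if abs(pct) > threshold_pct else SIGNIFICANT_BUT_BELOW_THRESHOLD
    return NOT_SIGNIFICANT
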