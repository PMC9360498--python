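"""End-to-end orchestration: analyze a bundle, aggregate, run the stats battery.

A *bundle* is the on-disk layout written by
:meth:`redoxim.synthetic_data.StudyBundle.write` (and the layout expected of
real data prepared for this pipeline):

    fields.csv        one row per FOV: channel paths, label-mask paths,
                      pixel size, bit depth, per-channel background mean/SD
    cells.csv         one row per cell: ids, labels, line/group/mitotic flags
    images/*.tif      NADH and Fp channel TIFFs
    masks/*.tif       16-bit label masks (cells, nuclei)

Every run is driven by a :class:`RunConfig`; reruns with identical inputs
and config reproduce all output tables byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .aggregation import (
    AnalysisMode,
    GroupSummary,
    aggregate,
    percent_difference,
    pool,
    reliability_gate,
)
from .errors import ContractError, FormatError, RedoximError
from .imaging_io import (
    BackgroundEstimate,
    read_annotations_from_masks,
    read_field,
    write_records,
)
from .redox_core import COMPARTMENTS, analyze_cell, subtract_and_threshold
from .redox_stats import (
    brown_forsythe_anova,
    compare_slopes,
    dunnett_t3,
    fit_line,
    significance_tier,
    welch_t,
)

logger = logging.getLogger(__name__)

INDICES = ("mean_fp", "mean_nadh", "mean_orr")


@dataclass
class RunConfig:
    """All tunable parameters of one pipeline run.

    ``snr_min`` is the per-pixel SNR threshold applied to both channels;
    ``reliability_threshold_pct`` is the minimum percent change a significant
    difference must exceed to be reported as reliable; ``alpha`` the
    significance level of every test.
    """

    input_dir: str = "."
    output_dir: str = "results"
    snr_min: float = 7.5
    threshold_on: str = "subtracted"  # or "raw"
    area_estimator: str = "weighted"  # or "count"
    area_source: str = "thresholded"  # or "roi"
    modes: tuple[str, ...] = ("dish_based", "cell_based")
    alpha: float = 0.05
    reliability_threshold_pct: float = 15.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ContractError(f"unknown config keys: {sorted(unknown)}")
        if "modes" in data:
            data["modes"] = tuple(data["modes"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["modes"] = list(self.modes)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def digest(self) -> str:
        data = asdict(self)
        data["modes"] = list(self.modes)
        return hashlib.sha256(json.dumps(data, sort_keys=True).encode()).hexdigest()[:16]


def load_bundle(input_dir: str | Path):
    """Load a bundle directory into fields and annotations."""
    root = Path(input_dir)
    fields_csv = root / "fields.csv"
    cells_csv = root / "cells.csv"
    for p in (fields_csv, cells_csv):
        if not p.exists():
            raise FormatError(f"missing required input file: {p}")
    field_table = pd.read_csv(fields_csv)
    sheet = pd.read_csv(cells_csv)
    fields = []
    annotations = []
    for row in field_table.itertuples(index=False):
        bg_nadh = BackgroundEstimate(row.bg_nadh_mean, row.bg_nadh_sd, "blank_image")
        bg_fp = BackgroundEstimate(row.bg_fp_mean, row.bg_fp_sd, "blank_image")
        fld = read_field(
            root / row.nadh_path,
            root / row.fp_path,
            field_id=str(row.field_id),
            dish_id=str(row.dish_id),
            pixel_size_um=float(row.pixel_size_um),
            bit_depth=int(row.bit_depth),
            background_nadh=bg_nadh,
            background_fp=bg_fp,
        )
        fields.append(fld)
        sub = sheet[sheet["field_id"].astype(str) == str(row.field_id)]
        annotations.extend(
            read_annotations_from_masks(
                root / row.cell_labels_path,
                root / row.nucleus_labels_path,
                sub,
                [fld],
            )
        )
    return fields, annotations


def analyze_records(fields, annotations, config: RunConfig) -> pd.DataFrame:
    """Run the per-cell measurement chain over in-memory fields/annotations."""
    by_field = {f.field_id: f for f in fields}
    channel_cache = {}
    rows = []
    for ann in annotations:
        fld = by_field[ann.field_id]
        if ann.field_id not in channel_cache:
            channel_cache[ann.field_id] = subtract_and_threshold(
                fld, snr_min=config.snr_min, threshold_on=config.threshold_on
            )
        try:
            rec = analyze_cell(
                fld,
                ann,
                channels=channel_cache[ann.field_id],
                area_estimator=config.area_estimator,
                area_source=config.area_source,
            )
        except RedoximError as exc:
            logger.warning("cell %s skipped: %s", ann.cell_id, exc)
            continue
        rows.append(rec.to_row())
    if not rows:
        raise ContractError("no cells produced records")
    return pd.DataFrame(rows)


def run_analyze(config: RunConfig):
    """Analyze a bundle on disk: per-cell CSV, exclusion log, run manifest."""
    fields, annotations = load_bundle(config.input_dir)
    records = analyze_records(fields, annotations, config)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_records(records, out / "per_cell_records.csv")
    excluded = records[records["excluded"].astype(bool)]
    lines = [
        f"analyzed cells: {len(records)}",
        f"excluded cells: {len(excluded)}",
    ]
    for dish, sub in records.groupby("dish_id"):
        lines.append(
            f"dish {dish}: analyzed {len(sub)}, excluded {int(sub['excluded'].sum())}"
        )
    (out / "run_log.txt").write_text("\n".join(lines) + "\n")
    manifest = {
        "redoxim_version": __version__,
        "config": asdict(config),
        "config_digest": config.digest(),
        "n_fields": len(fields),
        "n_cells": len(records),
        "n_excluded": int(excluded.shape[0]),
    }
    manifest["config"]["modes"] = list(config.modes)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return records


# ---------------------------------------------------------------------------
# Statistics battery
# ---------------------------------------------------------------------------


def _summaries(records: pd.DataFrame, mode: str, pooling: str) -> list[GroupSummary]:
    return aggregate(records, AnalysisMode(mode=mode, pooling=pooling))


def _find(summaries, group, index, compartment) -> GroupSummary | None:
    for s in summaries:
        if s.group == group and s.index == index and s.compartment == compartment:
            return s
    return None


def _row(comparison, mode, group, index, compartment, stat, pct, verdict):
    return {
        "comparison": comparison,
        "mode": mode,
        "group": group,
        "index": index,
        "compartment": compartment,
        "test": stat.test if stat is not None else "",
        "statistic": stat.statistic if stat is not None else np.nan,
        "df": stat.df if stat is not None else np.nan,
        "p_value": stat.p_value if stat is not None else np.nan,
        "p_adjusted": (stat.p_adjusted if stat and stat.p_adjusted is not None else np.nan),
        "effect_size": (stat.effect_size if stat and stat.effect_size is not None else np.nan),
        "pct_difference": pct if pct is not None else np.nan,
        "tier": significance_tier(
            stat.p_adjusted if stat and stat.p_adjusted is not None else stat.p_value
        )
        if stat is not None
        else "",
        "verdict": verdict or "",
    }


def compartment_comparison_rows(records, mode, pooling, config) -> list[dict]:
    """Within-group compartment battery: ANOVA over the three compartments
    followed by all-pairwise comparisons, for each redox index."""
    summaries = _summaries(records, mode, pooling)
    groups = sorted({s.group for s in summaries})
    rows = []
    for group in groups:
        for index in INDICES:
            comp_summaries = [_find(summaries, group, index, c) for c in COMPARTMENTS]
            if any(s is None or s.n_replicates < 2 for s in comp_summaries):
                rows.append(_row(f"compartments[{index}]", mode, group, index, "", None, None, "not_evaluable"))
                continue
            samples = [np.asarray(s.values) for s in comp_summaries]
            try:
                anova = brown_forsythe_anova(samples)
                rows.append(_row("compartments_anova", mode, group, index, "all", anova, None, None))
                for pair in dunnett_t3(samples, labels=COMPARTMENTS):
                    # report the later compartment relative to the earlier one,
                    # so e.g. the nucleus is compared *to* the cytoplasm
                    subject, ref_label = pair.labels[1], pair.labels[0]
                    subject_s = _find(summaries, group, index, subject)
                    ref = _find(summaries, group, index, ref_label)
                    pct = percent_difference(subject_s, ref)
                    pair = dataclasses.replace(
                        pair, statistic=-pair.statistic, labels=(subject, ref_label)
                    )
                    verdict = reliability_gate(
                        pair.p_adjusted, pct,
                        threshold_pct=config.reliability_threshold_pct,
                        alpha=config.alpha,
                    )
                    rows.append(
                        _row(
                            f"{subject}_vs_{ref_label}",
                            mode, group, index, subject, pair, pct, verdict,
                        )
                    )
            except RedoximError as exc:
                logger.warning("compartment battery %s/%s failed: %s", group, index, exc)
                rows.append(_row(f"compartments[{index}]", mode, group, index, "", None, None, "not_evaluable"))
    return rows


def receptor_group_rows(records, mode, config) -> list[dict]:
    """Triple-negative vs receptor-positive comparisons (pooled lines)."""
    summaries = _summaries(records, mode, "receptor_group")
    rows = []
    indices = [(i, c) for c in COMPARTMENTS for i in INDICES] + [("nc_ratio", "")]
    for index, comp in indices:
        a = _find(summaries, "triple_negative", index, comp)
        b = _find(summaries, "receptor_positive", index, comp)
        if a is None or b is None or a.n_replicates < 2 or b.n_replicates < 2:
            rows.append(_row("tn_vs_rp", mode, "pooled", index, comp, None, None, "not_evaluable"))
            continue
        stat = welch_t(np.asarray(a.values), np.asarray(b.values),
                       labels=("triple_negative", "receptor_positive"))
        pct = percent_difference(a, b)
        verdict = reliability_gate(
            stat.p_value, pct,
            threshold_pct=config.reliability_threshold_pct, alpha=config.alpha,
        )
        rows.append(_row("tn_vs_rp", mode, "pooled", index, comp, stat, pct, verdict))
    return rows


def mitotic_rows(records, mode, config) -> list[dict]:
    """Mitotic vs nonmitotic comparisons on the pooled triple-negative lines."""
    tn = records[records["receptor_group"] == "triple_negative"]
    if tn.empty or tn["mitotic"].astype(bool).nunique() < 2:
        return []
    summaries = _summaries(tn, mode, "mitotic_status")
    rows = []
    indices = [(i, c) for c in COMPARTMENTS for i in INDICES] + [("nc_ratio", "")]
    for index, comp in indices:
        a = _find(summaries, "mitotic", index, comp)
        b = _find(summaries, "nonmitotic", index, comp)
        if a is None or b is None or a.n_replicates < 2 or b.n_replicates < 2:
            continue
        stat = welch_t(np.asarray(a.values), np.asarray(b.values), labels=("mitotic", "nonmitotic"))
        pct = percent_difference(a, b)
        verdict = reliability_gate(
            stat.p_value, pct,
            threshold_pct=config.reliability_threshold_pct, alpha=config.alpha,
        )
        rows.append(_row("mitotic_vs_nonmitotic", mode, "triple_negative", index, comp, stat, pct, verdict))
    return rows


def regression_rows(records) -> list[dict]:
    """Cell-based nucleus-on-cytoplasm regressions, per line and index,
    plus mitotic-vs-nonmitotic slope comparisons where both exist."""
    rows = []
    usable = records[~records["excluded"].astype(bool)]
    for line, line_df in sorted(usable.groupby("cell_line")):
        for index in INDICES:
            fits = {}
            for status, sub in line_df.groupby(line_df["mitotic"].astype(bool)):
                x = sub[f"cytoplasm_{index}"].astype(float)
                y = sub[f"nucleus_{index}"].astype(float)
                keep = np.isfinite(x) & np.isfinite(y)
                if keep.sum() < 3 or x[keep].nunique() < 2:
                    continue
                fit = fit_line(x[keep].to_numpy(), y[keep].to_numpy())
                fits["mitotic" if status else "nonmitotic"] = fit
                rows.append(
                    {
                        "comparison": "nucleus_on_cytoplasm_regression",
                        "mode": "cell_based",
                        "group": f"{line}/{'mitotic' if status else 'nonmitotic'}",
                        "index": index,
                        "compartment": "nucleus~cytoplasm",
                        "test": "ols",
                        "statistic": fit.slope,
                        "df": fit.n - 2,
                        "p_value": fit.p_value,
                        "p_adjusted": np.nan,
                        "effect_size": fit.r_squared,
                        "pct_difference": np.nan,
                        "tier": significance_tier(fit.p_value),
                        "verdict": "",
                    }
                )
            if "mitotic" in fits and "nonmitotic" in fits:
                stat = compare_slopes(fits["mitotic"], fits["nonmitotic"])
                rows.append(
                    _row("slope_mitotic_vs_nonmitotic", "cell_based", line, index,
                         "nucleus~cytoplasm", stat, None, None)
                )
    return rows


def run_stats(config: RunConfig, records: pd.DataFrame) -> pd.DataFrame:
    """Run the full comparison battery and return the report table.

    One row per (comparison, mode, group, index, compartment) with the test
    statistic, df, raw and adjusted p, Cohen's d / R², percent difference
    and reliability verdict.
    """
    if records.empty:
        raise ContractError("run_stats: empty record table")
    rows: list[dict] = []
    for mode in config.modes:
        rows += compartment_comparison_rows(records, mode, "per_cell_line", config)
        rows += compartment_comparison_rows(records, mode, "receptor_group", config)
        rows += receptor_group_rows(records, mode, config)
        rows += mitotic_rows(records, mode, config)
    rows += regression_rows(records)
    report = pd.DataFrame(rows)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_records(report, out / "stats_report.csv")
    return report
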