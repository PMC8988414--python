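"""Statistical comparison of paired flow estimates.

Pearson product-moment correlation and Bland-Altman limits of agreement
(mean difference +/- 1.96 x SD of the differences, sample SD with the n-1
denominator) between the three per-site flow methods: benchtop-derived,
invasive-derived and Windkessel ("electrical"). Emitters reproduce the
shape of the study's summary tables: per-model input-flow balances, per-site
three-method flows, and per-model correlation matrices with an average row.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UndefinedCorrelationError
from .flow import SiteFlowReport, reports_to_frame

__all__ = [
    "PAIR_LABELS",
    "ComparisonResult",
    "pearson",
    "bland_altman",
    "compare_pair",
    "table1",
    "table2",
    "table3",
    "bland_altman_table",
    "summarize_tables",
]

#: The three method pairs, as (label, column_x, column_y).
PAIR_LABELS = (
    ("Benchtop/Invasive", "I_benchtop_cc_s", "I_invasive_cc_s"),
    ("Electrical/Invasive", "I_windkessel_cc_s", "I_invasive_cc_s"),
    ("Benchtop/Electrical", "I_benchtop_cc_s", "I_windkessel_cc_s"),
)


@dataclass(frozen=True)
class ComparisonResult:
    """Pearson r and Bland-Altman summary for one method pair."""

    pair_label: str
    pearson_r: float
    ba_mean_diff: float
    ba_limits: tuple[float, float]
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("comparison requires n >= 2")
        if not -1.0 <= self.pearson_r <= 1.0:
            raise ValueError("pearson_r outside [-1, 1]")
        lo, hi = self.ba_limits
        if not (lo - 1e-12 <= self.ba_mean_diff <= hi + 1e-12):
            raise ValueError("Bland-Altman limits must bracket the mean")


def _paired(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be 1-D vectors of equal length")
    if x.size < 2:
        raise ValueError("need at least two paired observations")
    return x, y


def pearson(x, y) -> float:
    """Pearson product-moment correlation of two paired flow vectors."""
    x, y = _paired(x, y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError(
            "correlation undefined for a zero-variance input"
        )
    return float(stats.pearsonr(x, y).statistic)


def bland_altman(x, y) -> tuple[float, tuple[float, float]]:
    """Mean difference and 95% limits of agreement for paired vectors.

    Differences d = x - y; limits are mean(d) +/- 1.96 * SD(d) with the
    sample (n-1) standard deviation.
    """
    x, y = _paired(x, y)
    d = x - y
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return mean, (mean - 1.96 * sd, mean + 1.96 * sd)


def compare_pair(x, y, pair_label: str) -> ComparisonResult:
    x, y = _paired(x, y)
    mean, limits = bland_altman(x, y)
    return ComparisonResult(
        pair_label=pair_label,
        pearson_r=pearson(x, y),
        ba_mean_diff=mean,
        ba_limits=limits,
        n=int(x.size),
    )


# -- table emitters --------------------------------------------------------


def _require_reports(reports: list[SiteFlowReport]) -> pd.DataFrame:
    if not reports:
        raise ValueError("no reports to summarize")
    return reports_to_frame(reports)


def table1(reports: list[SiteFlowReport]) -> pd.DataFrame:
    """Input-flow balance per model and state: total coronary inflow, aortic
    outflow, and their sum (the configured total input flow)."""
    df = _require_reports(reports)
    rows = []
    for (model, activity), grp in df.groupby(["model", "activity"], sort=False):
        coronary = grp["total_coronary_inflow_cc_s"].iloc[0]
        aorta = grp["aortic_outlet_flow_cc_s"].iloc[0]
        rows.append(
            {
                "model": model,
                "activity": activity,
                "coronary_inflow_cc_s": coronary,
                "leaving_aorta_cc_s": aorta,
                "total_cc_s": coronary + aorta,
            }
        )
    return pd.DataFrame(rows)


def table2(reports: list[SiteFlowReport]) -> pd.DataFrame:
    """Three-method flows at every site and state (one row per site x state)."""
    df = _require_reports(reports)
    return df[
        [
            "model",
            "site",
            "activity",
            "I_invasive_cc_s",
            "I_benchtop_cc_s",
            "I_windkessel_cc_s",
            "model_ffr",
        ]
    ].copy()


def table3(reports: list[SiteFlowReport]) -> pd.DataFrame:
    """Per-model Pearson correlations of the three method pairs over that
    model's site x state flows, plus an arithmetic-mean Average row."""
    df = _require_reports(reports)
    rows = []
    for model, grp in df.groupby("model", sort=False):
        row: dict[str, object] = {"model": model}
        for label, cx, cy in PAIR_LABELS:
            sub = grp.dropna(subset=[cx, cy])
            row[label] = (
                pearson(sub[cx], sub[cy]) if len(sub) >= 2 else math.nan
            )
        rows.append(row)
    out = pd.DataFrame(rows)
    avg: dict[str, object] = {"model": "Average"}
    for label, _, _ in PAIR_LABELS:
        avg[label] = out[label].mean()
    return pd.concat([out, pd.DataFrame([avg])], ignore_index=True)


def bland_altman_table(
    reports: list[SiteFlowReport], grouping: str = "pooled"
) -> pd.DataFrame:
    """Bland-Altman summaries for the three pairs.

    ``grouping="pooled"`` uses every site x state point across all models;
    ``grouping="per_model"`` first averages each model's points, then
    compares the per-model means.
    """
    if grouping not in ("pooled", "per_model"):
        raise ValueError(f"unknown grouping {grouping!r}")
    df = _require_reports(reports)
    rows = []
    for label, cx, cy in PAIR_LABELS:
        sub = df.dropna(subset=[cx, cy])
        if grouping == "per_model":
            sub = sub.groupby("model", sort=False)[[cx, cy]].mean().reset_index()
        if len(sub) < 2:
            continue
        mean, (lo, hi) = bland_altman(sub[cx], sub[cy])
        rows.append(
            {
                "pair": label,
                "mean_diff_cc_s": mean,
                "lower_loa_cc_s": lo,
                "upper_loa_cc_s": hi,
                "n": len(sub),
            }
        )
    return pd.DataFrame(rows)


def summarize_tables(
    reports: list[SiteFlowReport], ba_grouping: str = "pooled"
) -> dict[str, pd.DataFrame]:
    """All summary tables at once: input-flow balance, site flows,
    per-model correlations, and Bland-Altman limits."""
    return {
        "table1": table1(reports),
        "table2": table2(reports),
        "table3": table3(reports),
        "bland_altman": bland_altman_table(reports, grouping=ba_grouping),
    }
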