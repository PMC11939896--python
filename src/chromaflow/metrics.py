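"""Analytical-performance statistics for colorimetric assay validation.

Implements the standard validation battery for a clinical-chemistry
method: limit of detection (LoD = n * sd / slope), percent coefficient of
variation (intra/inter repeatability), spike-and-recovery accuracy,
cross-condition average variation, and method-comparison summaries
against a reference analyzer.

All functions return raw unrounded values; display rounding (2 decimals
for variation %, 1 for recovery %, 3 significant figures for %CV) is
applied only by the report generator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError


# ---------------------------------------------------------------------------
# Limit of detection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LoDInput:
    """Inputs of the LoD formula.

    ``replicate_sd`` is the standard deviation of replicate blank-level
    concentration estimates (assay units); ``slope`` the calibration slope
    or its concentration-domain analogue; ``n_multiplier`` the detection
    multiplier — deliberately a required parameter, since conventions
    differ (3.3 is classical; replicate-count n is also used).
    """

    replicate_sd: float
    slope: float
    n_multiplier: float

    def __post_init__(self) -> None:
        if self.replicate_sd < 0:
            raise ParameterError("replicate_sd must be >= 0")
        if self.slope <= 0:
            raise ParameterError("slope must be > 0")
        if self.n_multiplier <= 0:
            raise ParameterError("n_multiplier must be > 0")


def lod(inp: LoDInput) -> float:
    """Limit of detection: n * sd / slope."""
    return inp.n_multiplier * inp.replicate_sd / inp.slope


# ---------------------------------------------------------------------------
# Spike and recovery
# ---------------------------------------------------------------------------

def recovery(baseline: float, spike: float, measured: float) -> float:
    """Recovery % = (measured - baseline) / spike * 100."""
    if spike <= 0:
        raise ParameterError(f"spike must be > 0, got {spike}")
    return (measured - baseline) / spike * 100.0


@dataclass(frozen=True)
class RecoveryRecord:
    """One spike-and-recovery row."""

    baseline: float
    spike: float
    measured: float

    @property
    def recovery_pct(self) -> float:
        return recovery(self.baseline, self.spike, self.measured)


# ---------------------------------------------------------------------------
# Repeatability (%CV)
# ---------------------------------------------------------------------------

def percent_cv(values: Sequence[float]) -> float:
    """Coefficient of variation: 100 * sample sd / mean (ddof = 1)."""
    arr = np.asarray(values, dtype=np.float64)
    if arr.size < 2:
        raise ParameterError("need at least 2 values for %CV")
    mean = arr.mean()
    if mean <= 0:
        raise ParameterError(f"%CV undefined for mean {mean:g} <= 0")
    return float(100.0 * arr.std(ddof=1) / mean)


@dataclass(frozen=True)
class RepeatabilityReport:
    """%CV of one replicate group; intra = same sample repeated,
    inter = different samples at the same concentration — the statistic
    is identical, only the grouping differs."""

    group_label: str
    values: tuple[float, ...]
    mode: str = "intra"  # intra | inter

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        return float(np.std(self.values, ddof=1))

    @property
    def cv_pct(self) -> float:
        return percent_cv(self.values)


# ---------------------------------------------------------------------------
# Cross-condition average variation
# ---------------------------------------------------------------------------

def average_variation(actual: float, measurements: Sequence[float]) -> float:
    """Mean absolute relative deviation from the true concentration, in %.

    This is the consistency statistic for one analyte level measured
    under a grid of devices, reagent brands and lighting conditions.
    """
    if actual <= 0:
        raise ParameterError(f"actual concentration must be > 0, got {actual}")
    arr = np.asarray(measurements, dtype=np.float64)
    if arr.size < 1:
        raise ParameterError("need at least one measurement")
    return float(np.mean(np.abs(arr - actual) / actual) * 100.0)


@dataclass(frozen=True)
class VariationRow:
    actual: float
    measurements: tuple[float, ...]

    @property
    def avg_variation_pct(self) -> float:
        return average_variation(self.actual, self.measurements)


# ---------------------------------------------------------------------------
# Method comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MethodComparison:
    """Developed-vs-reference summary over paired measurements."""

    mean_difference: float
    mean_absolute_difference: float
    pearson_r: float | None  # None when a series has zero variance


def method_comparison(pairs: Sequence[tuple[float, float]]) -> MethodComparison:
    """Summaries of (reference, test) concentration pairs."""
    arr = np.asarray(pairs, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ParameterError("need at least 2 (reference, test) pairs")
    ref, test = arr[:, 0], arr[:, 1]
    diff = test - ref
    if np.std(ref) == 0 or np.std(test) == 0:
        r = None
    else:
        r = float(stats.pearsonr(ref, test).statistic)
    return MethodComparison(
        mean_difference=float(diff.mean()),
        mean_absolute_difference=float(np.abs(diff).mean()),
        pearson_r=r,
    )


# ---------------------------------------------------------------------------
# Report generation (CSV/Markdown summaries of the validation tables)
# ---------------------------------------------------------------------------

def _sigfig(x: float, n: int) -> float:
    if x == 0:
        return 0.0
    from math import floor, log10

    return round(x, -int(floor(log10(abs(x)))) + (n - 1))


def variation_table(rows: Sequence[VariationRow]) -> pd.DataFrame:
    """Cross-condition variation summary, one row per analyte level."""
    recs = []
    for row in rows:
        rec = {"actual": row.actual}
        for i, m in enumerate(row.measurements, start=1):
            rec[f"m{i}"] = m
        rec["avg_variation_pct"] = row.avg_variation_pct
        rec["avg_variation_pct_rounded"] = round(row.avg_variation_pct, 2)
        recs.append(rec)
    return pd.DataFrame(recs)


def recovery_table(records: Sequence[RecoveryRecord]) -> pd.DataFrame:
    recs = [
        {
            "baseline": r.baseline,
            "spike": r.spike,
            "measured": r.measured,
            "recovery_pct": r.recovery_pct,
            "recovery_pct_rounded": round(r.recovery_pct, 1),
        }
        for r in records
    ]
    return pd.DataFrame(recs)


def repeatability_table(reports: Sequence[RepeatabilityReport]) -> pd.DataFrame:
    recs = [
        {
            "group": r.group_label,
            "mode": r.mode,
            "n": len(r.values),
            "mean": r.mean,
            "sd": r.sd,
            "cv_pct": r.cv_pct,
            "cv_pct_rounded": _sigfig(r.cv_pct, 3),
        }
        for r in reports
    ]
    return pd.DataFrame(recs)


def comparison_table(
    pairs_by_assay: dict[str, Sequence[tuple[float, float]]]
) -> pd.DataFrame:
    recs = []
    for assay_id, pairs in pairs_by_assay.items():
        summ = method_comparison(pairs)
        recs.append(
            {
                "assay": assay_id,
                "n_pairs": len(pairs),
                "mean_difference": summ.mean_difference,
                "mean_absolute_difference": summ.mean_absolute_difference,
                "pearson_r": summ.pearson_r,
            }
        )
    return pd.DataFrame(recs)


def _df_to_markdown(df: pd.DataFrame) -> str:
    cols = [str(c) for c in df.columns]

    def fmt(v) -> str:
        if isinstance(v, float):
            return "" if pd.isna(v) else f"{v:g}"
        return "" if v is None else str(v)

    lines = ["| " + " | ".join(cols) + " |", "| " + " | ".join("---" for _ in cols) + " |"]
    for _, row in df.iterrows():
        lines.append("| " + " | ".join(fmt(row[c]) for c in df.columns) + " |")
    return "\n".join(lines)


def write_report(tables: dict[str, pd.DataFrame], out_dir) -> list:
    """Write each summary as CSV plus one combined Markdown document."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    md_parts = []
    for name, df in tables.items():
        csv_path = out / f"{name}.csv"
        df.to_csv(csv_path, index=False)
        written.append(csv_path)
        md_parts.append(f"## {name.replace('_', ' ').title()}\n\n" + _df_to_markdown(df))
    md_path = out / "report.md"
    md_path.write_text("# Validation report\n\n" + "\n\n".join(md_parts) + "\n")
    written.append(md_path)
    return written
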