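"""Cohort-level reporting: severity grouping and correlation analysis.

For a set of lesions, each carrying its anatomy (AS%, MLA) and the
curve-derived indices (f, s, S1, S2, optionally FFR), this module
computes the severity-group partition and the Pearson correlations of
each index against each available covariate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CohortRecord",
    "classify_severity",
    "pearson_r",
    "correlation_report",
    "cohort_to_csv",
    "cohort_from_csv",
    "UndefinedCorrelationError",
]

INDEX_COLUMNS = ("f", "s", "s1", "s2")
COVARIATE_COLUMNS = ("as_percent", "mla", "ffr")


class UndefinedCorrelationError(ValueError):
    """Raised for constant vectors, where Pearson r is undefined."""


@dataclass
class CohortRecord:
    """One lesion's anatomy and curve-derived indices."""

    id: str
    as_percent: float
    mla: float            # mm^2
    f: float              # mmHg.s/ml
    s: float              # mmHg.s^2/ml^2
    s1: float             # mmHg.ml/s
    s2: float
    ffr: float | None = None   # virtual or invasive, in (0, 1]

    def __post_init__(self):
        if min(self.f, self.s, self.s1, self.s2) < 0:
            raise ValueError("indices must be non-negative")
        if self.ffr is not None and not (0 < self.ffr <= 1):
            raise ValueError("ffr must lie in (0, 1]")


def classify_severity(as_percent: float) -> str:
    """Severity group of a lesion by area stenosis.

    severe for AS% > 70, middle for 50 <= AS% <= 70, mild below 50.
    The middle group is closed on both ends so the partition of
    [0, 100] is total.
    """
    if not (0 <= as_percent <= 100):
        raise ValueError("as_percent must lie in [0, 100]")
    if as_percent > 70:
        return "severe"
    if as_percent >= 50:
        return "middle"
    return "mild"


def pearson_r(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with a two-sided p-value.

    The p-value comes from the exact t transform with n - 2 degrees of
    freedom.  Raises for constant vectors, where r is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("x and y must be equal-length 1-D arrays with >= 3 entries")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for a constant vector")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def _records_frame(cohort: list[CohortRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in cohort])


def correlation_report(cohort: list[CohortRecord]) -> pd.DataFrame:
    """Correlations of each index against each available covariate.

    Returns a long-format table with one row per (index, covariate)
    pair and columns r, abs_r, p_value, n.  Absolute values are carried
    alongside signed r because the resistance indices anti-correlate
    with MLA and FFR by physiology.  Cells whose correlation is
    undefined (constant vectors) are reported as missing, not raised.
    """
    if len(cohort) < 3:
        raise ValueError("a correlation report requires at least 3 records")
    df = _records_frame(cohort)
    rows = []
    for index in INDEX_COLUMNS:
        for cov in COVARIATE_COLUMNS:
            if cov == "ffr" and df["ffr"].isna().any():
                continue
            sub = df[[index, cov]].dropna()
            try:
                r, p = pearson_r(sub[index], sub[cov])
                rows.append({"index": index, "covariate": cov, "r": r,
                             "abs_r": abs(r), "p_value": p, "n": len(sub)})
            except (UndefinedCorrelationError, ValueError):
                rows.append({"index": index, "covariate": cov, "r": np.nan,
                             "abs_r": np.nan, "p_value": np.nan, "n": len(sub)})
    return pd.DataFrame(rows)


def severity_counts(cohort: list[CohortRecord]) -> dict[str, int]:
    counts = {"severe": 0, "middle": 0, "mild": 0}
    for rec in cohort:
        counts[classify_severity(rec.as_percent)] += 1
    return counts


def report_to_files(cohort: list[CohortRecord], out_json: str | Path,
                    out_csv: str | Path | None = None) -> dict:
    """Serialize the correlation report plus severity counts."""
    table = correlation_report(cohort)
    doc = {
        "n_lesions": len(cohort),
        "severity_counts": severity_counts(cohort),
        "severity_group_rule": "severe: AS%>70; middle: 50<=AS%<=70; mild: AS%<50",
        "correlations": table.where(pd.notna(table), None).to_dict(orient="records"),
    }
    Path(out_json).write_text(json.dumps(doc, indent=1))
    if out_csv is not None:
        table.to_csv(out_csv, index=False)
    return doc


def cohort_to_csv(cohort: list[CohortRecord], path: str | Path) -> None:
    df = _records_frame(cohort).rename(columns={"mla": "mla_mm2"})
    df.to_csv(path, index=False)


def cohort_from_csv(path: str | Path) -> list[CohortRecord]:
    df = pd.read_csv(path).rename(columns={"mla_mm2": "mla"})
    records = []
    for _, row in df.iterrows():
        ffr = row.get("ffr")
        records.append(CohortRecord(
            id=str(row["id"]), as_percent=float(row["as_percent"]),
            mla=float(row["mla"]), f=float(row["f"]), s=float(row["s"]),
            s1=float(row["s1"]), s2=float(row["s2"]),
            ffr=None if pd.isna(ffr) else float(ffr),
        ))
    return records
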