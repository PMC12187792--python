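"""Robust per-element summary statistics and the log10 transform.

The survey reports, per element: min, max, mean, SD (n-1 denominator),
RSD% = 100*SD/mean, quartiles, median and the *unscaled* MAD
(median of absolute deviations from the median, no 1.4826 consistency
factor).  A robust coefficient of variation 100*MAD/median complements the
classical RSD for tightly-controlled elements such as carbon.

Because trace-element concentrations are typically log-normal, matrices fed
to clustering are log10-transformed medians: the median across analytical
replicates is taken first, then log10 (the alternative, median of logs, is
available via ``log_mode``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .io_model import ConcentrationTable, aggregate_replicates

__all__ = [
    "ElementSummary",
    "summarize_element",
    "summarize_table",
    "robust_cv",
    "log10_medians",
    "flag_inconsistent",
]

#: column order of the emitted summary table
SUMMARY_COLUMNS = ["min", "max", "mean", "sd", "rsd_percent", "q1", "median", "q3", "mad"]


@dataclass(frozen=True)
class ElementSummary:
    element: str
    n: int
    min: float
    max: float
    mean: float
    sd: float
    rsd_percent: float  # NaN when mean == 0
    q1: float
    median: float
    q3: float
    mad: float

    def is_consistent(self) -> bool:
        """Order sanity of the printed battery: min <= q1 <= median <= q3 <= max
        and mean within [min, max].  Inconsistent rows are flagged, never
        repaired (they can occur in transcribed tables)."""
        ordered = self.min <= self.q1 <= self.median <= self.q3 <= self.max
        mean_ok = self.min <= self.mean <= self.max
        return bool(ordered and mean_ok)


def _mad(x: np.ndarray) -> float:
    return float(np.median(np.abs(x - np.median(x))))


def summarize_element(
    values, element: str = "", quartile_method: str = "linear"
) -> ElementSummary:
    """Nine-statistic summary of one element's concentrations across sites."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise ValueError(f"element {element!r}: need >= 2 finite values, got {x.size}")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    q1, med, q3 = (float(q) for q in np.quantile(x, [0.25, 0.5, 0.75], method=quartile_method))
    rsd = 100.0 * sd / mean if mean > 0 else float("nan")
    return ElementSummary(
        element=element,
        n=int(x.size),
        min=float(np.min(x)),
        max=float(np.max(x)),
        mean=mean,
        sd=sd,
        rsd_percent=rsd,
        q1=q1,
        median=med,
        q3=q3,
        mad=_mad(x),
    )


def summarize_table(
    table: ConcentrationTable,
    replicate_rule: str = "median",
    quartile_method: str = "linear",
) -> pd.DataFrame:
    """Per-element summary battery across sites (replicates aggregated first).

    Columns follow the conventional report order Min..MAD; rows are elements.
    """
    agg = aggregate_replicates(table, rule=replicate_rule) if table.has_replicates else table
    wide = agg.to_wide()
    rows = []
    for element in wide.columns:
        vals = wide[element].dropna()
        if vals.size < 2:
            warnings.warn(f"element {element}: fewer than 2 values, skipped", UserWarning)
            continue
        rows.append(asdict(summarize_element(vals, element, quartile_method)))
    out = pd.DataFrame(rows).set_index("element")
    return out[["n"] + SUMMARY_COLUMNS]


def robust_cv(values) -> float:
    """Robust coefficient of variation, 100*MAD/median (percent).

    Returns NaN with a warning when the median is not positive.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("robust_cv of an empty vector")
    med = float(np.median(x))
    if med <= 0:
        warnings.warn("robust CV undefined for median <= 0", UserWarning, stacklevel=2)
        return float("nan")
    return 100.0 * _mad(x) / med


def log10_medians(
    table: ConcentrationTable,
    mode: str = "by_element",
    log_mode: str = "log_of_median",
) -> pd.DataFrame:
    """log10 of replicate medians, oriented for clustering.

    ``by_element`` puts elements on rows (for clustering element profiles),
    ``by_site`` puts sites on rows.  All values must be strictly positive --
    censoring substitution must already have happened upstream.
    """
    if mode not in ("by_element", "by_site"):
        raise ValueError(f"unknown mode {mode!r}")
    if log_mode not in ("log_of_median", "median_of_logs"):
        raise ValueError(f"unknown log_mode {log_mode!r}")

    df = table.data
    if (df["value_mg_kg"] <= 0).any() or df["value_mg_kg"].isna().any():
        bad = df[(df["value_mg_kg"] <= 0) | df["value_mg_kg"].isna()].iloc[0]
        raise ValueError(
            f"nonpositive or missing value for element {bad['element']} at site "
            f"{bad['site_id']}; apply a censoring policy upstream"
        )
    if log_mode == "log_of_median":
        med = df.groupby(["site_id", "element"])["value_mg_kg"].median()
        mat = np.log10(med).unstack("element")
    else:
        logs = df.assign(logv=np.log10(df["value_mg_kg"]))
        mat = logs.groupby(["site_id", "element"])["logv"].median().unstack("element")
    mat.columns.name = None
    mat.index.name = "site_id"
    return mat.T if mode == "by_element" else mat


def flag_inconsistent(summaries: pd.DataFrame) -> list[str]:
    """Elements whose printed battery violates min <= q1 <= median <= q3 <= max
    or mean outside [min, max] — reported, never corrected."""
    bad = []
    for element, row in summaries.iterrows():
        s = ElementSummary(element=str(element), n=int(row.get("n", 2)), **{
            k: float(row[k]) for k in SUMMARY_COLUMNS})
        if not s.is_consistent():
            bad.append(str(element))
    return bad
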