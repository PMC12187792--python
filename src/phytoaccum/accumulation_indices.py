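"""Bioconcentration factors, Al-normalized enrichment factors, and nutrient
stoichiometry.

The bioconcentration factor BcF = cE_frond / cE_substrate measures net
transfer of element E from a substrate horizon into the plant tissue; it is
unit-free and invariant to a common rescaling of both concentrations.

The enrichment factor uses aluminium as a conservative lithogenic
normalizer, EF = (E/Al)_frond / (E/Al)_substrate, so that passive mineral
dust on the tissue cancels out.  EF of Al itself is identically 1.  EF
values are binned into the conventional six-class scale:

    [0, 1.5)   not enriched        [5, 20)    severe
    [1.5, 2)   slight              [20, 40)   highly severe
    [2, 5)     moderate            [40, inf)  extreme

The printed class limits share endpoints; here they are half-open with the
shared endpoint in the upper class so that the classes partition [0, inf).

Mass-ratio stoichiometry (C:N, N:P, C:P) diagnoses nutrient limitation:
N-limited growth below N:P = 14, P-limited above N:P = 16 (configurable).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_model import ConcentrationTable, HORIZONS, aggregate_replicates

__all__ = [
    "EF_CLASS_LABELS",
    "EF_CLASS_EDGES",
    "StoichiometryResult",
    "bcf",
    "ef",
    "classify_ef",
    "bcf_table",
    "ef_table",
    "median_index",
    "median_index_table",
    "stoichiometry",
    "stoichiometry_table",
    "verdict_table",
]

EF_CLASS_LABELS = (
    "not_enriched",
    "slight",
    "moderate",
    "severe",
    "highly_severe",
    "extreme",
)
EF_CLASS_EDGES = (0.0, 1.5, 2.0, 5.0, 20.0, 40.0, np.inf)

#: median BcF below this in every horizon marks the element as excluded
EXCLUDER_BCF_CUTOFF = 0.1
#: median EF at or above this marks bioaccumulation
ACCUMULATION_EF_CUTOFF = 10.0


def bcf(cef: float, ces: float) -> float:
    """Bioconcentration factor cE_frond / cE_substrate.

    A zero substrate concentration yields NaN (with a warning), never inf.
    """
    if cef < 0:
        raise ValueError("frond concentration must be >= 0")
    if ces < 0:
        raise ValueError("substrate concentration must be >= 0")
    if ces == 0:
        warnings.warn("substrate concentration is 0; BcF undefined", UserWarning, stacklevel=2)
        return float("nan")
    return float(cef) / float(ces)


def ef(e_f: float, al_f: float, e_s: float, al_s: float) -> float:
    """Al-normalized enrichment factor (E/Al)_frond / (E/Al)_substrate."""
    if e_f < 0:
        raise ValueError("frond concentration must be >= 0")
    if min(al_f, e_s, al_s) < 0:
        raise ValueError("concentrations must be >= 0")
    if al_f == 0 or al_s == 0 or e_s == 0:
        warnings.warn("zero denominator; EF undefined", UserWarning, stacklevel=2)
        return float("nan")
    return (float(e_f) / float(al_f)) / (float(e_s) / float(al_s))


def classify_ef(value: float) -> str:
    """Assign an EF to exactly one of the six enrichment classes."""
    if not np.isfinite(value):
        raise ValueError(f"cannot classify non-finite EF {value!r}")
    if value < 0:
        raise ValueError(f"EF must be >= 0, got {value}")
    idx = int(np.searchsorted(EF_CLASS_EDGES[1:-1], value, side="right"))
    return EF_CLASS_LABELS[idx]


def _aligned_wide(frond: ConcentrationTable, substrate: ConcentrationTable,
                  replicate_rule: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    fw = aggregate_replicates(frond, replicate_rule).to_wide() if frond.has_replicates else frond.to_wide()
    sw = aggregate_replicates(substrate, replicate_rule).to_wide() if substrate.has_replicates else substrate.to_wide()
    sites = fw.index.intersection(sw.index)
    elements = fw.columns.intersection(sw.columns)
    return fw.loc[sites, elements], sw.loc[sites, elements]


def bcf_table(
    frond: ConcentrationTable,
    substrate: ConcentrationTable,
    replicate_rule: str = "median",
) -> pd.DataFrame:
    """Per (site, element) BcF against one substrate horizon.

    Returns long rows: site_id, element, horizon, index_kind, value.
    NaN propagates (zero substrate, missing data); nothing is dropped.
    """
    if substrate.compartment not in HORIZONS:
        raise ValueError(f"substrate must be one of {HORIZONS}")
    fw, sw = _aligned_wide(frond, substrate, replicate_rule)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = fw / sw
    ratio = ratio.where(sw > 0)  # zero substrate -> NaN, not inf
    out = ratio.stack(future_stack=True).rename("value").reset_index()
    out.columns = ["site_id", "element", "value"]
    out["horizon"] = substrate.compartment
    out["index_kind"] = "BcF"
    return out[["site_id", "element", "horizon", "index_kind", "value"]]


def ef_table(
    frond: ConcentrationTable,
    substrate: ConcentrationTable,
    replicate_rule: str = "median",
    normalizer: str = "Al",
) -> pd.DataFrame:
    """Per (site, element) Al-normalized EF with enrichment class."""
    if substrate.compartment not in HORIZONS:
        raise ValueError(f"substrate must be one of {HORIZONS}")
    fw, sw = _aligned_wide(frond, substrate, replicate_rule)
    if normalizer not in fw.columns or normalizer not in sw.columns:
        raise ValueError(f"normalizer {normalizer!r} missing from frond or substrate")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (fw.div(fw[normalizer], axis=0)) / (sw.div(sw[normalizer], axis=0))
    row_ok = (fw[normalizer] > 0) & (sw[normalizer] > 0)
    ratio = ratio.where(sw > 0)
    ratio.loc[~row_ok, :] = np.nan
    out = ratio.stack(future_stack=True).rename("value").reset_index()
    out.columns = ["site_id", "element", "value"]
    out["horizon"] = substrate.compartment
    out["index_kind"] = "EF"
    out["ef_class"] = [
        classify_ef(v) if np.isfinite(v) else None for v in out["value"]
    ]
    return out[["site_id", "element", "horizon", "index_kind", "value", "ef_class"]]


def median_index(results: pd.DataFrame, element: str, horizon: str) -> tuple[float, int]:
    """Median of an index across sites for one element/horizon.

    Returns ``(median, n_contributing)``; NaN values are dropped but counted
    out explicitly, and an all-NaN selection yields (NaN, 0).
    """
    sel = results[(results["element"] == element) & (results["horizon"] == horizon)]
    vals = sel["value"].dropna()
    if vals.empty:
        return float("nan"), 0
    return float(vals.median()), int(vals.size)


def median_index_table(results: pd.DataFrame) -> pd.DataFrame:
    """Per element x horizon median of an index table, with site counts."""
    grp = results.groupby(["element", "horizon"])["value"]
    out = grp.agg(median="median", n="count").reset_index()
    if "ef_class" in results.columns:
        out["ef_class"] = [
            classify_ef(v) if np.isfinite(v) else None for v in out["median"]
        ]
    return out


@dataclass(frozen=True)
class StoichiometryResult:
    site_id: int
    cn_ratio: float
    np_ratio: float
    cp_ratio: float
    n_limited: bool
    p_limited: bool


def stoichiometry(
    c: float,
    n: float,
    p: float,
    site_id: int = 0,
    n_limit_below: float = 14.0,
    p_limit_above: float = 16.0,
) -> StoichiometryResult:
    """C:N, N:P and C:P mass ratios with nutrient-limitation flags.

    Inputs are concentrations in mg/kg (any common unit works; the ratios
    are unit-free).  Defaults: N-limited when N:P < 14, P-limited when
    N:P > 16; between the two, neither flag is set.
    """
    if min(c, n, p) <= 0:
        raise ValueError("C, N and P concentrations must be > 0")
    np_ratio = n / p
    return StoichiometryResult(
        site_id=site_id,
        cn_ratio=c / n,
        np_ratio=np_ratio,
        cp_ratio=c / p,
        n_limited=bool(np_ratio < n_limit_below),
        p_limited=bool(np_ratio > p_limit_above),
    )


def stoichiometry_table(
    frond: ConcentrationTable,
    replicate_rule: str = "median",
    n_limit_below: float = 14.0,
    p_limit_above: float = 16.0,
) -> pd.DataFrame:
    """Per-site stoichiometry from a frond table containing C, N and P."""
    agg = aggregate_replicates(frond, replicate_rule) if frond.has_replicates else frond
    wide = agg.to_wide()
    for needed in ("C", "N", "P"):
        if needed not in wide.columns:
            raise ValueError(f"frond table lacks element {needed}")
    rows = []
    for site_id, row in wide.iterrows():
        res = stoichiometry(
            row["C"], row["N"], row["P"], site_id=int(site_id),
            n_limit_below=n_limit_below, p_limit_above=p_limit_above,
        )
        rows.append(res.__dict__)
    return pd.DataFrame(rows)


def verdict_table(bcf_medians: pd.DataFrame, ef_medians: pd.DataFrame) -> pd.DataFrame:
    """Element-by-element accumulation verdict.

    ``excluder``: median BcF < 0.1 in every horizon with data.
    ``accumulated``: median EF >= 10 in at least one horizon.
    Otherwise ``indifferent``.
    """
    bcf_piv = bcf_medians.pivot(index="element", columns="horizon", values="median")
    ef_piv = ef_medians.pivot(index="element", columns="horizon", values="median")
    elements = bcf_piv.index.union(ef_piv.index)
    rows = []
    for element in elements:
        b = bcf_piv.loc[element].dropna() if element in bcf_piv.index else pd.Series(dtype=float)
        e = ef_piv.loc[element].dropna() if element in ef_piv.index else pd.Series(dtype=float)
        excluder = bool(len(b)) and bool((b < EXCLUDER_BCF_CUTOFF).all())
        accumulated = bool(len(e)) and bool((e >= ACCUMULATION_EF_CUTOFF).any())
        verdict = "excluder" if excluder else ("accumulated" if accumulated else "indifferent")
        rows.append(
            {
                "element": element,
                "median_bcf_max": float(b.max()) if len(b) else float("nan"),
                "median_ef_max": float(e.max()) if len(e) else float("nan"),
                "verdict": verdict,
            }
        )
    return pd.DataFrame(rows).set_index("element")
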