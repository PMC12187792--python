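"""Shale-normalized rare-earth patterns and cerium anomalies.

REE concentrations are normalized element-by-element to a named shale
reference (PAAS by default) so that the smooth crustal abundance pattern
flattens out and redox-driven deviations become visible.  The cerium
anomaly compares measured, normalized Ce against the value geometrically
extrapolated from its neighbours:

    Ce* = Pr_N^2 / Nd_N          Ce/Ce* = Ce_N * Nd_N / Pr_N^2

Ce/Ce* < 1 is a negative anomaly (Ce depleted, typical of plants taking up
REE from oxidizing soil solutions where Ce(IV) is immobilized on Fe/Mn
oxides); > 1 is positive.  "Significantly" different from 1 is
operationalized as a symmetric band around 1 (default +/-0.10).

The ratio is invariant to a common dilution of the raw REE vector and to a
rescaling of the whole reference table, and is homogeneous of degree 1 in
the Ce concentration alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

from .io_model import ConcentrationTable, aggregate_replicates

__all__ = [
    "REE_ELEMENTS",
    "ReeReference",
    "load_reference",
    "available_references",
    "normalize",
    "ce_anomaly",
    "call_anomaly",
    "ree_pattern_table",
]

#: lanthanides measured by the survey plus chemically similar Y
REE_ELEMENTS = ("La", "Ce", "Pr", "Nd", "Y")


@dataclass(frozen=True)
class ReeReference:
    """A named, versioned shale composition used as normalization denominator."""

    name: str
    values: Mapping[str, float]  # element -> mg/kg
    source: str = ""

    def __post_init__(self) -> None:
        for element, v in self.values.items():
            if not v > 0:
                raise ValueError(f"reference value for {element} must be > 0")

    def __getitem__(self, element: str) -> float:
        try:
            return self.values[element]
        except KeyError:
            raise KeyError(
                f"element {element!r} absent from reference {self.name!r}"
            ) from None


def _reference_frame() -> pd.DataFrame:
    with resources.files("phytoaccum.data").joinpath("ree_references.csv").open() as fh:
        return pd.read_csv(fh)


def available_references() -> list[str]:
    return sorted(_reference_frame()["reference"].unique())


def load_reference(name: str = "PAAS-TM1985") -> ReeReference:
    """Load a shipped reference table by name (see :func:`available_references`)."""
    df = _reference_frame()
    sub = df[df["reference"] == name]
    if sub.empty:
        raise KeyError(f"unknown reference {name!r}; have {available_references()}")
    return ReeReference(
        name=name,
        values=dict(zip(sub["element"], sub["value_mg_kg"])),
        source=sub["source"].iloc[0],
    )


def normalize(conc: Mapping[str, float], ref: ReeReference) -> dict[str, float]:
    """Elementwise conc/reference. Every requested element must be in the
    reference and strictly positive."""
    out = {}
    for element, value in conc.items():
        if not value > 0:
            raise ValueError(f"concentration of {element} must be > 0, got {value}")
        out[element] = value / ref[element]
    return out


def ce_anomaly(ce_n: float, pr_n: float, nd_n: float) -> float:
    """Ce/Ce* by geometric extrapolation: Ce_N / (Pr_N^2 / Nd_N)."""
    if min(ce_n, pr_n, nd_n) <= 0:
        raise ValueError("normalized REE values must be > 0")
    return ce_n * nd_n / (pr_n * pr_n)


def call_anomaly(ce_ratio: float, band: float = 0.10) -> str:
    """Classify Ce/Ce* as ``negative``, ``none`` or ``positive`` using a
    symmetric band around 1."""
    if not ce_ratio > 0:
        raise ValueError("ce_ratio must be > 0")
    if band < 0:
        raise ValueError("band must be >= 0")
    if ce_ratio < 1.0 - band:
        return "negative"
    if ce_ratio > 1.0 + band:
        return "positive"
    return "none"


def ree_pattern_table(
    frond: ConcentrationTable,
    ref: ReeReference | str = "PAAS-TM1985",
    band: float = 0.10,
    replicate_rule: str = "median",
) -> pd.DataFrame:
    """Per-site shale-normalized REE pattern with Ce/Ce* and anomaly call.

    Output columns: the normalized elements present (``La_N`` .. ``Y_N``),
    ``ce_star``, ``ce_ratio``, ``anomaly`` and the reference name (an output
    is never detached from the table that normalized it).
    """
    if isinstance(ref, str):
        ref = load_reference(ref)
    agg = aggregate_replicates(frond, replicate_rule) if frond.has_replicates else frond
    wide = agg.to_wide()
    needed = ("Ce", "Pr", "Nd")
    for element in needed:
        if element not in wide.columns:
            raise ValueError(f"frond table lacks element {element}")
    present = [e for e in REE_ELEMENTS if e in wide.columns]
    rows = []
    for site_id, row in wide.iterrows():
        normed = normalize({e: float(row[e]) for e in present}, ref)
        ratio = ce_anomaly(normed["Ce"], normed["Pr"], normed["Nd"])
        rows.append(
            {
                "site_id": int(site_id),
                **{f"{e}_N": normed[e] for e in present},
                "ce_star": normed["Pr"] ** 2 / normed["Nd"],
                "ce_ratio": ratio,
                "anomaly": call_anomaly(ratio, band),
                "reference": ref.name,
            }
        )
    return pd.DataFrame(rows).set_index("site_id")
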