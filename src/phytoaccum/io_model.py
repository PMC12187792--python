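"""Data model and tabular IO for multi-element plant/substrate surveys.

The survey design is: composite fern-frond samples plus three substrate
horizons (organic humus Oh, mineral topsoil and subsoil) collected at a set
of numbered sites, with element concentrations reported in mg/kg dry mass
and analytical work done in independent replicates.  Site-level explanatory
factors (coordinates, elevation, bedrock group, climate zone, potential
annual evaporation class) are kept in a separate table keyed by site id.

Concentrations below the analytical detection limit may be written as
``"<x"`` strings; the configured policy substitutes ``x/2`` (default),
``x`` or a missing value.  Missing values are explicit NaN, never zero.
"""

from __future__ import annotations

import dataclasses
import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "COMPARTMENTS",
    "HORIZONS",
    "BEDROCK_CLASSES",
    "ELEMENT_SYMBOLS",
    "SiteRecord",
    "ConcentrationTable",
    "AnalysisConfig",
    "parse_interval",
    "read_concentration_table",
    "write_concentration_table",
    "read_site_table",
    "write_site_table",
    "aggregate_replicates",
    "join_site_factors",
]

COMPARTMENTS = ("frond", "humus", "topsoil", "subsoil")
#: substrate horizons an index can be computed against
HORIZONS = ("humus", "topsoil", "subsoil")
#: simplified five-group bedrock classification used by the survey
BEDROCK_CLASSES = ("SAND", "PHYL", "GRA", "PAR", "BAS")

# IUPAC element symbols, H..Og
ELEMENT_SYMBOLS = frozenset(
    "H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co "
    "Ni Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb "
    "Te I Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re "
    "Os Ir Pt Au Hg Tl Pb Bi Po At Rn Fr Ra Ac Th Pa U Np Pu Am Cm Bk Cf Es "
    "Fm Md No Lr Rf Db Sg Bh Hs Mt Ds Rg Cn Nh Fl Mc Lv Ts Og".split()
)

_DASHES = re.compile(r"[‐‑‒–—―;]|--")


def parse_interval(text: str) -> tuple[float, float]:
    """Parse an interval string like ``"550-600"`` or ``"550–600"``.

    Hyphen, en/em dashes and ``;`` separators are accepted interchangeably
    so that the midpoint is invariant to the formatting of the source table.
    """
    s = _DASHES.sub("-", str(text)).strip()
    parts = [p for p in s.split("-") if p != ""]
    if len(parts) != 2:
        raise ValueError(f"cannot parse interval {text!r}")
    lo, hi = float(parts[0]), float(parts[1])
    if not lo < hi:
        raise ValueError(f"interval lower bound must be < upper bound: {text!r}")
    return lo, hi


@dataclass(frozen=True)
class SiteRecord:
    """Per-site explanatory factors.

    ``evaporation_class`` is a closed interval in mm/y (e.g. ``"550-600"``);
    correlation work uses its midpoint because only the class, not the exact
    value, is recorded for each site.
    """

    site_id: int
    latitude: float
    longitude: float
    elevation: float  # m a.s.l.
    bedrock_class: str
    climate_zone: str
    evaporation_class: str
    humus_pH: float | None = None
    topsoil_pH: float | None = None

    def __post_init__(self) -> None:
        if self.elevation <= 0:
            raise ValueError(f"site {self.site_id}: elevation must be > 0")
        if self.bedrock_class not in BEDROCK_CLASSES:
            raise ValueError(
                f"site {self.site_id}: bedrock_class {self.bedrock_class!r} "
                f"not in {BEDROCK_CLASSES}"
            )
        parse_interval(self.evaporation_class)  # validates

    @property
    def evaporation_interval(self) -> tuple[float, float]:
        return parse_interval(self.evaporation_class)

    @property
    def evaporation_midpoint(self) -> float:
        lo, hi = self.evaporation_interval
        return 0.5 * (lo + hi)


class ConcentrationTable:
    """Site x element concentration matrix for one compartment.

    Stored long-form with columns ``site_id, element, replicate, value_mg_kg``.
    Values are mg/kg dry mass; missing measurements are NaN.  Replicates are
    numbered from 1; an unreplicated table has a single replicate index.
    """

    REQUIRED = ("site_id", "element", "replicate", "value_mg_kg")

    def __init__(
        self,
        data: pd.DataFrame,
        compartment: str,
        units: str = "mg/kg",
        provenance: Sequence[str] = (),
    ) -> None:
        if compartment not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {compartment!r}")
        missing = [c for c in self.REQUIRED if c not in data.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        df = data.loc[:, list(self.REQUIRED)].copy()
        df["site_id"] = df["site_id"].astype(int)
        df["element"] = df["element"].astype(str)
        df["replicate"] = df["replicate"].astype(int)
        df["value_mg_kg"] = pd.to_numeric(df["value_mg_kg"], errors="raise")

        neg = df[df["value_mg_kg"] < 0]
        if len(neg):
            row = neg.iloc[0]
            raise ValueError(
                f"negative concentration for element {row['element']} at site "
                f"{row['site_id']} (replicate {row['replicate']}): "
                f"{row['value_mg_kg']}"
            )
        dup = df.duplicated(subset=["site_id", "element", "replicate"])
        if dup.any():
            row = df[dup].iloc[0]
            raise ValueError(
                f"duplicate entry for (site {row['site_id']}, element "
                f"{row['element']}, replicate {row['replicate']})"
            )
        self.data = df.reset_index(drop=True)
        self.compartment = compartment
        self.units = units
        self.provenance: list[str] = list(provenance)

    # -- construction ------------------------------------------------------

    @classmethod
    def from_wide(
        cls, df: pd.DataFrame, compartment: str, replicate: int = 1
    ) -> "ConcentrationTable":
        """Build from a sites x elements frame (column ``site_id`` + one
        column per element)."""
        if "site_id" not in df.columns:
            raise ValueError("wide table needs a 'site_id' column")
        long = df.melt(id_vars=["site_id"], var_name="element", value_name="value_mg_kg")
        long["replicate"] = replicate
        return cls(long, compartment)

    @classmethod
    def from_long(cls, df: pd.DataFrame, compartment: str) -> "ConcentrationTable":
        df = df.copy()
        if "replicate" not in df.columns:
            df["replicate"] = 1
        return cls(df, compartment)

    # -- accessors ---------------------------------------------------------

    @property
    def elements(self) -> list[str]:
        return sorted(self.data["element"].unique())

    @property
    def site_ids(self) -> list[int]:
        return sorted(self.data["site_id"].unique())

    @property
    def has_replicates(self) -> bool:
        return int(self.data["replicate"].nunique()) > 1

    def values_for(self, element: str) -> pd.Series:
        """All replicate values of one element, indexed by (site, replicate)."""
        sub = self.data[self.data["element"] == element]
        if sub.empty:
            raise KeyError(f"element {element!r} not in table")
        return sub.set_index(["site_id", "replicate"])["value_mg_kg"]

    def to_wide(self) -> pd.DataFrame:
        """Sites x elements frame; requires a single replicate per cell."""
        if self.has_replicates:
            raise ValueError("aggregate replicates before converting to wide layout")
        wide = self.data.pivot(index="site_id", columns="element", values="value_mg_kg")
        wide.columns.name = None
        return wide.sort_index()

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ConcentrationTable({self.compartment}: {len(self.site_ids)} sites x "
            f"{len(self.elements)} elements, replicates={self.has_replicates})"
        )


@dataclass
class AnalysisConfig:
    """Run-level knobs with documented defaults.

    dl_policy
        substitution for "<x" censored values: ``half`` -> x/2 (default),
        ``value`` -> x, ``nan`` -> missing.
    replicate_rule
        ``median`` (default; robust to one bad digestion) or ``mean``.
    reference
        named REE normalization table (default ``PAAS-TM1985``).
    anomaly_band
        symmetric band around 1 for calling Ce anomalies (default 0.10).
    p_adjust
        multiplicity adjustment for correlation screens (``fdr_bh`` default).
    quartile_method
        numpy quantile interpolation (``linear`` = type 7, default).
    log_mode
        ``log_of_median`` (default: median across replicates, then log10)
        or ``median_of_logs``.
    """

    dl_policy: str = "half"
    replicate_rule: str = "median"
    reference: str = "PAAS-TM1985"
    anomaly_band: float = 0.10
    p_adjust: str = "fdr_bh"
    quartile_method: str = "linear"
    log_mode: str = "log_of_median"
    seed: int = 0

    _CHOICES = {
        "dl_policy": ("half", "value", "nan"),
        "replicate_rule": ("median", "mean"),
        "p_adjust": ("fdr_bh", "bonferroni", "none"),
        "log_mode": ("log_of_median", "median_of_logs"),
    }

    def __post_init__(self) -> None:
        for key, choices in self._CHOICES.items():
            if getattr(self, key) not in choices:
                raise ValueError(f"{key} must be one of {choices}")
        if self.anomaly_band < 0:
            raise ValueError("anomaly_band must be >= 0")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "AnalysisConfig":
        return cls(**json.loads(text))


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_CENSORED = re.compile(r"^\s*<\s*([0-9.eE+-]+)\s*$")


def _substitute_censored(raw, dl_policy: str):
    """Apply the detection-limit policy to one raw cell."""
    if isinstance(raw, str):
        m = _CENSORED.match(raw)
        if m:
            x = float(m.group(1))
            if dl_policy == "half":
                return x / 2.0
            if dl_policy == "value":
                return x
            return np.nan
        if raw.strip() in ("", "NA", "NaN", "nan"):
            return np.nan
        return float(raw)
    return raw


def _check_element_symbols(elements: Iterable[str]) -> None:
    unknown = sorted(set(elements) - ELEMENT_SYMBOLS)
    if unknown:
        warnings.warn(
            f"unknown element symbols retained: {', '.join(unknown)}",
            UserWarning,
            stacklevel=3,
        )


def read_concentration_table(
    path: str | Path,
    compartment: str,
    layout: str = "long",
    config: AnalysisConfig | None = None,
) -> ConcentrationTable:
    """Read a concentration CSV/TSV in ``wide`` or ``long`` layout.

    Long layout columns: ``site_id, element, value_mg_kg`` plus optional
    ``replicate`` and ``units`` (``g/kg`` values are converted to mg/kg).
    Wide layout: ``site_id`` plus one column per element symbol.
    """
    config = config or AnalysisConfig()
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path, dtype=str)
    else:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
        df = pd.read_csv(path, sep=sep, dtype=str)

    if layout == "wide":
        elements = [c for c in df.columns if c != "site_id"]
        _check_element_symbols(elements)
        for col in elements:
            df[col] = df[col].map(lambda v: _substitute_censored(v, config.dl_policy))
        df["site_id"] = df["site_id"].astype(int)
        table = ConcentrationTable.from_wide(df, compartment)
    elif layout == "long":
        required = {"site_id", "element", "value_mg_kg"}
        if not required <= set(df.columns):
            raise ValueError(f"long layout needs columns {sorted(required)}")
        df["value_mg_kg"] = df["value_mg_kg"].map(
            lambda v: _substitute_censored(v, config.dl_policy)
        )
        if "units" in df.columns:
            gkg = df["units"].fillna("mg/kg").str.strip() == "g/kg"
            df.loc[gkg, "value_mg_kg"] = df.loc[gkg, "value_mg_kg"] * 1000.0
            df = df.drop(columns=["units"])
        _check_element_symbols(df["element"].unique())
        table = ConcentrationTable.from_long(df, compartment)
    else:
        raise ValueError(f"unknown layout {layout!r}")

    table.provenance.append(f"read {path.name} ({layout}, dl_policy={config.dl_policy})")
    return table


def write_concentration_table(
    table: ConcentrationTable, path: str | Path, layout: str = "long"
) -> Path:
    """Write a table back to CSV; the inverse of :func:`read_concentration_table`."""
    path = Path(path)
    if layout == "wide":
        table.to_wide().reset_index().to_csv(path, index=False)
    elif layout == "long":
        table.data.to_csv(path, index=False)
    else:
        raise ValueError(f"unknown layout {layout!r}")
    return path


_SITE_COLS = [
    "site_id",
    "latitude",
    "longitude",
    "elevation",
    "bedrock_class",
    "climate_zone",
    "evaporation_class",
    "humus_pH",
    "topsoil_pH",
]


def read_site_table(path: str | Path) -> list[SiteRecord]:
    df = pd.read_csv(path, dtype={"evaporation_class": str}, float_precision="round_trip")
    records = []
    for _, row in df.iterrows():
        kwargs = {c: row[c] for c in _SITE_COLS if c in df.columns}
        for opt in ("humus_pH", "topsoil_pH"):
            if opt in kwargs and pd.isna(kwargs[opt]):
                kwargs[opt] = None
        kwargs["site_id"] = int(kwargs["site_id"])
        records.append(SiteRecord(**kwargs))
    return records


def write_site_table(sites: Sequence[SiteRecord], path: str | Path) -> Path:
    df = pd.DataFrame([dataclasses.asdict(s) for s in sites])
    df.to_csv(path, index=False)
    return Path(path)


def aggregate_replicates(
    table: ConcentrationTable, rule: str = "median"
) -> ConcentrationTable:
    """Collapse analytical replicates to one value per (site, element).

    With a single replicate this is the identity.  Mixed replicate counts are
    tolerated (a warning is emitted) and aggregation uses whatever is present.
    """
    if rule not in ("median", "mean"):
        raise ValueError(f"unknown aggregation rule {rule!r}")
    counts = table.data.groupby(["site_id", "element"])["replicate"].count()
    if counts.nunique() > 1:
        warnings.warn(
            "mixed replicate counts; aggregating available replicates",
            UserWarning,
            stacklevel=2,
        )
    agg = (
        table.data.groupby(["site_id", "element"], as_index=False)["value_mg_kg"]
        .agg(rule)
        .assign(replicate=1)
    )
    out = ConcentrationTable(
        agg,
        table.compartment,
        units=table.units,
        provenance=table.provenance + [f"replicates aggregated by {rule}"],
    )
    return out


def join_site_factors(
    table: ConcentrationTable, sites: Sequence[SiteRecord]
) -> pd.DataFrame:
    """Attach site factors to every concentration row.

    The result carries the evaporation-class midpoint (mm/y) so that the
    ordinal evaporation classes can enter rank correlations.
    """
    by_id = {s.site_id: s for s in sites}
    missing = sorted(set(table.site_ids) - set(by_id))
    if missing:
        raise ValueError(
            "site ids unmatched in site-factor table: "
            + ", ".join(str(m) for m in missing)
        )
    site_df = pd.DataFrame(
        [
            {
                **dataclasses.asdict(s),
                "evaporation_midpoint": s.evaporation_midpoint,
            }
            for s in sites
        ]
    )
    return table.data.merge(site_df, on="site_id", how="left", validate="m:1")
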