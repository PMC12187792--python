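"""Rank-correlation screening and correlation-distance Ward clustering.

Because element concentrations stay skewed even after log transformation,
all screening uses Spearman's rank correlation.  Categorical bedrock classes
enter as 0/1 indicators; the ordinal evaporation classes enter via their
interval midpoints.

Clustering follows the survey's software convention: dissimilarity
d = 1 - Pearson r between profiles, agglomerated with Ward's amalgamation
rule applied by the Lance-Williams update *directly to the supplied
dissimilarities* ("ward.D"-style):

    d(k, a+b) = [(n_a+n_k) d(k,a) + (n_b+n_k) d(k,b) - n_k d(a,b)] / (n_a+n_b+n_k)

This is deliberate: the Euclidean-only variant (as in scipy's ``ward``,
which squares the input) is *not* what legacy statistics packages compute on
a correlation distance.  Ties in merge distance are broken by lexicographic
leaf-label order, so the merge history is deterministic and independent of
input row order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_model import ConcentrationTable, SiteRecord
from .summary_stats import log10_medians

__all__ = [
    "CorrelationReport",
    "spearman_screen",
    "significance_stars",
    "factor_design",
    "pearson_distance",
    "LinkageTree",
    "ward_cluster",
    "cluster_elements",
    "cluster_sites",
]


def significance_stars(p: float) -> str:
    """Conventional significance flags: * <0.05, ** <0.01, *** <0.001."""
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def spearman_screen(
    frame: pd.DataFrame,
    targets: list[str],
    predictors: list[str],
    adjust: str = "fdr_bh",
) -> pd.DataFrame:
    """Spearman rho for every target x predictor pair.

    Complete-case per pair (n >= 3 required); a constant variable gives
    rho = NaN.  Raw two-sided p-values are reported alongside an optional
    screen-wide adjustment (Benjamini-Hochberg by default).
    """
    rows = []
    for t in targets:
        for p in predictors:
            if t == p:
                continue
            sub = frame[[t, p]].dropna()
            n = len(sub)
            if n < 3:
                raise ValueError(f"pair ({t}, {p}): needs >= 3 complete cases, got {n}")
            if sub[t].nunique() == 1 or sub[p].nunique() == 1:
                rho, pval = float("nan"), float("nan")
            else:
                rho, pval = stats.spearmanr(sub[t], sub[p])
            rows.append(
                {"variable_a": t, "variable_b": p, "rho": rho, "p_value": pval, "n": n}
            )
    report = pd.DataFrame(rows)
    if adjust and adjust != "none":
        mask = report["p_value"].notna()
        adj = np.full(len(report), np.nan)
        if mask.any():
            adj[mask.to_numpy()] = multipletests(
                report.loc[mask, "p_value"], method=adjust
            )[1]
        report["adjusted_p"] = adj
    else:
        report["adjusted_p"] = np.nan
    report["flag"] = report["p_value"].map(significance_stars)
    return report


# backwards-friendly alias used in docs
CorrelationReport = pd.DataFrame


def factor_design(sites: list[SiteRecord]) -> pd.DataFrame:
    """Numeric per-site design for correlation work.

    elevation, evaporation midpoint, optional pH columns and one 0/1
    indicator per bedrock class, indexed by site_id.
    """
    import dataclasses

    df = pd.DataFrame(
        [
            {
                **dataclasses.asdict(s),
                "evaporation_midpoint": s.evaporation_midpoint,
            }
            for s in sites
        ]
    ).set_index("site_id")
    for cls in sorted(df["bedrock_class"].unique()):
        df[f"bedrock_{cls}"] = (df["bedrock_class"] == cls).astype(float)
    keep = ["elevation", "evaporation_midpoint", "humus_pH", "topsoil_pH"] + [
        c for c in df.columns if c.startswith("bedrock_") and c != "bedrock_class"
    ]
    return df[[c for c in keep if c in df.columns]].astype(float)


def pearson_distance(matrix: pd.DataFrame) -> pd.DataFrame:
    """1 - Pearson r between the *rows* of ``matrix``.

    Symmetric, zero diagonal, entries in [0, 2].  A zero-variance row has no
    defined correlation and is a hard error naming the row.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with >= 2 rows")
    sd = X.std(axis=1)
    if (sd == 0).any():
        labels = list(matrix.index) if hasattr(matrix, "index") else list(range(len(sd)))
        bad = [str(labels[i]) for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance rows: {', '.join(bad)}")
    d = 1.0 - np.corrcoef(X)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    np.fill_diagonal(d, 0.0)
    labels = matrix.index if hasattr(matrix, "index") else pd.RangeIndex(X.shape[0])
    return pd.DataFrame(d, index=labels, columns=labels)


@dataclass
class LinkageTree:
    """Merge history of an agglomerative clustering.

    ``merges`` uses the scipy convention: row i merges cluster ids ``a`` and
    ``b`` (leaves are 0..n-1, the merge formed at step i has id n+i) at
    ``height`` into a cluster of ``size`` leaves.
    """

    merges: list[tuple[int, int, float, int]]
    labels: list[str]
    metric: str = "1-pearson_r"
    linkage: str = "ward.D"

    def __post_init__(self) -> None:
        n = len(self.labels)
        if len(self.merges) != n - 1:
            raise ValueError("a tree over n leaves has n-1 merges")
        if any(m[2] < 0 for m in self.merges):
            raise ValueError("merge heights must be nonnegative")

    def to_linkage_matrix(self) -> np.ndarray:
        """Scipy-compatible (n-1) x 4 linkage matrix (for dendrogram plotting)."""
        return np.array([[a, b, h, s] for a, b, h, s in self.merges], dtype=float)

    def leaf_order(self) -> list[str]:
        """Leaf labels in dendrogram order (left-to-right)."""
        n = len(self.labels)

        def walk(node: int) -> list[int]:
            if node < n:
                return [node]
            a, b, _, _ = self.merges[node - n]
            return walk(int(a)) + walk(int(b))

        return [self.labels[i] for i in walk(n + len(self.merges) - 1)]

    def to_newick(self) -> str:
        """Newick string with branch lengths = height differences."""
        n = len(self.labels)
        heights = {i: 0.0 for i in range(n)}
        for i, (_, _, h, _) in enumerate(self.merges):
            heights[n + i] = h

        def node(i: int, parent_h: float) -> str:
            bl = max(parent_h - heights[i], 0.0)
            if i < n:
                name = str(self.labels[i]).replace(" ", "_")
                return f"{name}:{bl:.6g}"
            a, b, h, _ = self.merges[i - n]
            return f"({node(int(a), h)},{node(int(b), h)}):{bl:.6g}"

        root = n + len(self.merges) - 1
        return node(root, heights[root]) + ";"

    def to_json(self) -> str:
        return json.dumps(
            {
                "labels": self.labels,
                "metric": self.metric,
                "linkage": self.linkage,
                "merges": [
                    {"a": a, "b": b, "height": h, "size": s}
                    for a, b, h, s in self.merges
                ],
            },
            indent=2,
        )


def ward_cluster(d: pd.DataFrame, labels: list[str] | None = None) -> LinkageTree:
    """Agglomerate a precomputed dissimilarity matrix with the ward.D update.

    Deterministic: equal candidate distances are resolved by the
    lexicographically smallest pair of cluster leaf-label sets, so the result
    does not depend on the row order of ``d``.
    """
    D = np.asarray(d, dtype=float)
    n = D.shape[0]
    if n < 2:
        raise ValueError("need at least 2 items to cluster")
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be square and symmetric")
    if labels is None:
        labels = [str(x) for x in (d.index if hasattr(d, "index") else range(n))]
    if len(labels) != n:
        raise ValueError("labels length mismatch")

    # active clusters: id -> (sorted leaf-label tuple, size)
    key = {i: (str(labels[i]),) for i in range(n)}
    size = {i: 1 for i in range(n)}
    dist = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(D[i, j])

    def get(a: int, b: int) -> float:
        return dist[(a, b) if a < b else (b, a)]

    active = set(range(n))
    merges: list[tuple[int, int, float, int]] = []
    next_id = n
    while len(active) > 1:
        best = None
        for a in sorted(active):
            for b in sorted(active):
                if b <= a:
                    continue
                ka, kb = key[a], key[b]
                pair_key = (ka, kb) if ka <= kb else (kb, ka)
                cand = (get(a, b), pair_key)
                if best is None or cand < best[0]:
                    best = (cand, a, b)
        (_, _), a, b = best[0], best[1], best[2]
        h = get(a, b)
        na, nb = size[a], size[b]
        # ward.D Lance-Williams update on raw dissimilarities
        for k in active - {a, b}:
            nk = size[k]
            dk = ((na + nk) * get(a, k) + (nb + nk) * get(b, k) - nk * h) / (
                na + nb + nk
            )
            dist[(min(k, next_id), max(k, next_id))] = dk
        lo, hi = (a, b) if key[a] <= key[b] else (b, a)
        merges.append((lo, hi, h, na + nb))
        key[next_id] = tuple(sorted(key[a] + key[b]))
        size[next_id] = na + nb
        active -= {a, b}
        active.add(next_id)
        next_id += 1
    return LinkageTree(merges=merges, labels=[str(x) for x in labels])


def cluster_elements(
    table: ConcentrationTable, log_mode: str = "log_of_median"
) -> LinkageTree:
    """Cluster element profiles across sites (log10 replicate medians)."""
    mat = log10_medians(table, mode="by_element", log_mode=log_mode)
    return ward_cluster(pearson_distance(mat), labels=[str(e) for e in mat.index])


def cluster_sites(
    table: ConcentrationTable, log_mode: str = "log_of_median"
) -> LinkageTree:
    """Cluster sites by their element profiles (log10 replicate medians)."""
    mat = log10_medians(table, mode="by_site", log_mode=log_mode)
    return ward_cluster(pearson_distance(mat), labels=[str(s) for s in mat.index])
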