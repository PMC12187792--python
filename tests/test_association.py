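import itertools

import numpy as np
import pandas as pd
import pytest

from phytoaccum.association import (
    LinkageTree,
    cluster_elements,
    cluster_sites,
    factor_design,
    pearson_distance,
    significance_stars,
    spearman_screen,
    ward_cluster,
)
from phytoaccum.io_model import ConcentrationTable
from phytoaccum.synthetic_data import SynthConfig, generate_dataset


# --------------------------------------------------------------------------
# independent oracle: Ward cluster distances have the closed form
#   D(A, B) = S(A u B) - S(A) - S(B),  S(C) = (2/|C|) * sum_{i<j in C} d_ij
# which satisfies the Lance-Williams Ward recursion for any dissimilarity
# matrix.  The oracle below re-evaluates this functional from the original
# matrix at every step (no distance updates), unlike the implementation.
# --------------------------------------------------------------------------


def _oracle_ward(D, labels):
    n = D.shape[0]

    def S(cluster):
        if len(cluster) < 2:
            return 0.0
        return (2.0 / len(cluster)) * sum(
            D[i, j] for i, j in itertools.combinations(sorted(cluster), 2)
        )

    def dist(a, b):
        return S(a | b) - S(a) - S(b)

    active = {frozenset([i]) for i in range(n)}
    key = {frozenset([i]): (labels[i],) for i in range(n)}
    merges = []
    while len(active) > 1:
        best = None
        for a, b in itertools.combinations(sorted(active, key=lambda c: key[c]), 2):
            ka, kb = key[a], key[b]
            pair = (ka, kb) if ka <= kb else (kb, ka)
            cand = ((dist(a, b), pair), a, b)
            if best is None or cand[0] < best[0]:
                best = cand
        (h, _), a, b = best
        merged = a | b
        key[merged] = tuple(sorted(key[a] + key[b]))
        merges.append((frozenset(key[a]) | frozenset(key[b]), h))
        active -= {a, b}
        active.add(merged)
    return merges


def _tree_merge_sets(tree: LinkageTree):
    n = len(tree.labels)
    members = {i: frozenset([tree.labels[i]]) for i in range(n)}
    out = []
    for i, (a, b, h, _) in enumerate(tree.merges):
        members[n + i] = members[a] | members[b]
        out.append((members[n + i], h))
    return out


def _random_distance(rng, n, ties=False):
    vals = rng.integers(1, 6, size=(n, n)) if ties else rng.uniform(0.1, 2.0, size=(n, n))
    D = np.triu(vals.astype(float), 1)
    D = D + D.T
    return D


class TestWardOracle:
    def test_first_merge_is_closest_pair(self):
        D = pd.DataFrame(
            [[0.0, 0.1, 1.0], [0.1, 0.0, 1.0], [1.0, 1.0, 0.0]],
            index=list("ABC"),
            columns=list("ABC"),
        )
        tree = ward_cluster(D)
        assert {tree.labels[tree.merges[0][0]], tree.labels[tree.merges[0][1]]} == {"A", "B"}
        assert tree.merges[0][2] == pytest.approx(0.1)

    @pytest.mark.parametrize("n", [2, 3, 4, 5, 6])
    @pytest.mark.parametrize("ties", [False, True])
    def test_agreement_with_exhaustive_oracle(self, n, ties):
        """Merge history (leaf sets and heights) matches the closed-form
        Ward functional re-evaluated from scratch, for many random matrices
        including tied distances."""
        rng = np.random.default_rng(12 + n)
        labels = [f"L{i}" for i in range(n)]
        for _ in range(15):
            D = _random_distance(rng, n, ties=ties)
            tree = ward_cluster(pd.DataFrame(D, index=labels, columns=labels))
            got = _tree_merge_sets(tree)
            want = _oracle_ward(D, labels)
            for (gs, gh), (ws, wh) in zip(got, want):
                assert gs == ws
                assert gh == pytest.approx(wh, rel=1e-9, abs=1e-9)

    def test_leaf_order_invariance(self):
        rng = np.random.default_rng(42)
        n = 7
        labels = [f"E{i}" for i in range(n)]
        D = _random_distance(rng, n)
        base = _tree_merge_sets(
            ward_cluster(pd.DataFrame(D, index=labels, columns=labels))
        )
        perm = rng.permutation(n)
        Dp = D[np.ix_(perm, perm)]
        labp = [labels[i] for i in perm]
        permuted = _tree_merge_sets(
            ward_cluster(pd.DataFrame(Dp, index=labp, columns=labp))
        )
        assert [s for s, _ in base] == [s for s, _ in permuted]
        for (_, h1), (_, h2) in zip(base, permuted):
            assert h1 == pytest.approx(h2, rel=1e-9)

    def test_single_item_is_error(self):
        with pytest.raises(ValueError):
            ward_cluster(pd.DataFrame([[0.0]], index=["A"], columns=["A"]))


class TestPearsonDistance:
    def test_correlated_anticorrelated_orthogonal(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        m = pd.DataFrame(
            [x, 2 * x + 1, -x, [-1.0, 1.0, 1.0, -1.0]],
            index=["a", "b", "c", "d"],
        )
        d = pearson_distance(m)
        assert d.loc["a", "b"] == pytest.approx(0.0, abs=1e-12)
        assert d.loc["a", "c"] == pytest.approx(2.0)
        assert d.loc["a", "d"] == pytest.approx(1.0, abs=1e-9)

    def test_symmetric_zero_diagonal_bounded(self, default_dataset):
        _, tables = default_dataset
        from phytoaccum.summary_stats import log10_medians

        d = pearson_distance(log10_medians(tables["frond"], "by_element"))
        arr = d.to_numpy()
        assert np.allclose(arr, arr.T)
        assert np.allclose(np.diag(arr), 0.0)
        assert arr.min() >= 0.0 and arr.max() <= 2.0

    def test_zero_variance_row_named(self):
        m = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]], index=["flat", "ok"])
        with pytest.raises(ValueError, match="flat"):
            pearson_distance(m)


class TestSpearmanScreen:
    def test_perfect_monotone(self):
        x = np.arange(10, dtype=float)
        frame = pd.DataFrame({"y": x**3, "yneg": -x, "x": x})
        report = spearman_screen(frame, ["y", "yneg"], ["x"], adjust="none")
        up = report[report["variable_a"] == "y"].iloc[0]
        down = report[report["variable_a"] == "yneg"].iloc[0]
        assert up["rho"] == pytest.approx(1.0)
        assert up["p_value"] < 0.01 and up["flag"] in ("**", "***")
        assert down["rho"] == pytest.approx(-1.0)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(size=30)
        y = rng.uniform(size=30)
        f1 = pd.DataFrame({"a": x, "b": y})
        f2 = pd.DataFrame({"a": np.exp(5 * x), "b": y**3})
        r1 = spearman_screen(f1, ["a"], ["b"], adjust="none")["rho"].iloc[0]
        r2 = spearman_screen(f2, ["a"], ["b"], adjust="none")["rho"].iloc[0]
        assert r1 == pytest.approx(r2)

    def test_constant_variable_reported_nan(self):
        frame = pd.DataFrame({"a": [1.0, 1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0, 4.0]})
        report = spearman_screen(frame, ["a"], ["b"], adjust="none")
        assert np.isnan(report["rho"].iloc[0])

    def test_adjusted_p_not_below_raw(self, default_dataset):
        sites, tables = default_dataset
        from phytoaccum.io_model import aggregate_replicates

        wide = aggregate_replicates(tables["frond"]).to_wide()
        frame = wide.join(factor_design(sites))
        report = spearman_screen(
            frame, ["Rb", "Cs", "Zn"], ["elevation", "evaporation_midpoint"]
        )
        ok = report.dropna(subset=["p_value"])
        assert (ok["adjusted_p"] >= ok["p_value"] - 1e-12).all()
        assert (ok["n"] == 35).all()

    def test_too_few_cases_is_error(self):
        frame = pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 1.0]})
        with pytest.raises(ValueError, match=">= 3"):
            spearman_screen(frame, ["a"], ["b"])

    def test_stars_mapping(self):
        assert significance_stars(0.04) == "*"
        assert significance_stars(0.005) == "**"
        assert significance_stars(0.0005) == "***"
        assert significance_stars(0.2) == ""


class TestClusterPipelines:
    def _block_table(self, n_sites=30, seed=0):
        """Two latent factors -> two element blocks with strong within-block
        correlation and none across."""
        rng = np.random.default_rng(seed)
        f1 = rng.normal(size=n_sites)
        f2 = rng.normal(size=n_sites)
        rows = []
        for j in range(3):
            rows.append((f"R{j}", 10 ** (1 + 0.5 * f1 + 0.05 * rng.normal(size=n_sites))))
            rows.append((f"N{j}", 10 ** (2 + 0.5 * f2 + 0.05 * rng.normal(size=n_sites))))
        data = []
        for element, values in rows:
            for site, v in enumerate(values, start=1):
                data.append(
                    {"site_id": site, "element": element, "replicate": 1, "value_mg_kg": v}
                )
        return ConcentrationTable(pd.DataFrame(data), "frond")

    def test_two_blocks_split_at_top(self):
        tree = cluster_elements(self._block_table())
        n = len(tree.labels)
        members = {i: {tree.labels[i]} for i in range(n)}
        for i, (a, b, _, _) in enumerate(tree.merges):
            members[n + i] = members[a] | members[b]
        top_a, top_b, _, _ = tree.merges[-1]
        sides = sorted([members[top_a], members[top_b]], key=len)
        assert sides[0] == {"R0", "R1", "R2"} or sides[0] == {"N0", "N1", "N2"}

    def test_duplicate_elements_merge_first(self):
        t = self._block_table()
        dup = t.data[t.data["element"] == "R0"].assign(element="R9")
        table = ConcentrationTable(pd.concat([t.data, dup]), "frond")
        tree = cluster_elements(table)
        first_a, first_b, h, _ = tree.merges[0]
        assert {tree.labels[first_a], tree.labels[first_b]} == {"R0", "R9"}
        assert h == pytest.approx(0.0, abs=1e-12)

    def test_granite_sites_co_cluster(self):
        """Granite-affine elements elevated x5 on granitic bedrock make the
        granite sites dominate one side of the site dendrogram."""
        cfg = SynthConfig(n_sites=35, seed=6)
        sites, tables = generate_dataset(cfg)
        granite = {str(s.site_id) for s in sites if s.bedrock_class == "GRA"}
        assert len(granite) >= 5
        tree = cluster_sites(tables["frond"])
        n = len(tree.labels)
        members = {i: {tree.labels[i]} for i in range(n)}
        for i, (a, b, _, _) in enumerate(tree.merges):
            members[n + i] = members[a] | members[b]
        top_a, top_b, _, _ = tree.merges[-1]
        share_a = len(members[top_a] & granite) / len(granite)
        share_b = len(members[top_b] & granite) / len(granite)
        assert max(share_a, share_b) >= 0.75

    def test_newick_parses_with_skbio_and_preserves_leaves(self, default_dataset):
        _, tables = default_dataset
        tree = cluster_elements(tables["frond"])
        nwk = tree.to_newick()
        from skbio import TreeNode
        import io

        parsed = TreeNode.read(io.StringIO(nwk))
        assert {t.name for t in parsed.tips()} == set(tree.labels)

    def test_json_merge_list(self, default_dataset):
        import json

        _, tables = default_dataset
        tree = cluster_sites(tables["frond"])
        payload = json.loads(tree.to_json())
        assert payload["linkage"] == "ward.D"
        assert len(payload["merges"]) == len(tree.labels) - 1
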