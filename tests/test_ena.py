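"""Epistemic network analysis: accumulation, projection, co-registration, tests."""

import itertools

import numpy as np
import pandas as pd
import pytest

from ethonet import (
    ENASpace,
    StanzaConfig,
    accumulate_adjacency,
    compare_groups,
    ena_project,
    group_mean_network,
    group_means_ci,
    mean_network,
    normalize_sphere,
    position_nodes,
    rank_compare,
)
from ethonet.coding_io import PresenceMatrix
from ethonet.errors import DegenerateInputError, ParameterError


def matrix_from_lines(conversations, elements):
    """conversations: {(unit, conv): list of element sets per line}."""
    keys, rows = [], []
    for (unit, conv), lines in conversations.items():
        for i, present in enumerate(lines):
            keys.append((unit, conv, i))
            rows.append([1.0 if e in present else 0.0 for e in elements])
    data = pd.DataFrame(
        rows,
        index=pd.MultiIndex.from_tuples(keys, names=["unit", "conversation", "line_index"]),
        columns=elements,
    )
    return PresenceMatrix(data, {u: "g" for (u, _c) in conversations}, {})


def brute_force_window_counts(lines, elements, window):
    """Independent double-loop pair counter for one conversation."""
    pairs = list(itertools.combinations(elements, 2))
    counts = dict.fromkeys(pairs, 0)
    for l, present in enumerate(lines):
        lo = 0 if window is None else max(0, l - window + 1)
        win = set().union(*lines[lo : l + 1]) if lines[lo : l + 1] else set()
        for (a, b) in pairs:
            if (a in present and b in win) or (b in present and a in win):
                counts[(a, b)] += 1
    return counts


class TestAccumulation:
    def test_within_line_pair(self):
        m = matrix_from_lines({("u", "c"): [{"A", "B"}]}, ["A", "B", "C"])
        vec = accumulate_adjacency(m, StanzaConfig(window=4))
        assert vec.loc["u", ("A", "B")] == 1.0
        assert vec.loc["u", ("A", "C")] == 0.0

    def test_window_reach(self):
        lines = [{"A"}, {"B"}]
        m = matrix_from_lines({("u", "c"): lines}, ["A", "B"])
        w2 = accumulate_adjacency(m, StanzaConfig(window=2))
        w1 = accumulate_adjacency(m, StanzaConfig(window=1))
        assert w2.loc["u", ("A", "B")] == 1.0
        assert w1.loc["u", ("A", "B")] == 0.0

    def test_window_never_crosses_conversations(self):
        m = matrix_from_lines({("u", "c1"): [{"A"}], ("u", "c2"): [{"B"}]}, ["A", "B"])
        vec = accumulate_adjacency(m, StanzaConfig(window=None))
        assert vec.loc["u", ("A", "B")] == 0.0

    @pytest.mark.parametrize("window", [1, 2, 4, None])
    def test_matches_brute_force_on_random_matrices(self, window, rng):
        elements = list("ABCDE")
        for trial in range(8):
            lines = [
                {e for e in elements if rng.random() < 0.3} for _ in range(30)
            ]
            m = matrix_from_lines({("u", "c"): lines}, elements)
            vec = accumulate_adjacency(m, StanzaConfig(window=window))
            expect = brute_force_window_counts(lines, elements, window)
            for pair, cnt in expect.items():
                assert vec.loc["u", pair] == cnt

    def test_additive_over_conversations(self, rng):
        elements = list("ABCD")
        lines1 = [{e for e in elements if rng.random() < 0.4} for _ in range(10)]
        lines2 = [{e for e in elements if rng.random() < 0.4} for _ in range(10)]
        both = matrix_from_lines({("u", "c1"): lines1, ("u", "c2"): lines2}, elements)
        only1 = matrix_from_lines({("u", "c1"): lines1}, elements)
        only2 = matrix_from_lines({("u", "c2"): lines2}, elements)
        cfg = StanzaConfig(window=3)
        total = accumulate_adjacency(both, cfg)
        parts = accumulate_adjacency(only1, cfg) + accumulate_adjacency(only2, cfg)
        assert np.allclose(total.to_numpy(), parts.to_numpy())

    def test_na_matrix_rejected(self):
        m = matrix_from_lines({("u", "c"): [{"A"}]}, ["A", "B"])
        m.data.iloc[0, 1] = np.nan
        with pytest.raises(ParameterError):
            accumulate_adjacency(m)


class TestNormalization:
    def test_three_four_five(self):
        v = pd.DataFrame([[3.0, 4.0]], index=["u"], columns=[("A", "B"), ("A", "C")])
        out, excl = normalize_sphere(v)
        assert excl == []
        assert np.allclose(out.to_numpy(), [[0.6, 0.8]])

    def test_idempotent_on_unit_vector(self):
        v = pd.DataFrame([[0.6, 0.8]], index=["u"], columns=[("A", "B"), ("A", "C")])
        out, _ = normalize_sphere(v)
        assert np.allclose(out.to_numpy(), v.to_numpy())

    def test_zero_vector_excluded_not_nan(self):
        v = pd.DataFrame(
            [[1.0, 0.0], [0.0, 0.0]], index=["u", "z"], columns=[("A", "B"), ("A", "C")]
        )
        with pytest.warns(UserWarning, match="empty networks"):
            out, excl = normalize_sphere(v)
        assert excl == ["z"]
        assert not out.isna().any().any()
        assert list(out.index) == ["u"]


def small_space(points, groups):
    """Hand-built projection space for statistics-level tests."""
    pts = pd.DataFrame(points, columns=["SVD1", "SVD2"])
    pts.index = [f"u{i}" for i in range(len(pts))]
    return ENASpace(
        normalized=pd.DataFrame(np.ones((len(pts), 1)), index=pts.index, columns=[("A", "B")]),
        unit_points=pts,
        axes=np.eye(1, 2),
        variance_explained=np.array([1.0, 0.0]),
        groups=pd.Series(groups, index=pts.index),
        elements=["A", "B"],
    )


class TestProjection:
    def _two_cluster_vectors(self):
        pairs = [("A", "B"), ("C", "D"), ("E", "F")]
        rows, names, groups = [], [], {}
        for i in range(4):
            rows.append([10.0 + i, 1.0, 1.0])
            names.append(f"g1_{i}")
            groups[f"g1_{i}"] = "g1"
        for i in range(4):
            rows.append([1.0, 10.0 + i, 1.0])
            names.append(f"g2_{i}")
            groups[f"g2_{i}"] = "g2"
        v = pd.DataFrame(rows, index=names, columns=pairs)
        return v, groups

    def test_mirrored_clusters_separate_on_svd1(self):
        v, groups = self._two_cluster_vectors()
        space = ena_project(v, groups=groups)
        m1 = space.unit_points.loc[[u for u in v.index if u.startswith("g1")], "SVD1"].mean()
        m2 = space.unit_points.loc[[u for u in v.index if u.startswith("g2")], "SVD1"].mean()
        assert m1 * m2 < 0

    def test_variance_ordering_and_centering(self):
        v, groups = self._two_cluster_vectors()
        space = ena_project(v, groups=groups)
        assert space.variance_explained[0] >= space.variance_explained[1]
        assert np.allclose(space.unit_points.mean(axis=0), 0.0, atol=1e-12)

    def test_duplication_leaves_axes_unchanged(self):
        v, groups = self._two_cluster_vectors()
        space = ena_project(v, groups=groups)
        v2 = pd.concat([v, v.rename(index=lambda s: s + "_dup")])
        space2 = ena_project(v2, groups={**groups, **{k + "_dup": groups[k] for k in groups}})
        assert np.allclose(np.abs(space.axes.T @ space2.axes), np.eye(2), atol=1e-9)

    def test_sign_convention_reproducible(self):
        v, groups = self._two_cluster_vectors()
        a = ena_project(v, groups=groups)
        b = ena_project(v.copy(), groups=groups)
        assert np.array_equal(a.unit_points.to_numpy(), b.unit_points.to_numpy())
        j = np.argmax(np.abs(a.axes[:, 0]))
        assert a.axes[j, 0] > 0

    def test_too_few_units_rejected(self):
        v = pd.DataFrame([[1.0, 2.0]], index=["u"], columns=[("A", "B"), ("A", "C")])
        with pytest.raises(DegenerateInputError):
            ena_project(v)


class TestNodePositions:
    def test_single_pair_networks_fit_exactly(self):
        # each unit's network is one distinct pair: centroid = its midpoint,
        # and the solver can place nodes to reproduce every point exactly
        pairs = [("A", "B"), ("C", "D"), ("E", "F"), ("G", "H")]
        v = pd.DataFrame(np.eye(4), index=[f"u{i}" for i in range(4)], columns=pairs)
        space = position_nodes(ena_project(v))
        for axis in ("SVD1", "SVD2"):
            assert space.fit[axis]["pearson"] >= 1.0 - 1e-9

    def test_fit_invariant_to_element_relabeling(self):
        pairs = [("A", "B"), ("B", "C"), ("A", "C")]
        rng = np.random.default_rng(3)
        v = pd.DataFrame(
            rng.random((5, 3)) + 0.1, index=[f"u{i}" for i in range(5)], columns=pairs
        )
        s1 = position_nodes(ena_project(v))
        ren = {"A": "X", "B": "Y", "C": "Z"}
        v2 = v.copy()
        v2.columns = [(ren[a], ren[b]) for a, b in pairs]
        s2 = position_nodes(ena_project(v2))
        for axis in ("SVD1", "SVD2"):
            assert s1.fit[axis]["pearson"] == pytest.approx(s2.fit[axis]["pearson"])

    def test_strong_cluster_corpus_fits_well(self):
        from ethonet import SyntheticConfig, generate_corpus

        _, matrix, _ = generate_corpus(SyntheticConfig(seed=77))
        vec = accumulate_adjacency(matrix, StanzaConfig(window=4))
        space = position_nodes(ena_project(vec))
        assert space.fit["SVD1"]["pearson"] >= 0.9
        assert space.fit["SVD2"]["pearson"] >= 0.9


class TestGroupStats:
    def test_identical_points_zero_width_ci(self):
        s = small_space([[1.0, 2.0]] * 4, ["g"] * 4)
        ci = group_means_ci(s)
        assert ci.loc["g", "SVD1_lo"] == ci.loc["g", "SVD1_hi"] == 1.0

    def test_ci_widens_with_level(self, rng):
        pts = np.column_stack([rng.normal(size=10), rng.normal(size=10)])
        s = small_space(pts, ["g"] * 10)
        w90 = group_means_ci(s, 0.90)
        w99 = group_means_ci(s, 0.99)
        assert (w99.loc["g", "SVD1_hi"] - w99.loc["g", "SVD1_lo"]) > (
            w90.loc["g", "SVD1_hi"] - w90.loc["g", "SVD1_lo"]
        )

    def test_singleton_group_flagged(self):
        s = small_space([[0, 0], [1, 1], [2, 2]], ["a", "a", "b"])
        ci = group_means_ci(s)
        assert np.isnan(ci.loc["b", "SVD1_lo"])
        assert ci.loc["b", "n"] == 1

    def test_complete_separation_effect_size(self):
        s = small_space(
            [[1, 0], [2, 0], [3, 0], [10, 0], [11, 0], [12, 0]],
            ["a"] * 3 + ["b"] * 3,
        )
        c = compare_groups(s, "a", "b", "SVD1")
        assert c.u == 0.0
        assert abs(c.effect_size) == pytest.approx(1.0)

    def test_self_split_effect_zero(self):
        s = small_space([[v, 0] for v in [1, 2, 3, 4, 1, 2, 3, 4]], ["a"] * 4 + ["b"] * 4)
        c = compare_groups(s, "a", "b", "SVD1")
        assert c.effect_size == pytest.approx(0.0)

    def test_all_tied_warns(self):
        s = small_space([[1.0, 0]] * 6, ["a"] * 3 + ["b"] * 3)
        with pytest.warns(UserWarning, match="tied"):
            c = compare_groups(s, "a", "b", "SVD1")
        assert c.p_value == 1.0 and c.effect_size == 0.0

    def test_u_matches_pairwise_counting(self, rng):
        for _ in range(20):
            n1, n2 = rng.integers(2, 13), rng.integers(2, 13)
            x = rng.integers(0, 6, size=n1).astype(float)
            y = rng.integers(0, 6, size=n2).astype(float)
            if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
                continue
            u, _p, r = rank_compare(x, y)
            brute = sum(
                1.0 if xi > yj else (0.5 if xi == yj else 0.0) for xi in x for yj in y
            )
            assert u == pytest.approx(brute)
            assert r == pytest.approx(1 - 2 * brute / (n1 * n2))


class TestMeanNetwork:
    def test_single_unit_group_is_its_vector(self):
        v = pd.DataFrame([[3.0, 4.0]], index=["u"], columns=[("A", "B"), ("A", "C")])
        norm, _ = normalize_sphere(v)
        mn = mean_network(norm, ["u"])
        assert np.allclose(mn.to_numpy(), [0.6, 0.8])

    def test_group_average_bounded_by_members(self, rng):
        v = pd.DataFrame(
            rng.random((5, 4)) + 0.05,
            index=[f"u{i}" for i in range(5)],
            columns=[("A", "B"), ("A", "C"), ("B", "C"), ("A", "D")],
        )
        norm, _ = normalize_sphere(v)
        mn = mean_network(norm, list(norm.index))
        assert (mn <= norm.max(axis=0) + 1e-12).all()
        assert (mn >= norm.min(axis=0) - 1e-12).all()

    def test_group_lookup(self):
        v, groups = TestProjection()._two_cluster_vectors()
        space = ena_project(v, groups=groups)
        mn = group_mean_network(space, "g1")
        assert mn.idxmax() == ("A", "B")
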