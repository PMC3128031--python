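import math

import numpy as np
import pytest

from ssrkit.selection import (
    SelectionConfig,
    asymmetric_uncertainty,
    empirical_entropy,
    greedy_select,
    marker_scores,
    mifs_select,
    mrmr_select,
    mutual_information,
    symmetric_uncertainty,
)
from ssrkit.simulate import SynthSpec, generate

from .conftest import make_table, random_table


class TestEmpiricalEntropy:
    def test_single_category_zero(self):
        assert empirical_entropy([5]) == 0.0

    def test_uniform_two(self):
        assert empirical_entropy([3, 3]) == pytest.approx(math.log(2))

    def test_hand_computed_three_category(self):
        # -0.25 ln 0.25 * 2 - 0.5 ln 0.5 = 1.0397...
        assert empirical_entropy([1, 1, 2]) == pytest.approx(1.0397207708399179)

    def test_zero_counts_ignored(self):
        assert empirical_entropy([3, 0, 3]) == pytest.approx(math.log(2))

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            empirical_entropy([0, 0])

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            empirical_entropy([1, -1])


def expand(counts_2x2):
    """Turn a 2x2 count table into paired category vectors."""
    xs, ys = [], []
    for i, row in enumerate(counts_2x2):
        for j, c in enumerate(row):
            xs += [f"x{i}"] * c
            ys += [f"y{j}"] * c
    return np.array(xs, dtype=object), np.array(ys, dtype=object)


class TestAsymmetricUncertainty:
    def test_bijective_mapping_power_one(self):
        g = ["a", "a", "b", "b", "c", "c"]
        s = ["P", "P", "Q", "Q", "R", "R"]
        score = asymmetric_uncertainty(g, s)
        assert score.power == pytest.approx(1.0)
        assert score.power_variance == pytest.approx(0.0, abs=1e-12)
        assert score.power_z == np.inf

    def test_exact_independence_power_zero(self):
        s, g = expand([[2, 2], [2, 2]])
        score = asymmetric_uncertainty(g, s)
        assert score.power == pytest.approx(0.0, abs=1e-12)
        assert score.power_z == 0.0

    def test_entropy_decomposition_oracle(self):
        # counts [[2,0],[1,1]]: rows = marker categories, cols = groups
        s, g = expand([[2, 0], [1, 1]])
        h_g = empirical_entropy([3, 1])
        h_s = empirical_entropy([2, 2])
        h_gs = empirical_entropy([2, 0, 1, 1])
        expected = (h_g + h_s - h_gs) / h_g
        assert asymmetric_uncertainty(g, s).power == pytest.approx(expected)

    def test_constant_group_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            asymmetric_uncertainty(["a", "a", "a"], ["x", "y", "z"])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            asymmetric_uncertainty(["a", "b"], ["x"])

    def test_variance_against_bootstrap_oracle(self):
        rng = np.random.default_rng(7)
        n = 2000
        g = rng.integers(0, 3, n)
        s = np.where(rng.random(n) < 0.6, g, rng.integers(0, 4, n))
        g, s = g.astype(object), s.astype(object)
        score = asymmetric_uncertainty(g, s)
        boots = []
        for _ in range(800):
            idx = rng.integers(0, n, n)
            boots.append(asymmetric_uncertainty(g[idx], s[idx]).power)
        boot_var = np.var(boots)
        assert score.power_variance == pytest.approx(boot_var, rel=0.15)

    def test_power_in_unit_interval(self):
        for seed in range(8):
            rng = np.random.default_rng(seed)
            g = rng.integers(0, 3, 40).astype(object)
            s = rng.integers(0, 5, 40).astype(object)
            p = asymmetric_uncertainty(g, s).power
            assert 0.0 <= p <= 1.0

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(1)
        g = rng.integers(0, 3, 60).astype(object)
        s = rng.integers(0, 4, 60).astype(object)
        base = asymmetric_uncertainty(g, s)
        relabeled = asymmetric_uncertainty(
            np.array([f"grp_{v}" for v in g], dtype=object),
            np.array([f"cat_{v}" for v in s], dtype=object),
        )
        assert relabeled.power == pytest.approx(base.power)
        assert relabeled.power_variance == pytest.approx(base.power_variance)


class TestSymmetricUncertainty:
    def test_self_redundancy_one(self):
        x = np.array(["a", "b", "a", "c"], dtype=object)
        score = symmetric_uncertainty(x, x)
        assert score.value == pytest.approx(1.0)
        assert score.z == np.inf

    def test_independent_outer_product_zero(self):
        x, y = expand([[2, 2], [2, 2]])
        assert symmetric_uncertainty(x, y).value == pytest.approx(0.0, abs=1e-12)

    def test_hand_tables(self):
        a = np.array(["A", "A", "B", "B"], dtype=object)
        b = np.array(["A", "B", "A", "B"], dtype=object)
        assert symmetric_uncertainty(a, b).value == pytest.approx(0.0, abs=1e-12)
        c = np.array(["C", "C", "D", "D"], dtype=object)
        assert symmetric_uncertainty(a, c).value == pytest.approx(1.0)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(3)
        x = rng.integers(0, 3, 50).astype(object)
        y = rng.integers(0, 4, 50).astype(object)
        ab = symmetric_uncertainty(x, y)
        ba = symmetric_uncertainty(y, x)
        assert ab.value == pytest.approx(ba.value)
        assert ab.variance == pytest.approx(ba.variance)

    def test_both_constant_rejected(self):
        with pytest.raises(ValueError):
            symmetric_uncertainty(["a", "a"], ["b", "b"])

    def test_variance_against_bootstrap_oracle(self):
        rng = np.random.default_rng(11)
        n = 2000
        x = rng.integers(0, 3, n)
        y = np.where(rng.random(n) < 0.5, x, rng.integers(0, 3, n))
        x, y = x.astype(object), y.astype(object)
        score = symmetric_uncertainty(x, y)
        boots = []
        for _ in range(800):
            idx = rng.integers(0, n, n)
            boots.append(symmetric_uncertainty(x[idx], y[idx]).value)
        assert score.variance == pytest.approx(np.var(boots), rel=0.15)

    @pytest.mark.parametrize("n", [100, 400, 1600])
    def test_variance_shrinks_as_one_over_n(self, n):
        rng = np.random.default_rng(n)
        x = rng.integers(0, 3, n)
        y = np.where(rng.random(n) < 0.5, x, rng.integers(0, 3, n))
        v = symmetric_uncertainty(x.astype(object), y.astype(object)).variance
        # O(1/n): n * var stays within a fixed band
        assert 1e-3 < n * v < 10.0


class TestGreedySelect:
    def test_alpha_zero_is_top_n_by_power(self):
        for seed in range(10):
            t = random_table(seed, n_markers=8)
            config = SelectionConfig(kit_size=3, alpha=0.0)
            result = greedy_select(t, config=config)
            scores = marker_scores(t)
            expected = [
                s.marker_id
                for s in sorted(scores, key=lambda s: -s.power)[:3]
            ]
            assert result.selected_markers == expected
            assert result.skipped == []

    def test_duplicate_of_top_marker_skipped_at_alpha_one(self):
        t = _table_with_duplicate_top_marker(seed=5)
        config = SelectionConfig(kit_size=3, alpha=1.0)
        result = greedy_select(t, config=config)
        assert "DUP" not in result.selected_markers
        skipped_ids = [s.score.marker_id for s in result.skipped]
        assert "DUP" in skipped_ids
        blocker = next(s for s in result.skipped if s.score.marker_id == "DUP")
        assert blocker.blocking_redundancy.value == pytest.approx(1.0)

    def test_duplicate_kept_at_alpha_zero(self):
        t = _table_with_duplicate_top_marker(seed=5)
        config = SelectionConfig(kit_size=3, alpha=0.0)
        result = greedy_select(t, config=config)
        assert "DUP" in result.selected_markers

    def test_independent_markers_not_skipped(self):
        # mutually independent markers at large n: redundancy Z ~ 0
        skipped_total = 0
        for rep in range(20):
            rng = np.random.default_rng(200 + rep)
            n = 400
            g = rng.integers(0, 4, n).astype(object)
            cols = {}
            for m in range(6):
                cols[f"SSR{m+1}"] = np.where(
                    rng.random(n) < 0.4, g, rng.integers(0, 4, n)
                ).astype(object)
            t = _categorical_table(cols, g)
            result = greedy_select(
                t, config=SelectionConfig(kit_size=4, alpha=1.0)
            )
            skipped_total += len(result.skipped)
            assert len(result.selected) == 4
        assert skipped_total == 0

    def test_redundant_high_power_marker_skipped(self):
        # markers independent given the group, plus an exact copy of the
        # strongest one: the copy ranks second by power yet is skipped, and
        # weaker non-redundant markers fill the kit instead
        rng = np.random.default_rng(77)
        n = 400
        g = rng.integers(0, 4, n).astype(object)
        cols = {}
        for m, p in enumerate([0.8, 0.5, 0.4, 0.3]):
            cols[f"SSR{m+1}"] = np.where(
                rng.random(n) < p, g, rng.integers(0, 4, n)
            ).astype(object)
        cols["DUP"] = cols["SSR1"].copy()  # redundant high-power marker
        t = _categorical_table(cols, g)
        result = greedy_select(t, config=SelectionConfig(kit_size=3, alpha=1.0))
        assert result.selected_markers[0] == "SSR1"
        assert "DUP" not in result.selected_markers
        assert len(result.selected) == 3
        assert "DUP" in [s.score.marker_id for s in result.skipped]

    def test_kit_size_larger_than_markers_warns(self):
        t = random_table(3, n_markers=4)
        with pytest.warns(RuntimeWarning, match="exceeds"):
            result = greedy_select(t, config=SelectionConfig(kit_size=99, alpha=0.0))
        assert len(result.selected) == 4

    def test_constant_marker_ranked_last_with_zero_power(self):
        rows = {
            f"S{i}": [v, "100"] for i, v in enumerate(["110", "112", "110", "112"])
        }
        t = make_table(rows, ["SSRA", "SSRC"], labels=["x", "y", "x", "y"])
        scores = marker_scores(t)
        by_id = {s.marker_id: s for s in scores}
        assert by_id["SSRC"].power == 0.0
        result = greedy_select(t, config=SelectionConfig(kit_size=1, alpha=0.0))
        assert result.selected_markers == ["SSRA"]

    def test_monotone_alpha_skipping(self):
        t = _table_with_duplicate_top_marker(seed=21)
        max_redundancy = {}
        for alpha in (0.0, 0.5, 1.0, 2.0):
            result = greedy_select(
                t, config=SelectionConfig(kit_size=4, alpha=alpha)
            )
            zs = [
                s.blocking_redundancy.z
                for s in result.skipped
                if np.isfinite(s.blocking_redundancy.z)
            ]
            max_redundancy[alpha] = len(result.skipped)
        # raising alpha never reduces the number of skipped markers here
        assert (
            max_redundancy[0.0]
            <= max_redundancy[0.5]
            <= max_redundancy[1.0]
            <= max_redundancy[2.0]
        )


def _categorical_table(columns: dict[str, np.ndarray], labels: np.ndarray):
    """Build a genotype table whose categories are single synthetic alleles."""
    n = len(labels)
    markers = list(columns)
    rows = {}
    for i in range(n):
        rows[f"S{i}"] = [str(100 + 2 * int(columns[m][i])) for m in markers]
    return make_table(rows, markers, labels=[str(l) for l in labels])


def _table_with_duplicate_top_marker(seed: int):
    """Synthetic table plus an exact category copy of its strongest marker."""
    spec = SynthSpec(
        n_groups=4,
        samples_per_group=15,
        n_markers=5,
        miscall_rate=0.05,
        profile_concentration=0.3,
        seed=seed,
    )
    t = generate(spec)
    scores = marker_scores(t)
    top = max(scores, key=lambda s: s.power).marker_id
    import numpy as _np

    from ssrkit.genotype_io import AlleleSet, GenotypeTable

    col = t.cells[:, t.marker_index(top)]
    dup = _np.array(
        [[AlleleSet(frozenset(a + 5000 for a in cell.alleles)) for cell in col]],
        dtype=object,
    ).T
    cells = _np.concatenate([t.cells, dup], axis=1)
    return GenotypeTable(
        sample_ids=t.sample_ids,
        marker_ids=t.marker_ids + ["DUP"],
        cells=cells,
        labels=t.labels,
    )


class TestMifsMrmr:
    def test_mifs_beta_zero_ranks_by_mutual_information(self):
        t = random_table(17, n_markers=6)
        config = SelectionConfig(kit_size=3, method="MIFS", beta=0.0)
        result = mifs_select(t, config=config)
        y = np.asarray(t.labels, dtype=object)
        mis = {}
        for m in t.marker_ids:
            cats = np.asarray(
                ["" if c.missing else c.to_string() for c in t.marker_column(m)],
                dtype=object,
            )
            keep = cats != ""
            mis[m] = mutual_information(y[keep], cats[keep])
        expected = sorted(t.marker_ids, key=lambda m: -mis[m])[:3]
        assert set(result.selected_markers) == set(expected)
        assert result.selected_markers[0] == expected[0]

    def test_mifs_defers_duplicate(self):
        t = _table_with_duplicate_top_marker(seed=5)
        config = SelectionConfig(kit_size=2, method="MIFS", beta=1.0)
        result = mifs_select(t, config=config)
        assert result.selected_markers[1] != "DUP"

    def test_single_marker_table(self):
        t = random_table(19, n_markers=1)
        config = SelectionConfig(kit_size=1, method="MIFS", beta=1.0)
        assert mifs_select(t, config=config).selected_markers == ["SSR1"]

    def test_mrmr_first_pick_is_max_relevance(self):
        t = random_table(23, n_markers=6)
        fs = mifs_select(
            t, config=SelectionConfig(kit_size=1, method="MIFS", beta=0.0)
        )
        mr = mrmr_select(t, config=SelectionConfig(kit_size=1, method="mRMR"))
        assert mr.selected_markers[0] == fs.selected_markers[0]

    def test_mrmr_defers_duplicate(self):
        t = _table_with_duplicate_top_marker(seed=7)
        result = mrmr_select(t, config=SelectionConfig(kit_size=2, method="mRMR"))
        assert result.selected_markers[1] != "DUP"

    def test_mrmr_independent_markers_follow_relevance(self):
        rng = np.random.default_rng(42)
        n = 300
        g = rng.integers(0, 3, n).astype(object)
        cols = {}
        for m, p in enumerate([0.7, 0.5, 0.3, 0.1]):
            cols[f"SSR{m+1}"] = np.where(
                rng.random(n) < p, g, rng.integers(0, 3, n)
            ).astype(object)
        t = _categorical_table(cols, g)
        result = mrmr_select(t, config=SelectionConfig(kit_size=4, method="mRMR"))
        assert result.selected_markers[0] == "SSR1"


class TestConfigValidation:
    def test_negative_alpha_rejected(self):
        with pytest.raises(ValueError):
            SelectionConfig(kit_size=3, alpha=-0.1)

    def test_zero_kit_rejected(self):
        with pytest.raises(ValueError):
            SelectionConfig(kit_size=0)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            SelectionConfig(kit_size=1, method="lasso")
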