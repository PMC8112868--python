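import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cytoclust.core import Panel, SampleTable, build_experiment
from cytoclust.differential import (
    bh_fdr,
    cluster_abundances,
    stat_test_clust,
    stat_test_expression,
    volcano_data,
    welch_t,
    wilcoxon_rank_sum,
)
from cytoclust.errors import DegenerateDataError, DesignError


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def exact_wilcoxon_p(x, y):
    """Enumeration over all group assignments of the pooled values."""
    pooled = np.concatenate([x, y])
    nx = len(x)
    ranks = pd.Series(pooled).rank().to_numpy()
    w_obs = ranks[:nx].sum()
    le = ge = total = 0
    for idx in itertools.combinations(range(len(pooled)), nx):
        w = ranks[list(idx)].sum()
        total += 1
        if w <= w_obs + 1e-9:
            le += 1
        if w >= w_obs - 1e-9:
            ge += 1
    return min(1.0, 2 * min(le, ge) / total)


def brute_force_bh(p):
    """Direct step-up definition: q_i = min_{j: p_j >= p_i} m p_(j) / rank(j)."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for pos_i, i in enumerate(order):
        q[i] = min(
            m * p[order[pos_j]] / (pos_j + 1) for pos_j in range(pos_i, m)
        )
    return np.clip(q, 0, 1)


# ---------------------------------------------------------------------------
# abundances
# ---------------------------------------------------------------------------

class TestAbundances:
    @pytest.fixture
    def labelled_exp(self):
        counts = {"S1": {"a": 10, "b": 30, "c": 60}, "S2": {"a": 5, "b": 0, "c": 5}}
        sids, labels = [], []
        for sid, pops in counts.items():
            for pop, n in pops.items():
                sids += [sid] * n
                labels += [pop] * n
        n = len(sids)
        exp = build_experiment(
            np.zeros((n, 1)), sids, Panel.from_channels(["m"]),
            SampleTable(pd.DataFrame({"sample_id": ["S1", "S2"]})),
        )
        exp.add_cell_labels("pop", labels)
        return exp

    def test_proportions(self, labelled_exp):
        ab = cluster_abundances(labelled_exp, "pop")
        np.testing.assert_allclose(
            ab.proportions.loc["S1", ["a", "b", "c"]], [0.1, 0.3, 0.6]
        )

    def test_absent_population_is_zero(self, labelled_exp):
        ab = cluster_abundances(labelled_exp, "pop")
        assert ab.proportions.loc["S2", "b"] == 0.0
        assert ab.counts.loc["S2", "b"] == 0

    def test_rows_sum_to_one(self, labelled_exp):
        ab = cluster_abundances(labelled_exp, "pop")
        np.testing.assert_allclose(ab.proportions.sum(axis=1), 1.0, atol=1e-9)


# ---------------------------------------------------------------------------
# wilcoxon
# ---------------------------------------------------------------------------

class TestWilcoxon:
    def test_worked_example(self):
        w, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert w == 6.0
        assert p == pytest.approx(0.1)  # 2/20 by enumeration of C(6,3) splits

    def test_identical_multisets(self):
        _, p = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert p == 1.0

    def test_exact_matches_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            nx, ny = rng.integers(2, 8, size=2)
            pooled = rng.permutation(np.arange(1, nx + ny + 1)).astype(float)
            x, y = pooled[:nx], pooled[nx:]
            _, p = wilcoxon_rank_sum(x, y)
            assert p == pytest.approx(exact_wilcoxon_p(x, y), abs=1e-12)

    def test_approx_close_to_exact(self):
        """Normal approximation (scipy asymptotic) within 0.02 of the exact
        enumeration path on the same 10+10 tie-free draws."""
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(1)
        for _ in range(10):
            x = rng.normal(size=10)
            y = rng.normal(0.5, 1, size=10)
            _, p_exact = wilcoxon_rank_sum(x, y)  # n=20, no ties -> exact
            p_approx = mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic"
            ).pvalue
            assert p_approx == pytest.approx(p_exact, abs=0.02)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([1.0], [2.0, 3.0])

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 10_000))
    def test_exact_p_enumeration_property(self, seed):
        rng = np.random.default_rng(seed)
        nx = int(rng.integers(2, 6))
        ny = int(rng.integers(2, 6))
        vals = rng.choice(np.arange(100), size=nx + ny, replace=False).astype(float)
        x, y = vals[:nx], vals[nx:]
        _, p = wilcoxon_rank_sum(x, y)
        assert p == pytest.approx(exact_wilcoxon_p(x, y), abs=1e-12)


class TestWelch:
    def test_worked_example(self):
        t, df, p = welch_t([1, 2, 3], [2, 3, 4])
        assert t == pytest.approx(-1.224744871, abs=1e-6)
        assert df == pytest.approx(4.0, abs=1e-9)
        assert p == pytest.approx(0.2879, abs=2e-4)

    def test_identical_groups(self):
        t, _, p = welch_t([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == 1.0

    def test_student_limit(self):
        # equal variances, equal n -> df = 2n - 2
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = x + 10.0
        _, df, _ = welch_t(x, y)
        assert df == pytest.approx(2 * 4 - 2, abs=1e-9)

    def test_degenerate(self):
        with pytest.raises(DegenerateDataError):
            welch_t([1.0, 1.0], [2.0, 2.0])


class TestBhFdr:
    def test_hand_example_one(self):
        np.testing.assert_allclose(bh_fdr([0.04, 0.01, 0.03]), [0.04, 0.03, 0.04])

    def test_hand_example_two(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p(self):
        np.testing.assert_allclose(bh_fdr([0.2]), [0.2])

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])

    def test_matches_brute_force_1000_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            m = int(rng.integers(1, 12))
            p = rng.uniform(size=m)
            np.testing.assert_allclose(bh_fdr(p), brute_force_bh(p), atol=1e-12)


# ---------------------------------------------------------------------------
# group tests
# ---------------------------------------------------------------------------

def _samples(n_a=3, n_b=3):
    ids = [f"A{i}" for i in range(n_a)] + [f"B{i}" for i in range(n_b)]
    return SampleTable(
        pd.DataFrame({"sample_id": ids, "group": ["A"] * n_a + ["B"] * n_b})
    )


def _abundance(props_by_sample):
    from cytoclust.differential import AbundanceTable

    props = pd.DataFrame(props_by_sample).T
    counts = (props * 1000).round().astype(int)
    return AbundanceTable(proportions=props, counts=counts)


class TestStatTestClust:
    def test_worked_example(self):
        ab = _abundance(
            {
                "A0": {"p1": 0.2, "p2": 0.8},
                "A1": {"p1": 0.22, "p2": 0.78},
                "A2": {"p1": 0.21, "p2": 0.79},
                "B0": {"p1": 0.1, "p2": 0.9},
                "B1": {"p1": 0.11, "p2": 0.89},
                "B2": {"p1": 0.12, "p2": 0.88},
            }
        )
        dr = stat_test_clust(ab, _samples(), "group", ("A", "B"))
        row = dr.set_index("population").loc["p1"]
        assert row["log2fc"] == pytest.approx(1.0, abs=0.1)
        assert row["p"] == pytest.approx(0.1)  # exact Wilcoxon 3 vs 3

    def test_identical_groups(self):
        same = {"p1": 0.5, "p2": 0.5}
        ab = _abundance({sid: same for sid in ["A0", "A1", "A2", "B0", "B1", "B2"]})
        dr = stat_test_clust(ab, _samples(), "group", ("A", "B"))
        assert (dr["p"] == 1.0).all()
        assert (dr["log2fc"] == 0.0).all()

    def test_contrast_swap_symmetry(self):
        rng = np.random.default_rng(2)
        ab = _abundance(
            {
                sid: dict(zip(["p1", "p2", "p3"], rng.dirichlet([5, 3, 2])))
                for sid in ["A0", "A1", "A2", "B0", "B1", "B2"]
            }
        )
        d1 = stat_test_clust(ab, _samples(), "group", ("A", "B"))
        d2 = stat_test_clust(ab, _samples(), "group", ("B", "A"))
        np.testing.assert_allclose(d1["log2fc"], -d2["log2fc"], atol=1e-12)
        np.testing.assert_allclose(d1["p"], d2["p"], atol=1e-12)
        np.testing.assert_allclose(d1["fdr"], d2["fdr"], atol=1e-12)

    def test_too_few_samples(self):
        ab = _abundance(
            {"A0": {"p": 1.0}, "B0": {"p": 1.0}, "B1": {"p": 1.0}}
        )
        st_ = SampleTable(
            pd.DataFrame({"sample_id": ["A0", "B0", "B1"], "group": ["A", "B", "B"]})
        )
        with pytest.raises(DesignError, match=">= 2"):
            stat_test_clust(ab, st_, "group", ("A", "B"))

    def test_ttest_mode(self):
        ab = _abundance(
            {
                "A0": {"p1": 0.3, "p2": 0.7},
                "A1": {"p1": 0.32, "p2": 0.68},
                "A2": {"p1": 0.29, "p2": 0.71},
                "B0": {"p1": 0.1, "p2": 0.9},
                "B1": {"p1": 0.12, "p2": 0.88},
                "B2": {"p1": 0.11, "p2": 0.89},
            }
        )
        dr = stat_test_clust(ab, _samples(), "group", ("A", "B"), test="ttest")
        assert (dr["test"] == "welch_t").all()
        assert dr.set_index("population").loc["p1", "p"] < 0.01


class TestStatTestExpression:
    @pytest.fixture
    def shifted_exp(self):
        """One population's marker shifted +1 in group A."""
        from cytoclust.simulate import Effect, default_spec, simulate_experiment

        spec = default_spec(
            seed=3,
            cells_per_sample=300,
            n_samples_per_group=4,
            effects=[Effect(population="P2", group="A", marker="M03", marker_shift=1.0)],
        )
        return simulate_experiment(spec)

    def test_shifted_pair_has_min_p(self, shifted_exp):
        exp, truth = shifted_exp
        dr = stat_test_expression(
            exp, truth["cell_population"], ["M01", "M03", "M05"],
            exp.samples, "group", ("A", "B"),
        )
        best = dr.loc[dr["p"].idxmin()]
        assert best["population"] == "P2" and best["marker"] == "M03"
        assert best["diff"] == pytest.approx(1.0, abs=0.25)

    def test_single_pair_q_equals_p(self, shifted_exp):
        exp, truth = shifted_exp
        dr = stat_test_expression(
            exp, truth["cell_population"], ["M03"], exp.samples, "group", ("A", "B"),
        )
        one = dr[dr["population"] == "P1"]
        # joint family: with several populations q != p, so re-run restricted
        mask = truth["cell_population"] == "P1"
        from cytoclust.core import subset_experiment

        sub = subset_experiment(exp, mask=mask)
        dr1 = stat_test_expression(
            sub, truth["cell_population"][mask], ["M03"],
            sub.samples, "group", ("A", "B"),
        )
        assert len(dr1) == 1
        assert dr1["fdr"].iloc[0] == pytest.approx(dr1["p"].iloc[0])


def test_export_for_differential_tools(tmp_path, sim_small):
    from cytoclust.differential import export_for_differential_tools

    exp, truth = sim_small
    paths = export_for_differential_tools(exp, truth["cell_population"], tmp_path)
    cells = pd.read_csv(paths["cells"])
    assert len(cells) == exp.n_cells
    assert {"cell", "sample_id", "population"} <= set(cells.columns)
    samples = pd.read_csv(paths["samples"])
    assert list(samples["sample_id"]) == exp.samples.ids


class TestVolcano:
    def _dr(self, fdrs):
        return pd.DataFrame(
            {"population": [f"p{i}" for i in range(len(fdrs))],
             "log2fc": np.linspace(-1, 1, len(fdrs)),
             "p": fdrs, "fdr": fdrs}
        )

    def test_just_below_threshold_significant(self):
        vd = volcano_data(self._dr([0.049]))
        assert bool(vd["significant"].iloc[0]) is True

    def test_exact_threshold_not_significant(self):
        vd = volcano_data(self._dr([0.05]))
        assert bool(vd["significant"].iloc[0]) is False

    def test_fdr_one_maps_to_zero(self):
        vd = volcano_data(self._dr([1.0]))
        assert vd["neg_log10_fdr"].iloc[0] == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            volcano_data(pd.DataFrame())
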