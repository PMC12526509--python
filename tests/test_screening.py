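"""Correlation screening: Pearson/p, exhaustive search, redundancy, VIF."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import smctex as st
from smctex.screening import _vif_values


class TestPearsonWithP:
    def test_identity_gives_r_one(self):
        x = np.arange(10.0)
        r, p = st.pearson_with_p(x, x)
        assert r == pytest.approx(1.0)
        assert p < 1e-12

    def test_orthogonal_contrast_gives_r_zero_p_one(self):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, 2.0, 2.0])
        r, p = st.pearson_with_p(x, y)
        assert r == pytest.approx(0.0, abs=1e-15)
        assert p == pytest.approx(1.0)

    def test_matches_scipy_on_random_columns(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            x, y = rng.normal(size=30), rng.normal(size=30)
            r, p = st.pearson_with_p(x, y)
            want = stats.pearsonr(x, y)
            assert r == pytest.approx(want.statistic, abs=1e-12)
            assert p == pytest.approx(want.pvalue, rel=1e-9, abs=1e-12)

    def test_zero_variance_undefined(self):
        r, p = st.pearson_with_p(np.ones(10), np.arange(10.0))
        assert np.isnan(r) and np.isnan(p)

    def test_nan_pairs_dropped(self):
        x = np.array([1.0, 2.0, np.nan, 4.0, 5.0])
        y = np.array([2.0, 4.0, 0.0, 8.0, 10.0])
        r, _ = st.pearson_with_p(x, y)
        assert r == pytest.approx(1.0)


def _equivalent_names(family, name):
    """Combinations whose |r| ties with `name` by exact algebraic identity.

    MSI is permutation-invariant; BDSI(i,j,k) = 1 − BDSI(i,k,j), an affine
    anti-relation, so the pair ties in |r|.  The ties are exact in algebra
    but differ in the last ulp between evaluation orders, so either member
    may win the argmax.
    """
    import smctex as st

    labs = [p.label for p in st.parse_index_name(name).positions]
    if family == "MSI":
        return {f"MSI({','.join(p)})" for p in itertools.permutations(labs)}
    if family == "BDSI":
        i, j, k = labs
        return {name, f"BDSI({i},{k},{j})"}
    return {name}


def _brute_best(features, y, family, labels):
    """Literal nested-loop search over the family's tuple space."""
    best = None
    arity = 2 if family in st.FAMILIES_2D else 3
    for tup in itertools.product(labels, repeat=arity):
        cols = [features[t].to_numpy(float) for t in tup]
        v = (st.eval_2d(family, *cols) if arity == 2
             else st.eval_3d(family, *cols))
        v = np.where(np.isfinite(v), v, np.nan)
        if np.isnan(v).mean() > 0.10:
            continue
        r, p = st.pearson_with_p(v, y)
        if np.isnan(r):
            continue
        name = f"{family}({','.join(tup)})"
        key = (-abs(r), name)
        if best is None or key < best[0]:
            best = (key, name, r)
    return best[1], best[2]


class TestExhaustiveSearch:
    @pytest.mark.parametrize("family", list(st.FAMILIES_2D) + list(st.FAMILIES_3D))
    def test_reduced_space_matches_nested_loops(self, family,
                                                random_position_table):
        labels = ["MEA1", "VAR2", "HOM3", "DIS4", "SEC6"]
        rng = np.random.default_rng(17)
        y = rng.normal(size=96)
        res = st.exhaustive_search(random_position_table, y, family,
                                   positions=labels)
        want_name, want_r = _brute_best(random_position_table, y, family, labels)
        assert abs(res.r) == pytest.approx(abs(want_r), abs=1e-9)
        assert res.best_name in _equivalent_names(family, want_name)

    def test_planted_perfect_correlate_wins(self, random_position_table):
        table = random_position_table.copy()
        rng = np.random.default_rng(8)
        y = rng.normal(size=96)
        table["HOM3"] = y  # plant
        res = st.exhaustive_search(table, y, "raw")
        assert res.best_name == "HOM3"
        assert res.r == pytest.approx(1.0)

    def test_restricted_space_never_beats_full_space(self,
                                                     random_position_table):
        rng = np.random.default_rng(31)
        y = rng.normal(size=96)
        full = st.exhaustive_search(random_position_table, y, "DTI")
        sub = st.exhaustive_search(random_position_table, y, "DTI",
                                   positions=["MEA1", "VAR2", "HOM3"])
        assert abs(sub.r) <= abs(full.r) + 1e-12

    def test_raw_candidates_all_significant(self, random_position_table):
        rng = np.random.default_rng(9)
        base = rng.normal(size=96)
        table = random_position_table.copy()
        table["MEA1"] = base + rng.normal(scale=0.4, size=96)
        res = st.exhaustive_search(table, base, "raw", alpha=0.05)
        assert "MEA1" in res.candidates
        for lab in res.candidates:
            _, p = st.pearson_with_p(table[lab], base)
            assert p < 0.05

    def test_all_undefined_raises(self):
        table = pd.DataFrame({"MEA1": np.full(20, np.nan),
                              "MEA2": np.full(20, np.nan)})
        with pytest.raises(ValueError, match="undefined"):
            st.exhaustive_search(table, np.arange(20.0), "raw",
                                 positions=["MEA1", "MEA2"])


class TestRedundancyFilter:
    def test_identical_columns_keep_one(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=50)
        a = y + rng.normal(scale=0.5, size=50)
        cols = pd.DataFrame({"A": a, "B": a.copy()})
        kept = st.redundancy_filter(cols, y, ["A", "B"])
        assert kept == ["A"]

    def test_orthogonal_columns_all_survive(self):
        rng = np.random.default_rng(4)
        cols = pd.DataFrame(rng.normal(size=(200, 4)),
                            columns=list("ABCD"))
        y = cols.sum(axis=1)
        kept = st.redundancy_filter(cols, y, list("ABCD"))
        assert sorted(kept) == list("ABCD")

    def test_pairwise_r_below_cut_by_construction(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=100)
        cols = pd.DataFrame({
            f"F{i}": base * w + rng.normal(scale=s, size=100)
            for i, (w, s) in enumerate([(1, .1), (1, .12), (.5, 1),
                                        (0, 1), (.8, .15), (.2, 2)])
        })
        kept = st.redundancy_filter(cols, base, list(cols.columns))
        for a, b in itertools.combinations(kept, 2):
            r, _ = st.pearson_with_p(cols[a], cols[b])
            assert abs(r) < 0.90

    def test_greedy_walk_matches_hand_simulation(self):
        rng = np.random.default_rng(6)
        base = rng.normal(size=120)
        cols = pd.DataFrame({
            "A": base + rng.normal(scale=0.05, size=120),
            "B": base + rng.normal(scale=0.06, size=120),
            "C": rng.normal(size=120),
        })
        # hand simulation: order by |r| with base, drop near-duplicates
        order = sorted(cols.columns,
                       key=lambda c: -abs(st.pearson_with_p(cols[c], base)[0]))
        kept_hand = []
        for c in order:
            if all(abs(st.pearson_with_p(cols[c], cols[k])[0]) < 0.90
                   for k in kept_hand):
                kept_hand.append(c)
        assert st.redundancy_filter(cols, base, list(cols.columns)) == kept_hand


class TestVIFFilter:
    def test_independent_columns_untouched(self):
        rng = np.random.default_rng(7)
        cols = pd.DataFrame(rng.normal(size=(500, 2)), columns=["a", "b"])
        assert st.vif_filter(cols, ["a", "b"]) == ["a", "b"]
        assert _vif_values(cols.to_numpy()).max() < 1.1

    def test_near_duplicate_dropped(self):
        rng = np.random.default_rng(8)
        x1 = rng.normal(size=200)
        cols = pd.DataFrame({"x1": x1,
                             "x2": x1 + rng.normal(scale=1e-4, size=200),
                             "x3": rng.normal(size=200)})
        kept = st.vif_filter(cols, ["x1", "x2", "x3"])
        assert len(kept) == 2 and "x3" in kept

    def test_matches_inverse_correlation_closed_form(self):
        rng = np.random.default_rng(9)
        cov = np.array([[1.0, 0.6, 0.3, 0.0],
                        [0.6, 1.0, 0.5, 0.1],
                        [0.3, 0.5, 1.0, 0.2],
                        [0.0, 0.1, 0.2, 1.0]])
        L = np.linalg.cholesky(cov)
        Z = rng.normal(size=(400, 4)) @ L.T
        got = _vif_values(Z)
        R = np.corrcoef(Z, rowvar=False)
        want = np.diag(np.linalg.inv(R))
        assert np.allclose(got, want, atol=1e-8)

    def test_matches_statsmodels_oracle(self):
        from statsmodels.stats.outliers_influence import variance_inflation_factor

        rng = np.random.default_rng(10)
        Z = rng.normal(size=(150, 4))
        Z[:, 1] += 0.9 * Z[:, 0]
        Zs = (Z - Z.mean(0)) / Z.std(0)
        want = [variance_inflation_factor(Zs, j) for j in range(4)]
        assert np.allclose(_vif_values(Z), want, rtol=1e-6)


def test_screen_family_survivors_nonredundant(small_features, small_dataset):
    _, _, smc = small_dataset
    y = (smc[smc.depth_layer == "0-20"].set_index("plot_id")["smc"]
         .reindex(small_features.index) * 100)
    res = st.screen_family(small_features, y, "DTI")
    assert res.survivors
    cols = st.materialize_features(small_features, res.survivors)
    for a, b in itertools.combinations(res.survivors, 2):
        r, _ = st.pearson_with_p(cols[a], cols[b])
        assert abs(r) < 0.90
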