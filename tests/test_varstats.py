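"""Variation statistics: log transform, CVs, ANOVA/Tukey with letters,
Pearson matrices, |r|-based trait clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from xylemtraits.varstats import (
    anova_tukey,
    cluster_traits,
    compact_letter_display,
    interspecific_cv,
    log_transform,
    pearson_matrix,
    within_species_cv,
)


class TestLogTransform:
    def test_round_trip_and_known_values(self):
        df = pd.DataFrame({"a": [1.0, np.e, 10.0], "b": [2.0, 3.0, 4.0]})
        out = log_transform(df)
        assert out.loc[0, "a"] == 0.0
        assert out.loc[1, "a"] == pytest.approx(1.0, rel=1e-12)
        assert np.allclose(np.exp(out), df, rtol=1e-12)

    def test_nonpositive_value_names_cell(self):
        df = pd.DataFrame({"x": [1.0, -2.0]})
        with pytest.raises(ValueError, match="'x'"):
            log_transform(df)


class TestCv:
    def test_identical_means_zero(self):
        df = pd.DataFrame({"t": [5.0, 5.0, 5.0]})
        assert interspecific_cv(df)["t"] == 0.0

    def test_hand_example(self):
        # means [1, 3]: 100*sqrt(2)/2
        df = pd.DataFrame({"t": [1.0, 3.0]})
        assert interspecific_cv(df)["t"] == pytest.approx(70.7107, abs=1e-3)

    def test_requires_two_species(self):
        with pytest.raises(ValueError):
            interspecific_cv(pd.DataFrame({"t": [1.0]}))

    def test_conductivity_has_widest_cv(self, derived):
        """Quartic diameter dependence makes K_s the most variable trait."""
        means = derived.groupby("species")[["K_s", "D_h", "TD", "TO", "MF",
                                            "TSR", "CWR", "FL"]].mean()
        cv = interspecific_cv(means)
        assert cv.idxmax() == "K_s"

    def test_within_species_cv_shape(self, derived):
        w = within_species_cv(derived, traits=["K_s", "TO"])
        assert w.shape == (17, 2) and (w.stack() >= 0).all()


class TestAnovaTukey:
    def test_identical_groups(self):
        df = pd.DataFrame({"species": ["a"] * 3 + ["b"] * 3,
                           "t": [1.0, 1.1, 0.9, 1.0, 1.1, 0.9]})
        res = anova_tukey(df, "t")
        assert res.p > 0.99
        assert res.letters["a"] == res.letters["b"]

    def test_separated_groups(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"species": ["a"] * 5 + ["b"] * 5,
                           "t": np.r_[rng.normal(0, 0.01, 5),
                                      rng.normal(10, 0.01, 5)]})
        res = anova_tukey(df, "t")
        assert res.p < 1e-3
        assert not set(res.letters["a"]) & set(res.letters["b"])

    def test_f_matches_sums_of_squares_oracle(self):
        """F equals an independent between/within SS decomposition to 1e-10."""
        rng = np.random.default_rng(7)
        groups = [rng.normal(m, 1.0, 8) for m in (0.0, 0.4, 1.1)]
        df = pd.DataFrame({
            "species": np.repeat(list("abc"), 8),
            "t": np.concatenate(groups)})
        res = anova_tukey(df, "t")
        grand = np.concatenate(groups).mean()
        ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
        f_oracle = (ss_between / 2) / (ss_within / (24 - 3))
        assert res.F == pytest.approx(f_oracle, abs=1e-10)
        assert res.p == pytest.approx(stats.f.sf(f_oracle, 2, 21), abs=1e-12)

    def test_group_size_preconditions(self):
        df = pd.DataFrame({"species": ["a", "a", "b"], "t": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="b"):
            anova_tukey(df, "t")

    def test_f_invariances(self, derived):
        sub = derived[derived["species"].isin(derived["species"].unique()[:4])]
        base = anova_tukey(sub, "TO").F
        shifted = sub.copy()
        shifted["TO"] = shifted["TO"] + 100.0
        scaled = sub.copy()
        scaled["TO"] = scaled["TO"] * 7.0
        assert anova_tukey(shifted, "TO").F == pytest.approx(base, rel=1e-8)
        assert anova_tukey(scaled, "TO").F == pytest.approx(base, rel=1e-8)

    def test_letters_consistent_with_pairwise_p(self, derived):
        """Species pairs with HSD p < alpha never share a letter, and pairs
        sharing a letter are never significantly different (exhaustive)."""
        res = anova_tukey(derived, "DT", alpha=0.05)
        labels = list(res.tukey_p.index)
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                share = bool(set(res.letters[a]) & set(res.letters[b]))
                if res.tukey_p.loc[a, b] < 0.05:
                    assert not share, (a, b)
                else:
                    assert share, (a, b)


class TestCompactLetterDisplay:
    def test_three_group_chain(self):
        # a != c but both overlap b -> b shares a letter with each
        p = np.array([[1, .5, .001], [.5, 1, .5], [.001, .5, 1]])
        letters = compact_letter_display(["g1", "g2", "g3"], p)
        assert set(letters["g1"]) & set(letters["g2"])
        assert set(letters["g2"]) & set(letters["g3"])
        assert not set(letters["g1"]) & set(letters["g3"])


class TestPearson:
    def test_self_and_exact_negative(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0]})
        df["y"] = -df["x"]
        r, p = pearson_matrix(df)
        assert r.loc["x", "x"] == 1.0 and p.loc["x", "x"] == 0.0
        assert r.loc["x", "y"] == pytest.approx(-1.0, abs=1e-12)

    def test_matches_textbook_formula(self):
        """r and p agree with direct covariance/SD computation to 1e-12."""
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(15, 10)),
                          columns=[f"t{i}" for i in range(10)])
        r, p = pearson_matrix(df)
        for i in range(10):
            for j in range(i + 1, 10):
                x, y = df.iloc[:, i], df.iloc[:, j]
                rr = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
                    ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
                assert r.iloc[i, j] == pytest.approx(rr, abs=1e-12)
                sp_r, sp_p = stats.pearsonr(x, y)
                assert p.iloc[i, j] == pytest.approx(sp_p, abs=1e-10)

    def test_positive_semidefinite(self, derived):
        means = derived.groupby("species")[["K_s", "D_h", "TO", "MF", "TSR",
                                            "CWR", "TD", "FL"]].mean()
        r, _ = pearson_matrix(means)
        evals = np.linalg.eigvalsh(r.to_numpy())
        assert evals.min() > -1e-10

    def test_zero_variance_warns(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0], "c": [5.0] * 4})
        with pytest.warns(UserWarning, match="zero-variance"):
            r, _ = pearson_matrix(df)
        assert np.isnan(r.loc["x", "c"])


class TestClusterTraits:
    def test_perfect_pair_merges_first(self):
        r = pd.DataFrame([[1, 1, .1], [1, 1, .2], [.1, .2, 1]],
                         index=list("abc"), columns=list("abc"), dtype=float)
        res = cluster_traits(r)
        assert res.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)
        order = res.leaf_order
        assert abs(order.index("a") - order.index("b")) == 1

    def test_block_structure_recovered(self):
        """Two |r| blocks come out as the two top-level clades."""
        block = np.full((2, 2), 0.9)
        np.fill_diagonal(block, 1.0)
        r = np.full((4, 4), 0.05)
        r[:2, :2] = block
        r[2:, 2:] = block
        rdf = pd.DataFrame(r, index=list("abcd"), columns=list("abcd"))
        order = cluster_traits(rdf).leaf_order
        first_two = set(order[:2])
        assert first_two in ({"a", "b"}, {"c", "d"})

    def test_three_traits_match_exhaustive_merge(self):
        """Average-linkage heights equal the brute-force merge sequence."""
        r = pd.DataFrame([[1.0, .8, .3], [.8, 1.0, .5], [.3, .5, 1.0]],
                         index=list("xyz"), columns=list("xyz"))
        z = cluster_traits(r).linkage
        # brute force: closest pair is (x, y) at 1-.8=.2; then the pair
        # cluster joins z at mean(1-.3, 1-.5)=.6
        assert z[0, 2] == pytest.approx(0.2, abs=1e-12)
        assert z[1, 2] == pytest.approx(0.6, abs=1e-12)

    def test_asymmetric_rejected(self):
        r = pd.DataFrame([[1.0, .2], [.5, 1.0]], index=["a", "b"],
                         columns=["a", "b"])
        with pytest.raises(ValueError):
            cluster_traits(r)
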