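"""Distance-based inference: oracles, cross-checks and constructions."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import f_oneway
from skbio.stats.distance import DistanceMatrix as SkbioDM
from skbio.stats.distance import permanova as skbio_permanova
from skbio.stats.distance import permdisp as skbio_permdisp

from meiostates import perm_stats as ps


def frame(array, prefix="s"):
    idx = [f"{prefix}{i}" for i in range(len(array))]
    return pd.DataFrame(np.asarray(array, dtype=float), index=idx)


class TestDistanceMatrix:
    def test_bray_curtis_reference_pair(self):
        d = ps.distance_matrix(frame([[2, 1], [1, 1]]), "bray-curtis")
        assert d.iloc[0, 1] == pytest.approx(0.2)

    def test_identical_and_disjoint_samples(self):
        d = ps.distance_matrix(frame([[3, 0], [3, 0], [0, 5]]), "bray-curtis")
        assert d.iloc[0, 1] == 0
        assert d.iloc[0, 2] == 1

    def test_all_zero_pair_defined_with_warning(self):
        with pytest.warns(UserWarning, match="all-zero"):
            d = ps.distance_matrix(frame([[0, 0], [0, 0]]), "bray-curtis")
        assert d.iloc[0, 1] == 0

    def test_negative_data_rejected(self):
        with pytest.raises(ValueError):
            ps.distance_matrix(frame([[-1, 2], [0, 1]]), "bray-curtis")

    def test_normalized_euclidean_is_zscore_distance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(8, 3)) * [1, 10, 100]
        d = ps.distance_matrix(frame(x), "euclidean-normalized")
        z = (x - x.mean(0)) / x.std(0, ddof=1)
        expect = np.linalg.norm(z[0] - z[1])
        assert d.iloc[0, 1] == pytest.approx(expect)


class TestPermanova:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_one_way_equals_classical_anova(self, seed):
        # pseudo-F on Euclidean distances of univariate data must equal
        # the classical one-way ANOVA F to machine precision
        rng = np.random.default_rng(seed)
        y = rng.normal(size=21)
        groups = np.repeat(list("abc"), 7)
        data = frame(y[:, None])
        design = pd.DataFrame({"g": groups}, index=data.index)
        dm = ps.distance_matrix(data, "euclidean")
        table = ps.permanova(dm, design, ("g",), n_perm=9, seed=0)
        expect = f_oneway(y[:7], y[7:14], y[14:]).statistic
        assert table.loc[0, "pseudo_F"] == pytest.approx(expect, rel=1e-12)

    def test_two_way_balanced_equals_classical_anova(self):
        # closed-form balanced two-way ANOVA oracle (computed from cell
        # means) for both main effects and the interaction
        rng = np.random.default_rng(3)
        a = np.repeat(list("pq"), 12)
        b = np.tile(np.repeat(list("xyz"), 4), 2)
        y = rng.normal(size=24) + (a == "p") * 0.8
        data = frame(y[:, None])
        design = pd.DataFrame({"A": a, "B": b}, index=data.index)
        dm = ps.distance_matrix(data, "euclidean")
        table = ps.permanova(dm, design, ("A", "B"), n_perm=9, seed=0).set_index("term")

        grand = y.mean()
        ss_a = sum(12 * (y[a == i].mean() - grand) ** 2 for i in "pq")
        ss_b = sum(8 * (y[b == j].mean() - grand) ** 2 for j in "xyz")
        cells = {(i, j): y[(a == i) & (b == j)] for i in "pq" for j in "xyz"}
        ss_cells = sum(4 * (v.mean() - grand) ** 2 for v in cells.values())
        ss_int = ss_cells - ss_a - ss_b
        ss_res = sum(((v - v.mean()) ** 2).sum() for v in cells.values())
        ms_res = ss_res / 18
        assert table.loc["A", "pseudo_F"] == pytest.approx((ss_a / 1) / ms_res)
        assert table.loc["B", "pseudo_F"] == pytest.approx((ss_b / 2) / ms_res)
        assert table.loc["A x B", "pseudo_F"] == pytest.approx((ss_int / 2) / ms_res)

    def test_statistic_matches_skbio_one_way(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(18, 4))
        x[:9] += 0.5
        data = frame(x)
        groups = ["g1"] * 9 + ["g2"] * 9
        design = pd.DataFrame({"g": groups}, index=data.index)
        dm = ps.distance_matrix(data, "bray-curtis" if (x >= 0).all() else "euclidean")
        mine = ps.permanova(dm, design, ("g",), n_perm=99, seed=0)
        theirs = skbio_permanova(
            SkbioDM(dm.to_numpy(), ids=list(dm.index)), groups, permutations=99, seed=0
        )
        assert mine.loc[0, "pseudo_F"] == pytest.approx(
            float(theirs["test statistic"]), rel=1e-10
        )

    def test_nested_design_partition_is_exhaustive(self, default_study, default_design):
        dm = ps.distance_matrix(default_study.meiofauna, "bray-curtis")
        table = ps.permanova(
            dm, default_design, ("state", "area"), site="site", n_perm=9, seed=0
        )
        g = ps.gower_center(dm.to_numpy())
        assert table["SS"].sum() == pytest.approx(np.trace(g))
        assert table["df"].tolist() == [1, 5, 5, 12, 96]

    def test_permutation_p_reproducible_and_positive(self, default_study, default_design):
        dm = ps.distance_matrix(default_study.meiofauna, "bray-curtis")
        kwargs = dict(site="site", n_perm=49, seed=11, terms=("state",))
        t1 = ps.permanova(dm, default_design, ("state", "area"), **kwargs)
        t2 = ps.permanova(dm, default_design, ("state", "area"), **kwargs)
        p = t1.loc[0, "p_perm"]
        assert p == t2.loc[0, "p_perm"]
        assert 0 < p <= 1

    def test_exact_enumeration_when_space_is_small(self, default_study, default_design):
        # a single-area State test has only C(4,2)=6 site arrangements
        mask = (default_design["area"] == "Area1").to_numpy()
        dm = ps.distance_matrix(default_study.meiofauna.loc[mask], "bray-curtis")
        table = ps.permanova(
            dm, default_design.loc[mask], ("state",), site="site", n_perm=999, seed=0
        )
        assert table.loc[0, "method"] == "exact"
        assert table.loc[0, "n_perm"] == 6


class TestPairwise:
    def test_t_is_sqrt_of_two_level_f(self):
        rng = np.random.default_rng(5)
        x = np.abs(rng.normal(size=(12, 3)))
        x[:6] *= 3
        data = frame(x)
        design = pd.DataFrame({"g": ["a"] * 6 + ["b"] * 6}, index=data.index)
        dm = ps.distance_matrix(data, "bray-curtis")
        pw = ps.pairwise_tests(dm, design, "g", n_perm=49, seed=1)
        two_level = ps.permanova(dm, design, ("g",), n_perm=9, seed=0)
        assert pw.loc[0, "t"] == pytest.approx(np.sqrt(two_level.loc[0, "pseudo_F"]))

    def test_displaced_group_flagged_only_in_its_pairs(self):
        rng = np.random.default_rng(8)
        base = np.abs(rng.normal(5, 1, size=(30, 4)))
        base[20:] += 12  # group c displaced
        data = frame(base)
        design = pd.DataFrame({"g": np.repeat(list("abc"), 10)}, index=data.index)
        dm = ps.distance_matrix(data, "bray-curtis")
        pw = ps.pairwise_tests(dm, design, "g", n_perm=199, seed=2).set_index(
            ["level_a", "level_b"]
        )
        assert pw.loc[("a", "c"), "p_perm"] <= 0.05
        assert pw.loc[("b", "c"), "p_perm"] <= 0.05
        assert pw.loc[("a", "b"), "p_perm"] > 0.05


class TestPermdisp:
    def test_translation_leaves_dispersion_equal(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(15, 4))
        data = frame(np.vstack([a, a + 6]))
        groups = pd.Series(["g1"] * 15 + ["g2"] * 15, index=data.index)
        res = ps.permdisp(
            ps.distance_matrix(data, "euclidean"), groups, n_perm=199, seed=0
        )
        assert res.p_perm > 0.05

    def test_scaled_cloud_detected(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(15, 4))
        data = frame(np.vstack([a, a * 3 + 10]))
        groups = pd.Series(["g1"] * 15 + ["g2"] * 15, index=data.index)
        res = ps.permdisp(
            ps.distance_matrix(data, "euclidean"), groups, n_perm=199, seed=0
        )
        assert res.p_perm <= 0.05

    def test_statistic_matches_skbio(self):
        # Euclidean case: no negative eigenvalues, so the reference
        # implementation's truncated embedding and ours coincide
        rng = np.random.default_rng(4)
        x = np.abs(rng.normal(size=(24, 5)))
        x[12:] *= 2
        data = frame(x)
        groups = ["g1"] * 12 + ["g2"] * 12
        dm = ps.distance_matrix(data, "euclidean")
        mine = ps.permdisp(dm, pd.Series(groups, index=data.index), n_perm=99, seed=0)
        theirs = skbio_permdisp(
            SkbioDM(dm.to_numpy(), ids=list(dm.index)),
            groups,
            test="centroid",
            permutations=99,
            seed=0,
        )
        assert mine.statistic == pytest.approx(float(theirs["test statistic"]), rel=1e-9)

    def test_degenerate_groups_have_zero_distances(self):
        data = frame(np.tile([1.0, 2.0], (6, 1)))
        groups = pd.Series(["a"] * 3 + ["b"] * 3, index=data.index)
        res = ps.permdisp(ps.distance_matrix(data, "euclidean"), groups, n_perm=19, seed=0)
        assert np.isnan(res.statistic) or res.statistic == pytest.approx(0, abs=1e-12)


class TestSimper:
    def test_identical_groups_zero_dissimilarity(self):
        data = frame(np.tile([4.0, 1.0, 0.0], (6, 1)))
        groups = pd.Series(["a"] * 3 + ["b"] * 3, index=data.index)
        out = ps.simper(data, groups)
        assert out.attrs["average_dissimilarity"] == pytest.approx(0.0)

    def test_contributions_sum_to_average_dissimilarity(self, default_study, default_design):
        out = ps.simper(default_study.meiofauna, default_design["state"])
        assert out["contribution"].sum() == pytest.approx(
            out.attrs["average_dissimilarity"], abs=1e-10
        )

    def test_planted_driver_taxon_ranked_first(self):
        rng = np.random.default_rng(6)
        base = np.abs(rng.normal(10, 1, size=(20, 5)))
        base[10:, 0] += 60  # one taxon carries the difference
        data = frame(base)
        groups = pd.Series(["a"] * 10 + ["b"] * 10, index=data.index)
        out = ps.simper(data, groups)
        assert out.loc[0, "taxon"] == 0
        assert out.loc[0, "pct_contribution"] > 50


class TestDistlm:
    def test_univariate_marginal_r2_is_squared_correlation(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=40)
        y = 2 * x + rng.normal(size=40)
        resp = frame(y[:, None], prefix="q")
        pred = pd.DataFrame({"x": x}, index=resp.index)
        dl = ps.distlm_forward(
            ps.distance_matrix(resp, "euclidean"), pred, n_perm=49, seed=1
        )
        assert dl.loc[0, "marginal_r2"] == pytest.approx(
            np.corrcoef(x, y)[0, 1] ** 2, rel=1e-10
        )

    def test_collinear_predictor_skipped(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=30)
        resp = frame((x + rng.normal(size=30))[:, None], prefix="q")
        pred = pd.DataFrame({"x": x, "x2": 2 * x}, index=resp.index)
        with pytest.warns(UserWarning, match="collinear"):
            dl = ps.distlm_forward(
                ps.distance_matrix(resp, "euclidean"), pred, n_perm=19, seed=0
            )
        assert list(dl["predictor"]) == ["x"]

    def test_planted_driver_selected_first(self):
        rng = np.random.default_rng(9)
        coverage = np.repeat(np.linspace(10, 90, 6), 4)
        response = 60 - 0.5 * coverage + rng.normal(0, 2, size=24)
        noise = rng.normal(size=24)
        resp = frame(response[:, None], prefix="q")
        pred = pd.DataFrame({"coverage": coverage, "noise": noise}, index=resp.index)
        dl = ps.distlm_forward(
            ps.distance_matrix(resp, "euclidean-normalized"), pred, n_perm=199, seed=0
        )
        assert dl.loc[0, "predictor"] == "coverage"
        assert dl.loc[0, "marginal_r2"] > 0.5
        assert dl.loc[0, "p_perm"] <= 0.01


class TestEffectSizes:
    @pytest.mark.parametrize(
        "xb, xm, expect",
        [(5.0, 5.0, 0.0), (2.0, 4.0, np.log(0.5))],
    )
    def test_reference_ratios(self, xb, xm, expect):
        r, _ = ps.log_response_ratio(xb, xm)
        assert r == pytest.approx(expect)

    def test_published_minorca_abundance_contrast(self):
        # site means (57.7, 24.9) vs (182.7, 213.7) → ln(41.3/198.2) ≈ −1.57
        r, _ = ps.log_response_ratio((57.7 + 24.9) / 2, (182.7 + 213.7) / 2)
        assert r == pytest.approx(-1.568, abs=0.005)

    def test_nonpositive_mean_is_na(self):
        r, se = ps.log_response_ratio(0.0, 3.0)
        assert np.isnan(r) and np.isnan(se)

    def test_delta_method_se(self):
        _, se = ps.log_response_ratio(10.0, 20.0, 2.0, 4.0, 4, 4)
        expect = np.sqrt(4 / (4 * 100) + 16 / (4 * 400))
        assert se == pytest.approx(expect)

    def test_effect_table_cumulative_is_mean_of_areas(self):
        values = pd.DataFrame(
            {
                "area": ["A1"] * 4 + ["A2"] * 4,
                "state": ["Barren", "Barren", "Meadow", "Meadow"] * 2,
                "v": [2.0, 2.0, 4.0, 4.0, 1.0, 1.0, 4.0, 4.0],
            }
        )
        out = ps.effect_table(values, ["v"]).set_index("area")
        assert out.loc["all", "R"] == pytest.approx(
            (np.log(0.5) + np.log(0.25)) / 2
        )
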