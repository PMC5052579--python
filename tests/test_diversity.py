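"""Structural and functional diversity indices, with brute-force oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skbio.diversity import alpha as skbio_alpha

from meiostates import printed
from meiostates.diversity import (
    alpha_indices,
    diversity_profile,
    expected_species,
    genus_of,
    maturity_index,
    pooled_profile,
    trophic_diversity,
)


def brute_force_es(counts, n):
    """Exhaustive Hurlbert expectation: mean species count over every
    possible n-individual subsample (independent oracle, N ≤ 12)."""
    pool = [sp for sp, c in enumerate(counts) for _ in range(c)]
    subsets = itertools.combinations(range(len(pool)), n)
    values = [len({pool[i] for i in combo}) for combo in subsets]
    return sum(values) / len(values)


class TestAlphaIndices:
    def test_equal_abundances_maximise_evenness(self):
        out = alpha_indices([5, 5, 5, 5])
        assert out["H"] == pytest.approx(np.log(4))
        assert out["J"] == pytest.approx(1.0)

    def test_single_species_degenerate(self):
        out = alpha_indices([7])
        assert out["H"] == 0.0
        assert out["D"] == 0.0
        assert np.isnan(out["J"])

    def test_empty_vector_all_na(self):
        out = alpha_indices([0, 0])
        assert all(np.isnan(v) for v in out.values())

    def test_pielou_from_shannon_matches_printed_site(self):
        # H′ 2.7 with SR 34 → J = 2.7/ln 34 ≈ 0.77, printing as 0.8
        j = 2.7 / np.log(34)
        assert round(j, 1) == 0.8

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.integers(1, 50), min_size=2, max_size=15))
    def test_against_reference_implementations(self, counts):
        out = alpha_indices(counts)
        arr = np.array(counts)
        assert out["H"] == pytest.approx(skbio_alpha.shannon(arr, base=np.e))
        assert out["D"] == pytest.approx(skbio_alpha.margalef(arr))
        if out["SR"] > 1:
            assert out["J"] == pytest.approx(skbio_alpha.pielou_e(arr))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.permutations([3, 9, 1, 14, 6]))
    def test_label_permutation_invariance(self, counts):
        ref = alpha_indices([3, 9, 1, 14, 6])
        out = alpha_indices(counts)
        for key in ref:
            assert out[key] == pytest.approx(ref[key], rel=1e-12)


class TestExpectedSpecies:
    def test_closed_form_example(self):
        # counts (5,3,2), n=2: mean over all C(10,2)=45 pairs is 76/45
        assert expected_species([5, 3, 2], 2) == pytest.approx(76 / 45)

    @pytest.mark.parametrize(
        "counts, n, expect",
        [([5, 3, 2], 10, 3), ([4, 4], 1, 1), ([2, 1], 5, np.nan)],
    )
    def test_boundaries(self, counts, n, expect):
        got = expected_species(counts, n)
        if np.isnan(expect):
            assert np.isnan(got)
        else:
            assert got == pytest.approx(expect)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        counts=st.lists(st.integers(1, 4), min_size=1, max_size=5),
        n=st.integers(1, 12),
    )
    def test_matches_brute_force_enumeration(self, counts, n):
        total = sum(counts)
        if n > total:
            assert np.isnan(expected_species(counts, n))
        else:
            assert expected_species(counts, n) == pytest.approx(
                brute_force_es(counts, n)
            )

    def test_monotone_in_subsample_size(self):
        counts = [40, 12, 7, 3, 1, 1]
        values = [expected_species(counts, n) for n in range(1, sum(counts) + 1)]
        assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))

    def test_large_counts_numerically_stable(self):
        # factorial evaluation would overflow; log-gamma must not
        out = expected_species([10_000, 5_000, 10], 51)
        assert 2.0 < out <= 3.0


class TestPooling:
    def test_pooling_identical_vectors_preserves_structure(self):
        v = pd.DataFrame([[10, 5, 1], [10, 5, 1]], columns=list("abc"))
        single = alpha_indices(v.iloc[0])
        pooled = pooled_profile(v, es_levels=())
        assert pooled["SR"] == single["SR"]
        assert pooled["H"] == pytest.approx(single["H"])

    def test_disjoint_vectors_add_richness(self):
        v = pd.DataFrame([[3, 2, 0, 0], [0, 0, 4, 1]], columns=list("abcd"))
        assert pooled_profile(v, es_levels=())["SR"] == 4

    def test_point_vs_habitat_diversity_ordering(self, default_study, default_design):
        # site pooling of the identified replicates: ES22 ≤ ES51 ≤ SR
        nema = default_study.nematodes
        sub = default_design.loc[nema.index]
        for (_, _, _), grp in sub.groupby(["area", "state", "site"]):
            prof = pooled_profile(nema.loc[grp.index])
            if not np.isnan(prof["ES51"]):
                assert prof["ES22"] <= prof["ES51"] + 1e-12
                assert prof["ES51"] <= prof["SR"] + 1e-12


class TestFunctionalIndices:
    @pytest.mark.parametrize(
        "proportions, expect",
        [
            ((0.5, 0.3, 0.2, 0.0), 0.62),
            ((1.0, 0.0, 0.0, 0.0), 0.0),
            ((0.25, 0.25, 0.25, 0.25), 0.75),
        ],
    )
    def test_trophic_diversity_values(self, proportions, expect):
        counts = [100 * p for p in proportions]
        assert trophic_diversity(counts) == pytest.approx(expect)

    def test_all_zero_guilds_na(self):
        assert np.isnan(trophic_diversity([0, 0, 0, 0]))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 30), min_size=4, max_size=4))
    def test_lumping_guilds_never_raises_diversity(self, counts):
        # 1A+1B lumped to 3 groups: the 3-guild value never exceeds the
        # 4-guild value (why a printed 1-ITD can exceed what its lumped
        # percentage columns imply)
        if sum(counts) == 0:
            return
        four = trophic_diversity(counts)
        three = trophic_diversity([counts[0] + counts[1], counts[2], counts[3]])
        assert three <= four + 1e-12

    @pytest.mark.parametrize(
        "freqs, scores, expect",
        [
            ({"a": 1.0}, {"a": 2}, 2.0),
            ({"a": 0.5, "b": 0.5}, {"a": 2, "b": 4}, 3.0),
            ({"a": 0.25, "b": 0.75}, {"a": 1, "b": 3}, 2.5),
        ],
    )
    def test_maturity_index_weighted_mean(self, freqs, scores, expect):
        mi = maturity_index(pd.Series(freqs), pd.Series(scores, dtype=float))
        assert mi == pytest.approx(expect)

    def test_missing_cp_score_names_genus(self):
        with pytest.raises(KeyError, match="Enigma"):
            maturity_index(pd.Series({"Enigma": 1.0}), pd.Series(dtype=float))

    def test_genus_stripping(self):
        assert genus_of("Sabatieria_sp2") == "Sabatieria"
        assert genus_of("Daptonema punctatum") == "Daptonema"

    def test_profile_bounds_on_synthetic_assemblages(self, default_study):
        pooled = default_study.nematodes.sum(axis=0)
        prof = diversity_profile(pooled, default_study.traits)
        assert 0 <= prof["itd"] <= 0.75
        assert 1 <= prof["mi"] <= 5
        assert prof["J"] <= 1


class TestPrintedTableConsistency:
    def test_pielou_identity_within_combined_rounding(self):
        # J and H′ are printed at 1 d.p., so the recomputed J can differ
        # from the printed one by up to 0.05 + 0.05/ln SR
        t = printed.table1b()
        recomputed = t["shannon"] / np.log(t["sr"])
        bound = 0.05 + 0.05 / np.log(t["sr"])
        assert ((recomputed - t["pielou"]).abs() <= bound).all()
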