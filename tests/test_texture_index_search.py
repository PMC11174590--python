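import numpy as np
import pandas as pd
import pytest

from canopyhydra.texture_index_search import (
    FAMILY_NAMES,
    SingularPairError,
    best_index_columns,
    search_all,
    search_family,
    texture_index,
)

from oracles import brute_force_search


class TestTextureIndex:
    def test_ndti_of_identical_vectors_is_zero(self):
        t = np.array([1.0, 2.0, 3.0])
        np.testing.assert_allclose(texture_index("NDTI", t, t), 0.0)

    def test_rti_reciprocal_identity(self):
        assert texture_index("RTI", [4.0], [2.0])[0] == pytest.approx(2.0)
        prod = texture_index("RTI", [2.0], [4.0]) * texture_index("RTI", [4.0], [2.0])
        assert prod[0] == pytest.approx(1.0)

    def test_rdti_hand_value(self):
        assert texture_index("RDTI", [2.0], [4.0])[0] == pytest.approx(0.25)

    def test_rdti_equals_reversed_dti_over_product(self, rng):
        ti = rng.uniform(0.5, 3.0, size=30)
        tj = rng.uniform(0.5, 3.0, size=30)
        lhs = texture_index("RDTI", ti, tj)
        rhs = texture_index("DTI", tj, ti) / (ti * tj)
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    @pytest.mark.parametrize(
        "family,ti,tj",
        [
            ("RTI", [1.0, 2.0], [1.0, 0.0]),
            ("RDTI", [1.0, 0.0], [1.0, 2.0]),
            ("RATI", [1.0, 2.0], [2.0, 0.0]),
            ("NDTI", [1.0, -2.0], [1.0, 2.0]),
        ],
    )
    def test_singularities_identify_sample(self, family, ti, tj):
        with pytest.raises(SingularPairError, match="sample index 1"):
            texture_index(family, ti, tj)

    def test_unknown_family(self):
        with pytest.raises(KeyError):
            texture_index("XTI", [1.0], [1.0])


def _toy_table(rng, n=20, m=6):
    return pd.DataFrame(
        rng.uniform(0.5, 2.5, size=(n, m)), columns=[f"f{k}" for k in range(m)]
    )


class TestSearchFamily:
    def test_perfect_linear_feature_found_with_dti(self, rng):
        table = _toy_table(rng)
        table["f1"] = np.full(len(table), 1.7)  # constant partner
        y = 2.0 * table["f0"].to_numpy() + 5.0
        hit, matrix = search_family("DTI", table, y)
        assert "f0" in (hit.feature_i, hit.feature_j)
        assert abs(hit.r) == pytest.approx(1.0)
        assert hit.p == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("family", FAMILY_NAMES)
    def test_matches_brute_force_oracle(self, rng, family):
        table = _toy_table(rng)
        y = rng.normal(70, 2, size=len(table))
        hit, matrix = search_family(family, table, y)
        oi, oj, orr, omat = brute_force_search(family, table, y)
        assert (hit.feature_i, hit.feature_j) == (oi, oj)
        assert hit.r == pytest.approx(orr, abs=1e-12)
        np.testing.assert_allclose(matrix.to_numpy(), omat, atol=1e-12)

    def test_best_dominates_matrix(self, rng):
        table = _toy_table(rng)
        y = rng.normal(70, 2, size=len(table))
        hit, matrix = search_family("NDTI", table, y)
        assert abs(hit.r) >= np.nanmax(np.abs(matrix.to_numpy())) - 1e-15

    def test_antisymmetry_and_symmetry_of_matrices(self, rng):
        table = _toy_table(rng)
        y = rng.normal(70, 2, size=len(table))
        for family in ("NDTI", "DTI"):
            M = search_family(family, table, y)[1].to_numpy()
            np.testing.assert_allclose(M, -M.T, atol=1e-12)
        for family in ("ATI", "RATI"):
            M = search_family(family, table, y)[1].to_numpy()
            np.testing.assert_allclose(M, M.T, atol=1e-12)

    def test_singular_pairs_skipped_and_counted(self, rng):
        table = _toy_table(rng)
        table["f2"] = 0.0  # poisons every reciprocal pair involving f2
        y = rng.normal(70, 2, size=len(table))
        hit, matrix = search_family("RDTI", table, y)
        assert hit.n_singular_pairs == 10  # ordered pairs touching f2, minus diagonal
        assert "f2" not in (hit.feature_i, hit.feature_j)
        assert matrix.loc["f2"].isna().all()

    def test_all_singular_raises(self):
        table = pd.DataFrame({"a": [0.0, 0.0, 0.0], "b": [0.0, 0.0, 0.0]})
        with pytest.raises(SingularPairError, match="every feature pair"):
            search_family("RTI", table, np.array([1.0, 2.0, 3.0]))

    def test_diagonal_excluded(self, rng):
        table = _toy_table(rng)
        y = rng.normal(70, 2, size=len(table))
        M = search_family("ATI", table, y)[1].to_numpy()
        assert np.isnan(np.diag(M)).all()

    def test_requires_min_samples(self, rng):
        table = _toy_table(rng, n=2)
        with pytest.raises(ValueError, match="3 samples"):
            search_family("DTI", table, np.array([1.0, 2.0]))


class TestSearchAll:
    def test_one_hit_per_family(self, rng):
        table = _toy_table(rng)
        y = rng.normal(70, 2, size=len(table))
        hits, matrices = search_all(table, y)
        assert set(hits) == set(FAMILY_NAMES)
        assert all(m.shape == (6, 6) for m in matrices.values())

    def test_planted_pair_recovered(self):
        from canopyhydra.synthetic_scene import planted_texture_table

        table, moisture = planted_texture_table(
            pair=("Variance1", "Correlation5"), family="RDTI", seed=11
        )
        hit, _ = search_family("RDTI", table, moisture)
        assert {hit.feature_i, hit.feature_j} == {"Variance1", "Correlation5"}

    def test_permutation_p_small_for_planted_signal(self):
        from canopyhydra.synthetic_scene import planted_texture_table

        table, moisture = planted_texture_table(seed=3)
        hit, _ = search_family(
            "RDTI", table.iloc[:, :12], moisture, n_permutations=99, seed=0
        )
        assert hit.p_permutation is not None
        assert hit.p_permutation <= 0.05

    def test_permutation_p_large_under_null(self, rng):
        table = _toy_table(rng, n=30)
        y = rng.normal(70, 2, size=30)
        hit, _ = search_family("ATI", table, y, n_permutations=99, seed=0)
        assert hit.p_permutation > 0.05  # naive p may be small; adjusted one is honest


class TestBestIndexColumns:
    def test_columns_match_hits(self, rng):
        table = _toy_table(rng)
        y = rng.normal(70, 2, size=len(table))
        hits, _ = search_all(table, y)
        cols = best_index_columns(hits, table)
        assert list(cols.columns) == list(FAMILY_NAMES)
        fam = "DTI"
        expected = table[hits[fam].feature_i] - table[hits[fam].feature_j]
        np.testing.assert_allclose(cols[fam], expected)
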