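"""Identity scoring: binary dissimilarity, PCoA, Fisher enrichment, BH, Pearson."""
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.spatial.distance import jaccard as scipy_jaccard
from scipy.spatial.distance import pdist, squareform

from microlens import (
    BinaryMatrix,
    MarkerCompendium,
    bh_adjust,
    binary_dissimilarity,
    discretise_top_k,
    dissimilarity_matrix,
    fisher_enrichment,
    fisher_pvalue,
    pcoa,
    query_marker_set,
    rank_by_proximity,
    replicate_correlation,
    score_query,
    simulate_query,
)
from microlens.errors import DegenerateInputError, IncompatibilityError, ValidationError


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def abc_dissimilarity(x, y) -> float:
    """Enumerate a/b/c positions one by one."""
    a = b = c = 0
    for xi, yi in zip(x, y):
        if xi and yi:
            a += 1
        elif xi:
            b += 1
        elif yi:
            c += 1
    return (b + c) / (a + b + c)


def hypergeom_tail(a: int, b: int, c: int, d: int) -> float:
    """Sum of hypergeometric point probabilities for overlap >= a."""
    n_universe, k_tissue, n_query = a + b + c + d, a + c, a + b
    total = comb(n_universe, n_query)
    return sum(
        comb(k_tissue, i) * comb(n_universe - k_tissue, n_query - i)
        for i in range(a, min(k_tissue, n_query) + 1)
    ) / total


def bh_stepup_brute(p):
    """Literal step-up: walk ranks from largest to smallest, carrying the min."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank, 1.0)
        q[i] = running
    return q


def binary_vectors(min_size=4, max_size=60):
    return st.lists(st.booleans(), min_size=min_size, max_size=max_size)


# ---------------------------------------------------------------------------
# binary dissimilarity
# ---------------------------------------------------------------------------

class TestBinaryDissimilarity:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ([1, 1, 0, 0], [1, 0, 1, 0], 2 / 3),
            ([1, 0, 1], [1, 0, 1], 0.0),
            ([1, 1, 0, 0], [0, 0, 1, 1], 1.0),
            ([1, 0, 0, 0], [1, 1, 0, 0], 0.5),
        ],
    )
    def test_hand_cases(self, x, y, expected):
        assert binary_dissimilarity(np.array(x), np.array(y)) == pytest.approx(expected)

    def test_joint_absences_ignored(self):
        base = binary_dissimilarity(np.array([1, 0, 1]), np.array([1, 1, 0]))
        padded = binary_dissimilarity(np.array([1, 0, 1, 0, 0]), np.array([1, 1, 0, 0, 0]))
        assert base == padded

    def test_all_zero_pair_rejected(self):
        with pytest.raises(DegenerateInputError):
            binary_dissimilarity(np.zeros(4), np.zeros(4))

    @given(binary_vectors(), st.data())
    def test_matches_enumeration_and_scipy(self, x, data):
        y = data.draw(st.lists(st.booleans(), min_size=len(x), max_size=len(x)))
        xv, yv = np.array(x), np.array(y)
        if not (xv | yv).any():
            xv[0] = True
        d = binary_dissimilarity(xv, yv)
        assert d == pytest.approx(abc_dissimilarity(xv, yv), abs=1e-15)
        assert d == pytest.approx(float(scipy_jaccard(xv, yv)), abs=1e-12)
        assert 0.0 <= d <= 1.0


class TestDissimilarityMatrix:
    def test_symmetric_zero_diagonal_and_matches_scalar_op(self, rng):
        bits_arr = rng.integers(0, 2, size=(30, 4)).astype(np.int8)
        bits_arr[0] = 1  # no all-zero column
        genes = [f"g{i:02d}" for i in range(30)]
        frame = pd.DataFrame(bits_arr, index=genes, columns=list("abcd"))
        bits = BinaryMatrix(frame, k_used=frame.sum(axis=0))
        d = dissimilarity_matrix(bits, frozenset(genes))
        assert (d.to_numpy() == d.to_numpy().T).all()
        assert (np.diag(d.to_numpy()) == 0).all()
        for i, si in enumerate("abcd"):
            for j, sj in enumerate("abcd"):
                if i < j:
                    expected = binary_dissimilarity(bits_arr[:, i], bits_arr[:, j])
                    assert d.iloc[i, j] == pytest.approx(expected)

    def test_identical_columns_have_zero_distance(self):
        frame = pd.DataFrame({"a": [1, 0, 1], "b": [1, 0, 1]}, index=list("xyz"), dtype=np.int8)
        bits = BinaryMatrix(frame, k_used=frame.sum(axis=0))
        d = dissimilarity_matrix(bits, frozenset("xyz"))
        assert d.loc["a", "b"] == 0.0

    def test_restricts_to_retained_genes(self):
        frame = pd.DataFrame({"a": [1, 1, 0], "b": [1, 0, 1]}, index=list("xyz"), dtype=np.int8)
        bits = BinaryMatrix(frame, k_used=frame.sum(axis=0))
        full = dissimilarity_matrix(bits, frozenset("xyz"))
        only_x = dissimilarity_matrix(bits, frozenset("x"))
        assert full.loc["a", "b"] == pytest.approx(2 / 3)
        assert only_x.loc["a", "b"] == 0.0


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------

class TestPcoa:
    def test_all_identical_points(self):
        d = pd.DataFrame(np.zeros((4, 4)), index=list("abcd"), columns=list("abcd"))
        res = pcoa(d)
        assert res.coordinates.shape[1] == 0
        np.testing.assert_allclose(res.eigenvalues, 0.0, atol=1e-12)

    def test_three_collinear_points(self):
        d = pd.DataFrame(
            [[0, 1, 2], [1, 0, 1], [2, 1, 0]], index=list("abc"), columns=list("abc"), dtype=float
        )
        res = pcoa(d)
        positive = res.eigenvalues[res.eigenvalues > 1e-10]
        np.testing.assert_allclose(positive, [2.0], atol=1e-10)
        coords = np.sort(res.coordinates.iloc[:, 0].to_numpy())
        np.testing.assert_allclose(coords, [-1.0, 0.0, 1.0], atol=1e-10)

    def test_equilateral_triangle(self):
        d = pd.DataFrame(1.0 - np.eye(3), index=list("abc"), columns=list("abc"))
        res = pcoa(d)
        positive = res.eigenvalues[res.eigenvalues > 1e-10]
        np.testing.assert_allclose(sorted(positive), [0.5, 0.5], atol=1e-10)

    def test_round_trip_of_planted_euclidean_configs(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 21))
            points = rng.normal(size=(n, 2))
            d_in = squareform(pdist(points))
            labels = [f"p{i}" for i in range(n)]
            res = pcoa(pd.DataFrame(d_in, index=labels, columns=labels))
            d_out = squareform(pdist(res.coordinates.to_numpy()))
            np.testing.assert_allclose(d_out, d_in, atol=1e-8)

    def test_matches_scikit_bio(self, rng):
        skbio_ordination = pytest.importorskip("skbio.stats.ordination")
        from skbio import DistanceMatrix

        points = rng.normal(size=(8, 3))
        d = squareform(pdist(points))
        labels = [f"p{i}" for i in range(8)]
        ours = pcoa(pd.DataFrame(d, index=labels, columns=labels))
        ref = skbio_ordination.pcoa(DistanceMatrix(d, ids=labels))
        ref_eigvals = np.sort(ref.eigvals.to_numpy())[::-1]
        n_pos = (ours.eigenvalues > 1e-10).sum()
        np.testing.assert_allclose(
            ours.eigenvalues[:n_pos], ref_eigvals[:n_pos], atol=1e-8
        )
        d_ref = squareform(pdist(ref.samples.to_numpy()[:, :n_pos]))
        d_ours = squareform(pdist(ours.coordinates.to_numpy()))
        np.testing.assert_allclose(d_ours, d_ref, atol=1e-8)

    def test_rejects_asymmetric_input(self):
        d = pd.DataFrame([[0.0, 1.0], [0.5, 0.0]], index=list("ab"), columns=list("ab"))
        with pytest.raises(ValidationError):
            pcoa(d)


class TestRankByProximity:
    def test_coincident_tissue_ranks_first_with_zero_distance(self, rng):
        points = rng.normal(size=(5, 2))
        points[2] = points[0]  # tissue "t2" coincides with query "q"
        labels = ["q", "t1", "t2", "t3", "t4"]
        d = squareform(pdist(points))
        res = pcoa(pd.DataFrame(d, index=labels, columns=labels))
        ranked = rank_by_proximity(res, "q")
        assert ranked.index[0] == "t2"
        assert ranked.iloc[0] == pytest.approx(0.0, abs=1e-8)

    def test_order_matches_brute_force(self, rng):
        for _ in range(10):
            n = int(rng.integers(4, 12))
            points = rng.normal(size=(n, 2))
            labels = [f"t{i}" for i in range(n)]
            d = squareform(pdist(points))
            res = pcoa(pd.DataFrame(d, index=labels, columns=labels))
            ranked = rank_by_proximity(res, "t0")
            coords = res.coordinates
            brute = sorted(
                (float(np.linalg.norm(coords.loc[l] - coords.loc["t0"])), l)
                for l in labels if l != "t0"
            )
            assert list(ranked.index) == [l for _, l in brute]

    def test_unknown_label_rejected(self, rng):
        points = rng.normal(size=(4, 2))
        labels = list("abcd")
        res = pcoa(pd.DataFrame(squareform(pdist(points)), index=labels, columns=labels))
        with pytest.raises(KeyError):
            rank_by_proximity(res, "zz")


# ---------------------------------------------------------------------------
# Fisher + BH
# ---------------------------------------------------------------------------

class TestFisher:
    @pytest.mark.parametrize(
        "table, expected",
        [
            ((5, 0, 0, 5), 1 / 252),   # perfect 5-gene overlap in a 10-gene universe
            ((2, 0, 1, 7), 1 / 15),    # query {g1,g2} vs tissue {g1,g2,g3}
        ],
    )
    def test_hand_cases(self, table, expected):
        assert fisher_pvalue(*table) == pytest.approx(expected, abs=1e-12)

    def test_disjoint_sets_give_p_one(self):
        assert fisher_pvalue(0, 5, 5, 90) == pytest.approx(1.0, abs=1e-12)

    def test_matches_brute_force_over_all_small_margins(self):
        for n_universe in (8, 15, 30):
            for k_tissue in range(0, n_universe + 1, max(1, n_universe // 5)):
                for n_query in range(0, n_universe + 1, max(1, n_universe // 5)):
                    for a in range(max(0, k_tissue + n_query - n_universe), min(k_tissue, n_query) + 1):
                        b, c = n_query - a, k_tissue - a
                        d = n_universe - a - b - c
                        assert fisher_pvalue(a, b, c, d) == pytest.approx(
                            hypergeom_tail(a, b, c, d), abs=1e-12
                        )


class TestBhAdjust:
    def test_hand_case(self):
        np.testing.assert_allclose(
            bh_adjust([0.005, 0.01, 0.03]), [0.015, 0.015, 0.03], atol=1e-15
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=50))
    def test_matches_brute_force_and_bounds(self, p):
        ours = bh_adjust(p)
        np.testing.assert_allclose(ours, bh_stepup_brute(p), atol=1e-12)
        assert (ours >= np.asarray(p) / len(p) - 1e-15).all()
        assert ((0 <= ours) & (ours <= 1)).all()

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(20):
            p = rng.uniform(size=int(rng.integers(1, 40)))
            ref = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(bh_adjust(p), ref, atol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])


class TestEnrichment:
    def _compendium(self):
        universe = frozenset(f"g{i}" for i in range(10))
        sets = {"lens": frozenset(["g0", "g1", "g2", "g3", "g4"]),
                "liver": frozenset(["g5", "g6", "g7", "g8", "g9"])}
        return MarkerCompendium(marker_sets=sets, gene_universe=universe,
                                top_m=5, spec_frac=0.5, top_lists=dict(sets))

    def test_counts_sum_to_universe_and_ranks(self):
        mc = self._compendium()
        table = fisher_enrichment(frozenset(["g0", "g1", "g2", "g3", "g4"]), mc)
        assert ((table[["a", "b", "c", "d"]].sum(axis=1)) == 10).all()
        assert table.index[0] == "lens"
        assert table.loc["lens", "p_value"] == pytest.approx(1 / 252, abs=1e-12)
        assert table.loc["lens", "rank"] == 1

    def test_fdr_applied_across_tissues(self):
        mc = self._compendium()
        table = fisher_enrichment(frozenset(["g0", "g1"]), mc)
        np.testing.assert_allclose(
            np.sort(table["fdr"]), np.sort(bh_adjust(table["p_value"].to_numpy()))
        )

    def test_empty_query_rejected(self):
        with pytest.raises(DegenerateInputError):
            fisher_enrichment(frozenset(), self._compendium())

    def test_permutation_equivariance(self, small_noisy_sim):
        """Relabelling tissues permutes the enrichment table identically."""
        sim = small_noisy_sim
        query = simulate_query(sim.expected, "tissue3", noise_sd=0.5, seed=9)
        score = score_query(sim.matrix, query, k=50, top_m=80, spec_frac=0.2)
        relabel = {t: f"x_{t}" for t in sim.matrix.samples}
        renamed = sim.matrix.data.rename(columns=relabel)
        from microlens import ExpressionMatrix

        score2 = score_query(ExpressionMatrix(renamed), query, k=50, top_m=80, spec_frac=0.2)
        t1 = score.enrichment.rename(index=relabel)
        t2 = score2.enrichment
        pd.testing.assert_frame_equal(t1.sort_index(), t2.sort_index())


class TestQueryMarkerSet:
    def test_query_identical_to_tissue_recovers_its_markers(self, noiseless_sim):
        from microlens import build_marker_sets

        mc = build_marker_sets(noiseless_sim.matrix, top_m=50, spec_frac=0.1)
        profile = noiseless_sim.matrix.data["tissue01"]
        assert query_marker_set(profile, mc) == mc.marker_sets["tissue01"]

    def test_unharmonised_universe_rejected(self, noiseless_sim):
        from microlens import build_marker_sets

        mc = build_marker_sets(noiseless_sim.matrix, top_m=50, spec_frac=0.1)
        profile = noiseless_sim.matrix.data["tissue01"].iloc[:-5]
        with pytest.raises(IncompatibilityError):
            query_marker_set(profile, mc)


class TestReplicateCorrelation:
    def test_identical_columns(self):
        s = pd.Series([1.0, 5.0, 9.0], index=list("abc"))
        assert replicate_correlation(s, s) == pytest.approx(1.0)

    def test_affine_invariance_without_log(self):
        s = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        assert replicate_correlation(s, 2 * s, log_transform=False) == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        a = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        b = pd.Series([3.0, 2.0, 1.0], index=list("abc"))
        assert replicate_correlation(a, b, log_transform=False) == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        a = pd.Series([2.0, 2.0, 2.0], index=list("abc"))
        b = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        with pytest.raises(DegenerateInputError):
            replicate_correlation(a, b)
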