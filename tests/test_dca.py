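"""Reweighting, frequencies, MI, mean-field couplings, and DI."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pairdca import AlignmentMatrix
from pairdca.alphabet import Q
from pairdca.dca import (
    FrequencyModel,
    PairScoreTable,
    compute_sequence_weights,
    direct_information,
    estimate_frequencies,
    infer_mean_field_couplings,
    mutual_information,
    run_dca,
)
from pairdca.exceptions import NumericalError, ParameterError


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def brute_force_weights(matrix, theta):
    """O(M^2 L) pairwise-identity reweighting, straight from the definition."""
    m, l = matrix.shape
    w = np.empty(m)
    for a in range(m):
        neighbours = 0
        for b in range(m):
            if (matrix[a] == matrix[b]).sum() / l >= 1.0 - theta:
                neighbours += 1
        w[a] = 1.0 / neighbours
    return w


def brute_force_mi(fij, fi, fj):
    """Direct double sum over the q x q joint table."""
    s = 0.0
    for a in range(Q):
        for b in range(Q):
            if fij[a, b] > 0:
                s += fij[a, b] * np.log(fij[a, b] / (fi[a] * fj[b]))
    return s


def two_site_model(rng, coupling_scale):
    """Analytic frequencies of an exactly known two-column joint."""
    pa = rng.dirichlet(np.ones(Q))
    pb = rng.dirichlet(np.ones(Q))
    k = rng.standard_normal((Q, Q)) * coupling_scale
    joint = np.outer(pa, pb) * np.exp(k)
    joint /= joint.sum()
    fi = np.stack([joint.sum(axis=1), joint.sum(axis=0)])
    fij = np.empty((2, 2, Q, Q))
    fij[0, 0] = np.diag(fi[0])
    fij[1, 1] = np.diag(fi[1])
    fij[0, 1] = joint
    fij[1, 0] = joint.T
    return FrequencyModel(q=Q, lam=0.0, m_eff=1.0, fi=fi, fij=fij), joint


# ---------------------------------------------------------------------------
# Sequence reweighting
# ---------------------------------------------------------------------------

class TestSequenceWeights:
    def test_identical_rows_collapse(self):
        aln = AlignmentMatrix.from_strings(["MKVH"] * 5, [f"s{i}" for i in range(5)])
        wv = compute_sequence_weights(aln, theta=0.2)
        assert np.allclose(wv.w, 0.2)
        assert wv.m_eff == pytest.approx(1.0)

    def test_dissimilar_rows_keep_full_weight(self):
        aln = AlignmentMatrix.from_strings(
            ["MKVHA", "WCDEF", "GHILN"], ["a", "b", "c"]
        )
        wv = compute_sequence_weights(aln, theta=0.2)
        assert np.all(wv.w == 1.0)
        assert wv.m_eff == pytest.approx(3.0)

    def test_matches_brute_force_exactly(self, make_random_alignment):
        # low-cardinality alphabet so similar pairs actually occur
        aln = make_random_alignment(100, 30)
        aln.matrix %= 3
        wv = compute_sequence_weights(aln, theta=0.2)
        expected = brute_force_weights(aln.matrix, 0.2)
        assert np.array_equal(wv.w, expected)

    def test_theta_out_of_range(self, make_random_alignment):
        aln = make_random_alignment(3, 4)
        with pytest.raises(ParameterError):
            compute_sequence_weights(aln, theta=1.0)


# ---------------------------------------------------------------------------
# Frequencies
# ---------------------------------------------------------------------------

class TestFrequencies:
    def test_conserved_column_no_pseudocount(self):
        aln = AlignmentMatrix.from_strings(["K", "K", "K"], ["a", "b", "c"])
        f = estimate_frequencies(aln, lam=0.0)
        k_code = "-ACDEFGHIKLMNPQRSTVWY".index("K")
        assert f.fi[0, k_code] == pytest.approx(1.0)
        assert f.fi[0].sum() == pytest.approx(1.0)
        assert np.count_nonzero(f.fi[0]) == 1

    def test_pseudocount_dominated_limit(self, make_random_alignment):
        aln = make_random_alignment(10, 4)
        f = estimate_frequencies(aln, lam=1e12)
        assert np.allclose(f.fi, 1.0 / Q, atol=1e-9)
        off_diag = [(i, j) for i in range(4) for j in range(4) if i != j]
        for i, j in off_diag:
            assert np.allclose(f.fij[i, j], 1.0 / Q**2, atol=1e-9)
        # diagonal blocks keep their pseudocount on the a == b cells only
        assert np.allclose(f.fij[0, 0], np.eye(Q) / Q, atol=1e-9)

    def test_unweighted_empirical_counts(self, make_random_alignment):
        aln = make_random_alignment(50, 6)
        f = estimate_frequencies(aln, lam=0.0)
        for i in range(6):
            counts = np.bincount(aln.matrix[:, i], minlength=Q) / 50
            assert np.allclose(f.fi[i], counts, atol=1e-12)
        # one pair by explicit 2-D histogram
        hist = np.zeros((Q, Q))
        for row in aln.matrix:
            hist[row[1], row[4]] += 1
        assert np.allclose(f.fij[1, 4], hist / 50, atol=1e-12)

    @given(seed=st.integers(0, 10_000), lam_ratio=st.floats(0.1, 3.0))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_conservation_invariants(self, seed, lam_ratio):
        rng = np.random.default_rng(seed)
        mat = rng.integers(0, Q, size=(20, 5), dtype=np.uint8)
        aln = AlignmentMatrix(mat, [f"s{i}" for i in range(20)])
        wv = compute_sequence_weights(aln)
        f = estimate_frequencies(aln, wv, lam=lam_ratio * wv.m_eff)
        assert np.allclose(f.fi.sum(axis=1), 1.0, atol=1e-12)
        assert np.allclose(f.fij.sum(axis=(2, 3)), 1.0, atol=1e-12)
        # marginalisation consistency, all pairs including the diagonal
        marg = f.fij.sum(axis=3)
        assert np.allclose(marg, np.broadcast_to(f.fi[:, None, :], marg.shape), atol=1e-12)
        assert (f.fi > 0).all()
        # off-diagonal pair tables are strictly positive under a pseudocount
        for i in range(5):
            for j in range(5):
                if i != j:
                    assert (f.fij[i, j] > 0).all()


# ---------------------------------------------------------------------------
# Mutual information
# ---------------------------------------------------------------------------

class TestMutualInformation:
    def test_independent_columns_zero(self, rng):
        f, _ = two_site_model(rng, coupling_scale=0.0)
        mi = mutual_information(f)
        assert mi[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_perfectly_correlated_binary(self):
        aln = AlignmentMatrix.from_strings(["AC", "AC", "KH", "KH"], list("abcd"))
        mi = mutual_information(estimate_frequencies(aln, lam=0.0))
        assert mi[0, 1] == pytest.approx(np.log(2), abs=1e-12)

    def test_matches_brute_force(self, make_random_alignment):
        aln = make_random_alignment(60, 8)
        f = estimate_frequencies(aln, lam=0.0)
        mi = mutual_information(f)
        for i in range(8):
            for j in range(i + 1, 8):
                expected = brute_force_mi(f.fij[i, j], f.fi[i], f.fi[j])
                assert mi[i, j] == pytest.approx(expected, abs=1e-12)


# ---------------------------------------------------------------------------
# Mean-field couplings and direct information
# ---------------------------------------------------------------------------

class TestCouplings:
    def test_independent_columns_couplings_shrink(self):
        norms = []
        for m in (300, 3000):
            rng = np.random.default_rng(7)
            mat = rng.integers(0, Q, size=(m, 6), dtype=np.uint8)
            aln = AlignmentMatrix(mat, [f"s{i}" for i in range(m)])
            wv = compute_sequence_weights(aln)
            f = estimate_frequencies(aln, wv, lam=wv.m_eff)
            coup = infer_mean_field_couplings(f)
            norms.append(np.linalg.norm(coup.couplings(0, 3)))
        assert norms[1] < norms[0]

    def test_coupling_symmetry(self, make_random_alignment):
        aln = make_random_alignment(40, 5)
        wv = compute_sequence_weights(aln)
        f = estimate_frequencies(aln, wv, lam=wv.m_eff)
        coup = infer_mean_field_couplings(f)
        for i in range(5):
            for j in range(5):
                if i != j:
                    assert np.array_equal(coup.couplings(i, j), coup.couplings(j, i).T)

    def test_singular_correlation_matrix(self):
        # two perfectly duplicated columns, no pseudocount -> C not invertible
        rng = np.random.default_rng(2)
        col = rng.integers(0, Q, size=30, dtype=np.uint8)
        aln = AlignmentMatrix(np.stack([col, col], axis=1), [f"s{i}" for i in range(30)])
        f = estimate_frequencies(aln, lam=0.0)
        with pytest.raises(NumericalError):
            infer_mean_field_couplings(f)


class TestDirectInformation:
    def test_zero_coupling_gives_zero_di(self, rng):
        f, _ = two_site_model(rng, coupling_scale=0.0)
        coup = infer_mean_field_couplings(f)
        di = direct_information(coup, f)
        assert di[0, 1] == pytest.approx(0.0, abs=1e-6)

    def test_two_site_weak_coupling_recovers_mi(self, rng):
        """For an isolated weakly coupled pair the direct model reproduces
        the generating joint, so DI approaches its MI."""
        f, joint = two_site_model(rng, coupling_scale=0.15)
        mi_true = brute_force_mi(joint, joint.sum(axis=1), joint.sum(axis=0))
        coup = infer_mean_field_couplings(f)
        di = direct_information(coup, f)
        # mean-field inversion is exact to first order in the coupling, so
        # a second-order discrepancy of a few percent is the expectation
        assert di[0, 1] == pytest.approx(mi_true, rel=0.10)

    def test_symmetry(self, make_random_alignment):
        aln = make_random_alignment(50, 6)
        wv = compute_sequence_weights(aln)
        f = estimate_frequencies(aln, wv, lam=wv.m_eff)
        coup = infer_mean_field_couplings(f)
        di = direct_information(coup, f)
        assert np.array_equal(di, di.T)
        assert (di > -1e-9).all()


# ---------------------------------------------------------------------------
# The composed chain
# ---------------------------------------------------------------------------

class TestRunDca:
    def test_pair_count_small(self, make_random_alignment):
        table = run_dca(make_random_alignment(30, 10))
        assert len(table) == 45

    def test_output_sorted_and_unique(self, make_random_alignment):
        table = run_dca(make_random_alignment(30, 10))
        f = table.frame
        assert (f["i"] < f["j"]).all()
        pairs = list(zip(f["i"], f["j"]))
        assert pairs == sorted(pairs)
        assert len(set(pairs)) == len(pairs)
        assert list(f.columns) == ["i", "j", "mi", "di"]

    def test_excluded_columns_keep_original_indices(self, make_random_alignment):
        aln = make_random_alignment(30, 8)
        table = run_dca(aln, exclude_columns=[3, 4])
        seen = set(table.frame["i"]) | set(table.frame["j"])
        assert seen == {1, 2, 5, 6, 7, 8}
        assert len(table) == 6 * 5 // 2

    def test_duplicating_rows_is_invariant(self, make_random_alignment):
        """5-fold duplication leaves M_eff, MI and DI essentially unchanged."""
        aln = make_random_alignment(40, 8)
        dup = AlignmentMatrix(
            np.repeat(aln.matrix, 5, axis=0),
            [f"{rid}.{k}" for rid in aln.row_ids for k in range(5)],
        )
        w1 = compute_sequence_weights(aln)
        w5 = compute_sequence_weights(dup)
        assert w5.m_eff == pytest.approx(w1.m_eff, abs=1e-9)
        t1 = run_dca(aln).frame
        t5 = run_dca(dup).frame
        assert np.abs(t1["mi"].values - t5["mi"].values).max() < 1e-9
        assert np.abs(t1["di"].values - t5["di"].values).max() < 1e-9

    def test_null_di_shrinks_with_alignment_depth(self):
        """On iid columns the largest DI is finite-sample noise and must
        decrease as the alignment deepens."""
        max_di = {}
        for m in (200, 2000):
            rng = np.random.default_rng(31)
            mat = rng.integers(0, Q, size=(m, 12), dtype=np.uint8)
            aln = AlignmentMatrix(mat, [f"s{i}" for i in range(m)])
            max_di[m] = run_dca(aln).frame["di"].max()
        assert max_di[2000] < max_di[200]


class TestPairScoreTableIO:
    def test_round_trip(self, tmp_path, make_random_alignment):
        table = run_dca(make_random_alignment(20, 6))
        path = tmp_path / "pairs.txt"
        table.write_text(path)
        back = PairScoreTable.read_text(path)
        assert np.allclose(back.frame.values, table.frame.values)
        # four whitespace-separated columns, N(N-1)/2 rows
        lines = path.read_text().splitlines()
        assert len(lines) == 15
        assert all(len(ln.split()) == 4 for ln in lines)
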