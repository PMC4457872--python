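"""Pseudo-likelihood objective, gauge, scoring, and ranking."""

import math

import numpy as np
import pytest

from dcapipe.msa import Alignment, SequenceWeights
from dcapipe.potts import (
    CouplingScoreMatrix,
    FitError,
    PottsModel,
    apc,
    eligible_pairs,
    fit_plm,
    frobenius_scores,
    neg_log_pseudolikelihood,
    rank_predictions,
    read_predictions,
    write_predictions,
    zero_sum_gauge,
)
from conftest import random_alignment


def conditional_nll_oracle(model, rows, w):
    """Independent oracle: explicit per-site conditional enumeration."""
    L, q = model.L, model.q
    total = 0.0
    for m, row in enumerate(rows):
        for i in range(L):
            logits = np.array(
                [
                    model.h[i, a]
                    + sum(model.J[i, j, a, row[j]] for j in range(L) if j != i)
                    for a in range(q)
                ]
            )
            logz = np.log(np.exp(logits - logits.max()).sum()) + logits.max()
            total -= w[m] * (logits[row[i]] - logz)
    return total


def random_symmetric_model(rng, L, q=21, scale=0.1):
    J = scale * rng.standard_normal((L, L, q, q))
    J = 0.5 * (J + np.transpose(J, (1, 0, 3, 2)))
    J[np.arange(L), np.arange(L)] = 0.0
    return PottsModel(h=scale * rng.standard_normal((L, q)), J=J)


class TestObjective:
    def test_zero_model_gives_uniform_conditionals(self, rng):
        aln = random_alignment(rng, M=9, L=7)
        w = SequenceWeights.uniform(aln.M)
        obj, _ = neg_log_pseudolikelihood(PottsModel.zeros(aln.L), aln, w)
        assert obj == pytest.approx(aln.M * aln.L * math.log(21), rel=1e-12)

    def test_matches_enumeration_on_two_state_model(self, rng):
        # L = 2, q = 2 instance small enough to enumerate by hand
        h = np.array([[0.3, -0.2], [0.1, 0.4]])
        J = np.zeros((2, 2, 2, 2))
        block = np.array([[0.5, -0.1], [0.2, 0.05]])
        J[0, 1] = block
        J[1, 0] = block.T
        model = PottsModel(h=h, J=J, lambda_h=0.0, lambda_J=0.0)
        rows = np.array([[1, 0]], dtype=np.int8)
        aln = Alignment(ids=["s"], rows=rows)
        w = SequenceWeights.uniform(1)
        obj, _ = neg_log_pseudolikelihood(model, aln, w)
        assert obj == pytest.approx(conditional_nll_oracle(model, rows, w.w), rel=1e-12)

    def test_matches_enumeration_on_random_instance(self, rng):
        aln = random_alignment(rng, M=4, L=3)
        model = random_symmetric_model(rng, 3, scale=0.3)
        w = SequenceWeights(rng.uniform(0.5, 2.0, 4))
        obj, _ = neg_log_pseudolikelihood(model, aln, w)
        expected = conditional_nll_oracle(model, aln.rows, w.w)
        expected += model.lambda_h * np.sum(model.h**2)
        iu = np.triu_indices(3, 1)
        expected += model.lambda_J * sum(
            np.sum(model.J[i, j] ** 2) for i, j in zip(*iu)
        )
        assert obj == pytest.approx(expected, rel=1e-12)

    def test_gradient_matches_central_finite_differences(self, rng):
        aln = random_alignment(rng, M=8, L=5)
        model = random_symmetric_model(rng, 5, scale=0.2)
        w = SequenceWeights(rng.uniform(0.5, 2.0, 8))
        _, grad = neg_log_pseudolikelihood(model, aln, w)
        eps = 1e-6
        for _ in range(25):
            i, j = sorted(rng.choice(5, size=2, replace=False))
            a, b = rng.integers(0, 21, size=2)
            Jp, Jm = model.J.copy(), model.J.copy()
            Jp[i, j, a, b] += eps
            Jp[j, i, b, a] += eps
            Jm[i, j, a, b] -= eps
            Jm[j, i, b, a] -= eps
            op, _ = neg_log_pseudolikelihood(PottsModel(h=model.h, J=Jp), aln, w)
            om, _ = neg_log_pseudolikelihood(PottsModel(h=model.h, J=Jm), aln, w)
            fd = (op - om) / (2 * eps)
            assert abs(fd - grad.J[i, j, a, b]) < 1e-4 * max(1.0, abs(fd))
        for _ in range(10):
            i = int(rng.integers(5))
            a = int(rng.integers(21))
            hp, hm = model.h.copy(), model.h.copy()
            hp[i, a] += eps
            hm[i, a] -= eps
            op, _ = neg_log_pseudolikelihood(PottsModel(h=hp, J=model.J), aln, w)
            om, _ = neg_log_pseudolikelihood(PottsModel(h=hm, J=model.J), aln, w)
            fd = (op - om) / (2 * eps)
            assert abs(fd - grad.h[i, a]) < 1e-4 * max(1.0, abs(fd))

    def test_shape_mismatch_rejected(self, rng):
        aln = random_alignment(rng, M=4, L=6)
        with pytest.raises(ValueError):
            neg_log_pseudolikelihood(PottsModel.zeros(5), aln, SequenceWeights.uniform(4))

    def test_nonfinite_parameters_rejected(self):
        h = np.zeros((3, 21))
        h[0, 0] = np.nan
        with pytest.raises(ValueError):
            PottsModel(h=h, J=np.zeros((3, 3, 21, 21)))


class TestZeroSumGauge:
    def test_zero_sum_block_unchanged(self, rng):
        model = random_symmetric_model(rng, 4)
        gauged = zero_sum_gauge(model)
        again = zero_sum_gauge(gauged)
        assert np.allclose(gauged.J, again.J, atol=1e-12)

    def test_constant_block_projects_to_zero(self):
        J = np.zeros((2, 2, 21, 21))
        J[0, 1] = 3.7
        J[1, 0] = 3.7
        gauged = zero_sum_gauge(PottsModel(h=np.zeros((2, 21)), J=J))
        assert np.allclose(gauged.J, 0.0, atol=1e-12)

    def test_row_col_means_vanish_and_conditionals_preserved(self, rng):
        model = random_symmetric_model(rng, 5)
        model = PottsModel(h=model.h, J=model.J, lambda_h=0.0, lambda_J=0.0)
        gauged = zero_sum_gauge(model)
        assert np.abs(gauged.J.mean(axis=3)).max() < 1e-12
        assert np.abs(gauged.J.mean(axis=2)).max() < 1e-12
        aln = random_alignment(np.random.default_rng(7), M=6, L=5)
        w = SequenceWeights.uniform(6)
        o1, _ = neg_log_pseudolikelihood(model, aln, w)
        o2, _ = neg_log_pseudolikelihood(gauged, aln, w)
        assert o1 == pytest.approx(o2, abs=1e-10)


class TestFrobeniusScores:
    def test_zero_model_gives_zero_scores(self):
        s = frobenius_scores(PottsModel.zeros(4))
        assert (s.S == 0).all() and not s.corrected

    def test_matches_direct_summation(self, rng):
        model = zero_sum_gauge(random_symmetric_model(rng, 4))
        s = frobenius_scores(model)
        for i in range(4):
            for j in range(4):
                expected = 0.0 if i == j else math.sqrt(np.sum(model.J[i, j] ** 2))
                assert s.S[i, j] == pytest.approx(expected, abs=1e-10)

    def test_invariant_under_row_column_shifts(self, rng):
        # J_ij(a,b) += f(a) + g(b) with compensating fields is a pure gauge
        # change and must not move the scores
        model = random_symmetric_model(rng, 4)
        s0 = frobenius_scores(model)
        J = model.J.copy()
        h = model.h.copy()
        f = rng.standard_normal(21)
        g = rng.standard_normal(21)
        i, j = 1, 3
        J[i, j] += f[:, None] + g[None, :]
        J[j, i] += f[None, :] + g[:, None]
        h[i] -= f
        h[j] -= g
        s1 = frobenius_scores(PottsModel(h=h, J=J))
        assert np.allclose(s0.S, s1.S, atol=1e-10)


class TestAPC:
    def test_constant_off_diagonal_cancels(self):
        S = np.full((5, 5), 2.5)
        np.fill_diagonal(S, 0.0)
        out = apc(CouplingScoreMatrix(S=S))
        assert np.allclose(out.S, 0.0, atol=1e-12)
        assert out.corrected

    def test_hand_computed_four_by_four(self):
        S = np.array(
            [
                [0.0, 1.0, 2.0, 3.0],
                [1.0, 0.0, 4.0, 5.0],
                [2.0, 4.0, 0.0, 6.0],
                [3.0, 5.0, 6.0, 0.0],
            ]
        )
        out = apc(CouplingScoreMatrix(S=S))
        row = S.sum(axis=1) / 3
        tot = S.sum() / 12
        for i in range(4):
            for j in range(4):
                expected = 0.0 if i == j else S[i, j] - row[i] * row[j] / tot
                assert out.S[i, j] == pytest.approx(expected, abs=1e-12)

    def test_all_zero_matrix_passes_through(self):
        out = apc(CouplingScoreMatrix(S=np.zeros((4, 4))))
        assert (out.S == 0).all() and out.corrected


class TestRanking:
    def test_eligible_pair_count_at_family_scale(self):
        assert len(eligible_pairs(624, 5)) == 191890

    def test_eligible_count_formula_vs_enumeration(self):
        for L in (6, 11, 23, 50):
            for m in (1, 2, 5, 7):
                brute = sum(
                    1 for i in range(L) for j in range(i + 1, L) if j - i >= m
                )
                formula = L * (L - 1) // 2 - sum(L - d for d in range(1, m))
                assert len(eligible_pairs(L, m)) == brute == formula

    def test_min_sep_excludes_local_pair(self, rng):
        S = np.zeros((20, 20))
        S[10, 13] = S[13, 10] = 5.0  # separation 3 < 5
        S[2, 12] = S[12, 2] = 1.0
        preds = rank_predictions(CouplingScoreMatrix(S=S), n_top=1, min_sep=5)
        assert [(i, j) for i, j, _ in preds] == [(2, 12)]

    def test_matches_exhaustive_sort_oracle(self, rng):
        S = rng.standard_normal((10, 10))
        S = 0.5 * (S + S.T)
        np.fill_diagonal(S, 0.0)
        preds = rank_predictions(CouplingScoreMatrix(S=S), n_top=5, min_sep=2)
        oracle = sorted(
            (
                (-S[i, j], i, j)
                for i in range(10)
                for j in range(i + 2, 10)
            )
        )[:5]
        assert [(i, j) for i, j, _ in preds] == [(i, j) for _, i, j in oracle]

    def test_oversized_request_rejected(self):
        with pytest.raises(ValueError):
            rank_predictions(CouplingScoreMatrix(S=np.zeros((6, 6))), n_top=100, min_sep=5)

    def test_prediction_list_roundtrip(self, tmp_path, rng):
        S = rng.standard_normal((8, 8))
        S = 0.5 * (S + S.T)
        np.fill_diagonal(S, 0.0)
        preds = rank_predictions(CouplingScoreMatrix(S=S), n_top=6, min_sep=2)
        p = tmp_path / "preds.tsv"
        write_predictions(preds, p)
        back = read_predictions(p)
        assert (back.pairs == preds.pairs).all()
        assert np.allclose(back.scores, preds.scores, rtol=1e-6)


class TestFit:
    def test_refit_is_bitwise_deterministic(self, rng):
        aln = random_alignment(rng, M=60, L=5, gap_prob=0.0)
        m1 = fit_plm(aln, tol=1e-4)
        m2 = fit_plm(aln, tol=1e-4)
        assert (m1.h == m2.h).all() and (m1.J == m2.J).all()

    def test_planted_bijective_dependence_is_top_pair(self, rng):
        # column 1 is a deterministic bijection of column 0; all other
        # columns are independent noise
        M, L = 1000, 6
        perm = rng.permutation(20) + 1
        rows = rng.integers(1, 21, size=(M, L))
        rows[:, 1] = perm[rows[:, 0] - 1]
        aln = Alignment(ids=[f"s{i}" for i in range(M)], rows=rows)
        model = fit_plm(aln, tol=1e-4)
        preds = rank_predictions(apc(frobenius_scores(model)), n_top=1, min_sep=1)
        assert [(i, j) for i, j, _ in preds] == [(0, 1)]

    def test_independent_uniform_columns_score_near_zero(self):
        # sampling null: no couplings should emerge from iid columns
        rng = np.random.default_rng(2024)
        rows = rng.integers(0, 21, size=(10000, 6))
        aln = Alignment(ids=[f"s{i}" for i in range(10000)], rows=rows)
        model = fit_plm(aln, tol=1e-5)
        scores = apc(frobenius_scores(model))
        assert np.abs(scores.S).max() < 0.05

    def test_doubling_weights_leaves_scores_unchanged(self, rng):
        aln = random_alignment(rng, M=80, L=4, gap_prob=0.0)
        s1 = apc(frobenius_scores(fit_plm(aln, SequenceWeights.uniform(80), tol=1e-5)))
        s2 = apc(frobenius_scores(fit_plm(aln, SequenceWeights(2 * np.ones(80)), tol=1e-5)))
        assert np.allclose(s1.S, s2.S, atol=1e-6)

    def test_iteration_cap_raises_with_last_iterate(self, rng):
        aln = random_alignment(rng, M=50, L=4, gap_prob=0.0)
        with pytest.raises(FitError) as exc:
            fit_plm(aln, tol=1e-12, max_iter=2)
        assert exc.value.last_model is not None
        assert exc.value.last_model.L == 4

    def test_objective_decreases_along_iterates(self, rng):
        import scipy.optimize

        aln = random_alignment(rng, M=40, L=4, gap_prob=0.0)
        from dcapipe.potts import _onehot_sparse, _plm_value_grad

        L, q, M_eff = 4, 21, 40.0
        O = _onehot_sparse(aln.rows, q)
        iu = np.triu_indices(L, 1)
        n_pairs = len(iu[0])

        def fun(x):
            h = x[: L * q].reshape(L, q)
            blocks = x[L * q:].reshape(n_pairs, q, q)
            Jmat = np.zeros((L * q, L * q))
            J4 = Jmat.reshape(L, q, L, q)
            J4[iu[0], :, iu[1], :] = blocks
            J4[iu[1], :, iu[0], :] = np.transpose(blocks, (0, 2, 1))
            obj, gh, gJ = _plm_value_grad(
                h, Jmat, aln.rows, np.ones(40), 0.01 * M_eff, 0.01 * M_eff, O=O
            )
            g = np.concatenate(
                [gh.ravel(), gJ.reshape(L, q, L, q)[iu[0], :, iu[1], :].ravel()]
            )
            return obj / M_eff, g / M_eff

        values = []
        scipy.optimize.minimize(
            fun,
            np.zeros(L * q + n_pairs * q * q),
            jac=True,
            method="L-BFGS-B",
            callback=lambda xk: values.append(fun(xk)[0]),
            options={"maxiter": 60},
        )
        diffs = np.diff(values)
        assert (diffs <= 1e-8).all()
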