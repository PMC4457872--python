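"""Symmetric pseudo-likelihood inference of a 21-state Potts model.

The family is modelled by the pairwise Markov random field

    P(S) = (1/Z) exp( sum_i h_i(s_i) + sum_{i<j} J_ij(s_i, s_j) )

whose parameters are learned by minimizing the L2-regularized negative
log-pseudo-likelihood: the sum over rows and sites of -log P(s_i | s_{\\i}),
which needs only the single-site conditionals and never the partition
function Z.  The symmetric variant shares one coupling block per unordered
pair (J_ij(a, b) = J_ji(b, a) by construction).

Scoring follows the standard route: shift every coupling block to the
zero-sum gauge (couplings are only defined up to per-position rescalings of
the fields, and the Frobenius norm is gauge-dependent), take the Frobenius
norm of each 21x21 block including the gap state, then subtract the average
product correction (APC) to suppress per-position background signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.optimize
import scipy.sparse
from scipy.special import logsumexp

from .alphabet import Q
from .msa import Alignment, SequenceWeights


class FitError(RuntimeError):
    """Optimization failed to reach the requested tolerance."""

    def __init__(self, message: str, last_model: "PottsModel | None" = None):
        super().__init__(message)
        self.last_model = last_model


@dataclass
class PottsModel:
    """Fields h (L, q) and couplings J (L, L, q, q) of the Potts model.

    J satisfies the shared-pair symmetry J[i, j, a, b] == J[j, i, b, a] and
    J[i, i] == 0.
    """

    h: np.ndarray
    J: np.ndarray
    lambda_h: float = 0.01
    lambda_J: float = 0.01

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=float)
        self.J = np.asarray(self.J, dtype=float)
        L, q = self.h.shape
        if self.J.shape != (L, L, q, q):
            raise ValueError("J must have shape (L, L, q, q)")
        if not (np.isfinite(self.h).all() and np.isfinite(self.J).all()):
            raise ValueError("model parameters must be finite")

    @property
    def L(self) -> int:
        return self.h.shape[0]

    @property
    def q(self) -> int:
        return self.h.shape[1]

    @classmethod
    def zeros(cls, L: int, q: int = Q, **kw) -> "PottsModel":
        return cls(h=np.zeros((L, q)), J=np.zeros((L, L, q, q)), **kw)

    def validate_symmetry(self, atol: float = 1e-10) -> bool:
        return bool(
            np.allclose(self.J, np.transpose(self.J, (1, 0, 3, 2)), atol=atol)
            and np.allclose(self.J[np.arange(self.L), np.arange(self.L)], 0.0, atol=atol)
        )

    def coupling_matrix(self) -> np.ndarray:
        """J reshaped to the (L*q, L*q) block matrix used by the solver."""
        L, q = self.L, self.q
        return np.transpose(self.J, (0, 2, 1, 3)).reshape(L * q, L * q)


@dataclass
class CouplingScoreMatrix:
    """Symmetric per-pair coupling scores S_ij with zero diagonal."""

    S: np.ndarray
    corrected: bool = False

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        L = self.S.shape[0]
        if self.S.shape != (L, L):
            raise ValueError("S must be square")
        if not np.allclose(self.S, self.S.T, atol=1e-9):
            raise ValueError("S must be symmetric")
        if not np.allclose(np.diag(self.S), 0.0):
            raise ValueError("S must have zero diagonal")

    @property
    def L(self) -> int:
        return self.S.shape[0]


@dataclass
class PredictionList:
    """Ranked contact predictions (i < j, 0-based columns), score-descending."""

    pairs: np.ndarray  # (n, 2) int
    scores: np.ndarray  # (n,)
    min_sep: int

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=int)
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.pairs) != len(self.scores):
            raise ValueError("pairs and scores must have equal length")
        if len(self.pairs):
            if np.any(self.pairs[:, 0] >= self.pairs[:, 1]):
                raise ValueError("pairs must satisfy i < j")
            sep = np.abs(self.pairs[:, 1] - self.pairs[:, 0])
            if np.any(sep < self.min_sep):
                raise ValueError("pair below minimum sequence separation")
            if np.any(np.diff(self.scores) > 1e-12):
                raise ValueError("scores must be non-increasing")

    @property
    def n(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        for (i, j), s in zip(self.pairs, self.scores):
            yield int(i), int(j), float(s)


# ---------------------------------------------------------------------------
# pseudo-likelihood objective


def _onehot_sparse(rows: np.ndarray, q: int) -> scipy.sparse.csr_matrix:
    M, L = rows.shape
    cols = (np.arange(L) * q)[None, :] + rows
    indptr = np.arange(0, M * L + 1, L)
    data = np.ones(M * L)
    return scipy.sparse.csr_matrix(
        (data, cols.ravel(), indptr), shape=(M, L * q)
    )


def _plm_value_grad(h, Jmat, rows, w, lambda_h, lambda_J, O=None):
    """Objective and gradient of the weighted, regularized neg-log-PL.

    Parameters are taken in solver layout: h (L, q) and the symmetric
    (L*q, L*q) block matrix Jmat with zero diagonal blocks.  Returns the
    gradient in the same layout; the Jmat gradient is already symmetrized
    for the shared-pair parameterization.
    """
    M, L = rows.shape
    q = h.shape[1]
    if O is None:
        O = _onehot_sparse(rows, q)
    logits = np.asarray(O @ Jmat)
    logits += h.reshape(1, L * q)
    logits3 = logits.reshape(M, L, q)
    lse = logsumexp(logits3, axis=2)  # (M, L)
    picked = np.take_along_axis(logits3, rows[:, :, None].astype(int), axis=2)[:, :, 0]
    obj = float(np.dot(w, (lse - picked).sum(axis=1)))

    # D[m, i*q+a] = w_m * (P(a | s_\i) - 1[s_i = a])
    P = np.exp(logits3 - lse[:, :, None])
    D = P.reshape(M, L * q) * w[:, None]
    idx = (np.arange(L) * q)[None, :] + rows  # one index per (m, i): no duplicates
    D[np.arange(M)[:, None], idx] -= w[:, None]

    grad_h = D.sum(axis=0).reshape(L, q)

    G = np.asarray((O.T @ D).T)  # G[(i,a),(j,b)] = sum_m D[m,(i,a)] O[m,(j,b)]
    gJ = G + G.T
    # zero the diagonal blocks: J_ii is not a parameter
    gJ4 = gJ.reshape(L, q, L, q)
    gJ4[np.arange(L), :, np.arange(L), :] = 0.0

    # L2 regularization: lambda_h * sum h^2 + lambda_J * sum_{i<j} ||J_ij||^2
    obj += lambda_h * float(np.sum(h * h))
    obj += lambda_J * 0.5 * float(np.sum(Jmat * Jmat))  # each pair counted twice
    grad_h += 2.0 * lambda_h * h
    gJ += lambda_J * 2.0 * 0.5 * (Jmat + Jmat.T)  # = 2 lambda_J Jmat for symmetric Jmat

    return obj, grad_h, gJ


def neg_log_pseudolikelihood(
    model: PottsModel, aln: Alignment, w: SequenceWeights
) -> tuple[float, PottsModel]:
    """Weighted, regularized negative log-pseudo-likelihood and its gradient.

    Returns ``(objective, gradient)`` where the gradient is packaged as a
    :class:`PottsModel` with the same shapes (gradient w.r.t. the shared
    coupling parameter of each unordered pair, stored symmetrically).
    """
    if model.L != aln.L:
        raise ValueError("model length does not match alignment length")
    if len(w.w) != aln.M:
        raise ValueError("weights length does not match alignment rows")
    Jmat = model.coupling_matrix()
    obj, grad_h, gJ = _plm_value_grad(
        model.h, Jmat, aln.rows, w.w, model.lambda_h, model.lambda_J
    )
    L, q = model.L, model.q
    grad_J = np.transpose(gJ.reshape(L, q, L, q), (0, 2, 1, 3))
    grad = PottsModel(h=grad_h, J=grad_J, lambda_h=model.lambda_h, lambda_J=model.lambda_J)
    return obj, grad


def fit_plm(
    aln: Alignment,
    w: SequenceWeights | None = None,
    lambda_h: float = 0.01,
    lambda_J: float = 0.01,
    tol: float = 1e-5,
    max_iter: int = 2000,
) -> PottsModel:
    """Fit the Potts model by symmetric pseudo-likelihood maximization.

    Deterministic L-BFGS from the all-zero model, minimizing the
    per-sequence-averaged pseudo-likelihood plus L2 penalties,

        (1/M_eff) sum_r w_r nll_r + lambda_h ||h||^2 + lambda_J sum_{i<j} ||J_ij||^2,

    which is the regularization convention under which lambda_h = lambda_J
    = 0.01 is the standard choice for this method.  ``tol`` is the
    projected-gradient tolerance at that per-sequence scale, so convergence
    is judged independently of the number (or weighting) of rows.  Raises
    :class:`FitError` carrying the last iterate if the iteration cap is hit
    first.
    """
    if aln.M < 2 or aln.L < 2:
        raise ValueError("need at least 2 rows and 2 columns")
    if w is None:
        w = SequenceWeights.uniform(aln.M)
    M, L = aln.rows.shape
    q = Q
    O = _onehot_sparse(aln.rows, q)
    M_eff = w.M_eff
    n_h = L * q

    iu = np.triu_indices(L, k=1)
    n_pairs = len(iu[0])

    def unpack(x):
        h = x[:n_h].reshape(L, q)
        blocks = x[n_h:].reshape(n_pairs, q, q)
        Jmat = np.zeros((L * q, L * q))
        J4 = Jmat.reshape(L, q, L, q)
        J4[iu[0], :, iu[1], :] = blocks
        J4[iu[1], :, iu[0], :] = np.transpose(blocks, (0, 2, 1))
        return h, Jmat

    # lambdas act at the per-sequence-averaged scale; scale them up so the
    # raw-sum kernel computes the equivalent objective, then divide through.
    lh, lJ = lambda_h * M_eff, lambda_J * M_eff

    def fun(x):
        h, Jmat = unpack(x)
        obj, grad_h, gJ = _plm_value_grad(h, Jmat, aln.rows, w.w, lh, lJ, O=O)
        gJ4 = gJ.reshape(L, q, L, q)
        g = np.concatenate([grad_h.ravel(), gJ4[iu[0], :, iu[1], :].ravel()])
        return obj / M_eff, g / M_eff

    x0 = np.zeros(n_h + n_pairs * q * q)
    res = scipy.optimize.minimize(
        fun,
        x0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "maxfun": 4 * max_iter, "gtol": tol,
                 "ftol": 1e-14, "maxcor": 10},
    )
    h, Jmat = unpack(res.x)
    model = PottsModel(
        h=h,
        J=np.transpose(Jmat.reshape(L, q, L, q), (0, 2, 1, 3)),
        lambda_h=lambda_h,
        lambda_J=lambda_J,
    )
    if res.status == 1:  # iteration/function cap hit before tolerance
        raise FitError(
            f"L-BFGS hit the iteration cap ({max_iter}) before reaching tol={tol}",
            last_model=model,
        )
    return model


# ---------------------------------------------------------------------------
# gauge, scores, ranking


def zero_sum_gauge(model: PottsModel) -> PottsModel:
    """Shift every coupling block to zero row/column means.

    The single-site conditionals (hence the pseudo-likelihood) are
    preserved by absorbing the a-dependent part of the shift into the
    fields: h_i(a) += sum_{j != i} mean_b J_ij(a, b).
    """
    J = model.J
    row_mean = J.mean(axis=3, keepdims=True)  # mean over b
    col_mean = J.mean(axis=2, keepdims=True)  # mean over a
    tot_mean = J.mean(axis=(2, 3), keepdims=True)
    J_new = J - row_mean - col_mean + tot_mean
    h_new = model.h + row_mean[:, :, :, 0].sum(axis=1)
    return PottsModel(h=h_new, J=J_new, lambda_h=model.lambda_h, lambda_J=model.lambda_J)


def frobenius_scores(model: PottsModel) -> CouplingScoreMatrix:
    """Frobenius norm of each zero-sum-gauged q x q coupling block.

    The gap state contributes to the norm like any other state (the block
    is the full 21 x 21 matrix).
    """
    gauged = zero_sum_gauge(model)
    S = np.sqrt(np.sum(gauged.J ** 2, axis=(2, 3)))
    np.fill_diagonal(S, 0.0)
    S = 0.5 * (S + S.T)  # exact symmetry against rounding
    return CouplingScoreMatrix(S=S, corrected=False)


def apc(scores: CouplingScoreMatrix) -> CouplingScoreMatrix:
    """Average product correction: S'_ij = S_ij - S̄_i S̄_j / S̄.

    Row means exclude the diagonal; an all-zero matrix is returned
    unchanged.
    """
    S = scores.S
    L = S.shape[0]
    if L < 2:
        return CouplingScoreMatrix(S=S.copy(), corrected=True)
    row_mean = (S.sum(axis=1)) / (L - 1)  # diagonal is zero, so excluded
    total_mean = S.sum() / (L * (L - 1))
    if total_mean == 0.0:
        return CouplingScoreMatrix(S=S.copy(), corrected=True)
    corrected = S - np.outer(row_mean, row_mean) / total_mean
    np.fill_diagonal(corrected, 0.0)
    return CouplingScoreMatrix(S=corrected, corrected=True)


def eligible_pairs(L: int, min_sep: int) -> np.ndarray:
    """All unordered column pairs (i, j), i < j, with j - i >= min_sep."""
    iu = np.triu_indices(L, k=max(min_sep, 1))
    return np.column_stack(iu)


def rank_predictions(
    scores: CouplingScoreMatrix, n_top: int, min_sep: int = 5
) -> PredictionList:
    """Top ``n_top`` pairs at separation >= ``min_sep`` by descending score.

    Ties are broken by (i, j) lexicographic ascending, making the ranking
    fully deterministic.
    """
    pairs = eligible_pairs(scores.L, min_sep)
    if n_top > len(pairs):
        raise ValueError(
            f"n_top={n_top} exceeds the {len(pairs)} pairs at separation >= {min_sep}"
        )
    vals = scores.S[pairs[:, 0], pairs[:, 1]]
    order = np.lexsort((pairs[:, 1], pairs[:, 0], -vals))[:n_top]
    return PredictionList(pairs=pairs[order], scores=vals[order], min_sep=min_sep)


def write_scores(scores: CouplingScoreMatrix, path) -> None:
    """Upper-triangle score triplets, tab-separated, 1-based columns."""
    with open(path, "w") as fh:
        fh.write("# i\tj\tscore (1-based columns, upper triangle, "
                 f"{'APC-corrected' if scores.corrected else 'raw Frobenius'})\n")
        iu = np.triu_indices(scores.L, k=1)
        for i, j in zip(*iu):
            fh.write(f"{i + 1}\t{j + 1}\t{scores.S[i, j]:.8g}\n")


def read_predictions(path) -> PredictionList:
    """Read a prediction list written by :func:`write_predictions`."""
    pairs, scores, min_sep = [], [], 1
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                if "min_sep=" in line:
                    min_sep = int(line.split("min_sep=")[1].split(",")[0])
                continue
            i, j, s = line.split("\t")
            pairs.append((int(i) - 1, int(j) - 1))
            scores.append(float(s))
    return PredictionList(pairs=np.asarray(pairs), scores=np.asarray(scores), min_sep=min_sep)


def write_predictions(preds: PredictionList, path) -> None:
    """Ranked predictions, tab-separated, 1-based, score-descending."""
    with open(path, "w") as fh:
        fh.write(f"# i\tj\tscore (1-based columns, min_sep={preds.min_sep}, "
                 "sorted by decreasing coupling score)\n")
        for i, j, s in preds:
            fh.write(f"{i + 1}\t{j + 1}\t{s:.8g}\n")
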