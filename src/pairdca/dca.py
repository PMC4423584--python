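"""Mean-field direct coupling analysis of a cleaned alignment.

Given an alignment over the 21-state alphabet (20 amino acids + gap), this
module estimates a global pairwise (Potts) model and scores every column
pair twice:

* **MI** — mutual information of the (reweighted, pseudocounted) empirical
  pair frequencies; captures direct *and* transitive covariation.
* **DI** — direct information: the mutual information of the two-site
  "direct" distribution built from the mean-field couplings with fields
  chosen so its marginals match the single-column frequencies; designed to
  strip the transitive part.

The procedure is the classic mean-field inverse-Potts chain: similarity
reweighting of sequences at identity threshold 1 - theta, pseudocounted
frequency estimation, inversion of the connected-correlation matrix over a
reduced 20-state alphabet (gap is the reference/gauge state), and a per-pair
two-site model solved by fixed-point iteration on the auxiliary fields.
Everything is expressed in nats.

The central output is the :class:`PairScoreTable` — one row per column pair
(i < j) with the four columns (i, j, MI, DI).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import lapack

from .alphabet import Q, one_hot
from .exceptions import (
    ConvergenceError,
    FormatError,
    NumericalError,
    ParameterError,
)
from .paired_msa import AlignmentMatrix

logger = logging.getLogger(__name__)

#: convergence tolerance on the two-site marginal mismatch (per entry)
FIELD_TOL = 1e-4
#: iteration cap for the two-site field fit
FIELD_MAX_ITER = 500
#: damping factor of the fixed-point update (0 = undamped)
FIELD_DAMPING = 0.1
_TINY = 1e-100


# ---------------------------------------------------------------------------
# Sequence reweighting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WeightVector:
    """Per-sequence weights from similarity-based reweighting.

    ``w[m] = 1 / #{m' : identity(m, m') >= 1 - theta}`` (self included);
    ``m_eff`` is their sum, the effective number of sequences.
    """

    w: np.ndarray
    m_eff: float
    theta: float


def compute_sequence_weights(
    aln: AlignmentMatrix, theta: float = 0.2, chunk: int = 512
) -> WeightVector:
    """Down-weight near-duplicate sequences.

    Two rows are neighbours when their fraction of identical positions
    (gap counted as a matchable state) is at least ``1 - theta``.  The
    pairwise identity counts are computed by a one-hot matrix product in
    row chunks, equivalent to the O(M^2 L) pairwise scan.
    """
    if not 0.0 <= theta < 1.0:
        raise ParameterError(f"theta must be in [0, 1), got {theta}")
    m, l = aln.M, aln.L
    x = one_hot(aln.matrix, dtype=np.float32)
    cutoff = 1.0 - theta
    neighbours = np.empty(m, dtype=np.int64)
    for start in range(0, m, chunk):
        stop = min(start + chunk, m)
        # identical-position counts between each chunk row and every row
        s = x[start:stop] @ x.T
        frac = s.astype(np.float64) / l
        neighbours[start:stop] = (frac >= cutoff).sum(axis=1)
    w = 1.0 / neighbours
    return WeightVector(w=w, m_eff=float(w.sum()), theta=theta)


# ---------------------------------------------------------------------------
# Frequencies
# ---------------------------------------------------------------------------

@dataclass
class FrequencyModel:
    """Reweighted, pseudocounted single- and pair-column frequencies.

    ``fi`` has shape (L, q); ``fij`` has shape (L, L, q, q) with the
    diagonal blocks ``fij[i, i, a, b] = fi(a) * [a == b]`` up to the
    pseudocount term, so that pair marginals are exactly consistent.
    """

    q: int
    lam: float
    m_eff: float
    fi: np.ndarray
    fij: np.ndarray

    @property
    def L(self) -> int:
        return self.fi.shape[0]


def estimate_frequencies(
    aln: AlignmentMatrix, weights: WeightVector | None = None, lam: float = 0.0
) -> FrequencyModel:
    """Weighted frequency counts with a uniform pseudocount of mass ``lam``.

    f_i(a)    = (lam/q   + sum_m w_m [A_mi = a])            / (lam + M_eff)
    f_ij(a,b) = (lam/q^2 + sum_m w_m [A_mi = a][A_mj = b])  / (lam + M_eff)

    and on the diagonal f_ii(a,b) keeps its pseudocount on the a == b cells
    only, so that sum_b f_ii(a,b) = f_i(a) holds exactly.
    """
    if lam < 0:
        raise ParameterError(f"pseudocount mass must be >= 0, got {lam}")
    m, l = aln.M, aln.L
    w = weights.w if weights is not None else np.ones(m)
    m_eff = float(w.sum())
    x = one_hot(aln.matrix, dtype=np.float64)  # (M, L*q)
    counts_i = w @ x  # (L*q,)
    counts_ij = (x * w[:, None]).T @ x  # (L*q, L*q)
    denom = lam + m_eff
    fi = (lam / Q + counts_i.reshape(l, Q)) / denom
    fij = (lam / Q**2 + counts_ij.reshape(l, Q, l, Q).transpose(0, 2, 1, 3)) / denom
    # consistent diagonal blocks: empirical diag counts + pseudocount on a==b
    eye = np.eye(Q)
    diag_counts = counts_i.reshape(l, Q)
    for i in range(l):
        fij[i, i] = (lam / Q * eye + np.diag(diag_counts[i])) / denom
    return FrequencyModel(q=Q, lam=lam, m_eff=m_eff, fi=fi, fij=fij)


# ---------------------------------------------------------------------------
# Mutual information
# ---------------------------------------------------------------------------

def mutual_information(freqs: FrequencyModel) -> np.ndarray:
    """MI (nats) for every column pair, as a symmetric (L, L) matrix.

    MI_ij = sum_ab f_ij(a,b) ln(f_ij(a,b) / (f_i(a) f_j(b))); cells with
    f_ij = 0 contribute nothing.  The diagonal is set to zero.

    Computed through the entropy identity MI_ij = H_i + H_j - H_ij, exact
    here because the pair tables marginalise to the single-column
    frequencies by construction; this needs a single log pass over the
    (L, L, q, q) array instead of three.
    """
    fi, fij = freqs.fi, freqs.fij
    plogp = np.zeros_like(fij)
    np.log(fij, out=plogp, where=fij > 0)
    plogp *= fij
    neg_hij = np.einsum("ijab->ij", plogp)
    plogp_i = np.zeros_like(fi)
    np.log(fi, out=plogp_i, where=fi > 0)
    plogp_i *= fi
    neg_hi = plogp_i.sum(axis=1)
    mi = neg_hij - neg_hi[:, None] - neg_hi[None, :]
    np.fill_diagonal(mi, 0.0)
    return mi


# ---------------------------------------------------------------------------
# Mean-field couplings
# ---------------------------------------------------------------------------

@dataclass
class CouplingModel:
    """Mean-field couplings over the reduced (q-1)-state alphabet.

    ``C`` is the connected-correlation matrix with row/column blocks indexed
    by (column, amino-acid state); the gap state is the gauge reference and
    does not appear.  ``inv_c`` is its inverse; the coupling block is
    e_ij = -inv_c[(i,:), (j,:)].
    """

    C: np.ndarray
    inv_c: np.ndarray
    L: int

    @property
    def q_reduced(self) -> int:
        return Q - 1

    def couplings(self, i: int, j: int) -> np.ndarray:
        """e_ij(a, b) for amino-acid states a, b (shape (q-1, q-1))."""
        r = self.q_reduced
        return -self.inv_c[i * r:(i + 1) * r, j * r:(j + 1) * r]


def infer_mean_field_couplings(freqs: FrequencyModel) -> CouplingModel:
    """Invert the connected-correlation matrix to get pair couplings.

    C_(i,a),(j,b) = f_ij(a,b) - f_i(a) f_j(b) restricted to the 20
    amino-acid states; with a positive pseudocount C is positive definite
    and invertible.
    """
    l = freqs.L
    r = Q - 1
    fi_r = freqs.fi[:, 1:]  # drop the gap (gauge) state
    fij_r = freqs.fij[:, :, 1:, 1:]
    c = fij_r - np.einsum("ia,jb->ijab", fi_r, fi_r)
    c = c.transpose(0, 2, 1, 3).reshape(l * r, l * r)
    # C is symmetric positive definite for any positive pseudocount, so a
    # Cholesky-based inverse (potrf + potri) beats a general LU inverse
    chol, info = lapack.dpotrf(c, lower=1)
    if info == 0:
        inv_half, info = lapack.dpotri(chol, lower=1)
    if info != 0:
        raise NumericalError(
            "connected-correlation matrix is singular or not positive "
            "definite; increase the pseudocount (lambda_ratio)"
        )
    # potri fills one triangle only (and leaves factor junk in the other);
    # inv_half is F-ordered, so its .T is a C-contiguous view whose *upper*
    # triangle holds the valid entries — triu on that view stays fast
    upper = inv_half.T
    inv_c = np.triu(upper) + np.triu(upper, 1).T
    if not np.isfinite(inv_c).all():
        raise NumericalError(
            "non-finite entries in the inverted correlation matrix; "
            "increase the pseudocount (lambda_ratio)"
        )
    return CouplingModel(C=c, inv_c=inv_c, L=l)


# ---------------------------------------------------------------------------
# Direct information
# ---------------------------------------------------------------------------

def _pair_exp_couplings(coup: CouplingModel, idx_i: np.ndarray, idx_j: np.ndarray) -> np.ndarray:
    """exp(e_ij) padded with the gap gauge state: shape (P, q, q)."""
    r = coup.q_reduced
    blocks = coup.inv_c.reshape(coup.L, r, coup.L, r)
    w = np.ones((len(idx_i), Q, Q))
    w[:, 1:, 1:] = np.exp(-blocks[idx_i, :, idx_j, :])
    return w


def direct_information(
    coup: CouplingModel,
    freqs: FrequencyModel,
    pairs: tuple[np.ndarray, np.ndarray] | None = None,
    tol: float = FIELD_TOL,
    max_iter: int = FIELD_MAX_ITER,
    damping: float = FIELD_DAMPING,
) -> np.ndarray:
    """DI (nats) for every column pair, as a symmetric (L, L) matrix.

    For each pair the two-site direct distribution
    P_ij(a,b) ∝ exp(e_ij(a,b)) ĥ_i(a) ĥ_j(b) is fitted by damped
    fixed-point iteration on the auxiliary fields ĥ until its marginals
    match f_i and f_j to ``tol``; DI is then the MI of P_ij against the
    product of the single-column frequencies.  All pairs are iterated
    simultaneously (vectorised); convergence is tracked per pair.
    """
    l = freqs.L
    if pairs is None:
        idx_i, idx_j = np.triu_indices(l, k=1)
    else:
        idx_i, idx_j = pairs
    if len(idx_i) == 0:
        return np.zeros((l, l))
    w = _pair_exp_couplings(coup, idx_i, idx_j)  # (P, q, q)
    pi = freqs.fi[idx_i]  # (P, q)
    pj = freqs.fi[idx_j]
    mu1 = pi.copy()
    mu2 = pj.copy()
    active = np.ones(len(idx_i), dtype=bool)
    for _ in range(max_iter):
        s1 = np.einsum("pab,pb->pa", w, mu2)  # (W mu2)_a
        s2 = np.einsum("pab,pa->pb", w, mu1)  # (W^T mu1)_b
        z = np.einsum("pa,pa->p", mu1, s1)
        marg1 = mu1 * s1 / z[:, None]
        marg2 = mu2 * s2 / z[:, None]
        err = np.maximum(
            np.abs(marg1 - pi).max(axis=1), np.abs(marg2 - pj).max(axis=1)
        )
        active = err > tol
        if not active.any():
            break
        new1 = pi / s1
        new1 /= new1.sum(axis=1, keepdims=True)
        new2 = pj / s2
        new2 /= new2.sum(axis=1, keepdims=True)
        mu1[active] = (1 - damping) * new1[active] + damping * mu1[active]
        mu2[active] = (1 - damping) * new2[active] + damping * mu2[active]
    else:
        bad = int(np.flatnonzero(active)[0])
        raise ConvergenceError(
            f"two-site field fit did not converge within {max_iter} iterations "
            f"for column pair ({int(idx_i[bad])}, {int(idx_j[bad])}); "
            f"{int(active.sum())} pairs unconverged"
        )
    p_dir = w * mu1[:, :, None] * mu2[:, None, :]
    p_dir /= p_dir.sum(axis=(1, 2), keepdims=True)
    prod = pi[:, :, None] * pj[:, None, :]
    di_pairs = np.einsum(
        "pab,pab->p", p_dir, np.log((p_dir + _TINY) / (prod + _TINY))
    )
    di = np.zeros((l, l))
    di[idx_i, idx_j] = di_pairs
    di[idx_j, idx_i] = di_pairs
    return di


# ---------------------------------------------------------------------------
# Pair score table
# ---------------------------------------------------------------------------

@dataclass
class PairScoreTable:
    """All-pairs scores: columns (i, j, mi, di), i < j, one row per pair.

    ``i`` and ``j`` are 1-based alignment column indices in the coordinate
    system of the *original* (concatenated) alignment, even when some
    columns (e.g. the artificial spacer) were excluded from the analysis.
    """

    frame: pd.DataFrame

    COLUMNS = ("i", "j", "mi", "di")

    def __post_init__(self):
        missing = set(self.COLUMNS) - set(self.frame.columns)
        if missing:
            raise FormatError(f"pair table missing columns {sorted(missing)}")
        self.frame = self.frame.loc[:, list(self.COLUMNS)].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    def write_text(self, path, header: bool = False) -> None:
        """Write the 4-column whitespace-separated pair file."""
        path = Path(path)
        with path.open("w") as fh:
            if header:
                fh.write("i j mi di\n")
            for row in self.frame.itertuples(index=False):
                fh.write(f"{int(row.i)} {int(row.j)} {row.mi:.17g} {row.di:.17g}\n")

    @classmethod
    def read_text(cls, path) -> "PairScoreTable":
        path = Path(path)
        try:
            frame = pd.read_csv(
                path, sep=r"\s+", comment="#", header=None, names=list(cls.COLUMNS)
            )
        except (ValueError, pd.errors.ParserError) as exc:
            raise FormatError(f"malformed pair table {path}: {exc}") from exc
        # tolerate an optional header line
        if len(frame) and str(frame.iloc[0]["i"]) == "i":
            frame = frame.iloc[1:]
        try:
            frame = frame.astype({"i": int, "j": int, "mi": float, "di": float})
        except ValueError as exc:
            raise FormatError(f"malformed pair table {path}: {exc}") from exc
        return cls(frame)


def run_dca(
    aln: AlignmentMatrix,
    theta: float = 0.2,
    lambda_ratio: float = 1.0,
    exclude_columns: Sequence[int] | None = None,
) -> PairScoreTable:
    """Full chain: weights -> frequencies -> MI -> couplings -> DI.

    ``lambda_ratio`` scales the pseudocount mass relative to M_eff (1.0
    reproduces the customary 50/50 data/pseudocount mix).  1-based column
    indices listed in ``exclude_columns`` (typically the artificial spacer)
    are removed before any statistic is computed; the emitted i, j indices
    stay in the original coordinate system.
    """
    weights = compute_sequence_weights(aln, theta=theta)
    keep = np.arange(1, aln.L + 1)
    if exclude_columns:
        excl = set(int(c) for c in exclude_columns)
        keep = np.array([c for c in keep if c not in excl])
        sub = AlignmentMatrix(
            aln.matrix[:, keep - 1].copy(), list(aln.row_ids), aln.reference_row
        )
    else:
        sub = aln
    lam = lambda_ratio * weights.m_eff
    freqs = estimate_frequencies(sub, weights, lam=lam)
    mi = mutual_information(freqs)
    coup = infer_mean_field_couplings(freqs)
    di = direct_information(coup, freqs)
    ii, jj = np.triu_indices(sub.L, k=1)
    frame = pd.DataFrame(
        {
            "i": keep[ii],
            "j": keep[jj],
            "mi": mi[ii, jj],
            "di": di[ii, jj],
        }
    )
    logger.info(
        "DCA: M=%d M_eff=%.1f N=%d pairs=%d", aln.M, weights.m_eff, sub.L, len(frame)
    )
    return PairScoreTable(frame)
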