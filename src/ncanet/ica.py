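"""Independent component analysis of expression data and consensus gene
selection over repeated runs.

The generative model is X = A.S: the n observed samples (rows of X, one per
array) are linear mixtures of n statistically independent expression modes
(rows of S, one loading per gene, m >> n). Separation uses the fixed-point
FastICA iteration with the tanh(a1*u) contrast and symmetric decorrelation.
Because the iteration starts from a random rotation and can settle in local
optima, significant genes are extracted by consensus: the algorithm is
re-run many times and a gene counts as significant when it recurs among the
top-|loading| genes of some component in a sufficient fraction of runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin

__all__ = [
    "RankDeficiencyError",
    "ICAResult",
    "GeneSelection",
    "whiten",
    "fastica",
    "amari_error",
    "consensus_significant_genes",
    "ConsensusICASelector",
]


class RankDeficiencyError(ValueError):
    """Sample covariance is singular; data cannot be whitened."""


def _as_sample_matrix(X) -> tuple[np.ndarray, list[str]]:
    """Genes x samples frame -> (n_samples x n_genes array, gene ids)."""
    if isinstance(X, pd.DataFrame):
        return X.values.T.astype(float), [str(g) for g in X.index]
    X = np.asarray(X, dtype=float)
    return X.T, [f"G{i}" for i in range(X.shape[0])]


def whiten(X) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Whiten a genes x samples matrix across genes.

    Returns ``(whitened, K, K_inv)`` where the whitening transform K acts
    on sample-space rows: ``whitened = K @ X.T``. The covariance of the
    whitened rows (computed mean-removed over genes) is the identity, and
    K and K_inv are exact mutual inverses; the transform is applied to the
    uncentered data so that de-whitening reproduces the input exactly.
    """
    D, _ = _as_sample_matrix(X)
    n, m = D.shape
    if m <= n:
        raise ValueError(f"need more genes ({m}) than samples ({n}) to whiten")
    Dc = D - D.mean(axis=1, keepdims=True)
    cov = Dc @ Dc.T / m
    evals, evecs = np.linalg.eigh(cov)
    if evals[-1] <= 0 or evals[0] < 1e-12 * evals[-1]:
        raise RankDeficiencyError(
            "sample covariance is singular (collinear or constant samples)"
        )
    K = (evecs / np.sqrt(evals)).T  # diag(1/sqrt(l)) @ U.T
    K_inv = evecs * np.sqrt(evals)  # U @ diag(sqrt(l))
    return K @ D, K, K_inv


@dataclass
class ICAResult:
    """Square ICA decomposition of one expression matrix.

    ``sources`` rows are expression modes (unit variance, mutually
    uncorrelated on the training data); ``mixing`` maps sources back to the
    centered observations; ``demixing`` is the orthogonal rotation applied
    to the *whitened* observations; ``whitening`` maps centered
    observations to whitened ones.
    """

    mixing: np.ndarray  # A, n x n
    demixing: np.ndarray  # W, n x n (acts on whitened data)
    whitening: np.ndarray  # K, n x n
    sources: np.ndarray  # S, n x m
    gene_ids: list[str]
    row_means: np.ndarray  # per-sample means removed before whitening
    n_iters: int
    converged: bool


def _sym_decorrelate(W: np.ndarray) -> np.ndarray:
    """W <- (W W^T)^(-1/2) W, the symmetric orthogonalization."""
    evals, evecs = np.linalg.eigh(W @ W.T)
    return (evecs / np.sqrt(evals)) @ evecs.T @ W


def fastica(
    X,
    a1: float = 1.0,
    max_iter: int = 200,
    tol: float = 1e-4,
    seed: int = 0,
) -> ICAResult:
    """Fixed-point ICA with the tanh(a1*u) contrast.

    ``X`` is a genes x samples matrix; a square ICA is fitted with as many
    components as samples. Symmetric decorrelation keeps the estimated
    rotation orthogonal at every step; iteration stops when the largest
    change in any demixing row direction falls below ``tol``.
    Non-convergence within ``max_iter`` is reported through the
    ``converged`` flag, never raised.
    """
    if not 1.0 <= a1 <= 2.0:
        raise ValueError(f"a1 must lie in [1, 2], got {a1}")
    D, gene_ids = _as_sample_matrix(X)
    n, m = D.shape
    means = D.mean(axis=1, keepdims=True)
    Xc = D - means
    Xw, K, K_inv = whiten(pd.DataFrame(Xc.T))
    rng = np.random.default_rng(seed)
    W = _sym_decorrelate(rng.normal(size=(n, n)))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        Y = W @ Xw
        G = np.tanh(a1 * Y)
        Gprime = a1 * (1.0 - G**2)
        W_new = (G @ Xw.T) / m - Gprime.mean(axis=1)[:, None] * W
        W_new = _sym_decorrelate(W_new)
        # max deviation of any row direction from its previous self
        lim = float(np.max(np.abs(np.abs(np.einsum("ij,ij->i", W_new, W)) - 1.0)))
        W = W_new
        if lim < tol:
            converged = True
            break
    S = W @ Xw
    A = K_inv @ W.T  # = inv(W @ K) since W is orthogonal
    return ICAResult(
        mixing=A,
        demixing=W,
        whitening=K,
        sources=S,
        gene_ids=gene_ids,
        row_means=means.ravel(),
        n_iters=it,
        converged=converged,
    )


def amari_error(A_est: np.ndarray, A_true: np.ndarray) -> float:
    """Normalized Amari separation index in [0, 1].

    Permutation- and scale-invariant distance between an estimated and the
    true mixing matrix; 0 means perfect separation up to sign, scale and
    component order.
    """
    P = np.abs(np.linalg.pinv(A_est) @ A_true)
    n = P.shape[0]
    rows = (P.sum(axis=1) / P.max(axis=1) - 1.0).sum()
    cols = (P.sum(axis=0) / P.max(axis=0) - 1.0).sum()
    return float((rows + cols) / (2.0 * n * (n - 1)))


@dataclass
class GeneSelection:
    """Consensus gene selection over repeated ICA runs."""

    frequency: pd.Series  # per-gene count of runs in which it was flagged
    n_runs: int
    top_k: int
    min_frequency: float
    selected: list[str]

    @property
    def threshold(self) -> int:
        return math.ceil(self.min_frequency * self.n_runs)

    def to_frame(self) -> pd.DataFrame:
        sel = set(self.selected)
        return pd.DataFrame(
            {
                "frequency": self.frequency,
                "selected": [int(g in sel) for g in self.frequency.index],
            }
        )


def consensus_significant_genes(
    X,
    n_runs: int = 50,
    top_k: int = 50,
    min_frequency: float = 0.5,
    a1: float = 1.0,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-4,
) -> GeneSelection:
    """Repeated-ICA consensus selection of significant genes.

    Run r (seeded ``seed + r``) flags, for every independent component, the
    ``top_k`` genes by absolute source loading; a gene counts once per run
    no matter how many components flag it. Genes flagged in at least
    ``ceil(min_frequency * n_runs)`` runs are selected, ordered by
    decreasing frequency (ties by gene order).
    """
    if n_runs < 1 or top_k < 1:
        raise ValueError("n_runs and top_k must be >= 1")
    if not 0.0 < min_frequency <= 1.0:
        raise ValueError("min_frequency must lie in (0, 1]")
    D, gene_ids = _as_sample_matrix(X)
    m = D.shape[1]
    k = min(top_k, m)
    freq = np.zeros(m, dtype=int)
    for r in range(n_runs):
        res = fastica(X, a1=a1, max_iter=max_iter, tol=tol, seed=seed + r)
        flagged = np.zeros(m, dtype=bool)
        for row in np.abs(res.sources):
            flagged[np.argpartition(row, -k)[-k:]] = True
        freq += flagged
    frequency = pd.Series(freq, index=gene_ids, name="frequency")
    thresh = math.ceil(min_frequency * n_runs)
    hits = np.flatnonzero(freq >= thresh)
    hits = hits[np.argsort(-freq[hits], kind="stable")]
    selected = [gene_ids[i] for i in hits]
    return GeneSelection(
        frequency=frequency,
        n_runs=n_runs,
        top_k=top_k,
        min_frequency=min_frequency,
        selected=selected,
    )


class ConsensusICASelector(SelectorMixin, BaseEstimator):
    """scikit-learn feature selector around repeated-ICA consensus.

    ``fit(X)`` expects X of shape (n_samples, n_features); y is ignored
    (the selection is unsupervised).
    """

    def __init__(
        self,
        n_runs=50,
        top_k=50,
        min_frequency=0.5,
        a1=1.0,
        max_iter=200,
        tol=1e-4,
        random_state=0,
    ):
        self.n_runs = n_runs
        self.top_k = top_k
        self.min_frequency = min_frequency
        self.a1 = a1
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, X, y=None):
        if isinstance(X, pd.DataFrame):
            expr = X.T
        else:
            X = np.asarray(X, dtype=float)
            expr = pd.DataFrame(X.T, index=[f"F{i}" for i in range(X.shape[1])])
        sel = consensus_significant_genes(
            expr,
            n_runs=self.n_runs,
            top_k=self.top_k,
            min_frequency=self.min_frequency,
            a1=self.a1,
            max_iter=self.max_iter,
            tol=self.tol,
            seed=self.random_state,
        )
        self.selection_ = sel
        self.frequency_ = sel.frequency.values
        chosen = set(sel.selected)
        self.support_mask_ = np.array([g in chosen for g in expr.index])
        self.n_features_in_ = expr.shape[0]
        return self

    def _get_support_mask(self):
        return self.support_mask_
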