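"""Network component analysis: topology-constrained bilinear decomposition.

The log-linear regulatory model writes the (log-ratio) expression of gene i
in sample t as a weighted sum of latent transcription-factor activities,

    E = C P + noise,   C constrained to a prescribed zero pattern Z0,

with C (N genes x L TFs) the control strengths and P (L x M) the TF
activities. Estimation alternates two exact least-squares half-steps —
solve C row-wise on each row's support given P, then solve P given C —
which never increase the Frobenius residual (the objective is biconvex).
The decomposition is unique at best up to a per-TF scaling; results are
normalized to unit-norm control-strength columns whose largest-magnitude
entry is positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .connectivity import ConnectivityPattern, check_nca_identifiability

__all__ = [
    "NCAConfig",
    "NCAResult",
    "EmptySupportRowError",
    "MissingStageError",
    "log_ratio_transform",
    "nca_decompose",
    "normalize_factors",
    "estimate_stage_tfas",
    "NetworkComponentAnalysis",
]


class EmptySupportRowError(ValueError):
    """A gene row has no admissible regulator in the topology."""


class MissingStageError(KeyError):
    """A requested stage is absent from the supplied stage datasets."""


@dataclass
class NCAConfig:
    """Solver controls for the alternating least-squares decomposition.

    tol is the relative change of the Frobenius residual between full
    iterations below which the run stops; n_restarts random restarts are
    run and the best final residual wins.
    """

    max_iter: int = 1000
    tol: float = 1e-6
    n_restarts: int = 10
    seed: int = 0
    log_base: float = 2.0
    reference: str = "mean-of-control"  # mean-of-control | first-sample | none
    # the 1/0 pattern values are the canonical NCA starting point and
    # reliably land in the well-conditioned basin; random restarts cover
    # the cases where they do not
    init_from_c0: bool = True

    def __post_init__(self):
        if self.max_iter < 1 or self.tol <= 0 or self.n_restarts < 1:
            raise ValueError("invalid solver controls")
        if self.log_base <= 1:
            raise ValueError("log_base must be > 1")
        if self.reference not in ("mean-of-control", "first-sample", "none"):
            raise ValueError(f"unknown reference policy {self.reference!r}")


@dataclass
class NCAResult:
    """Estimated control strengths and TF activities for one dataset."""

    cs: pd.DataFrame  # N x L, exactly zero off the support
    tfa: pd.DataFrame  # L x M
    residual_trace: list[float]  # Frobenius residual after each half-step
    final_residual: float
    restart_chosen: int
    converged: bool
    n_iter: int
    identifiability: dict | None = field(default=None)


def log_ratio_transform(
    expr_raw: pd.DataFrame, reference, log_base: float = 2.0
) -> pd.DataFrame:
    """Log-ratio transform: log_base(expr[i, t] / reference[i]).

    Linearizes the multiplicative regulation model; all raw values and
    per-gene references must be strictly positive.
    """
    ref = pd.Series(reference, index=expr_raw.index) if not isinstance(
        reference, pd.Series
    ) else reference.reindex(expr_raw.index)
    if ref.isna().any():
        raise ValueError("reference missing for some genes")
    bad_ref = ref[ref <= 0]
    if len(bad_ref):
        raise ValueError(f"nonpositive reference for gene {bad_ref.index[0]}")
    vals = expr_raw.values.astype(float)
    if (vals <= 0).any():
        i, t = np.argwhere(vals <= 0)[0]
        raise ValueError(
            f"nonpositive expression for gene {expr_raw.index[i]} "
            f"in sample {expr_raw.columns[t]}"
        )
    out = np.log(vals / ref.values[:, None]) / np.log(log_base)
    return pd.DataFrame(out, index=expr_raw.index, columns=expr_raw.columns)


def _solve_c(E: np.ndarray, P: np.ndarray, support: np.ndarray) -> np.ndarray:
    """Row-wise least squares for C with exact structural zeros."""
    N, L = support.shape
    C = np.zeros((N, L))
    for i in range(N):
        idx = np.flatnonzero(support[i])
        sol, *_ = np.linalg.lstsq(P[idx, :].T, E[i, :], rcond=None)
        C[i, idx] = sol
    return C


def normalize_factors(
    C: np.ndarray, P: np.ndarray, eps: float = 1e-12
) -> tuple[np.ndarray, np.ndarray]:
    """Fix the diagonal scale/sign ambiguity of a (C, P) pair.

    Each column of C is scaled to unit L2 norm with its largest-magnitude
    entry positive; the corresponding row of P absorbs the inverse factor,
    leaving the product C @ P unchanged.
    """
    C = C.copy()
    P = P.copy()
    for j in range(C.shape[1]):
        nrm = np.linalg.norm(C[:, j])
        if nrm <= eps:
            warnings.warn(f"column {j} of the control-strength matrix is zero")
            continue
        sign = np.sign(C[np.argmax(np.abs(C[:, j])), j]) or 1.0
        C[:, j] /= nrm * sign
        P[j, :] *= nrm * sign
    return C, P


def nca_decompose(
    E: pd.DataFrame | np.ndarray,
    pattern: ConnectivityPattern,
    config: NCAConfig | None = None,
    init_tfa: np.ndarray | None = None,
) -> NCAResult:
    """Constrained alternating least squares for E ~ C P, C in Z0.

    Rows of ``E`` must align with ``pattern.genes`` (a DataFrame is
    reindexed to the pattern's gene order). Activities are initialized
    i.i.d. standard normal per restart; with ``config.init_from_c0`` the
    first restart instead starts from the pattern's 1/0 initial values.
    The best restart by final residual is normalized and returned;
    divergence of every restart is reported via ``converged=False``.
    """
    config = config or NCAConfig()
    if isinstance(E, pd.DataFrame):
        missing = [g for g in pattern.genes if g not in E.index]
        if missing:
            raise ValueError(f"expression missing pattern genes: {missing[:5]}")
        Em = E.loc[pattern.genes].values.astype(float)
        sample_ids = [str(c) for c in E.columns]
    else:
        Em = np.asarray(E, dtype=float)
        sample_ids = [f"S{k + 1:02d}" for k in range(Em.shape[1])]
    N, L = pattern.support.shape
    if Em.shape[0] != N:
        raise ValueError("expression rows do not match pattern genes")
    M = Em.shape[1]
    support = pattern.support.astype(bool)
    empty = np.flatnonzero(~support.any(axis=1))
    if empty.size:
        raise EmptySupportRowError(
            f"genes with empty support: {[pattern.genes[i] for i in empty]}"
        )

    report = check_nca_identifiability(pattern, n_samples=M)
    if not report.overall:
        warnings.warn(
            "topology/sample configuration fails the NCA uniqueness criteria "
            f"(full_column_rank={report.full_column_rank}, "
            f"samples_sufficient={report.samples_sufficient}); the solution "
            "is not guaranteed unique up to scaling"
        )

    best = None
    for r in range(config.n_restarts):
        rng = np.random.default_rng(config.seed + r)
        trace: list[float] = []
        if init_tfa is not None and r == 0:
            P0 = np.asarray(init_tfa, dtype=float)
            if P0.shape != (L, M):
                raise ValueError("init_tfa must be L x M")
            C = _solve_c(Em, P0, pattern.support)
            trace.append(float(np.linalg.norm(Em - C @ P0)))
        elif config.init_from_c0 and r == 0:
            C = pattern.initial_values.astype(float).copy()
        else:
            P0 = rng.standard_normal((L, M))
            C = _solve_c(Em, P0, pattern.support)
            trace.append(float(np.linalg.norm(Em - C @ P0)))
        if np.linalg.matrix_rank(C) < L:
            warnings.warn("rank-deficient control-strength matrix during ALS")
        prev = np.inf
        converged = False
        n_iter = 0
        P = None
        for n_iter in range(1, config.max_iter + 1):
            P, *_ = np.linalg.lstsq(C, Em, rcond=None)
            trace.append(float(np.linalg.norm(Em - C @ P)))
            C = _solve_c(Em, P, pattern.support)
            resid = float(np.linalg.norm(Em - C @ P))
            trace.append(resid)
            # relative residual change, with an absolute floor for the
            # (near-)exact case where the relative metric is all roundoff
            if (
                abs(prev - resid) / max(prev, 1e-30) < config.tol
                or resid < 1e-12 * max(1.0, float(np.linalg.norm(Em)))
            ):
                converged = True
                break
            prev = resid
        P, *_ = np.linalg.lstsq(C, Em, rcond=None)
        final = float(np.linalg.norm(Em - C @ P))
        trace.append(final)
        if best is None or final < best[0]:
            best = (final, C, P, trace, r, converged, n_iter)

    final, C, P, trace, chosen, converged, n_iter = best
    C, P = normalize_factors(C, P)
    return NCAResult(
        cs=pd.DataFrame(C, index=pattern.genes, columns=pattern.tfs),
        tfa=pd.DataFrame(P, index=pattern.tfs, columns=sample_ids),
        residual_trace=trace,
        final_residual=final,
        restart_chosen=chosen,
        converged=converged,
        n_iter=n_iter,
        identifiability=report.to_dict(),
    )


def estimate_stage_tfas(
    stage_datasets: Mapping[str, pd.DataFrame],
    pattern: ConnectivityPattern,
    config: NCAConfig | None = None,
    stages: list[str] | None = None,
) -> tuple[dict[str, NCAResult], pd.DataFrame]:
    """Decompose each stage dataset and build a TF x stage trajectory table.

    One decomposition per stage; the first stage (normally the control) is
    the sign reference — each TF's control-strength column in a later stage
    is flipped when its dot product with the reference column is negative,
    so activity trajectories are comparable across stages. The trajectory
    value is the stage-mean activity of each TF.
    """
    config = config or NCAConfig()
    if stages is None:
        stages = list(stage_datasets)
    missing = [s for s in stages if s not in stage_datasets]
    if missing:
        raise MissingStageError(f"stage datasets missing: {missing}")
    results: dict[str, NCAResult] = {}
    ref_cs = None
    for stage in stages:
        res = nca_decompose(stage_datasets[stage], pattern, config)
        if ref_cs is None:
            ref_cs = res.cs.values
        else:
            C = res.cs.values.copy()
            P = res.tfa.values.copy()
            for j in range(C.shape[1]):
                if C[:, j] @ ref_cs[:, j] < 0:
                    C[:, j] *= -1.0
                    P[j, :] *= -1.0
            res.cs.iloc[:, :] = C
            res.tfa.iloc[:, :] = P
        results[stage] = res
    trajectory = pd.DataFrame(
        {stage: results[stage].tfa.mean(axis=1) for stage in stages},
        index=pattern.tfs,
    )
    trajectory.index.name = "tf"
    return results, trajectory


class NetworkComponentAnalysis(TransformerMixin, BaseEstimator):
    """scikit-learn estimator for topology-constrained decomposition.

    Parameters mirror :class:`NCAConfig`; ``pattern`` fixes the admissible
    zero pattern of the control-strength matrix. ``fit(X)`` expects X of
    shape (n_samples, n_genes) with genes ordered as ``pattern.genes``
    (or a DataFrame whose columns name them). After fitting:

    - ``cs_`` — genes x TFs control strengths (unit-norm columns);
    - ``tfa_`` — TFs x samples activities of the training samples;
    - ``residual_trace_``, ``final_residual_``, ``converged_``, ``n_iter_``,
      ``restart_chosen_``.

    ``transform(X)`` projects new samples onto the fitted control
    strengths by least squares, returning per-sample TF activities.
    """

    def __init__(
        self,
        pattern: ConnectivityPattern = None,
        max_iter: int = 1000,
        tol: float = 1e-6,
        n_restarts: int = 10,
        random_state: int = 0,
        init_from_c0: bool = True,
    ):
        self.pattern = pattern
        self.max_iter = max_iter
        self.tol = tol
        self.n_restarts = n_restarts
        self.random_state = random_state
        self.init_from_c0 = init_from_c0

    def _config(self) -> NCAConfig:
        return NCAConfig(
            max_iter=self.max_iter,
            tol=self.tol,
            n_restarts=self.n_restarts,
            seed=self.random_state,
            init_from_c0=self.init_from_c0,
        )

    def _to_expr(self, X) -> pd.DataFrame:
        if self.pattern is None:
            raise ValueError("a ConnectivityPattern is required")
        if isinstance(X, pd.DataFrame):
            return X.T
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.pattern.n_genes:
            raise ValueError(
                f"X has {X.shape[1]} features, pattern names "
                f"{self.pattern.n_genes} genes"
            )
        return pd.DataFrame(X.T, index=self.pattern.genes)

    def fit(self, X, y=None):
        expr = self._to_expr(X)
        res = nca_decompose(expr, self.pattern, self._config())
        self.result_ = res
        self.cs_ = res.cs
        self.tfa_ = res.tfa
        self.residual_trace_ = res.residual_trace
        self.final_residual_ = res.final_residual
        self.converged_ = res.converged
        self.n_iter_ = res.n_iter
        self.restart_chosen_ = res.restart_chosen
        self.n_features_in_ = expr.shape[0]
        return self

    def transform(self, X):
        expr = self._to_expr(X)
        P, *_ = np.linalg.lstsq(
            self.cs_.values, expr.loc[self.pattern.genes].values, rcond=None
        )
        return P.T

    def fit_transform(self, X, y=None):
        self.fit(X)
        return self.tfa_.values.T
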