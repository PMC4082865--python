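"""Sample normalization and the SAM two-class significance filter.

SAM (significance analysis of microarrays) scores each gene with a
moderated t-like statistic

    d_i = (mean2_i - mean1_i) / (s_i + s0)

where s_i is the pooled two-sample standard error and s0 a small positive
"fudge" constant that damps genes with tiny variances. Significance is
judged by comparing the ordered observed statistics against the mean
ordered statistics of a label-permutation null, and the false discovery
rate is estimated from the median permutation exceedance count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin

__all__ = [
    "ConstantSampleError",
    "SamResult",
    "normalize_samples",
    "sam_statistic",
    "sam_select",
    "SAMSelector",
]


class ConstantSampleError(ValueError):
    """A sample (column) is constant and cannot be standardized."""


def normalize_samples(expr: pd.DataFrame) -> pd.DataFrame:
    """Standardize each sample (column) to zero mean, unit SD.

    Uses the population standard-deviation convention (divide by n).
    """
    values = expr.values.astype(float)
    mean = values.mean(axis=0)
    sd = values.std(axis=0)  # ddof=0
    bad = np.flatnonzero(sd < 1e-12)
    if bad.size:
        raise ConstantSampleError(
            f"constant sample(s): {[str(expr.columns[b]) for b in bad]}"
        )
    return pd.DataFrame(
        (values - mean) / sd, index=expr.index, columns=expr.columns
    )


def _two_classes(labels) -> tuple[np.ndarray, list]:
    labels = np.asarray(pd.Series(labels).values)
    classes = sorted(pd.unique(labels).tolist())
    if len(classes) != 2:
        raise ValueError(f"expected exactly two classes, got {classes}")
    counts = [(labels == c).sum() for c in classes]
    if min(counts) < 2:
        raise ValueError("each class needs at least two samples")
    return labels, classes


def _d_components(values: np.ndarray, member2: np.ndarray):
    """Mean difference (class2 - class1) and pooled standard error s_i."""
    x2 = values[:, member2]
    x1 = values[:, ~member2]
    n1, n2 = x1.shape[1], x2.shape[1]
    diff = x2.mean(axis=1) - x1.mean(axis=1)
    ss = ((x1 - x1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (x2 - x2.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s = np.sqrt((1.0 / n1 + 1.0 / n2) * ss / (n1 + n2 - 2))
    return diff, s


def _auto_s0(diff: np.ndarray, s: np.ndarray) -> float:
    """Pick s0 minimizing the coefficient of variation of |d| over a
    percentile grid of the per-gene standard errors."""
    candidates = np.percentile(s, np.arange(0, 101, 5))
    best_s0, best_cv = float(candidates[0]), np.inf
    for cand in candidates:
        d = np.abs(diff / (s + cand))
        m = d.mean()
        if m <= 0:
            continue
        cv = d.std() / m
        if cv < best_cv:
            best_cv, best_s0 = cv, float(cand)
    return best_s0


def sam_statistic(
    expr: pd.DataFrame, labels, s0: float | str = "auto"
) -> tuple[pd.Series, float]:
    """Per-gene SAM d statistic for a two-class comparison.

    ``labels`` assigns each column of ``expr`` to one of two classes;
    the difference is class2 - class1 with classes in sorted label order.
    ``s0="auto"`` resolves the fudge factor by the percentile-grid
    coefficient-of-variation rule. Returns (d values, resolved s0).
    """
    labels, classes = _two_classes(labels)
    if len(labels) != expr.shape[1]:
        raise ValueError("labels must align with expression columns")
    member2 = labels == classes[1]
    diff, s = _d_components(expr.values.astype(float), member2)
    s0v = _auto_s0(diff, s) if isinstance(s0, str) else float(s0)
    if s0v < 0:
        raise ValueError("s0 must be nonnegative")
    d = diff / (s + s0v)
    return pd.Series(d, index=expr.index, name="d"), s0v


@dataclass
class SamResult:
    """Outcome of a SAM selection run."""

    d_values: pd.Series
    s0: float
    perm_d: np.ndarray  # n_perms x n_genes, each row sorted ascending
    delta: float
    selected: list[str]
    est_fdr: float

    @property
    def n_selected(self) -> int:
        return len(self.selected)

    def to_frame(self) -> pd.DataFrame:
        sel = set(self.selected)
        return pd.DataFrame(
            {
                "d": self.d_values,
                "selected": [int(g in sel) for g in self.d_values.index],
            }
        )


def _fdr_at(perm_d: np.ndarray, dbar: np.ndarray, delta: float, n_sel: int) -> float:
    if n_sel == 0:
        return 0.0
    exceed = (np.abs(perm_d - dbar) >= delta).sum(axis=1)
    return float(np.clip(np.median(exceed) / n_sel, 0.0, 1.0))


def sam_select(
    expr: pd.DataFrame,
    labels,
    delta: float | None = None,
    target_n: int | None = None,
    target_fdr: float | None = None,
    n_perms: int = 200,
    s0: float | str = "auto",
    seed: int = 0,
) -> SamResult:
    """Select significant genes by the SAM order-statistic rule.

    The permutation null shuffles the class labels ``n_perms`` times; a
    gene at sorted position i is selected when its observed order statistic
    deviates from the mean null order statistic by at least ``delta``.
    Exactly one of ``delta``, ``target_n`` (threshold tuned so the selection
    size is as close as possible to the target) or ``target_fdr`` (smallest
    delta whose estimated FDR is below the target) must be given.
    """
    if n_perms < 10:
        raise ValueError("n_perms must be >= 10")
    given = [x is not None for x in (delta, target_n, target_fdr)]
    if sum(given) != 1:
        raise ValueError("specify exactly one of delta, target_n, target_fdr")
    n_genes = expr.shape[0]
    if target_n is not None and target_n > n_genes:
        raise ValueError(f"target_n={target_n} exceeds gene count {n_genes}")

    d, s0v = sam_statistic(expr, labels, s0=s0)
    lab_arr, classes = _two_classes(labels)
    values = expr.values.astype(float)
    rng = np.random.default_rng(seed)
    perm_d = np.empty((n_perms, n_genes))
    for b in range(n_perms):
        perm = rng.permutation(lab_arr)
        diff_b, s_b = _d_components(values, perm == classes[1])
        perm_d[b] = np.sort(diff_b / (s_b + s0v))
    dbar = perm_d.mean(axis=0)

    order = np.argsort(d.values, kind="stable")
    dev = d.values[order] - dbar  # per sorted position
    absdev = np.abs(dev)

    if target_n is not None:
        if target_n >= n_genes:
            delta = 0.0
        else:
            desc = np.sort(absdev)[::-1]
            delta = float((desc[target_n - 1] + desc[target_n]) / 2.0)
    elif target_fdr is not None:
        cands = np.unique(absdev)
        delta = float(absdev.max()) + 1.0  # fallback: select nothing
        for cand in cands:
            n_sel = int((absdev >= cand).sum())
            if _fdr_at(perm_d, dbar, float(cand), n_sel) <= target_fdr:
                delta = float(cand)
                break
    delta = float(delta)

    sel_pos = np.flatnonzero(absdev >= delta)
    # order selected genes by decreasing deviation from the null
    sel_pos = sel_pos[np.argsort(-absdev[sel_pos], kind="stable")]
    selected = [str(expr.index[order[p]]) for p in sel_pos]
    est_fdr = _fdr_at(perm_d, dbar, delta, len(selected))
    return SamResult(
        d_values=d, s0=s0v, perm_d=perm_d, delta=delta,
        selected=selected, est_fdr=est_fdr,
    )


class SAMSelector(SelectorMixin, BaseEstimator):
    """scikit-learn feature selector wrapping :func:`sam_select`.

    Parameters
    ----------
    delta, target_n, target_fdr : exactly one selection rule (see
        :func:`sam_select`); ``target_fdr=0.05`` is the default rule.
    n_perms : number of label permutations for the null.
    s0 : fudge factor, or "auto" for the percentile-grid tuner.
    random_state : permutation seed.

    ``fit(X, y)`` expects X of shape (n_samples, n_features) and a
    two-class y, the scikit-learn orientation (samples in rows).
    """

    def __init__(
        self,
        delta=None,
        target_n=None,
        target_fdr=None,
        n_perms=200,
        s0="auto",
        random_state=0,
    ):
        self.delta = delta
        self.target_n = target_n
        self.target_fdr = target_fdr
        self.n_perms = n_perms
        self.s0 = s0
        self.random_state = random_state

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            expr = X.T
        else:
            X = np.asarray(X, dtype=float)
            expr = pd.DataFrame(
                X.T, index=[f"F{i}" for i in range(X.shape[1])]
            )
        delta, target_n, target_fdr = self.delta, self.target_n, self.target_fdr
        if delta is None and target_n is None and target_fdr is None:
            target_fdr = 0.05
        res = sam_select(
            expr, y, delta=delta, target_n=target_n, target_fdr=target_fdr,
            n_perms=self.n_perms, s0=self.s0, seed=self.random_state,
        )
        self.result_ = res
        self.d_values_ = res.d_values.values
        self.s0_ = res.s0
        self.delta_ = res.delta
        self.est_fdr_ = res.est_fdr
        sel = set(res.selected)
        self.support_mask_ = np.array([g in sel for g in expr.index])
        self.n_features_in_ = expr.shape[0]
        return self

    def _get_support_mask(self):
        return self.support_mask_
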