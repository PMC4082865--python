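"""Synthetic data generators with known ground truth.

Three generators cover the three statistical models the pipeline rests on:

* a bilinear regulatory model E = C.P + noise on a known sparse topology,
  for testing topology-constrained decomposition by parameter recovery;
* multi-stage expression with planted differentially expressed genes, for
  testing the significance filter and consensus gene selection;
* linear mixtures of independent super-Gaussian (Laplace) sources, for
  testing blind source separation.

Every generator is a pure function of its arguments including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectivity import ConnectivityPattern, check_nca_identifiability

__all__ = [
    "STAGES",
    "StageDesign",
    "SyntheticRegulatoryDataset",
    "TopologyConstructionError",
    "make_identifiable_topology",
    "generate_regulatory_dataset",
    "generate_stage_dataset",
    "generate_ica_mixtures",
]

#: Canonical disease-course stage labels, ordered by severity.
STAGES = ("control", "incipient", "moderate", "severe")


class TopologyConstructionError(RuntimeError):
    """No identifiable topology could be constructed for the parameters."""


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i + 1:0{width}d}" for i in range(n)]


def _tf_ids(n: int) -> list[str]:
    return [f"TF{j + 1:02d}" for j in range(n)]


def _sample_ids(n: int, prefix: str = "S") -> list[str]:
    return [f"{prefix}{k + 1:02d}" for k in range(n)]


@dataclass
class StageDesign:
    """Multi-stage study layout with planted differential expression.

    ``effect_size`` is the mean log-expression shift of planted genes in
    every non-reference stage (the first stage is the reference/control).
    """

    stages: tuple[str, ...] = STAGES
    samples_per_stage: tuple[int, ...] = (9, 7, 8, 7)
    planted_de_genes: frozenset[str] = frozenset()
    effect_size: float = 2.0

    def __post_init__(self):
        self.stages = tuple(self.stages)
        self.samples_per_stage = tuple(int(m) for m in self.samples_per_stage)
        self.planted_de_genes = frozenset(str(g) for g in self.planted_de_genes)
        if len(set(self.stages)) != len(self.stages):
            raise ValueError("stage labels must be unique")
        if len(self.samples_per_stage) != len(self.stages):
            raise ValueError("samples_per_stage must align with stages")
        if any(m < 1 for m in self.samples_per_stage):
            raise ValueError("each stage needs at least one sample")


@dataclass
class SyntheticRegulatoryDataset:
    """Bilinear regulatory dataset with ground-truth factors.

    ``expression`` (N genes x M samples, log scale) equals
    ``true_cs @ true_tfa`` plus i.i.d. Gaussian noise of standard deviation
    ``noise_sd``; ``true_cs`` is exactly zero off the topology support.
    """

    expression: pd.DataFrame
    true_cs: np.ndarray
    true_tfa: np.ndarray
    topology: ConnectivityPattern
    noise_sd: float
    seed: int
    stage_means: np.ndarray | None = field(default=None)

    def __post_init__(self):
        N, L = self.true_cs.shape
        L2, M = self.true_tfa.shape
        if L != L2 or self.expression.shape != (N, M):
            raise ValueError("inconsistent dataset dimensions")
        if ((self.true_cs != 0) & (self.topology.support == 0)).any():
            raise ValueError("true_cs nonzero outside the topology support")


def make_identifiable_topology(
    n_genes: int,
    n_tfs: int,
    targets_per_tf: int,
    seed: int = 0,
    max_retries: int = 50,
) -> ConnectivityPattern:
    """Construct a random 0/1 topology satisfying the NCA uniqueness criteria.

    Each TF receives two private targets (genes regulated by no other TF),
    which guarantees full column rank and the reduced-rank criterion, plus
    ``targets_per_tf - 2`` shared targets drawn from the remaining genes.
    The construction is verified with :func:`check_nca_identifiability` and
    retried with fresh assignments until it passes or the retry cap is hit.
    """
    if targets_per_tf < 2:
        raise ValueError("targets_per_tf must be >= 2")
    if n_genes < 2 * n_tfs:
        raise TopologyConstructionError(
            f"cannot place {n_tfs} TFs with 2 private targets each "
            f"in {n_genes} genes"
        )
    n_shared_pool = n_genes - 2 * n_tfs
    if n_tfs > 1 and targets_per_tf - 2 > n_shared_pool:
        raise TopologyConstructionError(
            f"targets_per_tf={targets_per_tf} needs {targets_per_tf - 2} shared "
            f"targets but only {n_shared_pool} non-private genes exist"
        )
    if n_tfs == 1 and targets_per_tf > n_genes:
        raise TopologyConstructionError("more targets requested than genes")

    genes = _gene_ids(n_genes)
    tfs = _tf_ids(n_tfs)
    rng = np.random.default_rng(seed)
    for attempt in range(max_retries):
        support = np.zeros((n_genes, n_tfs), dtype=np.int8)
        for j in range(n_tfs):
            support[2 * j, j] = 1
            support[2 * j + 1, j] = 1
            n_extra = targets_per_tf - 2
            if n_extra > 0:
                if n_tfs == 1:
                    pool = np.arange(2, n_genes)
                else:
                    pool = np.arange(2 * n_tfs, n_genes)
                extra = rng.choice(pool, size=n_extra, replace=False)
                support[extra, j] = 1
        pattern = ConnectivityPattern(genes=genes, tfs=tfs, support=support)
        report = check_nca_identifiability(pattern, n_samples=n_tfs)
        if report.full_column_rank and all(report.reduced_rank_ok.values()):
            return pattern
    raise TopologyConstructionError(
        f"no identifiable topology found in {max_retries} attempts"
    )


def generate_regulatory_dataset(
    topology: ConnectivityPattern,
    n_samples: int,
    cs_scale: float = 1.0,
    tfa_scale: float = 1.0,
    noise_sd: float = 0.1,
    seed: int = 0,
    tfa_means: np.ndarray | None = None,
) -> SyntheticRegulatoryDataset:
    """Draw a dataset from the bilinear model E = C.P + noise.

    Control-strength magnitudes are uniform on [0.5, 1.5] * cs_scale with
    independent random signs (bounded away from zero so recovery is
    well-posed); activities are i.i.d. normal(mean, tfa_scale^2), with
    optional per-TF means ``tfa_means`` (length L) for planted trends.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if topology.support.sum() == 0:
        raise ValueError("topology has empty support")
    rng = np.random.default_rng(seed)
    N, L = topology.support.shape
    mags = rng.uniform(0.5, 1.5, size=(N, L)) * cs_scale
    signs = rng.choice((-1.0, 1.0), size=(N, L))
    true_cs = topology.support * mags * signs
    means = np.zeros(L) if tfa_means is None else np.asarray(tfa_means, dtype=float)
    true_tfa = means[:, None] + rng.normal(0.0, tfa_scale, size=(L, n_samples))
    expr = true_cs @ true_tfa
    if noise_sd > 0:
        expr = expr + rng.normal(0.0, noise_sd, size=expr.shape)
    expression = pd.DataFrame(
        expr, index=topology.genes, columns=_sample_ids(n_samples)
    )
    return SyntheticRegulatoryDataset(
        expression=expression,
        true_cs=true_cs,
        true_tfa=true_tfa,
        topology=topology,
        noise_sd=float(noise_sd),
        seed=int(seed),
    )


def generate_stage_dataset(
    design: StageDesign,
    n_genes: int,
    base_sd: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Generate multi-stage expression with planted DE genes.

    Every gene g has a fixed baseline mu_g ~ N(0, 1); samples add i.i.d.
    N(0, base_sd^2) noise. Planted genes are shifted by ``effect_size`` in
    every non-reference stage; all other genes are identically distributed
    across stages. Returns the expression matrix and per-sample stage
    labels aligned with its columns.
    """
    genes = _gene_ids(n_genes)
    unknown = design.planted_de_genes - set(genes)
    if unknown:
        raise ValueError(f"planted genes not in the gene universe: {sorted(unknown)}")
    if n_genes <= len(design.planted_de_genes):
        raise ValueError("need more genes than planted DE genes")
    rng = np.random.default_rng(seed)
    baseline = rng.normal(0.0, 1.0, size=n_genes)
    planted_mask = np.array([g in design.planted_de_genes for g in genes])

    cols, labels, blocks = [], [], []
    for stage, m in zip(design.stages, design.samples_per_stage):
        block = baseline[:, None] + rng.normal(0.0, base_sd, size=(n_genes, m))
        if stage != design.stages[0]:
            block[planted_mask, :] += design.effect_size
        blocks.append(block)
        cols.extend(f"{stage}_{k + 1:02d}" for k in range(m))
        labels.extend([stage] * m)
    expr = pd.DataFrame(np.hstack(blocks), index=genes, columns=cols)
    return expr, pd.Series(labels, index=cols, name="stage")


def generate_ica_mixtures(
    n_sources: int,
    n_genes: int,
    seed: int = 0,
    mixing: np.ndarray | None = None,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Linear mixtures X = A.S of independent unit-variance Laplace sources.

    Laplace sources are super-Gaussian, matching the tanh contrast used by
    the fixed-point separation algorithm. The square mixing matrix is drawn
    with singular values uniform on [1, 3] (condition number <= 3, well
    inside the <= 100 contract) unless one is supplied. Returns the
    observations as a genes x samples frame (column k = mixture k), the
    mixing matrix and the source matrix (n_sources x n_genes).
    """
    if n_sources < 2:
        raise ValueError("n_sources must be >= 2")
    rng = np.random.default_rng(seed)
    # Laplace(0, b) has variance 2 b^2 -> b = 1/sqrt(2) gives unit variance.
    S = rng.laplace(0.0, 1.0 / np.sqrt(2.0), size=(n_sources, n_genes))
    if mixing is None:
        U, _ = np.linalg.qr(rng.normal(size=(n_sources, n_sources)))
        V, _ = np.linalg.qr(rng.normal(size=(n_sources, n_sources)))
        svals = rng.uniform(1.0, 3.0, size=n_sources)
        A = U @ np.diag(svals) @ V.T
    else:
        A = np.asarray(mixing, dtype=float)
        if A.shape != (n_sources, n_sources):
            raise ValueError("mixing must be square n_sources x n_sources")
    X = A @ S  # samples x genes
    expression = pd.DataFrame(
        X.T, index=_gene_ids(n_genes), columns=_sample_ids(n_sources, prefix="M")
    )
    return expression, A, S
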