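"""TF-target connectivity: interaction tables, the initial connectivity
matrix C0, and the NCA identifiability (uniqueness) criteria.

Network component analysis decomposes an expression matrix [E] as
[C][P] with the zero pattern of [C] fixed to a known regulatory topology
Z0. The decomposition is unique up to a per-TF diagonal scaling only when
(i) C has full column rank, (ii) deleting any one TF's column together
with the rows of its targets leaves a pattern of rank L-1, and
(iii) P has full row rank, which requires at least as many samples as TFs.
This module builds Z0/C0 from curated TF->target tables and evaluates the
three criteria.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "RegulatoryInteraction",
    "ConnectivityPattern",
    "IdentifiabilityReport",
    "InteractionParseError",
    "bundled_interaction_table",
    "read_interaction_table",
    "write_interaction_table",
    "match_tfs_to_genes",
    "select_top_tfs",
    "build_initial_connectivity",
    "check_nca_identifiability",
]


class InteractionParseError(ValueError):
    """Raised when an interaction table cannot be parsed."""


@dataclass(frozen=True)
class RegulatoryInteraction:
    """A single TF -> target-gene regulatory interaction."""

    tf: str
    target: str
    source_row: str | None = None

    def __post_init__(self):
        if not self.tf or not self.target:
            raise ValueError("tf and target symbols must be non-empty")


@dataclass
class ConnectivityPattern:
    """Sparse 0/1 genes x TFs topology Z0 with initial values C0.

    ``support`` is the admissible zero pattern: entry (i, j) is 1 iff TF j
    is allowed to regulate gene i. ``initial_values`` carries the starting
    control strengths (1 on the support, 0 elsewhere, at construction).
    """

    genes: list[str]
    tfs: list[str]
    support: np.ndarray
    initial_values: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.support = np.asarray(self.support)
        if self.support.shape != (len(self.genes), len(self.tfs)):
            raise ValueError("support shape does not match gene/TF lists")
        if not np.isin(self.support, (0, 1)).all():
            raise ValueError("support must be a 0/1 matrix")
        self.support = self.support.astype(np.int8)
        if self.initial_values is None:
            self.initial_values = self.support.astype(float)
        else:
            self.initial_values = np.asarray(self.initial_values, dtype=float)
            if self.initial_values.shape != self.support.shape:
                raise ValueError("initial_values shape mismatch")
            if ((self.initial_values != 0) & (self.support == 0)).any():
                raise ValueError("initial_values nonzero outside the support")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_tfs(self) -> int:
        return len(self.tfs)

    def regulated(self) -> "ConnectivityPattern":
        """Sub-pattern keeping only genes with at least one regulator.

        Dropping all-zero rows changes no column rank, so identifiability
        is preserved; decomposition requires every retained gene to have a
        nonempty support row.
        """
        keep = self.support.any(axis=1)
        return ConnectivityPattern(
            genes=[g for g, k in zip(self.genes, keep) if k],
            tfs=list(self.tfs),
            support=self.support[keep],
            initial_values=self.initial_values[keep],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.support, index=self.genes, columns=self.tfs)

    def write(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(path, sep="\t", index_label="gene")

    @classmethod
    def read(cls, path: str | Path) -> "ConnectivityPattern":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            genes=[str(g) for g in df.index],
            tfs=[str(t) for t in df.columns],
            support=df.values,
        )


@dataclass
class IdentifiabilityReport:
    """Outcome of the three NCA uniqueness criteria on a topology."""

    full_column_rank: bool
    reduced_rank_ok: dict[str, bool]
    samples_sufficient: bool
    n_tfs: int
    n_samples: int

    @property
    def overall(self) -> bool:
        return (
            self.full_column_rank
            and all(self.reduced_rank_ok.values())
            and self.samples_sufficient
        )

    def to_dict(self) -> dict:
        return {
            "full_column_rank": bool(self.full_column_rank),
            "reduced_rank_ok": {k: bool(v) for k, v in self.reduced_rank_ok.items()},
            "samples_sufficient": bool(self.samples_sufficient),
            "n_tfs": int(self.n_tfs),
            "n_samples": int(self.n_samples),
            "overall": bool(self.overall),
        }


def bundled_interaction_table() -> Path:
    """Path to the packaged curated TF->target table (TRANSFAC-derived
    interactions for the ten hippocampal TFs used in the worked example)."""
    return Path(resources.files("ncanet").joinpath("data/ad_tf_targets.tsv"))


def _parse_target_list(raw: str) -> list[str]:
    targets = []
    for tok in raw.split(","):
        tok = tok.strip()
        if tok.lower().startswith("and "):
            tok = tok[4:].strip()
        if tok:
            targets.append(tok.upper())
    return targets


def read_interaction_table(path: str | Path) -> list[RegulatoryInteraction]:
    """Parse a TF-target interaction table.

    Two layouts are accepted:

    * long format — two or more tab-separated columns, first two being
      (tf, target), one interaction per row, optional header ``tf\ttarget``;
    * wide format — one row per TF with a comma-separated target-gene list
      (column 4) and free-text description/location columns, the layout of
      curated promoter tables. A trailing "and" before the final target is
      stripped.

    Symbols are uppercased; duplicate (tf, target) pairs are collapsed with
    a warning.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    rows = [ln for ln in lines if ln.strip()]
    if not rows:
        raise InteractionParseError(f"{path}: empty interaction table")

    header = rows[0].split("\t")
    wide = len(header) >= 4 and any("target" in h.lower() for h in header)
    seen: dict[tuple[str, str], int] = {}
    out: list[RegulatoryInteraction] = []

    def add(tf: str, target: str, source_row: str | None, lineno: int):
        key = (tf, target)
        if key in seen:
            warnings.warn(
                f"{path}:{lineno}: duplicate interaction {tf}->{target} collapsed"
            )
            return
        seen[key] = lineno
        out.append(RegulatoryInteraction(tf, target, source_row))

    if wide:
        for lineno, ln in enumerate(rows[1:], start=2):
            cols = ln.split("\t")
            if len(cols) < 4:
                raise InteractionParseError(
                    f"{path}:{lineno}: expected >=4 tab-separated columns"
                )
            tf = cols[0].strip().upper()
            if not tf:
                raise InteractionParseError(f"{path}:{lineno}: empty TF symbol")
            desc = " | ".join(c.strip() for c in cols[1:3])
            targets = _parse_target_list(cols[3])
            if not targets:
                raise InteractionParseError(
                    f"{path}:{lineno}: TF {tf} has no parseable targets"
                )
            if len(cols) >= 5 and cols[4].strip():
                try:
                    declared = int(cols[4].strip())
                except ValueError:
                    declared = None
                if declared is not None and declared != len(targets):
                    warnings.warn(
                        f"{path}:{lineno}: declared target count {declared} != "
                        f"parsed {len(targets)} for {tf}"
                    )
            for t in targets:
                add(tf, t, desc, lineno)
    else:
        start = 0
        first = rows[0].split("\t")
        if first[0].strip().lower() == "tf":
            start = 1
        for lineno, ln in enumerate(rows[start:], start=start + 1):
            cols = ln.split("\t")
            if len(cols) < 2:
                raise InteractionParseError(
                    f"{path}:{lineno}: expected at least two columns (tf, target)"
                )
            tf, target = cols[0].strip().upper(), cols[1].strip().upper()
            if not tf or not target:
                raise InteractionParseError(f"{path}:{lineno}: empty symbol")
            extra = cols[2].strip() if len(cols) > 2 and cols[2].strip() else None
            add(tf, target, extra, lineno)

    if not out:
        raise InteractionParseError(f"{path}: no interactions parsed")
    return out


def write_interaction_table(
    interactions: list[RegulatoryInteraction], path: str | Path
) -> None:
    """Write interactions in long format (lossless round-trip)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        fh.write("tf\ttarget\n")
        for it in interactions:
            fh.write(f"{it.tf}\t{it.target}\n")


def match_tfs_to_genes(
    interactions: list[RegulatoryInteraction], selected_genes
) -> list[RegulatoryInteraction]:
    """Keep interactions whose target lies in the selected gene set.

    TFs left with no surviving target disappear from the result. Matching
    is exact after uppercasing; no alias resolution is attempted.
    """
    selected = {str(g).upper() for g in selected_genes}
    kept = [it for it in interactions if it.target in selected]
    if not kept:
        warnings.warn("no interactions matched the selected gene set")
    return kept


def select_top_tfs(
    interactions: list[RegulatoryInteraction],
    min_targets: int = 13,
    strict: bool = False,
) -> list[RegulatoryInteraction]:
    """Keep only TFs whose target count reaches ``min_targets``.

    The threshold is inclusive (count >= min_targets) by default; pass
    ``strict=True`` for a literal strictly-greater reading. Ties are kept.
    """
    if min_targets < 1:
        raise ValueError("min_targets must be >= 1")
    counts: dict[str, int] = {}
    for it in interactions:
        counts[it.tf] = counts.get(it.tf, 0) + 1
    if strict:
        keep = {tf for tf, c in counts.items() if c > min_targets}
    else:
        keep = {tf for tf, c in counts.items() if c >= min_targets}
    return [it for it in interactions if it.tf in keep]


def build_initial_connectivity(
    interactions: list[RegulatoryInteraction],
) -> ConnectivityPattern:
    """Assemble Z0/C0 from an interaction list.

    Genes are the sorted unique targets (rows), TFs the sorted unique
    regulators (columns); C0 is 1 on every known interaction and 0
    elsewhere. By construction no row or column is all-zero.
    """
    if not interactions:
        raise ValueError("cannot build a connectivity pattern from no interactions")
    genes = sorted({it.target for it in interactions})
    tfs = sorted({it.tf for it in interactions})
    gi = {g: i for i, g in enumerate(genes)}
    ti = {t: j for j, t in enumerate(tfs)}
    support = np.zeros((len(genes), len(tfs)), dtype=np.int8)
    for it in interactions:
        support[gi[it.target], ti[it.tf]] = 1
    return ConnectivityPattern(genes=genes, tfs=tfs, support=support)


def _support_rank(
    pattern: np.ndarray, rng: np.random.Generator, n_fill: int = 3
) -> int:
    """Generic rank of a support class: rank of the 0/1 matrix, corrected
    upward by random support-constrained fillings.

    The relevant quantity for uniqueness is the rank a generic matrix with
    this zero pattern attains. The 0/1 representative usually attains it,
    but can fall short through integer coincidences (structurally distinct
    columns that happen to be integer dependent); the random fillings
    (tolerance 1e-8) guard against that.
    """
    if pattern.size == 0:
        return 0
    best = int(np.linalg.matrix_rank(pattern.astype(float), tol=1e-8))
    for _ in range(n_fill):
        filled = pattern * rng.uniform(0.5, 1.5, size=pattern.shape)
        best = max(best, int(np.linalg.matrix_rank(filled, tol=1e-8)))
    return best


def check_nca_identifiability(
    pattern: ConnectivityPattern, n_samples: int, seed: int = 0
) -> IdentifiabilityReport:
    """Evaluate the three NCA uniqueness criteria for a topology.

    1. the connectivity matrix has full column rank L;
    2. for every TF, deleting its column and the rows of its targets leaves
       a pattern of rank L-1;
    3. the activity matrix can have full row rank, i.e. n_samples >= L.

    Ranks are computed on the 0/1 support (plus random fillings, see
    :func:`_generic_rank`).
    """
    rng = np.random.default_rng(seed)
    Z = pattern.support
    L = pattern.n_tfs
    # TFs with identical target sets can never be separated, whatever the
    # control-strength values: treat duplicate support columns as a
    # column-rank failure outright
    distinct_columns = len({tuple(col) for col in Z.T}) == L
    full = distinct_columns and _support_rank(Z, rng) == L
    reduced: dict[str, bool] = {}
    for j, tf in enumerate(pattern.tfs):
        keep_rows = Z[:, j] == 0
        keep_cols = [k for k in range(L) if k != j]
        sub = Z[np.ix_(keep_rows, keep_cols)]
        reduced[tf] = _support_rank(sub, rng) == L - 1 if L > 1 else True
    return IdentifiabilityReport(
        full_column_rank=bool(full),
        reduced_rank_ok=reduced,
        samples_sufficient=bool(n_samples >= L),
        n_tfs=L,
        n_samples=int(n_samples),
    )
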