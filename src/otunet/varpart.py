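"""PERMANOVA and distance-based redundancy analysis with adjusted R².

Both tests operate on the Gower-centered inner-product matrix of a distance
matrix D:

    G = -1/2 C D^2 C,        C = I - 11'/n

With H the hat (projection) matrix of the factor design, the PERMANOVA
pseudo-F is

    F = [tr(HGH)/q] / [tr((I-H)G(I-H))/(n-q-1)]

and its p-value comes from free permutation of sample labels. dbRDA variance
explained is R^2 = tr(HGH)/tr(G) (negative eigenvalues of G retained in the
trace), adjusted as R²_adj = 1 - (1-R²)(n-1)/(n-q-1); adjusted values can be
slightly negative for null factors, and are reported as-is.

Variance partitioning reports, per factor group X:

* total R²_adj  — model containing X alone (with its marginal PERMANOVA p);
* unique R²_adj — R²_adj(full) - R²_adj(all groups except X);
* "All"         — R²_adj of the full model.

Unique fractions are differences of adjusted values, so overlapping factors
(e.g. plant species unevenly distributed across habitats) show totals much
larger than their uniques.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

__all__ = [
    "DesignMatrix",
    "VariancePartition",
    "build_design",
    "permanova",
    "dbrda_r2",
    "varpart",
    "variance_table",
]


@dataclass
class DesignMatrix:
    """Centered indicator contrasts for one or more categorical factors."""

    X: np.ndarray  # n x p, column-centered
    columns: list  # column labels ("factor[level]")
    factor_columns: dict  # factor -> list of column indices
    sample_ids: list

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def subset(self, factors: list) -> "DesignMatrix":
        idx = [i for f in factors for i in self.factor_columns[f]]
        cols = [self.columns[i] for i in idx]
        fcols, off = {}, 0
        for f in factors:
            k = len(self.factor_columns[f])
            fcols[f] = list(range(off, off + k))
            off += k
        return DesignMatrix(self.X[:, idx], cols, fcols, self.sample_ids)


def build_design(sample_meta: pd.DataFrame, factors: list) -> DesignMatrix:
    """Dummy-code ``factors`` (reference level dropped), center the columns.

    All factors are unordered categoricals; month included. A factor with a
    single observed level yields no contrast columns.
    """
    X_cols, labels, factor_columns = [], [], {}
    for f in factors:
        if f not in sample_meta.columns:
            raise KeyError(f"unknown factor {f!r}")
        levels = sorted(sample_meta[f].astype(str).unique())
        idx = []
        for level in levels[1:]:  # first level = reference
            col = (sample_meta[f].astype(str) == level).to_numpy(dtype=float)
            X_cols.append(col - col.mean())
            labels.append(f"{f}[{level}]")
            idx.append(len(X_cols) - 1)
        factor_columns[f] = idx
    X = np.column_stack(X_cols) if X_cols else np.empty((len(sample_meta), 0))
    return DesignMatrix(X, labels, factor_columns, list(sample_meta.index))


def _gower_center(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    c = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * c @ (d**2) @ c


def _align(d: DistanceMatrix, design: DesignMatrix) -> np.ndarray:
    ids = [str(s) for s in design.sample_ids]
    if list(d.ids) != ids:
        d = d.filter(ids)
    return np.asarray(d.data, dtype=float)


def _hat(X: np.ndarray, require_full_rank: bool) -> tuple[np.ndarray, int]:
    if X.shape[1] == 0:
        raise ValueError("design has no contrasts (single group?)")
    rank = np.linalg.matrix_rank(X)
    if require_full_rank and rank < X.shape[1]:
        # name the columns that add no rank
        aliased, seen = [], np.empty((X.shape[0], 0))
        for j in range(X.shape[1]):
            cand = np.column_stack([seen, X[:, j]])
            if np.linalg.matrix_rank(cand) == seen.shape[1]:
                aliased.append(j)
            else:
                seen = cand
        raise ValueError(f"rank-deficient design; aliased columns at indices {aliased}")
    H = X @ np.linalg.pinv(X)
    return H, rank


def permanova(
    d: DistanceMatrix,
    design: DesignMatrix,
    n_perm: int = 999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Pseudo-F and free-permutation p-value (McArdle-Anderson form).

    Permutation p = (1 + #{F_perm >= F_obs}) / (n_perm + 1). Deterministic
    given ``seed``. Raises on rank-deficient designs, naming the aliased
    columns.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    dm = _align(d, design)
    G = _gower_center(dm)
    H, q = _hat(design.X, require_full_rank=True)
    n = G.shape[0]
    if n <= q + 1:
        raise ValueError(f"need n > q + 1 (n={n}, q={q})")
    tr_G = np.trace(G)

    def f_stat(h):
        tr_HG = float(np.sum(h * G))  # tr(HGH) = tr(HG), H symmetric idempotent
        return (tr_HG / q) / ((tr_G - tr_HG) / (n - q - 1))

    f_obs = f_stat(H)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        h_perm = H[np.ix_(perm, perm)]  # permuting labels == permuting H
        if f_stat(h_perm) >= f_obs:
            exceed += 1
    p = (1.0 + exceed) / (n_perm + 1.0)
    return float(f_obs), float(p)


def dbrda_r2(d: DistanceMatrix, design: DesignMatrix) -> tuple[float, float]:
    """dbRDA variance explained: (R², adjusted R²).

    Rank-aware: a rank-deficient design is fit through the pseudoinverse
    with q = matrix rank, so overlapping factor groups remain comparable.
    """
    dm = _align(d, design)
    G = _gower_center(dm)
    H, q = _hat(design.X, require_full_rank=False)
    n = G.shape[0]
    if n <= q + 1:
        raise ValueError(f"need n > q + 1 (n={n}, q={q})")
    r2 = float(np.sum(H * G) / np.trace(G))
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - q - 1)
    return r2, float(r2_adj)


@dataclass
class VariancePartition:
    """Per-factor total and unique adjusted R² with permutation p-values."""

    table: pd.DataFrame  # index: factor names + "All"; columns below
    n_permutations: int
    seed: int | None

    def __str__(self) -> str:
        return self.table.to_string(float_format=lambda v: f"{v:.3f}")


def varpart(
    d: DistanceMatrix,
    sample_meta: pd.DataFrame,
    factor_groups: dict,
    n_perm: int = 999,
    seed: int | None = None,
) -> VariancePartition:
    """Adjusted-R² variance partitioning over named factor groups.

    ``factor_groups`` maps a display name to the metadata factors it spans,
    e.g. ``{"habitat": ["habitat"], "plant": ["plant"]}``. Permutation
    p-values are attached to each marginal (total) model.
    """
    if len(factor_groups) < 2:
        raise ValueError("need at least two factor groups to partition")
    all_factors = [f for group in factor_groups.values() for f in group]
    design_full = build_design(sample_meta, all_factors)
    _, full_adj = dbrda_r2(d, design_full)
    rng = np.random.default_rng(seed)
    rows = {}
    for name, factors in factor_groups.items():
        marginal = build_design(sample_meta, list(factors))
        total_r2, total_adj = dbrda_r2(d, marginal)
        _, p = permanova(d, marginal, n_perm=n_perm, seed=int(rng.integers(2**31)))
        rest = [f for f in all_factors if f not in factors]
        if rest:
            _, rest_adj = dbrda_r2(d, build_design(sample_meta, rest))
            unique = full_adj - rest_adj
        else:
            unique = full_adj
        rows[name] = {
            "total_R2": total_r2,
            "total_R2_adj": total_adj,
            "unique_R2_adj": unique,
            "p": p,
        }
    rows["All"] = {
        "total_R2": np.nan,
        "total_R2_adj": full_adj,
        "unique_R2_adj": np.nan,
        "p": np.nan,
    }
    table = pd.DataFrame(rows).T
    table.index.name = "factor"
    return VariancePartition(table=table, n_permutations=n_perm, seed=seed)


def variance_table(partitions: dict, alpha: float = 0.05) -> pd.DataFrame:
    """Combine several VariancePartition results into one report table.

    ``partitions`` maps a dataset-variant name (all OTUs, network OTUs,
    keystone OTUs, methanotrophs, methanogens, ...) to its partition. Rows
    are factor x {total, unique}; entries carry a star when the marginal
    permutation p < alpha.
    """
    cols = {}
    for variant, vp in partitions.items():
        col = {}
        for factor, row in vp.table.iterrows():
            if factor == "All":
                col[("All", "total")] = f"{row['total_R2_adj']:.2f}"
                continue
            star = "*" if row["p"] < alpha else ""
            col[(factor, "total")] = f"{row['total_R2_adj']:.2f}{star}"
            col[(factor, "unique")] = f"{row['unique_R2_adj']:.2f}{star}"
        cols[variant] = col
    out = pd.DataFrame(cols)
    out.index = pd.MultiIndex.from_tuples(out.index, names=["factor", "component"])
    return out
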