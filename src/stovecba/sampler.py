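"""Correlated uniform sampling of the parameter space.

Marginals are uniform on each parameter's [low, high] range — the catalog
documents plausible bounds, not distributions — and pairwise rank
correlations are induced with the Iman-Conover reordering scheme: sampled
uniforms are rearranged column-by-column to follow the ranks of a
multivariate-normal reference sample, which preserves the marginals
exactly while imposing a distribution-free dependence structure.

The assembled correlation matrix need not be jointly consistent (the
pairwise assumptions were stated independently), so it is repaired to the
nearest positive semidefinite correlation matrix by eigenvalue clipping
before use; the size of the adjustment is reported on the result.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import Catalog, CorrelationSpec, ValidationError

__all__ = [
    "DrawMatrix",
    "build_correlation_matrix",
    "nearest_psd_correlation",
    "sample",
    "rank_to_normal",
    "normal_to_rank",
]


def rank_to_normal(r):
    """Spearman rank correlation -> Pearson correlation of normal scores."""
    return 2.0 * np.sin(np.pi * np.asarray(r, dtype=float) / 6.0)


def normal_to_rank(rho):
    """Pearson correlation of normal scores -> Spearman rank correlation."""
    return 6.0 / np.pi * np.arcsin(np.asarray(rho, dtype=float) / 2.0)


@dataclass
class DrawMatrix:
    """n_draws x n_params realizations plus the provenance to replay them."""

    values: pd.DataFrame
    seed: int
    psd_adjustment: float = 0.0
    target_rank_corr: pd.DataFrame | None = None

    @property
    def n_draws(self) -> int:
        return len(self.values)

    @property
    def columns(self) -> list[str]:
        return list(self.values.columns)

    def column(self, name: str) -> np.ndarray:
        return self.values[name].to_numpy()

    def draw(self, i: int) -> dict[str, float]:
        return self.values.iloc[i].to_dict()

    def as_mapping(self) -> dict[str, np.ndarray]:
        """Column arrays, suitable for the vectorized model functions."""
        return {c: self.values[c].to_numpy() for c in self.values.columns}

    def to_csv(self, path: str | Path) -> None:
        self.values.to_csv(path, index=False)


def build_correlation_matrix(
    spec: CorrelationSpec | list[tuple[str, str, float]],
    columns: list[str],
) -> np.ndarray:
    """Assemble the symmetric rank-correlation matrix over ``columns``.

    ``spec`` may be a CorrelationSpec whose pairs use concrete column names,
    or an already-expanded pair list.  Pairs are listed once; the matrix is
    symmetrized with a unit diagonal.  Callers needing a usable sampling
    matrix should pass the result through :func:`nearest_psd_correlation`.
    """
    pairs = spec.pairs if isinstance(spec, CorrelationSpec) else spec
    index = {c: i for i, c in enumerate(columns)}
    k = len(columns)
    mat = np.eye(k)
    for a, b, r in pairs:
        if not (-1.0 <= r <= 1.0):
            raise ValidationError(f"correlation ({a}, {b}): {r} outside [-1, 1]")
        if a not in index or b not in index:
            missing = a if a not in index else b
            raise ValidationError(f"correlation names unknown parameter {missing!r}")
        i, j = index[a], index[b]
        mat[i, j] = mat[j, i] = r
    return mat


def nearest_psd_correlation(mat: np.ndarray, tol: float = 1e-10):
    """Project a symmetric matrix to a positive semidefinite correlation matrix.

    Eigenvalues below ``tol`` are clipped and the result rescaled to a unit
    diagonal, iterating until the spectrum is clean (a light-weight variant
    of Higham's alternating projections; adequate for the mild inconsistency
    of independently stated pairwise correlations).

    Returns ``(repaired, max_abs_change)``.
    """
    out = np.asarray(mat, dtype=float).copy()
    out = (out + out.T) / 2.0
    for _ in range(100):
        vals, vecs = np.linalg.eigh(out)
        if vals.min() >= tol:
            break
        vals = np.clip(vals, tol, None)
        out = (vecs * vals) @ vecs.T
        d = np.sqrt(np.diag(out))
        out = out / np.outer(d, d)
        out = (out + out.T) / 2.0
    np.fill_diagonal(out, 1.0)
    return out, float(np.max(np.abs(out - mat)))


def sample(catalog: Catalog, n_draws: int, seed: int) -> DrawMatrix:
    """Draw ``n_draws`` correlated realizations of every catalog parameter.

    Degenerate ranges (low == high, i.e. model constants) become constant
    columns and are kept out of the correlation machinery.  The result is
    bit-reproducible for a given (seed, n_draws, catalog).
    """
    if n_draws < 2:
        raise ValueError("n_draws must be at least 2")
    ranges = catalog.parameter_ranges()
    columns = list(ranges)
    free = [c for c in columns if not ranges[c].is_degenerate]
    rng = np.random.default_rng(seed)

    # marginal uniforms, drawn for every free column
    uniforms = {
        c: rng.uniform(ranges[c].low, ranges[c].high, size=n_draws) for c in free
    }

    pairs = [
        (a, b, r)
        for a, b, r in catalog.correlations.expand(catalog)
        if a in uniforms and b in uniforms and r != 0.0
    ]
    adjustment = 0.0
    target = np.eye(len(free))
    if pairs and free:
        rank_target = build_correlation_matrix(pairs, free)
        normal_target = rank_to_normal(rank_target)
        np.fill_diagonal(normal_target, 1.0)
        repaired, adjustment = nearest_psd_correlation(normal_target)
        target = repaired

        # Iman-Conover: rank-reorder each uniform column to follow a
        # correlated normal reference sample
        jitter = 1e-12 * np.eye(len(free))
        chol = np.linalg.cholesky(target + jitter)
        scores = rng.standard_normal((n_draws, len(free)))
        if n_draws > len(free) + 1:
            # de-correlate the raw scores so the induced correlation is exact
            # up to rank-coarsening, not polluted by sampling noise; skipped
            # for tiny samples where the empirical correlation is singular
            emp = np.corrcoef(scores, rowvar=False)
            try:
                scores = scores @ np.linalg.inv(np.linalg.cholesky(emp)).T
            except np.linalg.LinAlgError:
                pass
        reference = scores @ chol.T
        order = np.argsort(np.argsort(reference, axis=0), axis=0)
        for j, c in enumerate(free):
            uniforms[c] = np.sort(uniforms[c])[order[:, j]]

    data = {}
    for c in columns:
        if c in uniforms:
            data[c] = uniforms[c]
        else:
            data[c] = np.full(n_draws, ranges[c].mid)
    values = pd.DataFrame(data, columns=columns)
    target_rank = pd.DataFrame(normal_to_rank(target), index=free, columns=free)
    return DrawMatrix(
        values=values,
        seed=seed,
        psd_adjustment=adjustment,
        target_rank_corr=target_rank,
    )


def sample_rank_correlation(dm: DrawMatrix, a: str, b: str) -> float:
    """Empirical Spearman correlation between two sampled columns."""
    rho, _ = stats.spearmanr(dm.column(a), dm.column(b))
    return float(rho)
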