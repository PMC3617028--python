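"""Spearman and partial Spearman rank correlations.

Spearman's rho is computed as the Pearson correlation of average-ranked
data (ties receive average ranks, the standard convention — abundance
tables are tie-rich).  The partial rank correlation between x and y given
controls z1..zk removes the monotone association each variable shares with
the controls:

    rho_xy.z = (rho_xy - rho_xz rho_yz) / sqrt((1 - rho_xz^2)(1 - rho_yz^2))

for one control, and the inverse-correlation-matrix generalisation

    rho_xy.Z = -P_xy / sqrt(P_xx P_yy),   P = R^{-1},

on the rank-transformed data for several.  The two routes agree for a
single control.  Significance, when requested, comes from a seeded
permutation test rather than an asymptotic approximation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.stats

logger = logging.getLogger(__name__)

_DEGENERACY_EPS = 1e-12


class DegenerateDataError(ValueError):
    """A correlation is undefined: constant input or a perfectly explanatory control."""


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    n: int
    controlled: tuple[str, ...] = ()
    method: str = "spearman"
    p_value: float | None = None


def _as_columns(
    controls, names: Sequence[str] | None
) -> tuple[list[np.ndarray], list[str]]:
    """Normalise the controls argument: array, sequence of arrays, or mapping."""
    if controls is None:
        return [], []
    if isinstance(controls, Mapping):
        cols = [np.asarray(v, dtype=float) for v in controls.values()]
        return cols, [str(k) for k in controls.keys()]
    arr = np.asarray(controls, dtype=float)
    if arr.ndim == 1:
        cols = [arr]
    else:
        cols = [np.asarray(c, dtype=float) for c in controls]
    if names is None:
        names = [f"z{i+1}" for i in range(len(cols))]
    if len(names) != len(cols):
        raise ValueError("number of control names must match number of controls")
    return cols, list(names)


def _ranks(x: np.ndarray) -> np.ndarray:
    return scipy.stats.rankdata(x, method="average")


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        raise DegenerateDataError("correlation undefined for a constant vector")
    return float(np.clip((a @ b) / denom, -1.0, 1.0))


def _check_pair(x: np.ndarray, y: np.ndarray, min_n: int) -> None:
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < min_n:
        raise ValueError(f"need at least {min_n} observations, got {len(x)}")


def spearman(
    x,
    y,
    n_permutations: int | None = None,
    seed: int | None = None,
) -> CorrelationResult:
    """Spearman rank correlation of two vectors.

    ``n_permutations`` requests a two-sided permutation p-value (``seed``
    makes it reproducible).  Constant input raises
    :class:`DegenerateDataError`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_pair(x, y, 3)
    rho = _pearson(_ranks(x), _ranks(y))
    p = None
    if n_permutations:
        p = _permutation_pvalue(x, y, None, rho, n_permutations, seed)
    return CorrelationResult(rho=rho, n=len(x), method="spearman", p_value=p)


def _rank_corr_matrix(columns: list[np.ndarray]) -> np.ndarray:
    ranked = np.vstack([_ranks(c) for c in columns])
    sd = ranked.std(axis=1)
    if np.any(sd == 0):
        raise DegenerateDataError("correlation undefined for a constant vector")
    return np.corrcoef(ranked)


def _partial_rho(x: np.ndarray, y: np.ndarray, zs: list[np.ndarray]) -> float:
    R = _rank_corr_matrix([x, y] + zs)
    # a control perfectly rank-correlated with x or y explains it entirely
    for k in range(2, R.shape[0]):
        if 1.0 - abs(R[0, k]) < _DEGENERACY_EPS or 1.0 - abs(R[1, k]) < _DEGENERACY_EPS:
            raise DegenerateDataError(
                "a control variable is perfectly rank-correlated with x or y"
            )
    if len(zs) == 1:
        r_xy, r_xz, r_yz = R[0, 1], R[0, 2], R[1, 2]
        return float(
            (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
        )
    try:
        P = np.linalg.inv(R)
    except np.linalg.LinAlgError as exc:
        raise DegenerateDataError(f"singular correlation matrix: {exc}") from exc
    return float(np.clip(-P[0, 1] / np.sqrt(P[0, 0] * P[1, 1]), -1.0, 1.0))


def partial_spearman(
    x,
    y,
    controls,
    names: Sequence[str] | None = None,
    n_permutations: int | None = None,
    seed: int | None = None,
) -> CorrelationResult:
    """Partial Spearman correlation of x and y controlling for one or more variables.

    ``controls`` may be a single vector, a sequence of vectors, or a mapping
    of name -> vector.  Rows with any missing value are dropped listwise.
    Constant controls are dropped with a warning; if none remain the result
    is the plain Spearman correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    zs, znames = _as_columns(controls, names)
    for z in zs:
        if z.shape != x.shape:
            raise ValueError("all controls must match the length of x and y")

    # listwise deletion of rows with missing values
    mask = np.isfinite(x) & np.isfinite(y)
    for z in zs:
        mask &= np.isfinite(z)
    if not mask.all():
        logger.info("dropping %d row(s) with missing values", int((~mask).sum()))
        x, y = x[mask], y[mask]
        zs = [z[mask] for z in zs]

    keep, kept_names = [], []
    for z, name in zip(zs, znames):
        if np.all(z == z[0]):
            warnings.warn(
                f"control {name!r} is constant and was dropped", stacklevel=2
            )
        else:
            keep.append(z)
            kept_names.append(name)
    if not keep:
        return spearman(x, y, n_permutations=n_permutations, seed=seed)

    _check_pair(x, y, 3 + len(keep))
    rho = _partial_rho(x, y, keep)
    p = None
    if n_permutations:
        p = _permutation_pvalue(x, y, keep, rho, n_permutations, seed)
    return CorrelationResult(
        rho=rho,
        n=len(x),
        controlled=tuple(kept_names),
        method="partial_spearman",
        p_value=p,
    )


def _permutation_pvalue(
    x: np.ndarray,
    y: np.ndarray,
    zs: list[np.ndarray] | None,
    observed: float,
    n_permutations: int,
    seed: int | None,
) -> float:
    """Two-sided permutation p-value: permute y (with its control rows intact)."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(len(y))
        if zs is None:
            stat = _pearson(_ranks(x), _ranks(y[perm]))
        else:
            stat = _partial_rho(x, y[perm], zs)
        if abs(stat) >= abs(observed) - 1e-15:
            hits += 1
    return (hits + 1) / (n_permutations + 1)
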