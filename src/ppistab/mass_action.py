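"""Dissociation-constant assignment and the self-consistent mass-action solver.

The cell is modelled at equilibrium: each protein i partitions its total
concentration C_i between a free folded monomer F_i, a collective
unfolded/misfolded/oligomerised pool U_i, and heterodimers D_ij with its
interaction partners,

    C_i = F_i + U_i + sum_j D_ij,       D_ij = F_i F_j / K_ij,

with U_i = exp(-dG_f,i) * F_i set by the protein's intrinsic folding
stability (dG_f in k_BT).  Substituting the law of mass action into the
conservation law yields a fixed point for the free concentrations,

    F_i = C_i / (1 + exp(-dG_f,i) + sum_j F_j / K_ij),

which :func:`solve_equilibrium` iterates to convergence starting from
F_i = C_i.  Only folded monomers interact; the unfolded pool of one protein
is assumed not to interact with any state of any other protein, and
complexes are restricted to dimers.

:func:`brute_force_equilibrium` solves the identical nonlinear system with
a generic multidimensional root finder in log-concentration space and is
intended as an independent cross-check on small networks.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.sparse

from .io_formats import InteractionEdge, ProteomeModel, ValidationError

logger = logging.getLogger(__name__)

StabilityMode = Literal["infinite", "explicit", "chain_length", "minimal"]

# exp() overflow guard for extremely destabilised proteins
_MAX_EXP_ARG = 700.0

_DAMPING_FLOOR = 1.0 / 64.0
_STALL_SWEEPS = 100


class ConvergenceError(RuntimeError):
    """Raised when an equilibrium computation fails to converge.

    Carries the last iterate (``state``) and the residual reached, so a
    caller can inspect how close the solve got.
    """

    def __init__(self, message: str, state: "EquilibriumState | None" = None,
                 residual: float = math.nan):
        super().__init__(message)
        self.state = state
        self.residual = residual


@dataclass
class SolverOptions:
    """Numerical controls for the equilibrium solve.

    rel_tol
        Per-protein relative change between consecutive sweeps below which
        the iteration stops (the mass-balance residual is additionally
        required to fall below the same relative tolerance).
    damping
        Mixing weight in (0, 1] for the fixed-point update; automatically
        halved (floor 1/64) when the residual stalls, which tames
        oscillations on very tight binders.
    stability_mode
        ``infinite`` treats every protein as infinitely stable (no unfolded
        pool; the headline upper-limit estimate of induced stability),
        ``explicit`` uses each protein's own ``dG_fold``, ``chain_length``
        assigns dG_f = chain_intercept + chain_slope * length, and
        ``minimal`` pins every protein at ``minimal_dg``.
    gauss_seidel
        Opt-in in-place sweep order; the default simultaneous (Jacobi)
        update makes results independent of protein ordering.
    """

    rel_tol: float = 1e-8
    max_iter: int = 100_000
    damping: float = 1.0
    stability_mode: StabilityMode = "infinite"
    chain_intercept: float = 0.0
    chain_slope: float = 0.05
    minimal_dg: float = 0.0
    gauss_seidel: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.rel_tol < 1):
            raise ValueError("rel_tol must be in (0, 1)")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not (0 < self.damping <= 1):
            raise ValueError("damping must be in (0, 1]")
        if self.stability_mode not in ("infinite", "explicit", "chain_length", "minimal"):
            raise ValueError(f"unknown stability_mode {self.stability_mode!r}")


@dataclass
class EquilibriumState:
    """Converged concentrations of a mass-action solve.

    Arrays are aligned with ``ids`` (proteins) and ``edge_keys`` (dimers).
    ``dG_eff`` holds the per-protein folding stability actually used by the
    solve, or ``None`` in infinite-stability mode.
    """

    ids: list[str]
    C: np.ndarray
    F: np.ndarray
    U: np.ndarray
    edge_keys: list[tuple[str, str]]
    K_d: np.ndarray
    D: np.ndarray
    dG_eff: np.ndarray | None
    converged: bool
    iterations: int
    residual: float

    def bound(self) -> np.ndarray:
        """Per-protein total dimer-bound concentration sum_j D_ij."""
        out = np.zeros_like(self.F)
        idx = {pid: i for i, pid in enumerate(self.ids)}
        for (a, b), d in zip(self.edge_keys, self.D):
            out[idx[a]] += d
            out[idx[b]] += d
        return out

    def mass_balance_error(self) -> np.ndarray:
        """Relative conservation residual |F + U + sum_j D - C| / C per protein."""
        return np.abs(self.F + self.U + self.bound() - self.C) / self.C

    def total_unfolded(self) -> float:
        return float(np.sum(self.U))

    def protein_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "C_total": self.C,
                "F": self.F,
                "U": self.U,
                "bound_total": self.bound(),
            }
        )

    def dimer_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "a": [k[0] for k in self.edge_keys],
                "b": [k[1] for k in self.edge_keys],
                "K_d": self.K_d,
                "D": self.D,
            }
        )


# ---------------------------------------------------------------------------
# K_d assignment
# ---------------------------------------------------------------------------


def assign_kd(
    model: ProteomeModel,
    rule: str = "abundance_recipe",
    params: Mapping | None = None,
    seed: int | None = None,
) -> ProteomeModel:
    """Assign a dissociation constant to every edge.

    Rules
    -----
    ``abundance_recipe``
        K_ij = alpha * min(C_i, C_j) (param ``alpha``, default 0.1).  The
        rationale: tightening an interaction beyond the point where the
        abundance-limiting partner is fully sequestered buys nothing, so
        evolved K_d values should track the scarcer partner's abundance.
    ``lognormal``
        i.i.d. draws with parameters ``median`` (nM, default 50) and
        ``log_sd`` (default 1.0); reproducible via ``seed``.
    ``fixed``
        every edge gets ``K`` nM (default 5).
    """
    params = dict(params or {})
    if rule == "abundance_recipe":
        alpha = float(params.pop("alpha", 0.1))
        if alpha <= 0:
            raise ValueError("alpha must be positive")
        conc = {p.id: p.C_total for p in model.proteins}
        new_edges = [
            replace(e, K_d=alpha * min(conc[e.a], conc[e.b])) for e in model.edges
        ]
    elif rule == "lognormal":
        median = float(params.pop("median", 50.0))
        log_sd = float(params.pop("log_sd", 1.0))
        if median <= 0 or log_sd <= 0:
            raise ValueError("lognormal median and log_sd must be positive")
        rng = np.random.default_rng(seed)
        draws = median * np.exp(rng.normal(0.0, log_sd, size=len(model.edges)))
        new_edges = [replace(e, K_d=float(k)) for e, k in zip(model.edges, draws)]
    elif rule == "fixed":
        K = float(params.pop("K", 5.0))
        if K <= 0:
            raise ValueError("K must be positive")
        new_edges = [replace(e, K_d=K) for e in model.edges]
    else:
        raise ValueError(f"unknown K_d assignment rule {rule!r}")
    if params:
        raise ValueError(f"unused parameters for rule {rule!r}: {sorted(params)}")
    return model.with_edges(new_edges)


# ---------------------------------------------------------------------------
# Stability handling
# ---------------------------------------------------------------------------


def effective_dg(model: ProteomeModel, options: SolverOptions) -> np.ndarray | None:
    """Per-protein folding stability implied by ``options.stability_mode``.

    Returns ``None`` in infinite-stability mode (unfolded pool suppressed
    entirely).
    """
    mode = options.stability_mode
    if mode == "infinite":
        return None
    if mode == "explicit":
        vals = []
        for p in model.proteins:
            if p.dG_fold is None:
                raise ValidationError(
                    f"stability_mode='explicit' requires dG_fold on every "
                    f"protein; missing for {p.id!r}"
                )
            vals.append(p.dG_fold)
        return np.asarray(vals, dtype=float)
    if mode == "chain_length":
        vals = []
        for p in model.proteins:
            if p.length is None:
                raise ValidationError(
                    f"stability_mode='chain_length' requires length on every "
                    f"protein; missing for {p.id!r}"
                )
            vals.append(options.chain_intercept + options.chain_slope * p.length)
        return np.asarray(vals, dtype=float)
    if mode == "minimal":
        return np.full(model.n_proteins, options.minimal_dg, dtype=float)
    raise ValueError(f"unknown stability_mode {mode!r}")


def unfold_ratio(dG_eff: np.ndarray | None, n: int) -> np.ndarray:
    """u_i = U_i / F_i = exp(-dG_f,i); zero in infinite-stability mode."""
    if dG_eff is None:
        return np.zeros(n)
    return np.exp(np.clip(-np.asarray(dG_eff, dtype=float), None, _MAX_EXP_ARG))


# ---------------------------------------------------------------------------
# Fixed-point core
# ---------------------------------------------------------------------------


def _fixed_point(
    C: np.ndarray,
    u: np.ndarray,
    W,
    options: SolverOptions,
    F0: np.ndarray | None = None,
) -> tuple[np.ndarray, int, bool, float]:
    """Iterate F <- (1-d) F + d C / (1 + u + W F) to self-consistency.

    ``W`` is the (sparse or dense) matrix with W[i, j] = 1/K_ij on edges and
    zero elsewhere, so (W F)_i is the focal protein's interaction constant
    K_int,i.  Returns (F, iterations, converged, residual) where residual is
    the max relative mass-balance error.
    """
    if len(C) == 0:
        return C.astype(float), 0, True, 0.0
    F = C.astype(float).copy() if F0 is None else np.asarray(F0, dtype=float).copy()
    damping = options.damping
    best = math.inf
    stall = 0
    change = math.inf
    residual = math.inf
    for it in range(1, options.max_iter + 1):
        denom = 1.0 + u + W @ F
        F_target = C / denom
        F_next = F_target if damping == 1.0 else (1.0 - damping) * F + damping * F_target
        change = float(np.max(np.abs(F_next - F) / np.maximum(F, 1e-300)))
        # residual of the un-damped balance at the new iterate
        denom_next = 1.0 + u + W @ F_next
        residual = float(np.max(np.abs(F_next * denom_next - C) / C))
        F = F_next
        if change < options.rel_tol and residual < options.rel_tol:
            return F, it, True, residual
        metric = max(change, residual)
        if metric < best:
            best = metric
            stall = 0
        else:
            stall += 1
            if stall >= _STALL_SWEEPS and damping > _DAMPING_FLOOR:
                damping = max(damping / 2.0, _DAMPING_FLOOR)
                stall = 0
                best = metric
                logger.info(
                    "residual stalled for %d sweeps; damping halved to %g",
                    _STALL_SWEEPS,
                    damping,
                )
    return F, options.max_iter, False, residual


def _gauss_seidel(
    C: np.ndarray,
    u: np.ndarray,
    W: np.ndarray,
    options: SolverOptions,
    F0: np.ndarray | None = None,
) -> tuple[np.ndarray, int, bool, float]:
    """In-place sweep variant; order-dependent but often faster to converge."""
    W = np.asarray(W if not scipy.sparse.issparse(W) else W.toarray())
    F = C.astype(float).copy() if F0 is None else np.asarray(F0, dtype=float).copy()
    d = options.damping
    for it in range(1, options.max_iter + 1):
        F_prev = F.copy()
        for i in range(len(C)):
            target = C[i] / (1.0 + u[i] + W[i] @ F)
            F[i] = (1.0 - d) * F[i] + d * target
        change = float(np.max(np.abs(F - F_prev) / np.maximum(F_prev, 1e-300)))
        residual = float(np.max(np.abs(F * (1.0 + u + W @ F) - C) / C))
        if change < options.rel_tol and residual < options.rel_tol:
            return F, it, True, residual
    return F, options.max_iter, False, residual


# ---------------------------------------------------------------------------
# Public solvers
# ---------------------------------------------------------------------------


def _build_W(model: ProteomeModel, idx: dict[str, int]):
    """Sparse symmetric matrix of 1/K_ij over the edge set."""
    n = model.n_proteins
    rows, cols, vals = [], [], []
    for e in model.edges:
        if e.K_d is None:
            raise ValidationError(
                f"edge ({e.a}, {e.b}) has no K_d; run assign_kd first"
            )
        i, j = idx[e.a], idx[e.b]
        rows += [i, j]
        cols += [j, i]
        vals += [1.0 / e.K_d, 1.0 / e.K_d]
    W = scipy.sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))
    return W


def _state_from_F(
    model: ProteomeModel,
    idx: dict[str, int],
    F: np.ndarray,
    u: np.ndarray,
    dG_eff: np.ndarray | None,
    converged: bool,
    iterations: int,
    residual: float,
) -> EquilibriumState:
    edge_keys = [e.key for e in model.edges]
    K_d = np.array([e.K_d for e in model.edges], dtype=float)
    D = np.array(
        [F[idx[e.a]] * F[idx[e.b]] / e.K_d for e in model.edges], dtype=float
    )
    return EquilibriumState(
        ids=model.ids,
        C=model.concentrations(),
        F=F,
        U=u * F,
        edge_keys=edge_keys,
        K_d=K_d,
        D=D,
        dG_eff=None if dG_eff is None else np.asarray(dG_eff, dtype=float),
        converged=converged,
        iterations=iterations,
        residual=residual,
    )


def solve_equilibrium(
    model: ProteomeModel,
    options: SolverOptions | None = None,
    F0: np.ndarray | None = None,
) -> EquilibriumState:
    """Solve the coupled mass-action equilibrium for free concentrations.

    Starts from F_i = C_i (or the warm start ``F0``) and iterates the
    conservation-law fixed point until two consecutive estimates agree to
    ``options.rel_tol`` for every protein and the mass-balance residual is
    below the same relative tolerance.

    Raises :class:`ConvergenceError` (carrying the last state) if the
    iteration cap is reached first.
    """
    options = options or SolverOptions()
    C = model.concentrations()
    if np.any(C <= 0):
        raise ValidationError("all concentrations must be positive")
    idx = model.index()
    dG_eff = effective_dg(model, options)
    u = unfold_ratio(dG_eff, model.n_proteins)
    W = _build_W(model, idx)
    core = _gauss_seidel if options.gauss_seidel else _fixed_point
    F, iterations, converged, residual = core(C, u, W, options, F0)
    state = _state_from_F(model, idx, F, u, dG_eff, converged, iterations, residual)
    if not converged:
        raise ConvergenceError(
            f"equilibrium not converged after {iterations} iterations "
            f"(max relative residual {residual:.3e})",
            state=state,
            residual=residual,
        )
    return state


def brute_force_equilibrium(
    model: ProteomeModel,
    options: SolverOptions | None = None,
) -> EquilibriumState:
    """Independent oracle: solve the same system with a generic root finder.

    Works in log-concentration space (x_i = ln F_i) so nonnegativity is
    built in, and drives the scaled mass-balance residuals to zero with
    Powell's hybrid method.  Intended for small networks; the fixed-point
    solver is the production path.
    """
    options = options or SolverOptions()
    C = model.concentrations()
    idx = model.index()
    dG_eff = effective_dg(model, options)
    u = unfold_ratio(dG_eff, model.n_proteins)
    W = _build_W(model, idx).toarray()

    def residuals(x: np.ndarray) -> np.ndarray:
        F = np.exp(x)
        return (F * (1.0 + u + W @ F) - C) / C

    def jacobian(x: np.ndarray) -> np.ndarray:
        F = np.exp(x)
        J = (F[:, None] * W * F[None, :] + np.diag(F * (1.0 + u + W @ F))) / C[:, None]
        return J

    if len(C) == 0:
        return _state_from_F(model, idx, C.astype(float), u, dG_eff, True, 0, 0.0)
    x0 = np.log(C / 2.0)
    sol = scipy.optimize.root(residuals, x0, jac=jacobian, method="hybr")
    x = sol.x
    # Newton polish: quadratic convergence takes the hybr iterate to
    # machine precision in a few steps
    for _ in range(10):
        r = residuals(x)
        if np.max(np.abs(r)) < 1e-13:
            break
        try:
            x = x - np.linalg.solve(jacobian(x), r)
        except np.linalg.LinAlgError:
            break
    resid = float(np.max(np.abs(residuals(x))))
    sol.x = x
    # hybr can report xtol failure after already reaching machine precision;
    # judge success by the residual actually achieved
    if resid > 1e-9:
        raise ConvergenceError(
            f"root finder failed: {sol.message} (max residual {resid:.3e})",
            residual=resid,
        )
    F = np.exp(sol.x)
    return _state_from_F(
        model, idx, F, u, dG_eff, True, int(sol.nfev), resid
    )
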