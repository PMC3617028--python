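"""Evolution of a toy proteome under unfolded-protein-load fitness.

The organism is a small fixed-topology proteome (default 15 proteins).
Fitness depends only on the total concentration of unfolded protein at the
network equilibrium,

    Phi = exp(-c * sum_i U_i),

with c a per-nM scaling factor.  Each generation proposes one mutation —
either a Gaussian step in one protein's intrinsic stability dG_f
(destabilising on average, reflected at the boundaries of the bounded
stability window [dG_min, dG_max] accessible to real sequences) or a resampling
of one interaction's dissociation constant from its lognormal prior — and
accepts it with the canonical-ensemble (Sella–Hirsh) Metropolis rule

    P_accept = min(1, (Phi_new / Phi_old)^nu),

where the selection exponent nu plays the role of (twice) the effective
population size: the stationary distribution is proportional to Phi^nu, so
1/nu acts as an evolutionary temperature.  nu = 0 is pure drift.  Abundances
and network topology never change; only stabilities and binding strengths
evolve.

Sweeping nu maps out the drift-selection balance: at small populations
proteins destabilise under mutation pressure and interactions carry the
burden of keeping the unfolded load down; at large populations intrinsic
stability is maintained and the interaction contribution concentrates on
the least stable proteins, tightening its anticorrelation with intrinsic
stability.  Because the acceptance rule depends on fitness only through
nu * ln(Phi'/Phi) = nu * c * (change in unfolded load), the selection
exponent and the toxicity scale enter the dynamics solely as the product
nu * c; the default c places the studied nu range across the
drift-to-selection transition.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .io_formats import InteractionEdge, ProteinRecord, ProteomeModel
from .mass_action import (
    ConvergenceError,
    EquilibriumState,
    SolverOptions,
    _fixed_point,
)
from .rank_stats import DegenerateDataError, spearman

logger = logging.getLogger(__name__)

_MAX_EXP_ARG = 700.0


@dataclass
class EvolutionConfig:
    """Parameters of an evolutionary run.

    Topology and abundances are fixed for the whole run.  If ``edges`` is
    None a connected Erdos-Renyi G(n, m) graph with the requested mean
    degree is drawn from ``seed``; if ``abundances`` is None they are drawn
    lognormally (median ``abundance_median`` nM, log-sd
    ``abundance_log_sd``) from the same seed, so every replicate and every
    nu value of a sweep shares one organism.

    The mutation kernel hits a random protein's stability with probability
    ``p_stability`` (Gaussian step, mean ``dG_step_mean`` < 0 encodes the
    destabilising bias of random mutations, reflected into the bounded
    stability window [``dG_min``, ``dG_max``] accessible to real sequences);
    otherwise a uniformly chosen edge's K_d is resampled from the
    lognormal prior (``kd_median`` nM, ``kd_log_sd``).

    ``fixation='kimura'`` swaps the Metropolis rule for the diffusion
    fixation probability (1 - e^(-2s)) / (1 - e^(-2 nu s)) with
    s = Phi_new/Phi_old - 1, as a robustness check.

    ``unfolded_feedback`` selects how the unfolded load is computed.  The
    default (False) follows the two-level scheme: free concentrations are
    solved on the network with every protein treated as highly stable, and
    each protein's unfolded fraction then follows from the two-state
    balance U/C = 1 / (1 + e^(dG_f) (1 + K_int)).  With True, the unfolded
    pool feeds back into the network solve itself (an unfolded protein also
    depletes the free monomer it offers its partners), which introduces a
    qualitatively different coupling: destabilised partners then provide
    less stabilisation, suppressing the compensation that the two-level
    scheme exhibits in the drift regime.
    """

    n_proteins: int = 15
    edges: Sequence[tuple[int, int]] | None = None
    mean_degree: float = 3.0
    abundances: Sequence[float] | None = None
    abundance_median: float = 300.0
    abundance_log_sd: float = 0.3
    c_scale: float = 0.002
    nu: float = 20.0
    n_generations: int = 20_000
    burn_in_fraction: float = 0.5
    p_stability: float = 0.5
    dG_step_mean: float = -0.5
    dG_step_sd: float = 1.0
    dG_max: float = 15.0
    dG_min: float = -4.0
    dG_init: float = 5.0
    kd_median: float = 500.0
    kd_log_sd: float = 2.5
    thin: int = 1
    fixation: Literal["metropolis", "kimura"] = "metropolis"
    unfolded_feedback: bool = False
    solver_rel_tol: float = 1e-8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 2:
            raise ValueError("n_proteins must be >= 2")
        if self.nu < 0:
            raise ValueError("selection exponent nu must be >= 0")
        if not (0 < self.burn_in_fraction < 1):
            raise ValueError("burn_in_fraction must be in (0, 1)")
        if self.dG_step_sd <= 0:
            raise ValueError("dG_step_sd must be positive")
        if not (0 <= self.p_stability <= 1):
            raise ValueError("p_stability must be in [0, 1]")
        if self.c_scale <= 0:
            raise ValueError("c_scale must be positive")
        if self.n_generations < 1 or self.thin < 1:
            raise ValueError("n_generations and thin must be >= 1")
        if not (self.dG_min < self.dG_max):
            raise ValueError("dG_min must be below dG_max")
        if not (self.dG_min <= self.dG_init <= self.dG_max):
            raise ValueError("dG_init must lie in [dG_min, dG_max]")
        if self.kd_median <= 0 or self.kd_log_sd <= 0:
            raise ValueError("kd prior parameters must be positive")
        if self.edges is not None and len(self.edges) == 0 and self.p_stability < 1:
            raise ValueError(
                "K_d mutations are enabled (p_stability < 1) but the "
                "topology has no edges"
            )
        if self.abundances is not None and len(self.abundances) != self.n_proteins:
            raise ValueError("abundances must have one entry per protein")


@dataclass
class EvolutionTrajectory:
    """Recorded time series of one evolutionary run.

    ``dG_fold`` and ``dG_int`` are (recorded generations x proteins);
    ``fitness`` and ``accepted`` are per recorded generation.  ``edges``
    and ``abundances`` document the fixed organism.
    """

    config: EvolutionConfig
    generations: np.ndarray
    fitness: np.ndarray
    accepted: np.ndarray
    dG_fold: np.ndarray
    dG_int: np.ndarray
    edges: list[tuple[int, int]]
    abundances: np.ndarray

    @property
    def dG_total(self) -> np.ndarray:
        return self.dG_fold + self.dG_int

    def _burn_index(self) -> int:
        return int(round(self.config.burn_in_fraction * len(self.generations)))

    def summary(self) -> dict:
        """Post-burn-in means and the across-protein rank correlation.

        The correlation is Spearman's rho between the per-protein time
        averages of dG_int and dG_fold over the retained half of the run.
        """
        start = self._burn_index()
        dgf = self.dG_fold[start:]
        dgi = self.dG_int[start:]
        per_protein_f = dgf.mean(axis=0)
        per_protein_i = dgi.mean(axis=0)
        try:
            corr = spearman(per_protein_i, per_protein_f).rho
        except DegenerateDataError:
            corr = math.nan
        return {
            "mean_dG_fold": float(dgf.mean()),
            "mean_dG_int": float(dgi.mean()),
            "mean_dG_total": float((dgf + dgi).mean()),
            "corr_int_fold": corr,
            "mean_fitness": float(self.fitness[start:].mean()),
            "acceptance_rate": float(self.accepted.mean()),
        }

    def frame(self) -> pd.DataFrame:
        """Long-format per-generation table (one row per recorded generation)."""
        df = pd.DataFrame(
            {
                "generation": self.generations,
                "fitness": self.fitness,
                "accepted": self.accepted,
                "mean_dG_fold": self.dG_fold.mean(axis=1),
                "mean_dG_int": self.dG_int.mean(axis=1),
                "mean_dG_total": self.dG_total.mean(axis=1),
            }
        )
        return df


# ---------------------------------------------------------------------------
# Fitness and fixation
# ---------------------------------------------------------------------------


def fitness(state: EquilibriumState, c_scale: float) -> float:
    """Phi = exp(-c * total unfolded concentration); in (0, 1].

    Requires a converged equilibrium solved with explicit stabilities —
    without an unfolded pool the fitness function has nothing to act on.
    """
    if not state.converged:
        raise ValueError("fitness requires a converged equilibrium state")
    if state.dG_eff is None:
        raise ValueError(
            "fitness requires explicit stabilities (infinite-stability "
            "states have no unfolded load)"
        )
    if c_scale <= 0:
        raise ValueError("c_scale must be positive")
    return math.exp(-c_scale * state.total_unfolded())


def acceptance_probability(fitness_old: float, fitness_new: float, nu: float) -> float:
    """Metropolis rule min(1, (Phi_new/Phi_old)^nu); nu = 0 is neutral drift."""
    if fitness_old <= 0 or fitness_new <= 0:
        raise ValueError("fitnesses must be positive")
    if nu < 0:
        raise ValueError("nu must be >= 0")
    log_ratio = math.log(fitness_new) - math.log(fitness_old)
    return math.exp(min(0.0, nu * log_ratio))


def kimura_probability(fitness_old: float, fitness_new: float, nu: float) -> float:
    """Diffusion fixation probability with s = Phi_new/Phi_old - 1, scaled by nu."""
    if fitness_old <= 0 or fitness_new <= 0:
        raise ValueError("fitnesses must be positive")
    if nu < 0:
        raise ValueError("nu must be >= 0")
    if nu == 0:
        return 1.0
    s = fitness_new / fitness_old - 1.0
    if abs(s) < 1e-12:
        return 1.0 / nu if nu > 1 else 1.0
    num = -math.expm1(-2.0 * s)
    den = -math.expm1(max(-_MAX_EXP_ARG, -2.0 * nu * s))
    return min(1.0, num / den)


# ---------------------------------------------------------------------------
# Mutation kernel
# ---------------------------------------------------------------------------


def _reflect(value: float, floor: float, ceiling: float) -> float:
    """Reflect a proposed stability into [floor, ceiling]."""
    while value > ceiling or value < floor:
        if value > ceiling:
            value = 2.0 * ceiling - value
        else:
            value = 2.0 * floor - value
    return value


def _draw_mutation(
    n_proteins: int, n_edges: int, config: EvolutionConfig, rng: np.random.Generator
) -> tuple[str, int, float]:
    """Draw one mutation: ('dG', protein index, step) or ('kd', edge index, new K_d)."""
    if n_edges == 0 or rng.random() < config.p_stability:
        i = int(rng.integers(n_proteins))
        step = rng.normal(config.dG_step_mean, config.dG_step_sd)
        return ("dG", i, float(step))
    e = int(rng.integers(n_edges))
    new_kd = config.kd_median * math.exp(rng.normal(0.0, config.kd_log_sd))
    return ("kd", e, float(new_kd))


def propose_mutation(
    model: ProteomeModel, config: EvolutionConfig, rng: np.random.Generator
) -> ProteomeModel:
    """Apply exactly one mutation to a copy of ``model``.

    Either one protein's ``dG_fold`` takes a Gaussian step (reflected into
    [``config.dG_min``, ``config.dG_max``]) or one edge's K_d is resampled
    from the lognormal prior.  Abundances and topology are untouched.
    """
    if model.n_proteins < 1:
        raise ValueError("model must contain at least one protein")
    if not model.edges and config.p_stability < 1:
        raise ValueError("K_d mutations enabled but the model has no edges")
    kind, index, value = _draw_mutation(
        model.n_proteins, model.n_edges, config, rng
    )
    if kind == "dG":
        target = model.proteins[index]
        if target.dG_fold is None:
            raise ValueError(
                f"protein {target.id!r} has no dG_fold; evolution requires "
                "explicit stabilities"
            )
        new_dg = _reflect(target.dG_fold + value, config.dG_min, config.dG_max)
        proteins = list(model.proteins)
        proteins[index] = replace(target, dG_fold=new_dg)
        return model.with_proteins(proteins)
    edges = list(model.edges)
    edges[index] = replace(edges[index], K_d=value)
    return model.with_edges(edges)


# ---------------------------------------------------------------------------
# Organism construction
# ---------------------------------------------------------------------------


def _default_topology(
    n: int, mean_degree: float, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Seed-fixed connected G(n, m) graph with the requested mean degree."""
    m = max(n - 1, int(round(mean_degree * n / 2.0)))
    for _ in range(1000):
        graph = nx.gnm_random_graph(n, m, seed=int(rng.integers(2**31)))
        if nx.is_connected(graph):
            return sorted(tuple(sorted(e)) for e in graph.edges())
    raise RuntimeError("could not draw a connected topology")


def build_organism(config: EvolutionConfig) -> tuple[list[tuple[int, int]], np.ndarray]:
    """Resolve the fixed topology and abundances implied by ``config``."""
    rng = np.random.default_rng(config.seed)
    if config.edges is None:
        edges = _default_topology(config.n_proteins, config.mean_degree, rng)
    else:
        edges = [tuple(sorted(e)) for e in config.edges]
        if any(a == b for a, b in edges):
            raise ValueError("self-edges are not allowed in the topology")
        if len(set(edges)) != len(edges):
            raise ValueError("duplicate edges in the topology")
    if config.abundances is None:
        C = config.abundance_median * np.exp(
            rng.normal(0.0, config.abundance_log_sd, size=config.n_proteins)
        )
    else:
        C = np.asarray(config.abundances, dtype=float)
        if np.any(C <= 0):
            raise ValueError("abundances must be positive")
    return edges, C


def organism_model(
    config: EvolutionConfig,
    dG: np.ndarray | None = None,
    kd: np.ndarray | None = None,
) -> ProteomeModel:
    """Materialise the toy organism as a :class:`ProteomeModel` (for I/O and tests)."""
    edges, C = build_organism(config)
    n = config.n_proteins
    ids = [f"T{i+1:02d}" for i in range(n)]
    if dG is None:
        dG = np.full(n, config.dG_init)
    if kd is None:
        rng = np.random.default_rng(config.seed + 1)
        kd = config.kd_median * np.exp(rng.normal(0.0, config.kd_log_sd, len(edges)))
    proteins = [
        ProteinRecord(ids[i], float(C[i]), dG_fold=float(dG[i])) for i in range(n)
    ]
    edge_records = [
        InteractionEdge(ids[a], ids[b], K_d=float(k)) for (a, b), k in zip(edges, kd)
    ]
    return ProteomeModel(proteins, edge_records)


# ---------------------------------------------------------------------------
# The chain
# ---------------------------------------------------------------------------


class _Engine:
    """Array-based organism state with a warm-started equilibrium solve."""

    def __init__(
        self,
        C: np.ndarray,
        edges: list[tuple[int, int]],
        dG: np.ndarray,
        kd: np.ndarray,
        rel_tol: float,
        unfolded_feedback: bool = False,
    ):
        self.C = C
        self.n = len(C)
        self.edges = edges
        self.dG = dG.astype(float).copy()
        self.kd = kd.astype(float).copy()
        self.unfolded_feedback = unfolded_feedback
        self.W = np.zeros((self.n, self.n))
        for (a, b), k in zip(edges, self.kd):
            self.W[a, b] = self.W[b, a] = 1.0 / k
        self.F = C.astype(float).copy()
        self._options = SolverOptions(rel_tol=rel_tol, max_iter=100_000, damping=1.0)

    def set_kd(self, edge_index: int, kd: float) -> None:
        a, b = self.edges[edge_index]
        self.kd[edge_index] = kd
        self.W[a, b] = self.W[b, a] = 1.0 / kd

    def solve(self) -> tuple[float, np.ndarray]:
        """Return (total unfolded load, per-protein dG_int) at equilibrium.

        Two-level scheme (default): the network solve treats every protein
        as highly stable, and the unfolded fraction follows per protein from
        U/C = 1/(1 + e^dG (1 + K_int)).  With ``unfolded_feedback`` the
        unfolded pool enters the network solve itself.
        """
        if self.unfolded_feedback:
            u = np.exp(np.clip(-self.dG, None, _MAX_EXP_ARG))
        else:
            u = np.zeros(self.n)
        F, iters, converged, residual = _fixed_point(
            self.C, u, self.W, self._options, F0=self.F
        )
        if not converged:
            # retry from the cold start before giving up
            F, iters, converged, residual = _fixed_point(
                self.C, u, self.W, self._options, F0=None
            )
            if not converged:
                raise ConvergenceError(
                    f"equilibrium failed (residual {residual:.3e})",
                    residual=residual,
                )
        self.F = F
        K_int = self.W @ F
        dG_int = np.log1p(K_int)
        if self.unfolded_feedback:
            total_U = float(np.sum(u * F))
        else:
            stab = np.exp(np.clip(self.dG, None, _MAX_EXP_ARG))
            total_U = float(np.sum(self.C / (1.0 + stab * (1.0 + K_int))))
        return total_U, dG_int


def run_evolution(config: EvolutionConfig) -> EvolutionTrajectory:
    """Run one Metropolis chain of propose -> re-solve -> accept/reject.

    Seed-reproducible; records every ``config.thin``-th generation.  A
    solver failure mid-chain aborts with the generation index.
    """
    edges, C = build_organism(config)
    if not edges and config.p_stability < 1:
        raise ValueError("K_d mutations enabled but the topology has no edges")
    rng = np.random.default_rng(config.seed + 2)
    n = config.n_proteins
    dG = np.full(n, float(config.dG_init))
    kd_rng = np.random.default_rng(config.seed + 1)
    kd = config.kd_median * np.exp(kd_rng.normal(0.0, config.kd_log_sd, len(edges)))
    engine = _Engine(
        C, edges, dG, kd, config.solver_rel_tol,
        unfolded_feedback=config.unfolded_feedback,
    )

    accept = (
        acceptance_probability if config.fixation == "metropolis" else kimura_probability
    )

    try:
        total_U, dG_int = engine.solve()
    except ConvergenceError as exc:
        raise ConvergenceError(f"initial equilibrium failed: {exc}") from exc
    log_phi = -config.c_scale * total_U

    n_rec = config.n_generations // config.thin
    rec_gen = np.zeros(n_rec, dtype=int)
    rec_fit = np.zeros(n_rec)
    rec_acc = np.zeros(n_rec, dtype=bool)
    rec_dgf = np.zeros((n_rec, n))
    rec_dgi = np.zeros((n_rec, n))

    r = 0
    for gen in range(1, config.n_generations + 1):
        kind, index, value = _draw_mutation(n, len(edges), config, rng)
        if kind == "dG":
            old_val = engine.dG[index]
            engine.dG[index] = _reflect(old_val + value, config.dG_min, config.dG_max)
        else:
            old_val = engine.kd[index]
            engine.set_kd(index, value)
        F_before = engine.F.copy()
        try:
            new_U, new_dG_int = engine.solve()
        except ConvergenceError as exc:
            raise ConvergenceError(
                f"equilibrium solver failed at generation {gen}: {exc}"
            ) from exc
        new_log_phi = -config.c_scale * new_U
        if config.fixation == "metropolis":
            p = math.exp(min(0.0, config.nu * (new_log_phi - log_phi)))
        else:
            p = accept(math.exp(max(-_MAX_EXP_ARG, log_phi)),
                       math.exp(max(-_MAX_EXP_ARG, new_log_phi)), config.nu)
        accepted = rng.random() < p
        if accepted:
            log_phi = new_log_phi
            dG_int = new_dG_int
        else:
            if kind == "dG":
                engine.dG[index] = old_val
            else:
                engine.set_kd(index, old_val)
            engine.F = F_before
        if gen % config.thin == 0:
            rec_gen[r] = gen
            rec_fit[r] = math.exp(max(-_MAX_EXP_ARG, log_phi))
            rec_acc[r] = accepted
            rec_dgf[r] = engine.dG
            rec_dgi[r] = dG_int
            r += 1

    return EvolutionTrajectory(
        config=config,
        generations=rec_gen,
        fitness=rec_fit,
        accepted=rec_acc,
        dG_fold=rec_dgf,
        dG_int=rec_dgi,
        edges=edges,
        abundances=C,
    )


def population_size_sweep(
    config: EvolutionConfig,
    nu_values: Sequence[float],
    replicates: int = 3,
) -> pd.DataFrame:
    """Replicate-averaged post-burn-in observables across population sizes.

    All runs share the organism (topology and abundances) fixed by
    ``config.seed``; replicates differ only in the mutation stream.
    Returns one row per nu with columns ``nu``, ``mean_dG_fold``,
    ``mean_dG_int``, ``mean_dG_total``, ``corr_int_fold``,
    ``acceptance_rate`` and ``n_replicates``.
    """
    if len(nu_values) < 2:
        raise ValueError("sweep needs at least two nu values")
    if replicates < 1:
        raise ValueError("need at least one replicate")
    edges, C = build_organism(config)
    rows = []
    for nu in nu_values:
        reps = []
        for rep in range(replicates):
            run_cfg = replace(
                config,
                nu=float(nu),
                edges=edges,
                abundances=C,
                seed=config.seed + 7919 * (rep + 1),
            )
            traj = run_evolution(run_cfg)
            reps.append(traj.summary())
        rows.append(
            {
                "nu": float(nu),
                "mean_dG_fold": float(np.mean([s["mean_dG_fold"] for s in reps])),
                "mean_dG_int": float(np.mean([s["mean_dG_int"] for s in reps])),
                "mean_dG_total": float(np.mean([s["mean_dG_total"] for s in reps])),
                "corr_int_fold": float(np.nanmean([s["corr_int_fold"] for s in reps])),
                "acceptance_rate": float(
                    np.mean([s["acceptance_rate"] for s in reps])
                ),
                "n_replicates": replicates,
            }
        )
        logger.info("nu=%g done: %s", nu, rows[-1])
    return pd.DataFrame(rows)
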