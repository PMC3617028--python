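"""Synthetic proteomes with the statistical structure the analysis assumes.

Real inputs for this kind of analysis — curated binary interactions,
absolute abundances, localisation calls, sequence-based aggregation
scores — require database access.  This module generates stand-ins with
the same broad statistics so the whole pipeline is exercisable and its
recovery properties testable:

* lognormal abundances spanning several orders of magnitude;
* sparse interaction networks with Poisson or heavy-tailed (power-law)
  degree structure, realised as simple graphs;
* lognormal dissociation constants (or the abundance-based recipe);
* optionally, intrinsic stabilities with a *planted* coupling to binding
  strength: less stable proteins get systematically tighter interactions
  (lower K_d), emulating compensatory evolution, so the association
  between instability and interaction-induced stabilisation is a
  recoverable planted truth rather than an accident;
* aggregation scores generated as a linear-plus-noise function of
  stability and log-abundance (negative coefficients), emulating the
  empirical behaviour of sequence-based aggregation predictors without
  claiming to model any of them.

Small fixed fixtures (heterodimer, star, three-protein chain) used by the
closed-form examples are exposed as functions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx
import numpy as np

from .io_formats import InteractionEdge, ProteinRecord, ProteomeModel
from . import mass_action

logger = logging.getLogger(__name__)

_GRAPH_ATTEMPTS = 100


@dataclass
class GeneratorSpec:
    """Parameters of the synthetic proteome generator.

    Degree models: ``poisson`` (param ``mean``) or ``powerlaw`` (params
    ``exponent``, ``min_degree``).  Stability: ``infinite`` leaves
    ``dG_fold`` unset; ``normal`` draws i.i.d. Normal(mean, sd) k_BT.
    ``kd_stability_coupling`` (gamma >= 0) tilts each assigned K_d by
    exp(gamma * (min(dG_a, dG_b) - stability_mean)): interactions whose
    least stable member sits below the population mean become tighter.
    Aggregation scores follow
    agg = beta_stability * dG_fold + beta_log_abundance * ln C + noise.
    """

    n_proteins: int = 300
    degree_model: str = "poisson"
    degree_params: Mapping = field(default_factory=lambda: {"mean": 3.0})
    abundance_median: float = 50.0
    abundance_log_sd: float = 1.5
    stability: str = "normal"
    stability_mean: float = 10.0
    stability_sd: float = 3.0
    kd_rule: str = "lognormal"
    kd_params: Mapping = field(default_factory=lambda: {"median": 50.0, "log_sd": 1.0})
    kd_stability_coupling: float = 0.5
    agg_beta_stability: float = -1.0
    agg_beta_log_abundance: float = -0.5
    agg_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 2:
            raise ValueError("n_proteins must be >= 2")
        if self.degree_model not in ("poisson", "powerlaw"):
            raise ValueError(f"unknown degree_model {self.degree_model!r}")
        if self.stability not in ("infinite", "normal"):
            raise ValueError(f"unknown stability model {self.stability!r}")
        if self.abundance_median <= 0 or self.abundance_log_sd <= 0:
            raise ValueError("abundance parameters must be positive")
        if self.kd_stability_coupling < 0:
            raise ValueError("kd_stability_coupling must be >= 0")
        if self.agg_beta_stability > 0 or self.agg_beta_log_abundance > 0:
            raise ValueError(
                "aggregation coefficients must be <= 0 (scores fall with "
                "stability and abundance)"
            )
        if self.agg_noise_sd < 0:
            raise ValueError("agg_noise_sd must be >= 0")


def _degree_sequence(spec: GeneratorSpec, rng: np.random.Generator) -> np.ndarray:
    n = spec.n_proteins
    if spec.degree_model == "poisson":
        mean = float(spec.degree_params.get("mean", 3.0))
        if mean <= 0:
            raise ValueError("poisson mean must be positive")
        deg = rng.poisson(mean, size=n)
    else:
        exponent = float(spec.degree_params.get("exponent", 2.5))
        min_degree = int(spec.degree_params.get("min_degree", 1))
        if exponent <= 1 or min_degree < 1:
            raise ValueError("powerlaw needs exponent > 1 and min_degree >= 1")
        deg = rng.zipf(exponent, size=n) + (min_degree - 1)
    return np.minimum(deg, n - 1)


def _simple_graph(spec: GeneratorSpec, rng: np.random.Generator) -> nx.Graph:
    """Realise the degree model as a simple graph (no self-loops/multi-edges).

    A configuration-model draw is simplified by discarding self-loops and
    parallel edges; unrealisable degree sequences are redrawn (logged), with
    an error after a bounded number of attempts.
    """
    for attempt in range(_GRAPH_ATTEMPTS):
        deg = _degree_sequence(spec, rng)
        if deg.sum() % 2 == 1:
            deg[int(rng.integers(len(deg)))] += 1
            logger.debug("degree sum odd; bumped one degree (attempt %d)", attempt)
        if not nx.is_graphical(deg.tolist()):
            logger.debug("non-graphical degree sequence; redrawing (attempt %d)", attempt)
            continue
        multigraph = nx.configuration_model(
            deg.tolist(), seed=int(rng.integers(2**31))
        )
        graph = nx.Graph(multigraph)
        graph.remove_edges_from(nx.selfloop_edges(graph))
        return graph
    raise RuntimeError(
        f"could not realise a graphical degree sequence in {_GRAPH_ATTEMPTS} attempts"
    )


def generate_proteome(spec: GeneratorSpec) -> ProteomeModel:
    """Draw a seed-reproducible synthetic proteome from ``spec``."""
    rng = np.random.default_rng(spec.seed)
    graph = _simple_graph(spec, rng)

    n = spec.n_proteins
    width = len(str(n))
    ids = [f"P{i:0{width}d}" for i in range(1, n + 1)]
    C = spec.abundance_median * np.exp(rng.normal(0.0, spec.abundance_log_sd, size=n))
    if spec.stability == "normal":
        dG = rng.normal(spec.stability_mean, spec.stability_sd, size=n)
    else:
        dG = None

    proteins = [
        ProteinRecord(
            id=ids[i],
            C_total=float(C[i]),
            dG_fold=None if dG is None else float(dG[i]),
        )
        for i in range(n)
    ]
    edges = [InteractionEdge(a=ids[i], b=ids[j]) for i, j in sorted(graph.edges())]
    model = ProteomeModel(proteins, edges)
    model = mass_action.assign_kd(
        model, rule=spec.kd_rule, params=spec.kd_params,
        seed=int(rng.integers(2**31)),
    )

    if dG is not None and spec.kd_stability_coupling > 0 and model.edges:
        gamma = spec.kd_stability_coupling
        idx = {pid: i for i, pid in enumerate(ids)}
        tilted = []
        for e in model.edges:
            weakest = min(dG[idx[e.a]], dG[idx[e.b]])
            factor = float(np.exp(gamma * (weakest - spec.stability_mean)))
            tilted.append(
                InteractionEdge(e.a, e.b, K_d=e.K_d * factor,
                                n_experiments=e.n_experiments)
            )
        model = model.with_edges(tilted)
    return model


def generate_agg_scores(model: ProteomeModel, spec: GeneratorSpec) -> ProteomeModel:
    """Fill in planted aggregation-propensity scores (requires explicit stabilities)."""
    if any(p.dG_fold is None for p in model.proteins):
        raise ValueError(
            "aggregation scores require explicit stabilities; generate the "
            "proteome with stability='normal'"
        )
    rng = np.random.default_rng(None if spec.seed is None else spec.seed + 1)
    noise = rng.normal(0.0, spec.agg_noise_sd, size=model.n_proteins)
    proteins = []
    for p, eps in zip(model.proteins, noise):
        score = (
            spec.agg_beta_stability * p.dG_fold
            + spec.agg_beta_log_abundance * np.log(p.C_total)
            + eps
        )
        proteins.append(
            ProteinRecord(
                id=p.id, C_total=p.C_total, dG_fold=p.dG_fold,
                agg_score=float(score), length=p.length,
            )
        )
    return model.with_proteins(proteins)


# ---------------------------------------------------------------------------
# Fixed example fixtures
# ---------------------------------------------------------------------------


def fixture_heterodimer() -> ProteomeModel:
    """A and B at 100 nM each, one edge with K_d = 5 nM.

    The symmetric closed form F^2/K + F - C = 0 gives F_A = F_B = 20 nM,
    D_AB = 80 nM, dG_int = ln 5 on both sides.
    """
    return ProteomeModel(
        [ProteinRecord("A", 100.0), ProteinRecord("B", 100.0)],
        [InteractionEdge("A", "B", K_d=5.0)],
    )


def fixture_star(k: int) -> ProteomeModel:
    """Hub H with ``k`` spokes S1..Sk; all concentrations 100 nM, K_d = 10 nM."""
    if k < 1:
        raise ValueError("need at least one spoke")
    proteins = [ProteinRecord("H", 100.0)] + [
        ProteinRecord(f"S{i}", 100.0) for i in range(1, k + 1)
    ]
    edges = [InteractionEdge("H", f"S{i}", K_d=10.0) for i in range(1, k + 1)]
    return ProteomeModel(proteins, edges)


def fixture_chain3() -> ProteomeModel:
    """Linear chain A-B-C; all concentrations 100 nM, K_d = 10 nM."""
    return ProteomeModel(
        [ProteinRecord("A", 100.0), ProteinRecord("B", 100.0), ProteinRecord("C", 100.0)],
        [InteractionEdge("A", "B", K_d=10.0), InteractionEdge("B", "C", K_d=10.0)],
    )
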