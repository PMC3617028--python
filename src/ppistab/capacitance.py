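"""Evolutionary capacitance: the proteome-wide stability a protein provides.

Knocking a protein out of the network removes the stabilisation it lends
its partners (and can shift stability elsewhere through the shared
equilibrium).  A protein's evolutionary capacitance is the cumulative
induced-stability loss across the proteome caused by its in-silico
knockout,

    Cap_i = sum_j max(0, dG_int,j(full) - dG_int,j(without i)),

summed over all proteins j != i that are *destabilised* by the knockout.
Indirect effects can have either sign — removing a competitor can free a
shared partner and stabilise a third party — but only positive stability
losses count towards the capacitance.  High-capacitance proteins buffer
destabilising variation in their partners the way chaperones do.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_formats import ProteomeModel
from .mass_action import ConvergenceError, SolverOptions, solve_equilibrium
from .stability import induced_stability, interaction_constants

logger = logging.getLogger(__name__)

#: Stability losses below this (k_BT) are solver noise, not destabilisation.
DESTABILIZATION_FLOOR = 1e-12


@dataclass
class CapacitanceReport:
    """Ranked per-protein capacitances plus per-affected-protein contributions.

    ``table`` columns: id, capacitance (k_BT), degree, rank (1 = highest).
    ``contributions`` columns: knocked_out, affected, ddG_int (k_BT > 0).
    ``failures`` lists (protein id, error message) for knockouts whose
    re-solve failed; their capacitance is NaN in the table.
    """

    table: pd.DataFrame
    contributions: pd.DataFrame
    failures: list[tuple[str, str]] = field(default_factory=list)


def knockout(model: ProteomeModel, protein: str) -> ProteomeModel:
    """Remove a protein and all its interactions from the network."""
    if protein not in model.index():
        raise KeyError(f"unknown protein id {protein!r}")
    proteins = [p for p in model.proteins if p.id != protein]
    edges = [e for e in model.edges if protein not in (e.a, e.b)]
    return ProteomeModel(proteins, edges, model.units)


def reduce_dosage(model: ProteomeModel, protein: str, fraction: float) -> ProteomeModel:
    """Scale a protein's total concentration by ``fraction`` in [0, 1).

    ``fraction == 0`` is equivalent to a full knockout (the protein is
    removed, since a zero concentration is not a valid record).
    """
    if not (0 <= fraction < 1):
        raise ValueError("dosage fraction must be in [0, 1)")
    if fraction == 0:
        return knockout(model, protein)
    if protein not in model.index():
        raise KeyError(f"unknown protein id {protein!r}")
    proteins = [
        replace(p, C_total=p.C_total * fraction) if p.id == protein else p
        for p in model.proteins
    ]
    return ProteomeModel(proteins, model.edges, model.units)


def _dg_int_by_id(model: ProteomeModel, options: SolverOptions) -> dict[str, float]:
    state = solve_equilibrium(model, options)
    dg = induced_stability(interaction_constants(state, model))
    return dict(zip(model.ids, np.atleast_1d(dg)))


def _contributions(
    full_dg: dict[str, float],
    ko_dg: dict[str, float],
    protein: str,
    partners: set[str],
    partners_only: bool,
    floor: float,
) -> list[tuple[str, float]]:
    out = []
    for pid, dg_full in full_dg.items():
        if pid == protein:
            continue
        if partners_only and pid not in partners:
            continue
        loss = dg_full - ko_dg.get(pid, 0.0)
        if loss > floor:
            out.append((pid, loss))
    return out


def capacitance_of(
    model: ProteomeModel,
    protein: str,
    options: SolverOptions | None = None,
    partners_only: bool = False,
    dosage: float = 0.0,
    floor: float = DESTABILIZATION_FLOOR,
) -> float:
    """Capacitance of one protein by knockout (or dosage reduction) and re-solve.

    ``partners_only`` restricts the sum to the protein's direct interaction
    partners instead of every destabilised protein in the network.
    ``dosage`` in [0, 1) scales the protein's concentration instead of
    removing it (0 = full knockout).
    """
    options = options or SolverOptions()
    if protein not in model.index():
        raise KeyError(f"unknown protein id {protein!r}")
    full_dg = _dg_int_by_id(model, options)
    perturbed = reduce_dosage(model, protein, dosage)
    ko_dg = _dg_int_by_id(perturbed, options)
    partners = set(model.partners()[protein])
    contribs = _contributions(full_dg, ko_dg, protein, partners, partners_only, floor)
    return float(sum(loss for _, loss in contribs))


def capacitance_report(
    model: ProteomeModel,
    options: SolverOptions | None = None,
    partners_only: bool = False,
    dosage: float = 0.0,
    floor: float = DESTABILIZATION_FLOOR,
) -> CapacitanceReport:
    """Knock out every protein in turn and rank by capacitance.

    The full-network equilibrium is solved once; each knockout re-solves
    the reduced network.  A knockout whose re-solve fails is recorded in
    ``failures`` and the run continues.
    """
    options = options or SolverOptions()
    full_dg = _dg_int_by_id(model, options)
    degree = model.degree()
    adjacency = model.partners()

    caps: dict[str, float] = {}
    rows: list[tuple[str, str, float]] = []
    failures: list[tuple[str, str]] = []
    for pid in model.ids:
        try:
            perturbed = reduce_dosage(model, pid, dosage)
            ko_dg = _dg_int_by_id(perturbed, options)
        except ConvergenceError as exc:
            logger.warning("knockout of %s failed to converge: %s", pid, exc)
            failures.append((pid, str(exc)))
            caps[pid] = float("nan")
            continue
        contribs = _contributions(
            full_dg, ko_dg, pid, set(adjacency[pid]), partners_only, floor
        )
        caps[pid] = float(sum(loss for _, loss in contribs))
        rows.extend((pid, affected, loss) for affected, loss in contribs)

    table = pd.DataFrame(
        {
            "id": model.ids,
            "capacitance": [caps[pid] for pid in model.ids],
            "degree": [degree[pid] for pid in model.ids],
        }
    )
    # ties broken by id so that re-runs produce identical ranks
    order = table.sort_values(
        ["capacitance", "id"], ascending=[False, True], na_position="last"
    ).reset_index(drop=True)
    rank = {pid: i + 1 for i, pid in enumerate(order["id"])}
    table["rank"] = [rank[pid] for pid in table["id"]]
    contributions = pd.DataFrame(rows, columns=["knocked_out", "affected", "ddG_int"])
    if failures:
        logger.warning("%d knockout(s) failed: %s", len(failures), [f[0] for f in failures])
    return CapacitanceReport(table=table, contributions=contributions, failures=failures)
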