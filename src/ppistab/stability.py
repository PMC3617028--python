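"""Interaction-induced stability from a converged network equilibrium.

Binding partners deplete a protein's free monomer pool, and with it the
unfolded pool that exchanges with the free monomer.  At self-consistency
the depletion is summarised by the dimensionless interaction constant

    K_int,i = sum_j F_j / K_ij

over the focal protein's partners j (free concentrations F_j from the full
network solve), and the corresponding effective stabilisation is

    dG_int,i = ln(1 + K_int,i)        [k_BT, always >= 0].

For a protein with intrinsic stability dG_f the unfolded fraction in the
network is U/C = 1 / (1 + exp(dG_f) (1 + K_int)); the factor (1 + K_int)
is exactly the extra suppression relative to the same protein with no
partners, which is what justifies reading ln(1 + K_int) as added stability.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .io_formats import KBT_TO_KCAL_PER_MOL, ProteomeModel
from .mass_action import EquilibriumState


def _require_converged(state: EquilibriumState) -> None:
    if not state.converged:
        raise ValueError("equilibrium state is not converged")


def interaction_constants(state: EquilibriumState, model: ProteomeModel) -> np.ndarray:
    """Vector of K_int,i = sum over partners j of F_j / K_ij, aligned with model.ids."""
    _require_converged(state)
    idx = model.index()
    pos = {pid: i for i, pid in enumerate(state.ids)}
    K_int = np.zeros(model.n_proteins)
    for e in model.edges:
        K_int[idx[e.a]] += state.F[pos[e.b]] / e.K_d
        K_int[idx[e.b]] += state.F[pos[e.a]] / e.K_d
    return K_int


def interaction_constant(
    state: EquilibriumState, model: ProteomeModel, protein: str
) -> float:
    """K_int for one protein; raises ``KeyError`` for an unknown id."""
    idx = model.index()
    if protein not in idx:
        raise KeyError(f"unknown protein id {protein!r}")
    return float(interaction_constants(state, model)[idx[protein]])


def induced_stability(K_int) -> float | np.ndarray:
    """dG_int = ln(1 + K_int) in k_BT; zero iff the interaction constant is zero."""
    K_int = np.asarray(K_int, dtype=float)
    if np.any(K_int < 0):
        raise ValueError("K_int must be nonnegative")
    out = np.log1p(K_int)
    return float(out) if out.ndim == 0 else out


def unfolded_fraction(dG_fold: float, K_int: float) -> float:
    """Equilibrium unfolded fraction U/C = 1 / (1 + e^{dG_fold} (1 + K_int))."""
    if not math.isfinite(dG_fold):
        raise ValueError("dG_fold must be finite")
    if K_int < 0:
        raise ValueError("K_int must be nonnegative")
    return 1.0 / (1.0 + math.exp(dG_fold) * (1.0 + K_int))


def stability_profile(state: EquilibriumState, model: ProteomeModel) -> pd.DataFrame:
    """Per-protein stability table from a converged equilibrium.

    Columns: ``id``, ``C_total``, ``K_int``, ``dG_int`` (k_BT),
    ``dG_total`` (k_BT; NaN in infinite-stability mode, where no intrinsic
    stability is defined), ``monomer_fraction``, ``unfolded_fraction``
    (NaN in infinite-stability mode) and ``bound_fraction``.
    """
    _require_converged(state)
    K_int = interaction_constants(state, model)
    dG_int = induced_stability(K_int)
    bound = state.bound()
    if state.dG_eff is None:
        dG_total = np.full(model.n_proteins, np.nan)
        unfolded = np.full(model.n_proteins, np.nan)
    else:
        dG_total = state.dG_eff + dG_int
        unfolded = state.U / state.C
    return pd.DataFrame(
        {
            "id": state.ids,
            "C_total": state.C,
            "K_int": K_int,
            "dG_int": dG_int,
            "dG_total": dG_total,
            "monomer_fraction": state.F / state.C,
            "unfolded_fraction": unfolded,
            "bound_fraction": bound / state.C,
        }
    )


def add_kcal_columns(profile: pd.DataFrame) -> pd.DataFrame:
    """Append display columns converting the k_BT energies to kcal/mol (298 K)."""
    out = profile.copy()
    for col in ("dG_int", "dG_total"):
        if col in out.columns:
            out[f"{col}_kcal_per_mol"] = out[col] * KBT_TO_KCAL_PER_MOL
    return out
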