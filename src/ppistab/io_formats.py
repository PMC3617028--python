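"""Proteome tables, interaction edge lists, and result I/O.

A proteome is described by two tab-separated files:

* a **protein table** with columns ``id`` and ``C_total`` (total cellular
  concentration in nM) and optional columns ``dG_fold`` (intrinsic folding
  stability in units of k_BT, positive = folded state favoured),
  ``agg_score`` (a dimensionless aggregation-propensity score, e.g. from a
  sequence-based predictor) and ``length`` (residue count);
* an **edge list** with columns ``a`` and ``b`` (protein ids) and optional
  columns ``K_d`` (dissociation constant of the heterodimer in nM) and
  ``n_experiments`` (number of independent experimental observations of the
  interaction, used for evidence filtering).

All concentrations are in nM and all energies in k_BT throughout the
package; :data:`KBT_TO_KCAL_PER_MOL` converts energies for display and
:func:`molecules_per_cell_to_nm` converts copy-number abundances.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

AVOGADRO = 6.02214076e23

#: k_BT at 298 K expressed in kcal/mol, used only when writing display columns.
KBT_TO_KCAL_PER_MOL = 0.593

#: Default cell volume used by the copy-number converter (haploid yeast).
DEFAULT_CELL_VOLUME_FL = 42.0


class FormatError(ValueError):
    """A required column is missing or a file cannot be parsed."""


class ValidationError(ValueError):
    """Parsed data violates a proteome invariant (ids, signs, self-edges)."""


def molecules_per_cell_to_nm(
    copies: float, cell_volume_fl: float = DEFAULT_CELL_VOLUME_FL
) -> float:
    """Convert molecules/cell to a concentration in nM.

    ``cell_volume_fl`` is the cell volume in femtolitres; the default of
    42 fL corresponds to a haploid budding-yeast cell.
    """
    if cell_volume_fl <= 0:
        raise ValueError("cell volume must be positive")
    litres = cell_volume_fl * 1e-15
    return copies / (AVOGADRO * litres) * 1e9


def nm_to_molecules_per_cell(
    conc_nm: float, cell_volume_fl: float = DEFAULT_CELL_VOLUME_FL
) -> float:
    """Inverse of :func:`molecules_per_cell_to_nm`."""
    if cell_volume_fl <= 0:
        raise ValueError("cell volume must be positive")
    litres = cell_volume_fl * 1e-15
    return conc_nm * 1e-9 * AVOGADRO * litres


@dataclass(frozen=True)
class ProteinRecord:
    """One protein: identity, abundance, and optional annotations.

    ``dG_fold`` may be ``None``, meaning the protein is treated as
    infinitely stable (its unfolded pool is negligible); ``agg_score``
    is an externally supplied aggregation-propensity score consumed by
    the correlation analyses, never computed here.
    """

    id: str
    C_total: float
    dG_fold: float | None = None
    agg_score: float | None = None
    length: int | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("protein id must be a nonempty string")
        if not (self.C_total > 0) or not math.isfinite(self.C_total):
            raise ValidationError(
                f"protein {self.id!r}: C_total must be positive and finite, "
                f"got {self.C_total!r}"
            )
        if self.agg_score is not None and not math.isfinite(self.agg_score):
            raise ValidationError(f"protein {self.id!r}: agg_score must be finite")
        if self.length is not None and self.length <= 0:
            raise ValidationError(f"protein {self.id!r}: length must be positive")


@dataclass(frozen=True)
class InteractionEdge:
    """One undirected heterodimer interaction between proteins ``a`` and ``b``.

    ``K_d`` (nM) may be ``None`` before a dissociation-constant assignment
    rule has been applied.  Self-interactions are rejected: the dimer
    equations treat heterodimers only.
    """

    a: str
    b: str
    K_d: float | None = None
    n_experiments: int | None = None

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise ValidationError(
                f"self-interaction ({self.a}, {self.b}) is not allowed; the "
                "dimer model covers heterodimers only"
            )
        if self.K_d is not None and not (self.K_d > 0 and math.isfinite(self.K_d)):
            raise ValidationError(
                f"edge ({self.a}, {self.b}): K_d must be positive and finite"
            )
        if self.n_experiments is not None and self.n_experiments < 0:
            raise ValidationError(
                f"edge ({self.a}, {self.b}): n_experiments must be >= 0"
            )

    @property
    def key(self) -> tuple[str, str]:
        """Canonical undirected key (sorted endpoint pair)."""
        return (self.a, self.b) if self.a <= self.b else (self.b, self.a)


@dataclass
class ProteomeModel:
    """A proteome: proteins plus the undirected interaction network.

    Invariants (checked by :meth:`validate`, which runs on construction):
    unique nonempty protein ids, every edge endpoint present, no
    self-edges, no duplicate undirected edges.
    """

    proteins: list[ProteinRecord]
    edges: list[InteractionEdge]
    units: tuple[str, str] = ("nM", "kBT")

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ---------------------------------------------------
    def validate(self) -> None:
        ids = [p.id for p in self.proteins]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate protein ids: {dupes}")
        known = set(ids)
        missing = sorted(
            {e.a for e in self.edges if e.a not in known}
            | {e.b for e in self.edges if e.b not in known}
        )
        if missing:
            raise ValidationError(
                f"edges reference unknown protein ids: {missing}"
            )
        keys = [e.key for e in self.edges]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise ValidationError(f"duplicate undirected edges: {dupes}")

    # -- convenience accessors ---------------------------------------
    @property
    def ids(self) -> list[str]:
        return [p.id for p in self.proteins]

    @property
    def n_proteins(self) -> int:
        return len(self.proteins)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def index(self) -> dict[str, int]:
        """Map protein id -> position in :attr:`proteins`."""
        return {p.id: i for i, p in enumerate(self.proteins)}

    def protein(self, pid: str) -> ProteinRecord:
        try:
            return self.proteins[self.index()[pid]]
        except KeyError:
            raise KeyError(f"unknown protein id {pid!r}") from None

    def partners(self) -> dict[str, list[str]]:
        """Adjacency map id -> sorted list of partner ids."""
        adj: dict[str, list[str]] = {p.id: [] for p in self.proteins}
        for e in self.edges:
            adj[e.a].append(e.b)
            adj[e.b].append(e.a)
        return {k: sorted(v) for k, v in adj.items()}

    def degree(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.partners().items()}

    def concentrations(self) -> np.ndarray:
        return np.array([p.C_total for p in self.proteins], dtype=float)

    def copy(self) -> "ProteomeModel":
        return ProteomeModel(list(self.proteins), list(self.edges), self.units)

    def with_proteins(self, proteins: Sequence[ProteinRecord]) -> "ProteomeModel":
        return ProteomeModel(list(proteins), list(self.edges), self.units)

    def with_edges(self, edges: Sequence[InteractionEdge]) -> "ProteomeModel":
        return ProteomeModel(list(self.proteins), list(edges), self.units)

    # -- frames -------------------------------------------------------
    def protein_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [p.id for p in self.proteins],
                "C_total": [p.C_total for p in self.proteins],
                "dG_fold": [p.dG_fold for p in self.proteins],
                "agg_score": [p.agg_score for p in self.proteins],
                "length": [p.length for p in self.proteins],
            }
        )

    def edge_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "a": [e.a for e in self.edges],
                "b": [e.b for e in self.edges],
                "K_d": [e.K_d for e in self.edges],
                "n_experiments": [e.n_experiments for e in self.edges],
            }
        )


# ---------------------------------------------------------------------------
# Reading and writing
# ---------------------------------------------------------------------------

_PROTEIN_REQUIRED = ("id", "C_total")
_EDGE_REQUIRED = ("a", "b")


def _require_columns(df: pd.DataFrame, required: Iterable[str], what: str) -> None:
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{what} is missing required column {col!r}")


def _opt(row: Mapping, col: str):
    if col not in row:
        return None
    val = row[col]
    if val is None or (isinstance(val, float) and math.isnan(val)):
        return None
    return val


def read_protein_table(path) -> list[ProteinRecord]:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, _PROTEIN_REQUIRED, f"protein table {path}")
    records = []
    for row in df.to_dict("records"):
        length = _opt(row, "length")
        records.append(
            ProteinRecord(
                id=str(row["id"]),
                C_total=float(row["C_total"]),
                dG_fold=(None if (v := _opt(row, "dG_fold")) is None else float(v)),
                agg_score=(None if (v := _opt(row, "agg_score")) is None else float(v)),
                length=None if length is None else int(length),
            )
        )
    return records


def read_edge_list(path) -> list[InteractionEdge]:
    """Read an edge list, collapsing duplicate undirected edges.

    When the same undirected pair appears more than once (e.g. listed both
    as (A,B) and (B,A)), the copy with the largest ``n_experiments`` is
    kept, so evidence filtering sees the strongest support for the pair.
    """
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, _EDGE_REQUIRED, f"edge list {path}")
    best: dict[tuple[str, str], InteractionEdge] = {}
    for row in df.to_dict("records"):
        edge = InteractionEdge(
            a=str(row["a"]),
            b=str(row["b"]),
            K_d=(None if (v := _opt(row, "K_d")) is None else float(v)),
            n_experiments=(
                None if (v := _opt(row, "n_experiments")) is None else int(v)
            ),
        )
        prev = best.get(edge.key)
        if prev is None:
            best[edge.key] = edge
        else:
            logger.info("collapsing duplicate edge %s", edge.key)
            prev_n = -1 if prev.n_experiments is None else prev.n_experiments
            new_n = -1 if edge.n_experiments is None else edge.n_experiments
            if new_n > prev_n:
                best[edge.key] = edge
    return list(best.values())


def read_proteome(protein_table_path, edge_list_path) -> ProteomeModel:
    """Read and validate a proteome from a protein table and an edge list."""
    proteins = read_protein_table(protein_table_path)
    edges = read_edge_list(edge_list_path)
    return ProteomeModel(proteins, edges)


def write_proteome(model: ProteomeModel, protein_table_path, edge_list_path) -> None:
    """Write a proteome back to the two-file TSV representation."""
    write_results(model.protein_frame(), protein_table_path)
    write_results(model.edge_frame(), edge_list_path)


def write_results(table: pd.DataFrame, path) -> None:
    """Write a result table as TSV with full float precision.

    Column order is preserved as given; re-reading the file reproduces all
    numeric values exactly (pandas round-trips floats via ``repr``).
    """
    table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Evidence filtering
# ---------------------------------------------------------------------------


def filter_by_evidence(model: ProteomeModel, min_experiments: int = 2) -> ProteomeModel:
    """Keep only interactions confirmed in at least ``min_experiments`` experiments.

    Proteins are never removed: a protein left without partners legitimately
    has zero interaction-induced stability and still contributes its
    unfolded pool downstream.  Edges without an ``n_experiments`` annotation
    are treated as single-experiment evidence.
    """
    if min_experiments < 1:
        raise ValueError("min_experiments must be >= 1")
    kept = [
        e
        for e in model.edges
        if (1 if e.n_experiments is None else e.n_experiments) >= min_experiments
    ]
    logger.info(
        "evidence filter (min_experiments=%d): %d/%d edges kept",
        min_experiments,
        len(kept),
        len(model.edges),
    )
    return model.with_edges(kept)
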