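"""Operating and ecological diagrams over the (s_in, D) plane.

For every point of a grid of inlet concentrations and dilution rates the
full equilibrium analysis is run and each *stable* equilibrium contributes
one outcome:

* the **ecological diagram** records the set of surviving OTUs per stable
  equilibrium — which species coexist where;
* the **operating diagram** collapses each survivor set to its operational
  label: partial nitrification (``PN``, AOB survive but all NOB washed
  out, nitrite accumulates), complete nitrification (``CN``, some NOB
  survive, nitrate is produced), or washout (``WO``, no biomass).

Cells carrying two or more stable equilibria with *different* survivor
sets are flagged bistable: the reactor's fate there depends on its initial
condition.  Cells where the analysis finds only marginal equilibria (or
fails) are labelled ``unknown`` rather than guessed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .equilibria import EquilibriumAnalyzer
from .model import CommunityModel

__all__ = ["CellOutcome", "DiagramGrid", "ecological_diagram", "operating_diagram"]


@dataclass(frozen=True)
class CellOutcome:
    """One stable outcome at one operating point."""

    survivors: tuple[int, ...]
    label: str  # 'PN' | 'CN' | 'WO' | 'unknown'


@dataclass(frozen=True)
class DiagramGrid:
    """Outcome sets over the (s_in, D) plane.

    ``cells[i][j]`` holds the outcomes at ``(s_in_axis[i], D_axis[j])``,
    sorted for determinism.
    """

    s_in_axis: np.ndarray
    D_axis: np.ndarray
    cells: tuple[tuple[tuple[CellOutcome, ...], ...], ...]
    kind: str  # 'ecological' | 'operating'

    def outcomes(self, i: int, j: int) -> tuple[CellOutcome, ...]:
        return self.cells[i][j]

    def is_bistable(self, i: int, j: int) -> bool:
        """True when >= 2 stable equilibria with different survivor sets
        coexist at the cell (not merely different concentrations)."""
        survs = {c.survivors for c in self.cells[i][j] if c.label != "unknown"}
        return len(survs) >= 2

    def labels(self, i: int, j: int) -> tuple[str, ...]:
        return tuple(sorted({c.label for c in self.cells[i][j]}))

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per (s_in, D, outcome)."""
        rows = []
        for i, s_in in enumerate(self.s_in_axis):
            for j, D in enumerate(self.D_axis):
                for rank, c in enumerate(self.cells[i][j]):
                    rows.append(
                        {
                            "s_in_g_per_L": float(s_in),
                            "D_per_day": float(D),
                            "outcome_rank": rank,
                            "survivor_set": "+".join(f"x{k+1}" for k in c.survivors) or "-",
                            "label": c.label,
                            "bistable": self.is_bistable(i, j),
                        }
                    )
        return pd.DataFrame(rows)


def _label_of(survivors: tuple[int, ...], g2: frozenset[int]) -> str:
    if not survivors:
        return "WO"
    if set(survivors) & g2:
        return "CN"
    return "PN"


def ecological_diagram(
    model: CommunityModel,
    s_in_axis: np.ndarray,
    D_axis: np.ndarray,
    cap: int = 12,
) -> DiagramGrid:
    """Survivor sets of the stable equilibria over the operating plane.

    A single analyzer is reused across cells so the per-support symbolic
    elimination is done once.  Per-cell failures are recorded as a lone
    ``unknown`` outcome and do not abort the sweep.
    """
    s_in_axis = np.asarray(s_in_axis, float)
    D_axis = np.asarray(D_axis, float)
    if np.any(s_in_axis <= 0) or np.any(D_axis <= 0):
        raise ValueError("axes must be strictly positive")
    analyzer = EquilibriumAnalyzer(model, cap=cap)
    g2 = frozenset(model.grouping.g2_indices.tolist())
    rows = []
    for s_in in s_in_axis:
        row = []
        for D in D_axis:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    pts = analyzer.find_all(float(D), float(s_in))
                stable = [p for p in pts if p.stability == "stable"]
                if stable:
                    outs = sorted(
                        {
                            CellOutcome(survivors=p.survivors, label=_label_of(p.survivors, g2))
                            for p in stable
                        },
                        key=lambda c: c.survivors,
                    )
                else:
                    outs = [CellOutcome(survivors=(), label="unknown")]
            except Exception:  # pragma: no cover - defensive per-cell guard
                outs = [CellOutcome(survivors=(), label="unknown")]
            row.append(tuple(outs))
        rows.append(tuple(row))
    return DiagramGrid(s_in_axis=s_in_axis, D_axis=D_axis, cells=tuple(rows), kind="ecological")


def operating_diagram(ecological: DiagramGrid) -> DiagramGrid:
    """Collapse an ecological diagram to PN/CN/WO operational labels.

    Purely a relabelling — no new analysis; multi-label cells (e.g. a
    PN-or-CN bistability) keep one outcome per distinct label.
    """
    if ecological.kind != "ecological":
        raise ValueError("input must be an ecological diagram")
    rows = []
    for i in range(ecological.s_in_axis.size):
        row = []
        for j in range(ecological.D_axis.size):
            labels = sorted({c.label for c in ecological.cells[i][j]})
            row.append(tuple(CellOutcome(survivors=(), label=lab) for lab in labels))
        rows.append(tuple(row))
    return DiagramGrid(
        s_in_axis=ecological.s_in_axis,
        D_axis=ecological.D_axis,
        cells=tuple(rows),
        kind="operating",
    )
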