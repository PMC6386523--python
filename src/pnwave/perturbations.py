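"""Mutant and transgenic clones as per-cell kinetic overrides.

A clone is a set of cells whose local kinetics are altered while the rest of
the tissue keeps wildtype parameters:

* ``EGFR_KO`` — no EGFR gain inside the clone (mu_E = 0).
* ``EGFR_CONST`` / ``ECTOPIC_EGFR`` — E production held at its maximum
  (the self-activation Hill factor clamped to 1).
* ``LSC_KO`` — no L'sc synthesis (mu_L = 0).
* ``LSC_CONST`` — L'sc production held at its maximum.
* ``NOTCH_DOWN`` — no basal Notch production (beta = 0).
* ``NOTCH_UP`` — additional constant Notch synthesis at rate beta/2.
* ``NOTCH_NULL`` — complete loss of Notch production (beta = 0 and trans
  gain mu_N = 0), the strong RNAi-like knockdown.

The phenotype classifier compares the wavefront position within the clone's
columns against a wildtype run at an evaluation time; a shift of at least
one column counts as ADVANCED/DELAYED, and a clone none of whose cells ever
transition is LOST.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .lattice import CellLattice
from .model_core import ModelParams, Variant
from .observables import front_field, wavefront_position
from .simulate import LocalKinetics, Trajectory

__all__ = [
    "CloneCondition",
    "CloneSpec",
    "Phenotype",
    "apply_clone",
    "rect_clone_cells",
    "disc_clone_cells",
    "classify_clone_phenotype",
]


class CloneCondition(str, enum.Enum):
    EGFR_KO = "EGFR_KO"
    EGFR_CONST = "EGFR_CONST"
    LSC_KO = "LSC_KO"
    LSC_CONST = "LSC_CONST"
    NOTCH_DOWN = "NOTCH_DOWN"
    NOTCH_UP = "NOTCH_UP"
    NOTCH_NULL = "NOTCH_NULL"
    ECTOPIC_EGFR = "ECTOPIC_EGFR"


class Phenotype(str, enum.Enum):
    ADVANCED = "ADVANCED"
    DELAYED = "DELAYED"
    LOST = "LOST"
    UNCHANGED = "UNCHANGED"


@dataclass(frozen=True)
class CloneSpec:
    """A cell set plus the named condition overriding its kinetics."""

    cells: tuple[int, ...]
    condition: CloneCondition
    magnitude: float | None = None  # condition-specific override (e.g. the
    # extra Notch synthesis rate for NOTCH_UP; defaults to beta/2)


def rect_clone_cells(lattice: CellLattice, col_range: tuple[int, int],
                     row_range: tuple[float, float]) -> tuple[int, ...]:
    """Cells of a rectangular patch with column in [col0, col1] and y in
    [y0, y1] (inclusive)."""
    c0, c1 = col_range
    y0, y1 = row_range
    y = lattice.coordinates[:, 1]
    sel = (lattice.column >= c0) & (lattice.column <= c1) & (y >= y0) & (y <= y1)
    return tuple(np.flatnonzero(sel))


def disc_clone_cells(lattice: CellLattice, center: int, radius: float) -> tuple[int, ...]:
    d = np.linalg.norm(lattice.coordinates - lattice.coordinates[center], axis=1)
    return tuple(np.flatnonzero(d <= radius + 1e-9))


def apply_clone(params: ModelParams, clones, n_cells: int) -> LocalKinetics:
    """Per-cell effective kinetics for one or more clones.

    Cells outside every clone keep the wildtype parameters exactly; an empty
    clone list is a no-op.
    """
    if params.variant is not Variant.INTEGRATED:
        raise ValueError("clones are defined for the integrated model")
    if isinstance(clones, CloneSpec):
        clones = [clones]
    lk = LocalKinetics.uniform(params, n_cells)
    for clone in clones:
        cells = np.asarray(clone.cells, dtype=int)
        if len(cells) == 0:
            continue
        if cells.min() < 0 or cells.max() >= n_cells:
            raise ValueError("clone cells outside the lattice")
        cond = clone.condition
        if cond is CloneCondition.EGFR_KO:
            lk.mu_E[cells] = 0.0
        elif cond in (CloneCondition.EGFR_CONST, CloneCondition.ECTOPIC_EGFR):
            lk.force_E[cells] = True
        elif cond is CloneCondition.LSC_KO:
            lk.mu_L[cells] = 0.0
        elif cond is CloneCondition.LSC_CONST:
            lk.force_L[cells] = True
        elif cond is CloneCondition.NOTCH_DOWN:
            lk.beta[cells] = 0.0
        elif cond is CloneCondition.NOTCH_UP:
            extra = clone.magnitude if clone.magnitude is not None else params.beta / 2.0
            lk.extra_N[cells] += extra
        elif cond is CloneCondition.NOTCH_NULL:
            lk.beta[cells] = 0.0
            lk.mu_N[cells] = 0.0
        else:  # pragma: no cover - enum is exhaustive
            raise ValueError(f"unknown clone condition {cond}")
    return lk


def classify_clone_phenotype(traj_wt: Trajectory, traj_clone: Trajectory,
                             clone: CloneSpec, t_eval: float,
                             min_shift: float = 1.0) -> Phenotype:
    """Compare the wavefront inside the clone's columns against wildtype.

    LOST if no clone cell reaches Omega >= 0.5 by the end of the clone run;
    otherwise the front positions (restricted to the clone's column range,
    all rows) at ``t_eval`` are compared, with ``min_shift`` columns as the
    minimal detectable shift.
    """
    if traj_wt.lattice.n_cells != traj_clone.lattice.n_cells:
        raise ValueError("wildtype and clone runs must share a lattice")
    cells = np.asarray(clone.cells, dtype=int)
    if len(cells) == 0:
        return Phenotype.UNCHANGED
    if traj_clone.fields["Omega"][-1][cells].max() < 0.5:
        return Phenotype.LOST

    lat = traj_wt.lattice
    cols = lat.column[cells]
    y = lat.coordinates[:, 1]
    yc = y[cells]
    # the front is tracked within the clone's rows (all columns), so shifts
    # register whether the wave sits before, inside or beyond the clone
    mask = (y >= yc.min() - 1e-9) & (y <= yc.max() + 1e-9)
    field, norm = front_field(traj_wt)
    i_wt = int(np.argmin(np.abs(traj_wt.times - t_eval)))
    i_cl = int(np.argmin(np.abs(traj_clone.times - t_eval)))
    p_wt = wavefront_position(traj_wt.state(i_wt), lat, field, norm, mask=mask)
    p_cl = wavefront_position(traj_clone.state(i_cl), lat, field, norm, mask=mask)
    if not np.isfinite(p_cl) and not np.isfinite(p_wt):
        return Phenotype.UNCHANGED
    if not np.isfinite(p_wt):
        p_wt = cols.min() - 1.0
    if not np.isfinite(p_cl):
        p_cl = cols.min() - 1.0
    shift = p_cl - p_wt
    if shift >= min_shift:
        return Phenotype.ADVANCED
    if shift <= -min_shift:
        return Phenotype.DELAYED
    return Phenotype.UNCHANGED
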