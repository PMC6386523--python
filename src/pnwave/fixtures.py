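"""Synthetic tissue states with known ground truth, for testing observables.

Each fixture returns a (TissueState, ground_truth) pair where the ground
truth dict records the analytically known values of the observables the
fixture is designed to probe (front position, pulse width, pattern index).
"""

from __future__ import annotations

import enum

import numpy as np

from .lattice import CellLattice, LatticeKind
from .simulate import TissueState

__all__ = ["FixtureKind", "make_fixture"]


class FixtureKind(str, enum.Enum):
    STEP_FRONT = "STEP_FRONT"
    GAUSSIAN_PULSE = "GAUSSIAN_PULSE"
    CHECKERBOARD = "CHECKERBOARD"
    RANDOM_FIELD = "RANDOM_FIELD"


def _zeros_state(n: int) -> TissueState:
    return TissueState(phi_E=np.zeros(n), phi_L=np.zeros(n), phi_D=np.zeros(n),
                       phi_N=np.zeros(n), omega=np.zeros(n))


def make_fixture(kind: FixtureKind, lattice: CellLattice,
                 seed: int | None = None, **kw) -> tuple[TissueState, dict]:
    """Build a deterministic (or seeded) synthetic state.

    STEP_FRONT(column=c): omega = 1 for columns < c, else 0; the half-level
        front position is c - 1/2 (in column units).
    GAUSSIAN_PULSE(center=c, width=w): phi_L = exp(-(col-c)^2/(2 w^2)); the
        half-height span is 2 w sqrt(2 ln 2) columns.
    CHECKERBOARD: phi_N alternates +1/0 along a chain; pattern index -1.
    RANDOM_FIELD(seed): iid uniform phi_N; expected pattern index 0.
    """
    n = lattice.n_cells
    state = _zeros_state(n)
    if kind is FixtureKind.STEP_FRONT:
        col = int(kw.get("column", max(lattice.column.max() // 2, 1)))
        state.omega = (lattice.column < col).astype(float)
        state.phi_E = state.omega.copy()
        return state, {"front_position": col - 0.5}
    if kind is FixtureKind.GAUSSIAN_PULSE:
        c = float(kw.get("center", lattice.column.max() / 2))
        w = float(kw.get("width", 2.0))
        state.phi_L = np.exp(-((lattice.column - c) ** 2) / (2 * w ** 2))
        return state, {"half_height_span": 2 * w * np.sqrt(2 * np.log(2))}
    if kind is FixtureKind.CHECKERBOARD:
        if lattice.kind is not LatticeKind.CHAIN_1D:
            raise ValueError("the two-coloring ground truth needs a chain "
                             "(hexagonal lattices are not bipartite)")
        state.phi_N = (np.arange(n) % 2).astype(float)
        return state, {"pattern_index": -1.0}
    if kind is FixtureKind.RANDOM_FIELD:
        rng = np.random.default_rng(seed)
        state.phi_N = rng.uniform(size=n)
        return state, {"pattern_index": 0.0, "seed": seed}
    raise ValueError(f"unknown fixture kind {kind}")
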