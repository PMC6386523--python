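"""Quantitative read-outs of simulated tissues.

All spatial measures work on column profiles: cells are grouped by their
column index along the wave axis (chains and rectangular hexagonal patches)
and the per-column mean of a field defines a 1D profile.  Positions and
widths are reported in column units, i.e. "cells" along the wave axis.

The salt-and-pepper index is a Moran-type neighbour-pair correlation of a
standardized field; values near -1 indicate perfectly anti-correlated
(lateral-inhibition) patterning, values near 0 a spatially random field.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lattice import CellLattice
from .model_core import Variant, upper_stable_root
from .simulate import TissueState, Trajectory

__all__ = [
    "WaveMetrics",
    "NO_FRONT",
    "column_profile",
    "wavefront_position",
    "wave_speed",
    "transition_zone_width",
    "notch_prepeak",
    "salt_and_pepper_index",
    "nb_region_radius",
    "front_field",
]

#: Sentinel returned when a state contains no wavefront.
NO_FRONT = -np.inf


def front_field(traj: Trajectory) -> tuple[str, float]:
    """Which field carries the front for a trajectory's variant, and the
    level against which it is normalised: Omega (already in [0,1]) for the
    integrated model, phi_E relative to the elevated stable state otherwise."""
    if traj.params.variant is Variant.INTEGRATED:
        return "Omega", 1.0
    return "E", upper_stable_root(traj.params)


def column_profile(values: np.ndarray, lattice: CellLattice,
                   mask: np.ndarray | None = None
                   ) -> tuple[np.ndarray, np.ndarray]:
    """(columns, per-column mean of ``values``) over cells in ``mask``."""
    if np.all(lattice.column < 0):
        raise ValueError("lattice has no column structure along the wave axis")
    sel = np.ones(lattice.n_cells, dtype=bool) if mask is None else np.asarray(mask)
    cols = lattice.column[sel]
    vals = np.asarray(values, dtype=float)[sel]
    if vals.size == 0:
        raise ValueError("empty cell selection")
    uniq = np.unique(cols)
    prof = np.array([vals[cols == c].mean() for c in uniq])
    return uniq.astype(float), prof


def wavefront_position(state: TissueState, lattice: CellLattice,
                       field: str = "Omega", norm: float = 1.0,
                       threshold: float = 0.5,
                       mask: np.ndarray | None = None) -> float:
    """Furthest column at which the normalised field crosses ``threshold``.

    The profile is scanned for downward crossings; the furthest one is
    linearly interpolated between columns.  Returns the last column if the
    whole profile is above threshold and the ``NO_FRONT`` sentinel if it
    never reaches it.
    """
    values = {"E": state.phi_E, "L": state.phi_L, "D": state.phi_D,
              "N": state.phi_N, "Omega": state.omega}[field]
    x, prof = column_profile(np.asarray(values) / norm, lattice, mask)
    above = prof >= threshold
    if not above.any():
        return NO_FRONT
    crossings = np.flatnonzero(above[:-1] & ~above[1:])
    if len(crossings) == 0:
        return float(x[-1]) if above[-1] else NO_FRONT
    i = crossings[-1]
    frac = (prof[i] - threshold) / (prof[i] - prof[i + 1])
    return float(x[i] + frac * (x[i + 1] - x[i]))


@dataclass
class WaveMetrics:
    """Summary of one travelling-wave trajectory."""

    speed: float
    speed_r2: float
    zone_width: float
    front_positions: np.ndarray  # (T, 2) columns (time, position)


def wave_speed(traj: Trajectory, window: tuple[float, float] = (0.2, 1.0),
               mask: np.ndarray | None = None) -> tuple[float, float]:
    """Least-squares front speed (columns/time) and fit R² over a time
    window given as fractions of the run duration (default: drop the first
    20%, the initiation transient).  States without a front, or with the
    front at the final column (boundary collision), are excluded."""
    field, norm = front_field(traj)
    t0 = traj.times[0] + window[0] * (traj.times[-1] - traj.times[0])
    t1 = traj.times[0] + window[1] * (traj.times[-1] - traj.times[0])
    lat = traj.lattice
    max_col = lat.column[mask].max() if mask is not None else lat.column.max()
    ts, xs = [], []
    for i, t in enumerate(traj.times):
        if not (t0 <= t <= t1):
            continue
        p = wavefront_position(traj.state(i), lat, field, norm, mask=mask)
        if np.isfinite(p) and p < max_col - 0.5:
            ts.append(t)
            xs.append(p)
    if len(ts) < 3:
        raise ValueError("fewer than 3 usable front positions in the window")
    ts, xs = np.array(ts), np.array(xs)
    A = np.column_stack([ts, np.ones_like(ts)])
    coef, *_ = np.linalg.lstsq(A, xs, rcond=None)
    ss_tot = float(((xs - xs.mean()) ** 2).sum())
    ss_res = float(((A @ coef - xs) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res < 1e-12 else 0.0)
    return float(coef[0]), float(r2)


def front_positions(traj: Trajectory, mask: np.ndarray | None = None) -> np.ndarray:
    field, norm = front_field(traj)
    out = [(t, wavefront_position(traj.state(i), traj.lattice, field, norm, mask=mask))
           for i, t in enumerate(traj.times)]
    return np.array(out)


def wave_metrics(traj: Trajectory, mask: np.ndarray | None = None) -> WaveMetrics:
    """Bundle speed, fit quality, zone width and the front trace."""
    speed, r2 = wave_speed(traj, mask=mask)
    width = (transition_zone_width(traj, mask=mask)
             if traj.params.variant is not Variant.E_ONLY else float("nan"))
    return WaveMetrics(speed=speed, speed_r2=r2, zone_width=width,
                       front_positions=front_positions(traj, mask=mask))


def transition_zone_width(traj: Trajectory,
                          window: tuple[float, float] = (0.2, 0.8),
                          mask: np.ndarray | None = None) -> float:
    """Time-averaged width (in columns) of the L'sc expression zone.

    Per recorded state, the zone is the set of columns where the L profile
    is at least half of its instantaneous maximum; the width is the column
    span of that set plus one (a single qualifying column has width 1).
    Averaged over the steady propagation window (central part of the run by
    default).  Returns NaN if L is identically zero throughout.
    """
    if traj.params.variant is Variant.E_ONLY:
        raise ValueError("the single-component model has no L'sc zone")
    t0 = traj.times[0] + window[0] * (traj.times[-1] - traj.times[0])
    t1 = traj.times[0] + window[1] * (traj.times[-1] - traj.times[0])
    widths = []
    for i, t in enumerate(traj.times):
        if not (t0 <= t <= t1):
            continue
        x, prof = column_profile(traj.fields["L"][i], traj.lattice, mask)
        m = prof.max()
        if m <= 0:
            continue
        qual = x[prof >= m / 2]
        widths.append(float(qual.max() - qual.min() + 1.0))
    return float(np.mean(widths)) if widths else float("nan")


def notch_prepeak(traj: Trajectory, time: float,
                  min_excess: float = 0.02) -> tuple[bool, float]:
    """Is there a pulse of Notch activity ahead of the transition zone?

    At the state nearest ``time``, the zone centre is the argmax of the L
    profile.  We look for a local maximum of the N profile strictly ahead of
    the zone centre that exceeds the neuroepithelial plateau (the mean N
    over the far-ahead fifth of columns) by at least ``min_excess``
    relatively.  Returns (found, offset of the peak from the zone centre in
    columns); (False, NaN) when there is no wave.
    """
    if traj.params.variant is not Variant.INTEGRATED:
        raise ValueError("Notch pre-peak detection needs the integrated model")
    i = int(np.argmin(np.abs(traj.times - time)))
    x, profL = column_profile(traj.fields["L"][i], traj.lattice)
    _, profN = column_profile(traj.fields["N"][i], traj.lattice)
    if profL.max() <= 0:
        return False, float("nan")
    ic = int(np.argmax(profL))
    ahead = np.arange(ic + 1, len(x))
    if len(ahead) < 3:
        return False, float("nan")
    n_plateau = max(2, len(ahead) // 5)
    plateau = profN[ahead[-n_plateau:]].mean()
    best = None
    for j in range(ic + 1, len(x) - 1):
        if profN[j] >= profN[j - 1] and profN[j] >= profN[j + 1]:
            if profN[j] > plateau * (1 + min_excess):
                if best is None or profN[j] > profN[best]:
                    best = j
    if best is None:
        return False, float("nan")
    return True, float(x[best] - x[ic])


def salt_and_pepper_index(state: TissueState, lattice: CellLattice,
                          field: str = "N",
                          mask: np.ndarray | None = None) -> float:
    """Moran-type neighbour correlation of a field over masked cells.

    The field is standardized over the mask (z-scores with the population
    std); the index is the mean of z_i * z_j over undirected neighbour pairs
    with both ends in the mask.  -1 for a perfectly alternating two-coloring
    of a bipartite lattice, ~0 for spatially random fields.  Returns NaN
    (undefined) for a constant field.
    """
    values = {"E": state.phi_E, "L": state.phi_L, "D": state.phi_D,
              "N": state.phi_N, "Omega": state.omega}[field]
    values = np.asarray(values, dtype=float)
    sel = np.ones(lattice.n_cells, dtype=bool) if mask is None else np.asarray(mask)
    v = values[sel]
    if v.size < 2 or v.std() == 0:
        return float("nan")
    z = np.full(lattice.n_cells, np.nan)
    z[sel] = (v - v.mean()) / v.std()
    prods = [z[i] * z[j]
             for i, nb in enumerate(lattice.neighbors) if sel[i]
             for j in nb if j > i and sel[j]]
    if not prods:
        raise ValueError("mask contains no neighbour pairs")
    return float(np.mean(prods))


def nb_region_radius(state: TissueState, lattice: CellLattice,
                     center: int) -> float:
    """Radius of the neuroblast region around a nucleation cell: the largest
    distance from ``center`` to any cell with Omega >= 0.5 (0 if none)."""
    nb = np.asarray(state.omega) >= 0.5
    if not nb.any():
        return 0.0
    d = np.linalg.norm(lattice.coordinates[nb] - lattice.coordinates[center], axis=1)
    return float(d.max())
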