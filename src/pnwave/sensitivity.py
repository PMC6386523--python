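"""Morris elementary-effects screening of kinetic parameters.

One-at-a-time trajectories through parameter space yield, per parameter and
per output, three screening indices: m (signed mean elementary effect,
positive and negative influences may cancel), m* (mean absolute effect, the
overall importance), and sigma (standard deviation of the effects; non-zero
values flag nonlinearity and/or parameter interactions).

The sampler follows the standard radial-trajectory construction on a
p-level grid in the unit cube: a random base point, a random visiting order
of the k coordinates, and one jump of Delta = p/(2(p-1)) (in normalized
units) per coordinate.  Rate-like parameters map to their native range
log-uniformly.  Elementary effects are computed per native-unit change, so
an index carries the units of output per parameter unit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lattice import build_chain
from .model_core import ModelParams
from .observables import transition_zone_width, wave_speed
from .simulate import ICKind, InitialCondition, integrate

__all__ = [
    "ParamRange",
    "MorrisPlan",
    "MorrisResult",
    "SimulationProtocol",
    "morris_sample",
    "elementary_effects",
    "morris_indices",
    "run_sensitivity",
]


@dataclass(frozen=True)
class ParamRange:
    name: str
    low: float
    high: float
    log: bool = False  # log-uniform grid (rates)

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"{self.name}: need low < high")
        if self.log and self.low <= 0:
            raise ValueError(f"{self.name}: log scale needs low > 0")

    def to_native(self, u):
        """Map normalized [0,1] coordinates to native units."""
        u = np.asarray(u, dtype=float)
        if self.log:
            return self.low * (self.high / self.low) ** u
        return self.low + (self.high - self.low) * u


@dataclass(frozen=True)
class MorrisPlan:
    parameters: tuple[ParamRange, ...]
    levels: int = 4
    trajectories: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError("need at least 2 grid levels")
        if self.trajectories < 2:
            raise ValueError("need at least 2 trajectories")

    @property
    def delta(self) -> float:
        """Normalized grid jump p/(2(p-1))."""
        p = self.levels
        return p / (2.0 * (p - 1.0))

    @property
    def k(self) -> int:
        return len(self.parameters)


def morris_sample(plan: MorrisPlan) -> list[np.ndarray]:
    """r one-at-a-time trajectories of (k+1) points in normalized [0,1]^k.

    Consecutive points differ in exactly one coordinate by +/- delta; all
    coordinates lie on the p-level grid {0, 1/(p-1), ..., 1}.
    """
    rng = np.random.default_rng(plan.seed)
    p, d, k = plan.levels, plan.delta, plan.k
    # base levels restricted so that +delta stays inside [0,1]
    base_levels = np.arange(0, p) / (p - 1.0)
    base_levels = base_levels[base_levels + d <= 1.0 + 1e-12]
    trajs = []
    for _ in range(plan.trajectories):
        x = rng.choice(base_levels, size=k)
        signs = rng.choice([-1.0, 1.0], size=k)
        # flip signs that would leave the cube
        for i in range(k):
            if x[i] + signs[i] * d < -1e-12 or x[i] + signs[i] * d > 1 + 1e-12:
                signs[i] = -signs[i]
        order = rng.permutation(k)
        pts = [x.copy()]
        for i in order:
            x = x.copy()
            x[i] = x[i] + signs[i] * d
            pts.append(x)
        trajs.append(np.clip(np.array(pts), 0.0, 1.0))
    return trajs


def to_native(plan: MorrisPlan, pts: np.ndarray) -> np.ndarray:
    cols = [pr.to_native(pts[:, j]) for j, pr in enumerate(plan.parameters)]
    return np.column_stack(cols)


def elementary_effects(points: np.ndarray, outputs: np.ndarray,
                       plan: MorrisPlan) -> dict[str, list[float]]:
    """Per-parameter elementary effects from one trajectory.

    ``points`` are native-unit coordinates of the (k+1) trajectory points and
    ``outputs`` the aligned model outputs.  Each consecutive pair changes
    exactly one parameter; the effect is (output_after - output_before)
    divided by the signed native-unit step.  Non-finite outputs invalidate
    the steps they touch (the caller counts exclusions).
    """
    points = np.asarray(points, dtype=float)
    outputs = np.asarray(outputs, dtype=float)
    if len(points) != len(outputs):
        raise ValueError("outputs must align with trajectory points")
    effects: dict[str, list[float]] = {pr.name: [] for pr in plan.parameters}
    for a in range(len(points) - 1):
        dx = points[a + 1] - points[a]
        changed = np.flatnonzero(np.abs(dx) > 1e-12)
        if len(changed) != 1:
            raise ValueError("trajectory step must change exactly one parameter")
        j = changed[0]
        if not (np.isfinite(outputs[a]) and np.isfinite(outputs[a + 1])):
            continue
        effects[plan.parameters[j].name].append(
            float((outputs[a + 1] - outputs[a]) / dx[j]))
    return effects


@dataclass
class MorrisResult:
    """Screening indices per parameter per output, plus bookkeeping."""

    table: pd.DataFrame   # columns: output, parameter, m, m_star, sigma, n_effects
    n_failed: int = 0     # runs with non-finite outputs, excluded

    def indices(self, output: str, parameter: str) -> tuple[float, float, float]:
        row = self.table[(self.table.output == output)
                         & (self.table.parameter == parameter)].iloc[0]
        return float(row.m), float(row.m_star), float(row.sigma)

    def ranked(self, output: str, by: str = "m_star") -> list[str]:
        sub = self.table[self.table.output == output]
        return list(sub.sort_values(by, ascending=False).parameter)


def morris_indices(all_effects: dict[str, list[float]], output: str = "y",
                   allow_few: bool = False) -> pd.DataFrame:
    """Assemble m / m* / sigma per parameter.  Parameters with fewer than
    two effects raise, unless ``allow_few`` marks them NaN instead (the
    degenerate-run policy of full screening runs)."""
    rows = []
    for name, eff in all_effects.items():
        eff = np.asarray(eff, dtype=float)
        if len(eff) < 2:
            if not allow_few:
                raise ValueError(f"parameter {name}: need >= 2 elementary effects")
            rows.append({"output": output, "parameter": name,
                         "m": float("nan"), "m_star": float("nan"),
                         "sigma": float("nan"), "n_effects": len(eff)})
            continue
        rows.append({"output": output, "parameter": name,
                     "m": eff.mean(), "m_star": np.abs(eff).mean(),
                     "sigma": eff.std(ddof=1), "n_effects": len(eff)})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SimulationProtocol:
    """How each sampled parameter point is turned into (speed, width)."""

    base_params: ModelParams = None  # type: ignore[assignment]
    n_cells: int = 60
    n_ic_columns: int = 3
    t_end: float = 40.0
    dt: float = 0.02
    record_every: float = 1.0
    speed_window: tuple[float, float] = (0.3, 1.0)
    min_r2: float = 0.8  # fits below this count as degenerate (no wave)


def _evaluate(protocol: SimulationProtocol, overrides: dict[str, float]
              ) -> tuple[float, float]:
    params = protocol.base_params.with_updates(**overrides)
    lattice = build_chain(protocol.n_cells)
    ic = InitialCondition(kind=ICKind.LEFT_COLUMNS, n_columns=protocol.n_ic_columns)
    traj = integrate(params, lattice, ic, t_end=protocol.t_end,
                     dt=protocol.dt, record_every=protocol.record_every)
    try:
        speed, r2 = wave_speed(traj, window=protocol.speed_window)
    except ValueError:
        return float("nan"), float("nan")
    if not np.isfinite(speed) or r2 < protocol.min_r2 or speed <= 0:
        speed = float("nan")
    width = transition_zone_width(traj)
    return speed, width


def run_sensitivity(plan: MorrisPlan, protocol: SimulationProtocol,
                    scale: str = "normalized",
                    progress: bool = False) -> MorrisResult:
    """Sample the plan, simulate every point, and assemble Morris indices
    for wave speed and transition-zone width.  Degenerate runs (no wave,
    poor front fit) are excluded from the effects with a count reported.

    ``scale`` chooses the units of the elementary effects: "normalized"
    divides output changes by the jump in the unit-cube coordinate (making
    indices comparable across parameters with different ranges — the
    conventional choice for ranking), "native" divides by the jump in the
    parameter's own units.
    """
    if scale not in ("normalized", "native"):
        raise ValueError("scale must be 'normalized' or 'native'")
    trajs = morris_sample(plan)
    eff_speed: dict[str, list[float]] = {pr.name: [] for pr in plan.parameters}
    eff_width: dict[str, list[float]] = {pr.name: [] for pr in plan.parameters}
    n_failed = 0
    for t_idx, pts in enumerate(trajs):
        native = to_native(plan, pts)
        step_points = pts if scale == "normalized" else native
        speeds, widths = [], []
        for row in native:
            overrides = {pr.name: v for pr, v in zip(plan.parameters, row)}
            s, w = _evaluate(protocol, overrides)
            if not (np.isfinite(s) and np.isfinite(w)):
                n_failed += 1
            speeds.append(s)
            widths.append(w)
        for target, outs in ((eff_speed, speeds), (eff_width, widths)):
            got = elementary_effects(step_points, np.array(outs), plan)
            for name, eff in got.items():
                target[name].extend(eff)
        if progress:  # pragma: no cover - cosmetic
            print(f"trajectory {t_idx + 1}/{len(trajs)} done")
    if all(len(v) == 0 for v in eff_speed.values()):
        raise ValueError("all runs degenerate; no wave metrics available")
    table = pd.concat([morris_indices(eff_speed, "speed", allow_few=True),
                       morris_indices(eff_width, "width", allow_few=True)],
                      ignore_index=True)
    return MorrisResult(table=table, n_failed=n_failed)


def default_plan(base: ModelParams, trajectories: int = 50, levels: int = 4,
                 seed: int = 0, span: float = 0.5) -> MorrisPlan:
    """Screening plan over the kinetic rates of the integrated model:
    log-uniform ranges spanning (1-span)x to (1+span)x the preset values."""
    names = ["eta", "mu_E", "k_E", "mu_L", "k_L", "mu_D", "k_D",
             "mu_N", "k_N", "beta"]
    prs = []
    for n in names:
        v = getattr(base, n)
        prs.append(ParamRange(n, v * (1 - span), v * (1 + span), log=True))
    return MorrisPlan(parameters=tuple(prs), levels=levels,
                      trajectories=trajectories, seed=seed)
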