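"""Time integration of the model hierarchy on cell lattices.

Deterministic runs use explicit forward-Euler stepping; stochastic runs add
Euler–Maruyama noise increments (strength ``gamma``, std gamma*sqrt(dt)) to
each signalling field and clip at zero, modelling biochemical fluctuations
in production and turnover.  The step size is validated against an explicit
stability bound, dt <= 0.2 / (max decay rate + 6*eta*c), where c is the
lattice stencil prefactor.

States are recorded at a cadence decoupled from the step size, so long runs
stay cheap in memory.  A :class:`Trajectory` bundles the recorded states
with the parameters, lattice and seed that produced it and can round-trip
through an HDF5 container (layout: /times, /fields/{E,L,D,N,Omega},
/lattice/*, /meta attrs) or export flat per-snapshot tables.
"""

from __future__ import annotations

import dataclasses
import enum
import json
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .lattice import CellLattice, LatticeKind
from .model_core import CellFields, HillSpec, ModelParams, Variant, hill, \
    upper_stable_root

__all__ = [
    "TissueState",
    "ICKind",
    "InitialCondition",
    "LocalKinetics",
    "Trajectory",
    "stable_dt",
    "apply_initial_condition",
    "integrate",
    "save_trajectory",
    "load_trajectory",
    "snapshot_frame",
]

#: Per-cell values of all dynamical fields at one time point (array-valued
#: :class:`~pnwave.model_core.CellFields`).
TissueState = CellFields

FIELD_NAMES = ("E", "L", "D", "N", "Omega")
_ATTRS = ("phi_E", "phi_L", "phi_D", "phi_N", "omega")


class ICKind(str, enum.Enum):
    LEFT_COLUMNS = "LEFT_COLUMNS"
    ANGULAR_SECTOR = "ANGULAR_SECTOR"
    CELL_SET = "CELL_SET"
    UNIFORM = "UNIFORM"


@dataclass(frozen=True)
class InitialCondition:
    """Where and how strongly E is initially elevated.

    ``amplitude=None`` means "the elevated stable signalling state", i.e. the
    upper stable root of the E kinetics, resolved when the run starts.
    """

    kind: ICKind = ICKind.LEFT_COLUMNS
    amplitude: float | None = None
    n_columns: int = 3
    theta: tuple[float, float] = (np.pi / 3, 5 * np.pi / 3)
    cells: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.amplitude is not None and self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        t1, t2 = self.theta
        if not (0 <= t1 <= 2 * np.pi and 0 <= t2 <= 2 * np.pi):
            raise ValueError("angle interval must lie within [0, 2*pi]")


def apply_initial_condition(ic: InitialCondition, lattice: CellLattice,
                            default_amplitude: float = 1.0) -> TissueState:
    """Build the t=0 state: phi_E = amplitude on the selected cells, all
    other fields zero, every cell neuroepithelial (omega = 0)."""
    n = lattice.n_cells
    amp = ic.amplitude if ic.amplitude is not None else default_amplitude
    E = np.zeros(n)
    if ic.kind is ICKind.LEFT_COLUMNS:
        if np.all(lattice.column < 0):
            raise ValueError("LEFT_COLUMNS needs a lattice with columns "
                             "(chain or rectangular patch)")
        E[lattice.column < ic.n_columns] = amp
    elif ic.kind is ICKind.ANGULAR_SECTOR:
        if lattice.kind is not LatticeKind.HEX_DISC:
            raise ValueError("ANGULAR_SECTOR initial conditions require a disc")
        t1, t2 = ic.theta
        sel = np.zeros(n, dtype=bool)
        b = lattice.boundary_cells()
        ang = lattice.angle[b]
        inside = (ang >= t1) & (ang <= t2) if t1 <= t2 else (ang >= t1) | (ang <= t2)
        sel[b[inside]] = True
        E[sel] = amp
    elif ic.kind is ICKind.CELL_SET:
        cells = np.asarray(ic.cells, dtype=int)
        if len(cells) and (cells.min() < 0 or cells.max() >= n):
            raise ValueError("cell indices out of range for this lattice")
        E[cells] = amp
    elif ic.kind is ICKind.UNIFORM:
        E[:] = amp
    else:  # pragma: no cover - enum is exhaustive
        raise ValueError(f"unknown IC kind {ic.kind}")
    return TissueState(phi_E=E, phi_L=np.zeros(n), phi_D=np.zeros(n),
                       phi_N=np.zeros(n), omega=np.zeros(n))


@dataclass
class LocalKinetics:
    """Per-cell overrides of the kinetics (the effect of clones).

    Arrays of length n_cells; ``force_E``/``force_L`` clamp the respective
    Hill production factor to its maximum ("constitutively active"), and
    ``extra_N`` is an unconditional additive Notch production term.
    """

    mu_E: np.ndarray
    mu_L: np.ndarray
    mu_N: np.ndarray
    beta: np.ndarray
    extra_N: np.ndarray
    force_E: np.ndarray
    force_L: np.ndarray

    @classmethod
    def uniform(cls, params: ModelParams, n: int) -> "LocalKinetics":
        ones = np.ones(n)
        return cls(mu_E=params.mu_E * ones, mu_L=params.mu_L * ones,
                   mu_N=params.mu_N * ones, beta=params.beta * ones,
                   extra_N=np.zeros(n), force_E=np.zeros(n, dtype=bool),
                   force_L=np.zeros(n, dtype=bool))


@dataclass
class Trajectory:
    """Recorded states of one run, with full provenance."""

    times: np.ndarray                       # (T,), strictly increasing
    fields: dict[str, np.ndarray]           # name -> (T, n_cells)
    params: ModelParams
    lattice: CellLattice
    seed: int | None = None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        for name, arr in self.fields.items():
            if arr.shape != (len(self.times), self.lattice.n_cells):
                raise ValueError(f"field {name} has shape {arr.shape}")

    @property
    def n_times(self) -> int:
        return len(self.times)

    def state(self, i: int) -> TissueState:
        return TissueState(*(self.fields[name][i] for name in FIELD_NAMES))

    def state_at(self, t: float) -> TissueState:
        return self.state(int(np.argmin(np.abs(self.times - t))))


def stable_dt(params: ModelParams, lattice: CellLattice) -> float:
    """Largest admissible explicit step: 0.2/(max decay + 6*eta*c)."""
    return 0.2 / (params.max_decay + 6.0 * params.eta * lattice.coupling_constant)


def _params_meta(params: ModelParams) -> str:
    d = dataclasses.asdict(params)
    d["variant"] = params.variant.value
    d["hill_specs"] = {k: {"exponent": s.exponent, "threshold": s.threshold}
                       for k, s in params.hill_specs.items()}
    return json.dumps(d)


def _params_from_meta(s: str) -> ModelParams:
    d = json.loads(s)
    d["variant"] = Variant(d["variant"])
    d["hill_specs"] = {k: HillSpec(**v) for k, v in d["hill_specs"].items()}
    return ModelParams(**d)


def integrate(params: ModelParams, lattice: CellLattice, ic: InitialCondition,
              t_end: float, dt: float | None = None, record_every: float = 0.5,
              seed: int | None = None,
              local: LocalKinetics | None = None) -> Trajectory:
    """Integrate a model variant from an initial condition.

    Parameters
    ----------
    dt
        Explicit step; defaults to a quarter of the stability bound.  A dt
        above the bound raises.
    record_every
        Cadence of recorded states (first and final states always kept).
    seed
        Required when ``params.gamma`` > 0; ignored otherwise.
    local
        Optional per-cell kinetic overrides (clones); integrated model only.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    bound = stable_dt(params, lattice)
    if dt is None:
        dt = bound / 4.0
    if dt <= 0 or dt > bound * (1 + 1e-12):
        raise ValueError(f"dt={dt} exceeds the stability bound {bound:.4g}")
    if params.gamma > 0 and seed is None:
        raise ValueError("stochastic runs (gamma > 0) require a seed")
    if local is not None and params.variant is not Variant.INTEGRATED:
        raise ValueError("per-cell overrides apply to the integrated model only")

    rng = np.random.default_rng(seed) if params.gamma > 0 else None
    n = lattice.n_cells
    state0 = apply_initial_condition(ic, lattice, upper_stable_root(params))
    Lmat = lattice.laplacian_matrix()
    A = lattice.adjacency
    deg = lattice.degrees.astype(float)
    lk = local if local is not None else LocalKinetics.uniform(params, n)
    h = params.h

    E = state0.phi_E.copy()
    Lf = state0.phi_L.copy()
    D = state0.phi_D.copy()
    N = state0.phi_N.copy()
    Om = state0.omega.copy()

    variant = params.variant
    n_steps = int(np.ceil(t_end / dt - 1e-9))
    rec_times = [0.0]
    rec = {name: [arr.copy()] for name, arr in
           zip(FIELD_NAMES, (E, Lf, D, N, Om))}
    next_rec = record_every

    for step in range(1, n_steps + 1):
        t = step * dt
        diff = params.eta * (Lmat @ E)
        if variant is Variant.E_ONLY:
            dE = diff + lk.mu_E * hill(E, h("E_auto")) - params.k_E * E
            dL = dD = dN = dOm = None
        elif variant is Variant.E_L:
            hE = hill(E, h("E_auto"))
            dE = diff + lk.mu_E * hE * (1.0 - hill(Lf, h("L_on_E"))) - params.k_E * E
            dL = params.mu_L * hill(E, h("E_on_L")) - params.k_L * Lf
            dD = dN = dOm = None
        else:
            ne = 1.0 - Om
            hE = np.where(lk.force_E, 1.0, hill(E, h("E_auto")))
            gainE = lk.mu_E * hE * (1.0 - hill(Lf, h("L_on_E"))) \
                + params.sigma_N * hill(N, h("N_on_E"))
            # constitutive activation is transgene-driven: it persists after
            # the NE->NB transition, so force_E cells skip the (1-Om) gate
            occE = np.where(lk.force_E, 1.0, ne)
            dE = diff + occE * gainE - params.k_E * E

            gateN_L = 1.0 - hill(N, h("N_on_L"))
            actL = np.where(lk.force_L, 1.0, hill(E, h("E_on_L")) * gateN_L)
            dL = ne * lk.mu_L * actL - params.k_L * Lf

            driveD = params.basal_D + (1.0 - params.basal_D) * hill(E, h("E_on_D"))
            actD = driveD * (1.0 - hill(N, h("N_on_D")))
            dD = ne * params.mu_D * actD - params.k_D * D

            nbD = (A @ D) / deg
            prodN = (lk.beta + lk.mu_N * hill(nbD, h("D_trans"))) \
                * (1.0 - hill(D, h("D_cis"))) * (1.0 - hill(Lf, h("L_on_N")))
            dN = prodN + lk.extra_N - params.k_N * N

            drive = hill(Lf, h("L_on_Omega")) + hill(E, h("E_on_Omega")) * (
                1.0 - hill(N, h("N_on_Omega")))
            dOm = params.k_Omega * ne * drive

        E = E + dt * dE
        if dL is not None:
            Lf = Lf + dt * dL
        if dD is not None:
            D = D + dt * dD
            N = N + dt * dN
            Om = Om + dt * dOm
        if rng is not None:
            s = params.gamma * np.sqrt(dt)
            E = E + s * rng.standard_normal(n)
            if variant is not Variant.E_ONLY:
                Lf = Lf + s * rng.standard_normal(n)
            if variant is Variant.INTEGRATED:
                D = D + s * rng.standard_normal(n)
                N = N + s * rng.standard_normal(n)
        np.maximum(E, 0.0, out=E)
        np.maximum(Lf, 0.0, out=Lf)
        np.maximum(D, 0.0, out=D)
        np.maximum(N, 0.0, out=N)
        np.clip(Om, 0.0, 1.0, out=Om)

        if t >= next_rec - dt / 2 or step == n_steps:
            rec_times.append(t)
            for name, arr in zip(FIELD_NAMES, (E, Lf, D, N, Om)):
                rec[name].append(arr.copy())
            next_rec += record_every

    return Trajectory(times=np.array(rec_times),
                      fields={k: np.stack(v) for k, v in rec.items()},
                      params=params, lattice=lattice, seed=seed)


# -- persistence -----------------------------------------------------------

def save_trajectory(traj: Trajectory, path) -> None:
    """Write a trajectory to an HDF5 container (documented layout:
    /times, /fields/{E,L,D,N,Omega}, /lattice/*, /meta attrs)."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("times", data=traj.times)
        g = f.create_group("fields")
        for name in FIELD_NAMES:
            g.create_dataset(name, data=traj.fields[name])
        lat = f.create_group("lattice")
        lat.create_dataset("coordinates", data=traj.lattice.coordinates)
        lat.create_dataset("column", data=traj.lattice.column)
        lat.create_dataset("angle", data=traj.lattice.angle)
        cells, edges = traj.lattice.to_tables()
        lat.create_dataset("edges", data=edges.to_numpy())
        lat.attrs["kind"] = traj.lattice.kind.value
        f.attrs["params"] = _params_meta(traj.params)
        f.attrs["seed"] = -1 if traj.seed is None else traj.seed


def load_trajectory(path) -> Trajectory:
    import h5py

    with h5py.File(path, "r") as f:
        times = f["times"][:]
        fields = {name: f["fields"][name][:] for name in FIELD_NAMES}
        coords = f["lattice/coordinates"][:]
        edges = f["lattice/edges"][:]
        neighbors: list[list[int]] = [[] for _ in range(len(coords))]
        for a, b in edges:
            neighbors[a].append(b)
            neighbors[b].append(a)
        lat = CellLattice(
            kind=LatticeKind(f["lattice"].attrs["kind"]),
            coordinates=coords,
            neighbors=[np.array(sorted(x), dtype=int) for x in neighbors],
            column=f["lattice/column"][:],
            angle=f["lattice/angle"][:],
        )
        params = _params_from_meta(f.attrs["params"])
        seed = int(f.attrs["seed"])
    return Trajectory(times=times, fields=fields, params=params,
                      lattice=lat, seed=None if seed < 0 else seed)


def snapshot_frame(traj: Trajectory, i: int) -> pd.DataFrame:
    """Flat per-snapshot table: cell_id, x, y, E, L, D, N, Omega."""
    lat = traj.lattice
    data = {"cell_id": np.arange(lat.n_cells),
            "x": lat.coordinates[:, 0], "y": lat.coordinates[:, 1]}
    for name in FIELD_NAMES:
        data[name] = traj.fields[name][i]
    return pd.DataFrame(data)
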