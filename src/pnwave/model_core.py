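"""Reaction kinetics of the proneural-wave model hierarchy.

Three nested model variants describe the signalling state of each cell of the
optic-lobe neuroepithelium:

* ``E_ONLY`` — a single diffusible, self-activating component E standing in
  for the EGFR/Rhomboid/Spitz autocrine feedback loop.  Its kinetics are
  bistable: a quiescent state and an elevated signalling state, connected by
  a travelling front.
* ``E_L`` — E plus the proneural gene product L (L'sc).  L is activated by E
  and shuts the E gain down, turning the bistable front into an excitable
  pulse: the travelling transition zone.
* ``INTEGRATED`` — E, L, Delta (D), Notch (N) and a cell-state order
  parameter Ω (0 = neuroepithelial cell, 1 = neuroblast).  Delta–Notch
  signalling adds trans-activation between neighbours, cis-inhibition within
  a cell, Notch→Delta repression, mutual E↔N coupling and L↔N repression.

All functions here are pure per-cell rate functions; they accept scalars or
NumPy arrays and know nothing about lattices or integrators.  The only
non-local input is the mean Delta level over a cell's neighbours, which the
caller supplies.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "Variant",
    "HillSpec",
    "ModelParams",
    "CellFields",
    "hill",
    "hill_deriv",
    "reaction_E",
    "reaction_EL",
    "reaction_integrated",
    "kinetic_roots_E",
    "upper_stable_root",
]


class Variant(str, enum.Enum):
    """Which tier of the model hierarchy a parameter set belongs to."""

    E_ONLY = "E_ONLY"
    E_L = "E_L"
    INTEGRATED = "INTEGRATED"


@dataclass(frozen=True)
class HillSpec:
    """A sigmoidal regulatory response h(x) = (x/a)^n / (1 + (x/a)^n).

    Parameters
    ----------
    exponent
        Hill coefficient n > 0 (dimensionless steepness).
    threshold
        Half-activation level a > 0, in the concentration units of the
        regulating field; h(a) = 1/2 exactly.
    """

    exponent: float = 3.0
    threshold: float = 1.0

    def __post_init__(self) -> None:
        if self.exponent <= 0:
            raise ValueError(f"Hill exponent must be > 0, got {self.exponent}")
        if self.threshold <= 0:
            raise ValueError(f"Hill threshold must be > 0, got {self.threshold}")


def hill(x, spec: HillSpec):
    """Evaluate the Hill response of ``spec`` at non-negative ``x``.

    Returns values in [0, 1); strictly increasing; equals 1/2 at the
    threshold.  With threshold 1 this is the plain x^n / (1 + x^n).
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("hill() requires non-negative input")
    u = (x / spec.threshold) ** spec.exponent
    out = u / (1.0 + u)
    return out if out.ndim else float(out)


def hill_deriv(x, spec: HillSpec):
    """dh/dx of the Hill response (used by the two-cell stability analysis)."""
    x = np.asarray(x, dtype=float)
    a, n = spec.threshold, spec.exponent
    u = (x / a) ** n
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(x > 0, n * u / (x * (1.0 + u) ** 2), 0.0)
    # limit x->0: 0 for n > 1, 1/a for n == 1
    if n == 1:
        d = np.where(x == 0, 1.0 / a, d)
    return d if d.ndim else float(d)


#: Names of the regulatory links of the integrated model, one HillSpec each.
#: "X_on_Y" parameterises the response of Y's kinetics to the level of X.
INTERACTIONS = (
    "E_auto",      # E self-activation (positive feedback)
    "L_on_E",      # L shuts down E gain (transition-driven downregulation)
    "N_on_E",      # Notch upregulates EGFR signalling
    "E_on_L",      # EGFR activates L'sc
    "N_on_L",      # Notch represses L'sc
    "E_on_D",      # EGFR upregulates Delta
    "N_on_D",      # Notch represses Delta (same cell)
    "D_trans",     # neighbour Delta trans-activates Notch
    "D_cis",       # own Delta cis-inhibits Notch
    "L_on_N",      # L'sc represses Notch expression
    "L_on_Omega",  # L'sc promotes the NE->NB transition
    "E_on_Omega",  # EGFR promotes the transition when Notch is low
    "N_on_Omega",  # Notch gates the E-driven transition route
)


def _default_hills() -> dict[str, HillSpec]:
    return {name: HillSpec() for name in INTERACTIONS}


@dataclass(frozen=True)
class ModelParams:
    """Kinetic parameters of one model variant.

    Rates are expressed in the paper's natural units: time in units of the E
    decay time 1/k_E and position in units of the cell spacing, so ``eta`` is
    a diffusion constant in cell-spacings² per E-decay-time.

    Fields irrelevant to the chosen :class:`Variant` are ignored (E_ONLY uses
    eta, mu_E, k_E and the ``E_auto`` Hill spec; E_L adds mu_L, k_L and
    ``L_on_E``/``E_on_L``; INTEGRATED uses everything).
    """

    variant: Variant = Variant.E_ONLY
    eta: float = 1.0
    mu_E: float = 4.0
    k_E: float = 1.0
    mu_L: float = 0.0
    k_L: float = 1.0
    mu_D: float = 0.0
    k_D: float = 1.0
    mu_N: float = 0.0
    k_N: float = 1.0
    beta: float = 0.0
    basal_D: float = 0.0
    sigma_N: float = 0.0
    k_Omega: float = 0.0
    gamma: float = 0.0
    hill_specs: Mapping[str, HillSpec] = field(default_factory=_default_hills)

    def __post_init__(self) -> None:
        if not 0.0 <= self.basal_D <= 1.0:
            raise ValueError(f"basal_D must lie in [0, 1], got {self.basal_D}")
        for name in ("eta", "mu_E", "k_E", "mu_L", "k_L", "mu_D", "k_D",
                     "mu_N", "k_N", "beta", "sigma_N", "k_Omega", "gamma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        missing = set(INTERACTIONS) - set(self.hill_specs)
        if self.variant is Variant.INTEGRATED and missing:
            raise ValueError(f"missing Hill specs: {sorted(missing)}")
        if "E_auto" not in self.hill_specs:
            raise ValueError("every variant needs the 'E_auto' Hill spec")

    def h(self, name: str):
        return self.hill_specs[name]

    def with_updates(self, **kw) -> "ModelParams":
        """Copy with scalar fields and/or hill_specs replaced."""
        return replace(self, **kw)

    @property
    def max_decay(self) -> float:
        if self.variant is Variant.E_ONLY:
            return self.k_E
        if self.variant is Variant.E_L:
            return max(self.k_E, self.k_L)
        return max(self.k_E, self.k_L, self.k_D, self.k_N, self.k_Omega)


@dataclass
class CellFields:
    """The dynamical fields of one cell (or arrays over cells)."""

    phi_E: float | np.ndarray = 0.0
    phi_L: float | np.ndarray = 0.0
    phi_D: float | np.ndarray = 0.0
    phi_N: float | np.ndarray = 0.0
    omega: float | np.ndarray = 0.0

    def validate(self) -> None:
        for name in ("phi_E", "phi_L", "phi_D", "phi_N"):
            if np.any(np.asarray(getattr(self, name)) < 0):
                raise ValueError(f"{name} must be non-negative")
        om = np.asarray(self.omega)
        if np.any(om < 0) or np.any(om > 1):
            raise ValueError("omega must lie in [0, 1]")


def _require(params: ModelParams, variant: Variant) -> None:
    if params.variant is not variant:
        raise ValueError(
            f"operation requires variant {variant.value}, got {params.variant.value}"
        )


def reaction_E(fields: CellFields, params: ModelParams):
    """Local (non-diffusive) rate of E in the single-component model:
    mu_E * h(phi_E) - k_E * phi_E."""
    _require(params, Variant.E_ONLY)
    return params.mu_E * hill(fields.phi_E, params.h("E_auto")) - params.k_E * fields.phi_E


def reaction_EL(fields: CellFields, params: ModelParams):
    """Local rates (dE/dt, dL/dt) of the excitable E–L model.

    E gain is the self-activating Hill response quenched by L,
    mu_E*h(E)*(1 - h(L)); L is produced downstream of E, mu_L*h(E).
    """
    _require(params, Variant.E_L)
    hE = hill(fields.phi_E, params.h("E_auto"))
    hL = hill(fields.phi_L, params.h("L_on_E"))
    dE = params.mu_E * hE * (1.0 - hL) - params.k_E * fields.phi_E
    dL = params.mu_L * hill(fields.phi_E, params.h("E_on_L")) - params.k_L * fields.phi_L
    return dE, dL


def reaction_integrated(fields: CellFields, neighbor_mean_D, params: ModelParams):
    """Local rates (dE, dL, dD, dN, dΩ) of the integrated model.

    The kinetics realise one term per regulatory arrow:

    * E: self-activation quenched by L, plus Notch→E reinforcement
      (sigma_N * h(N)); production gated by neuroepithelial occupancy (1-Ω).
    * L: activated by E, repressed by N, gated by (1-Ω).
    * D: activated by E on top of a small ligand-independent basal drive
      (fraction ``basal_D`` of mu_D), repressed by N in the same cell, gated
      by (1-Ω).  The basal drive is what Notch "oversaturation" holds down
      in the neuroepithelium; without it the lateral-inhibition loop would
      be inert wherever EGFR signalling is quiescent.
    * N: basal production beta plus trans-activation by neighbour Delta,
      cis-inhibited by the cell's own Delta and repressed by L.  Not gated by
      Ω: neuroblasts recover basal Notch signalling.
    * Ω: irreversible NE→NB conversion, promoted by L and by E when Notch is
      low; rate is always >= 0.

    ``neighbor_mean_D`` is the arithmetic mean of phi_D over the cell's
    lattice neighbours (scalar or per-cell array).
    """
    _require(params, Variant.INTEGRATED)
    nbD = np.asarray(neighbor_mean_D, dtype=float)
    if np.any(nbD < 0):
        raise ValueError("neighbor_mean_D must be non-negative")
    E, L, D, N, Om = (fields.phi_E, fields.phi_L, fields.phi_D,
                      fields.phi_N, fields.omega)
    ne = 1.0 - np.asarray(Om, dtype=float)  # neuroepithelial occupancy

    gainE = params.mu_E * hill(E, params.h("E_auto")) * (1.0 - hill(L, params.h("L_on_E")))
    gainE = gainE + params.sigma_N * hill(N, params.h("N_on_E"))
    dE = ne * gainE - params.k_E * E

    actL = hill(E, params.h("E_on_L")) * (1.0 - hill(N, params.h("N_on_L")))
    dL = ne * params.mu_L * actL - params.k_L * L

    driveD = params.basal_D + (1.0 - params.basal_D) * hill(E, params.h("E_on_D"))
    actD = driveD * (1.0 - hill(N, params.h("N_on_D")))
    dD = ne * params.mu_D * actD - params.k_D * D

    prodN = (params.beta + params.mu_N * hill(nbD, params.h("D_trans")))
    prodN = prodN * (1.0 - hill(D, params.h("D_cis"))) * (1.0 - hill(L, params.h("L_on_N")))
    dN = prodN - params.k_N * N

    drive = hill(L, params.h("L_on_Omega")) + hill(E, params.h("E_on_Omega")) * (
        1.0 - hill(N, params.h("N_on_Omega")))
    dOm = params.k_Omega * ne * drive

    return dE, dL, dD, dN, dOm


def kinetic_roots_E(params: ModelParams, upper: float = 50.0, n_scan: int = 20000):
    """All non-negative roots of mu_E*h(x) - k_E*x, by bracketed bisection.

    Scans [0, upper] on a fine grid for sign changes and polishes each with
    Brent's method.  x = 0 is always a root and is included.
    """
    spec = params.h("E_auto")

    def f(x):
        return params.mu_E * hill(x, spec) - params.k_E * x

    xs = np.linspace(0.0, upper, n_scan)
    fs = f(xs)
    roots = [0.0]
    for i in range(1, len(xs) - 1):
        if fs[i] == 0.0 and xs[i] > 0:
            roots.append(xs[i])
        elif fs[i] * fs[i + 1] < 0:
            roots.append(brentq(f, xs[i], xs[i + 1], xtol=1e-14, rtol=8.9e-16))
    # deduplicate near-identical roots
    out: list[float] = []
    for r in sorted(roots):
        if not out or r - out[-1] > 1e-8:
            out.append(r)
    return out


def upper_stable_root(params: ModelParams) -> float:
    """The elevated stable signalling state of the E kinetics.

    Used as the default amplitude for "elevated levels of E" initial
    conditions; falls back to mu_E/k_E when the kinetics are monostable.
    """
    roots = kinetic_roots_E(params)
    if len(roots) >= 2:
        return roots[-1]
    return params.mu_E / params.k_E if params.k_E > 0 else 1.0
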