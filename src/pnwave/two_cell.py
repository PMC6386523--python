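"""Two-cell Delta-Notch subsystem: fixed points, linear stability, and the
(beta, lambda) lateral-inhibition phase diagram.

The subsystem isolates the Delta-Notch module of the tissue model in two
coupled cells (EGFR signalling and the cell state are frozen):

    dN_i/dt = [beta + lambda * h_t(D_j)] * (1 - h_c(D_i)) - k_N * N_i
    dD_i/dt = mu_D * (1 - h_r(N_i)) - k_D * D_i          (j = the other cell)

with h_t the trans-activation response (neighbour Delta activates Notch),
h_c the cis-inhibition response (own Delta inhibits Notch) and h_r the
Notch-mediated repression of Delta.  beta is the basal (ligand-independent)
Notch production rate and lambda the Delta-mediated gain.

Lateral inhibition is diagnosed by linear stability of the symmetric fixed
point against anti-symmetric perturbations (dD_1 = -dD_2, dN_1 = -dN_2):
a positive leading eigenvalue means small differences between the two cells
are amplified and the pair resolves into complementary high-Delta/low-Notch
and low-Delta/high-Notch states.  High basal Notch "oversaturates" the
system - Notch represses Delta everywhere before trans-signalling can act -
and suppresses the instability.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .model_core import HillSpec, hill, hill_deriv

__all__ = [
    "TwoCellParams",
    "PhaseDiagram",
    "two_cell_rates",
    "symmetric_fixed_point",
    "lateral_inhibition_occurs",
    "phase_diagram",
    "simulate_pair",
]


@dataclass(frozen=True)
class TwoCellParams:
    """Kinetics of the isolated two-cell Delta-Notch pair.

    Defaults mirror the Delta-Notch arm of the tissue model with EGFR frozen
    at a neuroepithelial resting level (mu_D is the effective basal Delta
    production that Notch represses).
    """

    beta: float = 1.0
    lambda_: float = 10.0
    mu_D: float = 1.0
    k_D: float = 1.0
    k_N: float = 2.0
    trans: HillSpec = field(default_factory=lambda: HillSpec(3, 0.5))
    cis: HillSpec = field(default_factory=lambda: HillSpec(3, 1.0))
    repress: HillSpec = field(default_factory=lambda: HillSpec(3, 3.0))

    def __post_init__(self) -> None:
        if self.beta < 0 or self.lambda_ < 0:
            raise ValueError("beta and lambda must be >= 0")
        if min(self.mu_D, self.k_D, self.k_N) <= 0:
            raise ValueError("mu_D, k_D, k_N must be > 0")


def two_cell_rates(state, params: TwoCellParams) -> np.ndarray:
    """Rates (dD1, dN1, dD2, dN2) at state (D1, N1, D2, N2)."""
    D1, N1, D2, N2 = np.asarray(state, dtype=float)
    if min(D1, N1, D2, N2) < 0:
        raise ValueError("two-cell state must be non-negative")
    p = params
    dN1 = (p.beta + p.lambda_ * hill(D2, p.trans)) * (1 - hill(D1, p.cis)) - p.k_N * N1
    dN2 = (p.beta + p.lambda_ * hill(D1, p.trans)) * (1 - hill(D2, p.cis)) - p.k_N * N2
    dD1 = p.mu_D * (1 - hill(N1, p.repress)) - p.k_D * D1
    dD2 = p.mu_D * (1 - hill(N2, p.repress)) - p.k_D * D2
    return np.array([dD1, dN1, dD2, dN2])


def symmetric_fixed_point(params: TwoCellParams) -> tuple[float, float]:
    """(D*, N*) of the symmetric state, by bracketed root-finding.

    On the symmetric manifold D* = mu_D (1 - h_r(N*)) / k_D, so the problem
    reduces to one equation in N*, which is solved with Brent's method on
    [0, (beta + lambda)/k_N].
    """
    p = params

    def d_of_n(n):
        return p.mu_D * (1 - hill(n, p.repress)) / p.k_D

    def g(n):
        d = d_of_n(n)
        return (p.beta + p.lambda_ * hill(d, p.trans)) * (1 - hill(d, p.cis)) \
            - p.k_N * n

    hi = (p.beta + p.lambda_) / p.k_N + 1.0
    if g(0.0) < 0:  # beta = 0 and no trans drive: N* = 0
        return d_of_n(0.0), 0.0
    n_star = brentq(g, 0.0, hi, xtol=1e-13, rtol=8.9e-16)
    return d_of_n(n_star), n_star


def _antisymmetric_jacobian(params: TwoCellParams, d: float, n: float) -> np.ndarray:
    """Jacobian of the (dD, dN) dynamics restricted to the anti-symmetric
    subspace, evaluated at the symmetric fixed point."""
    p = params
    prod = p.beta + p.lambda_ * hill(d, p.trans)
    # dN-equation: cis acts on own D (sign -), trans on the other cell's D;
    # anti-symmetric combination flips the trans contribution's sign.
    dN_dD = -prod * hill_deriv(d, p.cis) \
        - p.lambda_ * hill_deriv(d, p.trans) * (1 - hill(d, p.cis))
    dD_dN = -p.mu_D * hill_deriv(n, p.repress)
    return np.array([[-p.k_D, dD_dN], [dN_dD, -p.k_N]])


def lateral_inhibition_occurs(params: TwoCellParams, tol: float = 1e-9) -> bool:
    """True iff the symmetric state is unstable to anti-symmetric
    perturbations (the pair patterns into complementary fates)."""
    d, n = symmetric_fixed_point(params)
    J = _antisymmetric_jacobian(params, d, n)
    lead = np.linalg.eigvals(J).real.max()
    return bool(lead > tol)


@dataclass
class PhaseDiagram:
    beta_grid: np.ndarray
    lambda_grid: np.ndarray
    classification: np.ndarray  # (len(beta), len(lambda)) booleans
    errors: list[tuple[int, int, str]] = field(default_factory=list)


def phase_diagram(beta_grid, lambda_grid,
                  params_base: TwoCellParams | None = None) -> PhaseDiagram:
    """Classify lateral inhibition on a (beta, lambda) grid.

    Per-point failures are recorded, not fatal.
    """
    base = params_base if params_base is not None else TwoCellParams()
    beta_grid = np.asarray(beta_grid, dtype=float)
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    if np.any(np.diff(beta_grid) <= 0) or np.any(np.diff(lambda_grid) <= 0):
        raise ValueError("grids must be strictly increasing")
    cls = np.zeros((len(beta_grid), len(lambda_grid)), dtype=bool)
    errors: list[tuple[int, int, str]] = []
    for i, b in enumerate(beta_grid):
        for j, lam in enumerate(lambda_grid):
            try:
                cls[i, j] = lateral_inhibition_occurs(
                    replace(base, beta=float(b), lambda_=float(lam)))
            except Exception as exc:  # recorded, not fatal
                errors.append((i, j, str(exc)))
    return PhaseDiagram(beta_grid, lambda_grid, cls, errors)


def simulate_pair(params: TwoCellParams, asymmetry: float = 0.01,
                  t_end: float = 400.0) -> tuple[np.ndarray, bool]:
    """Integrate the pair from a slightly asymmetric state near the
    symmetric fixed point; returns (final state, patterned?), where
    patterned means |D1 - D2| exceeds 10% of the mean Delta level.

    This is the brute-force cross-check for the linear-stability
    classification.
    """
    d, n = symmetric_fixed_point(params)
    d = max(d, 1e-3)
    x0 = np.array([d * (1 + asymmetry), n, d * (1 - asymmetry), max(n, 1e-3)])
    sol = solve_ivp(lambda t, x: two_cell_rates(np.maximum(x, 0.0), params),
                    (0.0, t_end), x0, rtol=1e-8, atol=1e-10)
    xf = np.maximum(sol.y[:, -1], 0.0)
    d1, _, d2, _ = xf
    mean_d = (d1 + d2) / 2
    patterned = mean_d > 1e-12 and abs(d1 - d2) > 0.1 * mean_d
    return xf, bool(patterned)
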