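# Methods

## The model hierarchy

`pnwave` simulates the proneural wave of the *Drosophila* optic lobe: a
travelling transition zone that converts neuroepithelial cells (NE) into
neuroblasts (NB), driven by EGFR signalling and the proneural gene *l'sc*,
and modulated by Delta–Notch signalling. Three nested variants share one
code path:

**E-only (bistable front).** A single diffusible field ϕE condenses the
EGFR/Rhomboid/Spitz autocrine loop:

    ∂ϕE/∂t = η ∇²ϕE + μ h(ϕE) − k ϕE,     h(x) = (x/a)ⁿ / (1 + (x/a)ⁿ)

With μ/k = 4, n = 3, a = 1 the kinetics are bistable (stable states at 0 and
≈3.935, threshold ≈0.537) and support a front that invades the quiescent
state at constant speed, leaving elevated signalling behind.

**E + L (excitable pulse).** L'sc (ϕL) is produced downstream of EGFR and
quenches the EGFR gain:

    ∂ϕE/∂t = η ∇²ϕE + μE h(ϕE)(1 − h(ϕL)) − kE ϕE
    ∂ϕL/∂t = μL h(ϕE) − kL ϕL

with μL = 0.4, kL = 0.2. The slow L build-up converts the bistable front
into an excitable pulse: the only homogeneous attractor is the quiescent
state, a super-threshold kick triggers a large transient excursion, and the
travelling solution is a localized pulse of signalling and proneural
expression — the transition zone.

**Integrated model.** Per cell on a lattice, five fields: ϕE, ϕL, Delta ϕD,
Notch ϕN, and an irreversible cell-state order parameter Ω (0 = NE,
1 = NB). Writing h_XY for the Hill response of interaction "X on Y" and
⟨ϕD⟩ for the mean Delta over lattice neighbours:

    dϕE/dt = η ∇²ϕE + (1−Ω)[μE h_EE(ϕE)(1 − h_LE(ϕL)) + σN h_NE(ϕN)] − kE ϕE
    dϕL/dt = (1−Ω) μL h_EL(ϕE)(1 − h_NL(ϕN)) − kL ϕL
    dϕD/dt = (1−Ω) μD [b_D + (1−b_D) h_ED(ϕE)] (1 − h_ND(ϕN)) − kD ϕD
    dϕN/dt = [β + μN h_T(⟨ϕD⟩)] (1 − h_C(ϕD)) (1 − h_LN(ϕL)) − kN ϕN
    dΩ/dt  = k_Ω (1−Ω) [h_LΩ(ϕL) + h_EΩ(ϕE)(1 − h_NΩ(ϕN))]

Each term realizes one regulatory arrow: EGFR self-activation quenched by
L'sc; Notch→EGFR reinforcement (σN); EGFR→L'sc activation repressed by
Notch; EGFR→Delta upregulation on top of a small ligand-independent basal
Delta drive (fraction b_D of μD), both repressed by Notch in the same cell;
Notch production from a basal rate β plus trans-activation by neighbour
Delta, subject to cis-inhibition by the cell's own Delta and to repression
by L'sc; and an irreversible NE→NB conversion promoted by L'sc and by EGFR
when Notch is low. Production of E, L and D is gated by the neuroepithelial
occupancy (1−Ω), so completed neuroblasts cease transition-zone signalling;
Notch production is not gated, so neuroblasts recover basal Notch — low
Notch is a property of the transition zone only, as observed.

The basal Delta drive deserves a note: without it, Delta production would be
strictly slaved to EGFR activity and the lateral-inhibition loop would be
inert in quiescent neuroepithelium. The "oversaturation" mechanism — basal
Notch keeps Delta from rising before EGFR signalling arrives — presupposes
that Delta *could* rise without EGFR; b_D is that latent drive, and it is
also what the isolated two-cell Delta–Notch subsystem (below) exposes as its
μ_D. Default b_D = 0.15.

## Default parameters ("reconstructed defaults")

The front and pulse presets use the printed values (μ = 4, n = 3, a = 1;
μL = 0.4, kL = 0.2). The integrated model's parameter table is not
reproduced here from any source; the shipped defaults are the package's own
calibration, chosen once so that the model jointly displays the documented
tissue phenomenology (travelling zone with colocalized E/L/D pulses and a
Notch pre-peak; the six clone phenotypes; suppression of lateral inhibition
by basal Notch; EGFR-dominated speed control) and then frozen:

| parameter | value | meaning (units: cell spacing, E-decay time 1/kE) |
|---|---|---|
| η | 0.05 | EGFR signal diffusion (spacings²/time) |
| μE, kE | 8, 1 | EGFR gain and decay |
| μL, kL | 0.4, 0.2 | L'sc production and decay (slow: sets the zone) |
| μD, kD | 4, 1 | Delta production and decay |
| μN, kN | 10, 2 | Delta-mediated Notch gain (trans) and Notch decay |
| β | 10 | basal Notch production (NE plateau ϕN ≈ 5) |
| b_D | 0.15 | basal (EGFR-independent) fraction of Delta drive |
| σN | 0.05 | Notch→EGFR reinforcement |
| k_Ω | 0.4 | NE→NB conversion rate |

Hill interactions default to n = 3, a = 1 except where an interaction's
threshold sets a scale separation: N_on_L and N_on_D use a = 3 and
N_on_Omega a = 2 (the NE Notch plateau ≈5 holds L'sc, Delta and conversion
off; the zone's Notch trough ≈0.5–1.5 releases them); L_on_N uses a = 0.3
(zone-level L'sc collapses Notch); D_trans a = 0.5 and D_cis a = 1 set the
lateral-inhibition loop gain; L_on_Omega uses n = 2, a = 0.35 so that even
attenuated L'sc (as in Notch-overexpressing tissue) eventually drives
conversion rather than deadlocking it. μE = 8 (not the printed 4 of the
reduced models) keeps the excitation threshold low enough that the front
propagates robustly at the small η of the tissue simulations, including
into clone territory lacking the σN reinforcement.

The wavefront mechanism under these defaults: the E front ignites cell by
cell; Notch holds L'sc, Delta and conversion off until cis-inhibition and
L'sc-mediated repression collapse Notch locally; the Notch trough releases
the transition. The conversion lag behind the E front is therefore
Notch-limited, which is what makes Notch-downregulated clones advance the
(Ω-defined) wavefront and Notch-overexpressing clones delay it, while the
transient trans-activation of neighbours ahead of the zone produces the
Notch pre-peak.

## Numerics

* Explicit forward-Euler stepping; step size validated against
  dt ≤ 0.2/(max decay rate + 6 η c), with c the Laplacian stencil factor
  (1 on chains, 2/3 on hexagonal lattices, exact for quadratics at unit
  spacing). Default dt is a quarter of the bound; tissue runs use dt = 0.02.
* No-flux boundaries arise from neighbour-deficient stencils; total mass
  under pure diffusion is conserved to machine precision.
* Stochastic runs add independent Euler–Maruyama increments of standard
  deviation γ√dt to each signalling field (not Ω), then clip at zero.
  Ω is clipped to [0, 1].
* Hexagonal lattices use unit centre spacing; rectangular patches are
  column-offset ("odd-q", odd columns shifted +1/2) so the wave axis is the
  x/column direction; discs are generated from the axial basis and carry
  per-cell polar angles for sector initial conditions. Results are invariant
  to the offset parity choice up to single-cell shifts.
* "Elevated E" initial conditions default to the upper stable root of the
  E kinetics, guaranteeing super-threshold excitation.

## Noise strength

The stochastic tissue protocol uses γ = 0.03 by default. Additive noise at
strengths of order the kinetic rates (γ ≈ μE/2) ignites the excitable E
field everywhere within a couple of time units — every cell converts long
before the wave could cross the tissue, for any basal-Notch level — so no
wave phenomenology survives at such amplitudes under these kinetics. γ was
therefore calibrated (once) to the largest scale at which the sector-
initiated wave stays coherent over the full disc protocol; the
lateral-inhibition contrast between the two basal-Notch regimes is then wide
(median neighbour-correlation index ≈ −0.29 at β = 1 versus ≈ −0.02 at
β = 10) and insensitive to γ over at least a factor of two.

## Observables and calibration constants

* **Wavefront position**: furthest column at which the per-column mean of
  Ω (or ϕE normalized by the upper stable root, for the E-only model)
  crosses 1/2, linearly interpolated; −∞ sentinel when absent.
* **Wave speed**: least-squares slope of front position vs time, dropping
  the first 20% of the run (initiation transient) and boundary-collision
  states; reported with the fit R².
* **Transition-zone width**: time-averaged column span where the ϕL
  profile is at least half its instantaneous maximum (a single qualifying
  column has width 1), over the central 60% of the run. Width is measured
  on L'sc because the zone is defined by proneural expression.
* **Notch pre-peak**: a local maximum of the ϕN column profile ahead of the
  L'sc zone centre exceeding the far-field plateau by ≥2%.
* **Salt-and-pepper index**: Moran-type neighbour correlation of the
  standardized field over a cell mask; −1 for a perfect alternating
  two-coloring of a chain, ≈0 for spatially random fields. The
  lateral-inhibition detection protocol measures ϕN over interior
  neuroepithelial cells (Ω < 0.5, ϕE < 0.5, all neighbours likewise) at
  t = 15 of the disc protocol; the decision thresholds −0.2 (patterned)
  and −0.05 (suppressed) are package calibration constants.
* **Clone phenotypes**: LOST if no clone cell reaches Ω ≥ 0.5 by the end of
  the run (t = 50); otherwise the wavefront within the clone's rows is
  compared with wildtype at the evaluation snapshot (t = 25, or t = 17.5
  for constitutively active EGFR), with one column as the minimal
  detectable shift. The clone itself is a 5-column × 7-row rectangle placed
  ahead of the initial front. Constitutive (transgene-driven) EGFR forcing
  persists after conversion, i.e. force-activated cells skip the (1−Ω)
  gate in the E equation — which is also what lets a single such cell
  nucleate a target wave.

## Morris screening

The sampler builds r one-at-a-time trajectories on a p = 4 level grid with
jump Δ = p/(2(p−1)) = 2/3 in normalized coordinates; rate parameters map
log-uniformly onto ±50% ranges around the preset. Elementary effects are
available per native parameter unit or per normalized jump; rankings use
the normalized scale, since per-unit effects are incomparable across
parameters with different magnitudes. Indices: m (mean), m* (mean
absolute), σ (sample standard deviation). Runs whose front fit fails
(R² < 0.8 or no front) are excluded and counted. The default screening
protocol is a 60-cell chain integrated to t = 40 — large enough for a
steady zone, small enough that a full r = 50 plan runs in minutes.

## Two-cell subsystem

The Delta–Notch pair isolates lateral inhibition (EGFR and Ω frozen):

    dN_i/dt = [β + λ h_T(D_j)] (1 − h_C(D_i)) − kN N_i
    dD_i/dt = μ_D (1 − h_R(N_i)) − kD D_i

with the tissue model's Hill responses and μ_D = 1 (the basal Delta drive at
a neuroepithelial resting state). The symmetric fixed point reduces to one
scalar root-find in N*; lateral inhibition is declared when the Jacobian
restricted to the anti-symmetric subspace (δD₁ = −δD₂, δN₁ = −δN₂) has a
positive leading eigenvalue. A brute-force cross-check integrates the pair
from 1%-asymmetric initial conditions and calls it patterned when the final
Delta levels differ by more than 10% of their mean; the two routes agree on
100/100 points of the default (β, λ) grid (β up to 30, λ up to 20). High β
"oversaturates" the pair: Notch represses Delta below the trans-activation
threshold everywhere, D* falls monotonically with β, and the patterned
region is bounded in β at every λ.

## What the synthetic protocols do and do not show

All inputs are generated by the package itself (there is no external data):
step-front, Gaussian-pulse, checkerboard and random-field fixtures carry
analytic ground truth for the observables, and the study protocols above
are idealizations — static lattices without growth, division or
rearrangement, a single condensed EGFR variable, additive white noise, and
qualitative clone geometry. Passing tests show that the implemented
mechanisms produce the documented phenomenology under these idealizations;
they do not validate kinetic parameter values against measurements, nor do
they speak to pathways deliberately left out (JAK/STAT, Hippo).

## Known limitations

* The integrated-model defaults are a calibrated reconstruction; other
  parameter sets may realize the same phenomenology.
* The conversion-lag mechanism makes clone phenotypes sensitive to the
  Notch gate thresholds; margins at the shipped defaults are ≥1.5 columns.
* At η below ≈0.02 (spacings²/time) discrete-lattice pinning stops the
  front; the shipped tissue presets stay well above this.
* Explicit Euler is first-order; halving dt changes front speeds by ≪1%
  at the default steps, but stiff parameter extremes in sensitivity scans
  are excluded by the degenerate-run filter rather than resolved.
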