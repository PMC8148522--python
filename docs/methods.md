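# Methods

This note records the model, the numerical choices, and the limits of
validity of `edchannel`.

## Physical model

Ion permeation through a channel is reduced to one dimension: a single
ion diffuses along the pore axis `z` on a potential of mean force (PMF)
`A(z)` with constant diffusivity `D`, between two absorbing boundaries
`z_min` and `z_max` that represent the bulk reservoirs.  An applied
membrane voltage `ΔV` enters as a *boxcar field*: the electric potential
`V(z)` rises linearly from 0 to `ΔV` inside a window `[z_a, z_b]`
(by default the whole channel) and is constant outside it.  The total
energy governing the dynamics is

    E(z) = A(z) + q e V(z),

with `q` the ion's charge in elementary units.  **Sign convention:**
positive `ΔV` raises the energy of a `q = +1` ion at `z_max`, i.e. it
*opposes* forward (z_min → z_max) cation motion.

The coarse-grained dynamics is the overdamped Langevin equation, whose
ensemble behaviour is the Smoluchowski (1D Nernst–Planck) equation

    J = −D ∂ρ/∂z − β D ρ ∂E/∂z,        β = 1/kT.

Units throughout: Å, ns, kcal/mol, elementary charges, mV, K.
Conversions: `k_B = 0.0019872041 kcal/mol/K`, `1 e·mV = 0.0230605
kcal/mol`, `1 e/ns = 160.2176634 pA`, thermal voltage `kT/e = 25.693 mV`
at 298.15 K.

## Closed-form steady-state solutions (the oracle)

With absorbing boundaries, the steady state admits quadrature solutions
used as ground truth throughout the package and its tests:

* committor (splitting probability)
  `P(z) = ∫_{z_min}^{z} e^{βE} dz' / ∫_{z_min}^{z_max} e^{βE} dz'`;
* net flux for reservoir line densities ρ(z_min), ρ(z_max):
  `J = [ρ(z_min) e^{βE(z_min)} − ρ(z_max) e^{βE(z_max)}] / ∫ e^{βE}/D dz`,
  which splits into one-sided fluxes `J_f` (entered at z_min) and `J_b`
  with `J = J_f − J_b`;
* one-sided densities `ρ_f ∝ e^{−βE} ∫_z^{z_max} e^{βE}` and
  `ρ_b ∝ e^{−βE} ∫_{z_min}^z e^{βE}`, normalized to 1 at their entry
  boundary so that the pair is mutually consistent with `(J_f, J_b)` at
  unit reservoir densities.

All `e^{βE}` factors are evaluated with `max(βE)` subtracted, so
surfaces with tall barriers (checked to 40 kcal/mol) do not overflow.
Quadratures are trapezoidal on the surface grid; `edchannel validate`
verifies second-order grid convergence and compares the committor to an
independent finite-difference boundary-value solve.

## Stochastic simulator

Trajectories follow Euler–Maruyama:
`z_{n+1} = z_n − βD E'(z_n) dt + √(2D dt) ξ_n`, with `E'` interpolated
linearly from the grid gradient.  Ensembles are injected at a point `ε`
inside one boundary (default: one histogram bin width) and propagated to
absorption at either boundary.

Two discrete-time biases matter and both are handled with the
Broadie–Glasserman–Kou continuity correction (constant
`−ζ(1/2)/√(2π) · √(2D dt) ≈ 0.5826 σ_step`):

1. *absorption*: a discrete walk misses intra-step boundary touches, so
   the absorbing thresholds are shifted inward by the correction;
2. *first-passage counting*: per-bin "reach" counts `N(z)` (how many
   trajectories ever visited a plane, needed by committor estimators)
   are taken from each trajectory's extreme excursion shifted by the
   same constant and evaluated at bin centers.

Without the correction, crossing fractions at accessible `dt` are biased
by several binomial standard deviations; with it, free-diffusion
crossing fractions match `ε/L` within statistics.

Defaults and guards: `dt = bin_width²/(32 D)` (per-step RMS displacement
of a quarter bin); runs are refused if the RMS step exceeds two bins, if
the channel has fewer than 16 bins, or if `ε` is not in `(0, L/4)`;
trajectories truncated at `max_steps` are counted, warned about beyond
1 ppm, and fail the run beyond 0.1%.  Every ensemble is reproducible
from one integer seed; replicate campaigns draw per-set seeds from a
single root seed by `SeedSequence` stream splitting.

## Estimators

* **Detailed-balance weight** `w`: at `ΔV = 0` forward and backward
  crossing fluxes must cancel; `w` is the ratio of per-injection
  crossing probabilities from two calibration ensembles and multiplies
  all backward counts afterwards.
* **Committor**: one-sided `P = n_cross/N_f(z)` (forward) or
  `1 − n_cross/N_b(z)` (backward); two-sided
  `P = [n_f + w(N_b − n_b)]/[N_f + w N_b]`, valid wherever either
  ensemble visited.  When the forward direction has zero crossings, the
  backward profile is patched onto the forward one at a plane `z'` by
  continuity (the α-patched profile).  Bins whose denominators vanish,
  or that lie outside the injection points (where first-passage algebra
  does not hold), are masked — never interpolated.
* **Currents**: `J = (n_f − w n_b)/t_S` with Poisson errors `n^{-1/2}`;
  the stochastic time `t_S` is set by matching crossing counts to a
  reference simulation of known duration.

## PMF reconstruction

All methods reconstruct `ΔA(z)` up to an additive constant (referenced
at the first valid bin) and subtract the applied-voltage term at the end:

* **IEEM** (integrated electrodiffusion equation; needs `D` and net
  flux): `ΔA = −kT [ln(ρ/ρ_ref) + J ∫ dz/(Dρ)] − q e V(z)`.
* **CWDM** (current-weighted densities):
  `ΔA = −kT ln[J_b ρ_f(z) + J_f ρ_b(z)] + C − q e V(z)`; exact when each
  one-sided density is entry-normalized.  *Unavailable* when either
  direction has zero crossings.
* **CPM** (committor + density), one-sided:
  `ΔA = −kT ln[ρ_f/(1 − P)]` or `−kT ln[ρ_b/P]` (minus the voltage
  term); both-direction data are merged by a WHAM-style estimator
  `ΔA = −kT ln[(g_f + w g_b)/(n_f(1 − P) + w n_b P)] + C − q e V(z)`,
  where the measured crossing counts are the statistically optimal
  weights (no iteration needed).  CPM remains available in the
  rare-event regime where CWDM fails.

Replicate campaigns reconstruct one PMF per independent data set and
report across-set mean and SD; pooling trajectories before estimating is
deliberately not offered.

## Current–voltage curves from one voltage

The ratio of the integrated ED equation at two voltages gives

    J_f(ref)/J_f(V) = 1 + βq(E_V − E_ref) ∫ f(z) e^{βq(V_V − V_ref)} dz,

with `f = 1 − P` (committor mode) or `f = e^{βΔE} ρ_f/ρ_f(z_min)`
(density mode); the backward current picks up the boundary factor
`e^{βq(ΔV_V − ΔV_ref)}`.  The reconstructed curve passes through the
reference point exactly; a non-positive ratio far from the reference is
reported as numerical breakdown, never clipped.

Reversal potentials scale the cis-side (z_min-entry) fluxes of all ions
by a concentration ratio `r` and locate the zero of `Σ q_i (r J_f,i −
J_b,i)` by Brent bracketing within the Nernst bound `±(kT/e) ln r` plus
a margin.  The two-ion Goldman–Hodgkin–Katz voltage equation converts
`|ΔV_R|` into a permeability ratio `x = (r e^u − 1)/(r − e^u)`,
`u = |ΔV_R| e/kT`, defined only below the Nernst limit `e^u < r`.

## Synthetic surfaces

Four archetypes emulate the PMF shapes met in practice: `flat_well`
(wide, weakly attractive pore — near-GHK behaviour), `central_barrier`
(single activated crossing), `mouth_barriers` (twin entrance barriers
with an interior well — rectifying), and `tall_barrier` (≥5 kcal/mol —
the rare-event regime where one direction records no crossings at
accessible ensemble sizes).  Arbitrary tabulated PMFs load from
two-column TSV.

## Limitations

* Strictly 1D and single-ion: no ion–ion correlations, knock-on, or
  saturation; currents are linear in reservoir concentrations, so
  reversal-potential scaling assumes the unsaturated regime.
* `D` is constant along the pore.
* The boxcar field is imposed, not solved self-consistently
  (no Poisson coupling to the ion distribution).
* Discrete-time corrections are first-order in `√dt`; with the default
  `dt`, residual bias is below statistical noise at 10^6 trajectories.
* One-sided quantities are undefined between a boundary and its
  injection point; those bins are masked and slightly shrink the
  reconstructed window (by `ε` per side).
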