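# Methods

## Model

`lignosim` simulates the early stage of enzymatic hydrolysis of a single
representative lignocellulose particle in a finite batch. The particle is a
non-shrinking porous cylinder of radius *R* (much shorter than its length,
so end effects and the axial/angular coordinates drop out) containing
uniformly distributed cellulose, hemicellulose and lignin. Only cellulose
reacts; hemicellulose and lignin are inert mass and volume. The state at
radius *r* and time *t* is

* `C_E^F(r,t)` — free cellulase concentration in the pore fluid
  (mol/cm³ of pore fluid),
* `C_E^S(r,t)` — adsorbed cellulase per total particle volume (mol/cm³),
* `ε(r,t)` — accessible porosity.

The three balances are:

1. **Free enzyme.** Diffusion through the evolving pore network with
   effective diffusivity `ε·D_E`, where `D_E = D_pore/τ`, minus the
   adsorption sink, minus a dilution term as pore volume grows:

   `∂C_F/∂t = D_E [∂²C_F/∂r² + (1/r)∂C_F/∂r + (ε'/ε)∂C_F/∂r]
              − (1/ε)∂C_S/∂t − (C_F/ε)∂ε/∂t`

   The adsorption sink carries the 1/ε factor because bound enzyme is
   bookkept per total volume while free enzyme is per pore-fluid volume;
   without it the model would not conserve enzyme.

2. **Bound enzyme.** A time-dependent Langmuir isotherm,
   `∂C_S/∂t = k_ads·C_F·(C_max(ε) − C_S) − k_des·C_S`, whose capacity
   `C_max(ε) = C_max,0·(ε_f − ε)/(ε_f − ε_0)` declines linearly with
   porosity: consuming cellulose removes wall surface and with it binding
   sites. When overshoot puts `C_S > C_max` the adsorption term turns
   negative (net displacement), which is accepted and clamped only in the
   capacity itself.

3. **Porosity.** Hydrolysis is booked at desorption: each desorbing enzyme
   carries `M_p` moles of glucose out of the walls,
   `∂ε/∂t = k_des·C_S·M_p·MM_glu·H_glu/ρ_C^IV`, frozen once `ε ≥ ε_f`
   (hydrolyzable cellulose exhausted).

The bulk is a well-stirred finite reservoir of volume `V_B` coupled through
the outer surface: `dC_bulk/dt = −(2πR/V_B)·ε_s·D_E·∂C_F/∂r|_R`, with a
no-flux symmetry condition on the axis. All enzyme starts in the bulk.
Enzyme never leaves the system — desorbed enzymes return to the pore fluid;
only sugars are removed.

## Accessibility from the pore-size distribution

Pores are parallel-wall slits. A bin of width *w* and specific volume *v*
contributes wall area `2v/w` when both walls are reachable
(`w ≥ 2·d_E`), `v/w` when only one is (`d_E ≤ w < 2·d_E`), and nothing
when the cellulase (diameter `d_E` = 51 Å) cannot enter. Boundary widths
are assigned to the higher-accessibility class; the slit rule itself does
not fix them. Binding-site density is the accessible surface times
σ = 2.1e−12 mol/cm², the footprint of a 51 Å sphere. Derived quantities:
`ε_0` = accessible specific volume × ρ_p;
`ε_f = ε_0 + d·f_cell·ρ_p/ρ_C^IV` (digestible cellulose volume turned into
pores, an error above 1); `C_max,0` = site density × ρ_p. By construction
the yield saturates exactly at the digestibility *d*. An optional switch
scales the accessible surface by the cellulose mass fraction; it is off by
default (the whole accessible wall is treated as cellulose surface).

## Operating conditions

Per unit particle length, the particle mass is `m_p = ρ_p·πR²` and the bulk
volume `V_B = m_p/b_l`. Enzyme loading is molar:
`e_l` = enzyme moles per mole of initially accessible binding sites, so
`C_E0 = e_l · site_density · b_l`. A mass loading (mg protein/g substrate)
converts to `e_l` through an assumed lumped cellulase molar mass
(default 65 kg/mol). A biomass loading dense enough that `V_B` falls below
the particle's own pore volume is rejected as infeasible.

## Numerics

Method of Lines on a uniform cell-centred radial grid: *n* cells with
centres at `(i−1/2)Δr` (staggered off the axis so the 1/r singularity never
appears), faces at `iΔr`, bulk as node *n*+1 — 3(*n*+1) stiff ODEs. The
diffusion operator is a conservative finite-volume divergence with centred
second-order face fluxes (arithmetic-mean face porosity); the surface
gradient uses a second-order one-sided stencil through the bulk value, and
the identical flux expression feeds the outermost cell and the bulk ODE.
The semi-discrete system therefore conserves total enzyme moles exactly,
and the audited drift measures time-integration error alone. The surface
porosity in the boundary flux is the outermost interior value — the bulk
node's ε ≡ 1 is bookkeeping, not a physical surface layer.

Integration uses SciPy's BDF (variable-order backward differentiation,
the standard stiff multistep family) with rtol 1e−8 and per-block absolute
tolerances scaled to each block's natural magnitude (1e−6 × the larger of
`C_E0` and `C_max,0` for the two concentration blocks, 1e−9 for porosity),
with the Jacobian sparsity pattern supplied. Output times are geometric by
default over a 24 h horizon. Default *n* = 50. Runs are deterministic:
identical inputs give bitwise-identical trajectories.

**Conservation audit.** Total moles = `V_B·C_bulk + Σ ε·C_F·dV + Σ C_S·dV`
over the shells `dV = 2πr·Δr`. The audit reports the maximum relative drift
from the initial loading; the acceptance bar is 2% and the measured drift
at default settings is ~1e−6 of the loading.

**Degenerate inputs.** `e_l = 0` gives a constant trajectory; a PSD with no
accessible volume gives `ε_0 = C_max,0 = 0` and identically zero yield;
`d = 0` freezes porosity at `ε_0` (capacity stays flat until ε passes it).
Porosity in rate evaluations is floored at 1e−9 before division.

## Parameters

| symbol | meaning | default | units |
|---|---|---|---|
| k_ads | adsorption rate constant | 3e10 | cm³/(mol·min) |
| k_des | desorption rate constant | 0.068 | 1/min |
| σ | binding sites per surface | 2.1e−12 | mol/cm² |
| M_p | glucose per enzyme per cycle (fitted) | 755 | mol/mol |
| τ | tortuosity (fitted) | 2 | — |
| D_pore | pore diffusivity | Stokes–Einstein, ≈1.0e−4 | cm²/min |
| H_glu | anhydroglucose/glucose mass ratio | 0.9 | — |
| MM_glu | glucose molar mass | 180 | g/mol |
| d_E | cellulase footprint diameter | 51 | Å |

`D_pore` defaults to the Stokes–Einstein diffusivity of a 51 Å sphere in
water at 50 °C (viscosity 5.47e−4 Pa·s); override it when a measured value
is available. `M_p` and τ are the calibration targets; everything else is
treated as known.

## Calibration

`fit_mp_tau` minimises the unweighted sum of squared yield residuals
(optionally inverse-variance weighted) over all records of a
multi-substrate dataset, in `z = (log10 M_p, τ)` for conditioning, with
bounds M_p ∈ [1, 5000], τ ∈ [1, 10]. A deterministic 6-point start grid is
screened by SSE (one objective evaluation each, all reported) and the best
two starts are polished with a trust-region reflective solver. The
finite-difference step for the Jacobian is held at 1e−3 in z, well above
the forward solver's noise floor — with the default step the Jacobian is
dominated by integration error and the fit stalls. Identifiability needs
regime contrast: small-particle records pin M_p (reaction-limited), large
or low-loading records pin τ (diffusion-limited). Noise-free
self-consistency recovers generating parameters to optimizer tolerance.
Calibration forward runs use *n* = 12 and rtol 1e−6; the calibration-scale
problems are converged well below the fit tolerances at these settings.

## Synthetic fixtures

The generator emits four deterministic archetypes spanning a pretreatment
series: `native` (scarcely accessible, d ≈ 0.2), `mild`, `severe`
(d ≈ 0.85, site density ≈ 1.4 µmol/g cellulose — inside the 0.12–1.5
µmol/g span reported for acid-pretreated hardwoods, with ε_f ≤ 1), all at
25 µm diameter, and `ds2_beech` (200 µm radius, accessible surface
≈ 24 m²/g, emulating a wet-sieved 300–500 µm dilute-acid pretreated beech).
Seeds jitter pore volumes by ≤3% and digestibility by ≤0.02; the physics
downstream is seed-free. The fixtures emulate realistic accessibility,
composition and size, but not: particle size distributions (monodisperse),
component gradients across the wall, lignin binding, enzyme deactivation or
product inhibition — passing tests therefore validate the transport/
adsorption/erosion mechanism and its numerics, not a full bioprocess.

## Design choices and limitations

* The free-enzyme balance is solved in dimensional variables with scaled
  per-block tolerances rather than a nondimensional form; scaling hooks are
  the atol vector in `solver._atol_vector`.
* The two-phase signature of enzyme-starved runs (`e_l < 1`) is quantified
  with coverage referenced to the *initial* site capacity: the glucose
  release rate is proportional to total bound enzyme, so the maximum rate
  arrives strictly after coverage has reached 95% of its plateau.
* Out of scope by design: external mass transfer and external-surface
  adsorption (both negligible or unmeasurable at this scale), enzyme
  deactivation, product inhibition, pore jamming, lignin binding, particle
  fragmentation/swelling, oligomer speciation and multi-enzyme speciation.
  These bound the model to early hydrolysis times.
* The well-mixed three-ODE oracle, the closed-form Langmuir equilibrium and
  the desorption-flux integral used in the tests are independent
  reimplementations, not calls into the solver under test.
* Reported problem sizes: the reference verification run uses *n* = 50 and
  a 24 h horizon; grid-convergence checks double to *n* = 100; calibration
  exercises use *n* = 12 with two-substrate (8-record) datasets.
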