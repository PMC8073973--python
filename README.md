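# lignosim

Diffusion–reaction simulation of enzymatic lignocellulose hydrolysis in
evolving porous particles.

## What it does, and for whom

Saccharification of pretreated biomass is run with a *finite* amount of
cellulase: how fast glucose appears depends on whether enzymes can reach
the cellulose surface before the bulk reservoir empties. `lignosim` is for
bioprocess modellers and pretreatment researchers who want to untangle
those effects. It simulates a representative porous cylindrical particle in
a batch: cellulases diffuse from the bulk into the pore network, adsorb and
desorb on the accessible cellulose walls via a time-dependent Langmuir
isotherm, and every desorption event erodes the walls — porosity grows,
diffusion gets easier, binding sites disappear, and glucose accumulates.

The coupled balances on a radial grid (free enzyme `C_E^F`, bound enzyme
`C_E^S`, porosity ε, plus a finite bulk node):

```
∂C_F/∂t = D_E[∂²C_F/∂r² + (1/r)∂C_F/∂r + (ε'/ε)∂C_F/∂r] − (1/ε)∂C_S/∂t − (C_F/ε)∂ε/∂t
∂C_S/∂t = k_ads·C_F·(C_max(ε) − C_S) − k_des·C_S,   C_max(ε) linear in ε
∂ε/∂t   = k_des·C_S·M_p·MM_glu·H_glu / ρ_C^IV
dC_bulk/dt = −(2πR/V_B)·ε_s·D_E·∂C_F/∂r|_R
```

Cellulose accessibility comes from a wet-state pore-size distribution via a
slit-pore rule (two reachable walls for pores wider than two cellulase
diameters, one wall between one and two, nothing below 51 Å). The lumped
hydrolytic capacity `M_p` (glucose per enzyme per binding cycle) and the
pore tortuosity τ are the two calibrated parameters. See
`docs/methods.md` for the full model, numerics and assumptions.

## Worked example

```python
import numpy as np
import lignosim as ls

spec = ls.generate_synthetic_substrate(seed=1, archetype="severe")
traj = ls.simulate(spec, e_l=1.0, b_l=0.02, n=50, t_end=24 * 60.0)
res = ls.compute_result(traj)
k = int(np.argmin(np.abs(traj.times - 60.0)))  # output time nearest 1 h
print(f"yield(~1h) = {res.yield_fraction[k]:.3f}, "
      f"final = {res.yield_fraction[-1]:.3f}, "
      f"drift = {ls.enzyme_balance_audit(traj):.2e}")
```

prints

```
yield(~1h) = 0.465, final = 0.863, drift = 9.47e-07
```

i.e. at stoichiometric enzyme loading (`e_l = 1`, exactly enough cellulase
to cover every initially accessible binding site) and 2% dry matter, the
severely pretreated 25 µm fixture reaches 46% of theoretical glucose in the
first hour and saturates at its digestibility cap (d = 0.863) within 24 h,
with the enzyme mole balance closed to a drift of ~1e−6 of the loading.

The `examples/` scripts walk through each capability: accessibility from a
pore-size distribution (`01`), a full time course with the conservation
audit (`02`), enzyme-loading × particle-radius sweeps (`03`) and the
combined least-squares calibration of `(M_p, τ)` (`04`). A thin CLI wraps
the same functions: `lignosim simulate|sweep|fit|fixture|audit --help`.

### File formats

* Substrate spec (YAML/JSON): `radius_cm`, `apparent_density_g_cm3`,
  `cellulose_fraction`, `digestibility`, `cellulose_density_g_cm3`,
  `psd` (list of `{width_angstrom, volume_cm3_per_g}` or a CSV path with
  that header), optional `psd_cumulative`, `label`.
* Yield dataset (CSV): `substrate_id, time_min, yield_fraction`
  (+ optional `yield_se, e_l, b_l`).
* Outputs: long-format trajectory CSV
  (`time_min, node_index, r_cm, C_E_F, C_E_S, epsilon`), results CSV
  (`time_min, yield_fraction, titer_g_per_L, mean_coverage, bulk_fraction`)
  and a JSON manifest recording every parameter and the conservation drift.

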