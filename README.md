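# mechanotrace

Continuum–molecular analysis of membrane-protein mechanics from particle
trajectories: local stress tensor fields, surface tractions on a protein
density isocontour, lipid–protein binding quantification, and Arrhenius–Bell
unbinding kinetics.

## The scientific problem

Mechanosensitive channels such as MscL convert membrane tension into a
conformational change, and the forces doing the work cross the bilayer–protein
interface. Two complementary descriptions meet at that interface:

* **Continuum:** the Cauchy stress tensor σ(x), estimated on a voxel grid from
  particle positions, velocities and pairwise forces,

  σ(x) = (1/V_vox) ⟨ −Σᵢ mᵢ vᵢ⊗vᵢ w₁(xᵢ) + Σ_{i<j} f_ij⊗r_ij w₂(x; xᵢ, xⱼ) ⟩ₜ ,

  with tension-positive sign (pressure = −tr σ/3). On a surface with outward
  unit normal n̂ the traction **t = σ·n̂** gives the force per unit area one
  side exerts on the other; it decomposes into a normal magnitude t_n = t·n̂
  and a tangential (shear) part t_t = t − t_n n̂. The surface itself is an
  isocontour of the time-averaged, Gaussian-filtered mass density.

* **Molecular:** individual lipids hydrogen-bond lysine side chains through
  their headgroup oxygens (P–N distance ≈ 0.4 nm) and insert one acyl tail
  into hydrophobic surface cavities — the "tightly-bound" lipids that act as
  handles for force transmission. Pulling such a lipid with a constant force
  f accelerates dissociation per the Arrhenius–Bell law

  k(f) = (1/τ₀) · exp(f·x_β / kT),  ΔG = kT · ln(τ₀/τ_D),

  where x_β is the distance from the bound state to the transition state,
  τ₀ the spontaneous dissociation time and τ_D the inverse attempt rate.

`mechanotrace` implements this full analysis chain and exercises it on
synthetic toy systems with analytic oracles (ideal gas, harmonic dimer, a
coarse five-fold membrane-protein fixture with planted binding ground truth,
and Bell-law event times), so every pipeline stage is tested against a known
answer. It does not run molecular dynamics.

## Worked example

```python
import numpy as np
import mechanotrace as mt

# 1. stress oracle: an ideal gas obeys PV = NkT
gas = mt.gen_ideal_gas(1000, 310.15, (10, 10, 10), n_frames=100, seed=1)
grid = mt.compute_stress_grid(gas, mt.StressOptions(spacing=0.5, filter_width=0))
print(round(grid.pressure(), 1))            # 42.7  (bar; NkT/V = 42.8 at 310.15 K)

# 2. binding census on the planted fixture
traj, truth = mt.gen_membrane_protein_fixture(seed=1)
records = mt.classify_tightly_bound(traj)
print(len(records),                          # 10 tightly-bound lipids
      sum(r.inserted_tail == "short" for r in records))   # 8 insert the short tail

# 3. unbinding kinetics at five pulling forces
datasets = mt.gen_unbinding_times(seed=1)    # 530...1000 pN, Bell-law draws
bell, fits = mt.fit_kinetics_pipeline(datasets, n_bootstrap=100, seed=1)
print(round(bell.xbeta, 1))                  # 36.2  (pm, dissociation distance)
barrier = mt.barrier_estimate(bell.tau0)     # attempt times 1-20 ps
print(round(barrier.dg_low, 1), round(barrier.dg_high, 1))  # 10.2 13.2 (kT)
```

The numbers mean: the gridded stress reproduces the ideal-gas pressure
(42.8 bar) to sampling accuracy; the tightly-bound classifier recovers the
10 planted lipids (2 per protein monomer) and the 8/10 short-tail insertion
preference; and the kinetics pipeline — per-force exponential fits of the
unbound fraction P_u(t) = 1 − e^(−kt), then a log-linear regression of ln k
on force — recovers the dissociation distance x_β ≈ 35 pm and brackets the
binding barrier between ~10 and ~13 kT for attempt times of 20 and 1 ps.

A full demo pipeline (stress → traction surface in legacy-VTK → binding
tables → kinetics report → pulling plan) runs from the shell:

```sh
mechanotrace run --seed 1 --out demo_out
```

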