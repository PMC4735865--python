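# oxycav

Analysis of molecular-oxygen binding to internal protein cavities from
NMR titration, paramagnetic relaxation enhancement (PRE), and
molecular-dynamics trajectory data.

Dissolved O₂ is paramagnetic: when it partitions into a hydrophobic
cavity it shifts nearby resonances and accelerates proton relaxation
with a steep 1/r⁶ distance dependence. `oxycav` provides the three
quantitative analyses that turn those observables into binding
constants, per-site occupancies and ligand dynamics, for anyone
studying gas or small-ligand association with protein interiors (the
canonical test case being the cavity-enlarged L99A mutant of T4
lysozyme, whose xenon-binding sites serve as proxies for the O₂
locations):

1. **Binding isotherm** — under fast exchange the observed shift of
   nucleus *i* at dissolved-O₂ concentration [O₂] is

   Δδᵢ([O₂]) = Δδ_max,ᵢ · K[O₂] / (1 + K[O₂]),

   fitted globally over all nuclei with a single association constant
   *K* (M⁻¹) and per-nucleus saturation shifts Δδ_max (ppm).
   Derived quantities: K_d = 1/K (mM) and the bound fraction
   K[O₂]/(1+K[O₂]).

2. **Multi-site PRE model** — the longitudinal relaxation enhancement
   of proton *p* near *n* paramagnet sites is

   ΔR₁(p) = Σᵢ cᵢ·10⁵·rᵢ(p)⁻⁶ + f,

   with proton–site distances rᵢ (Å) from a hydrogen-bearing
   structure, occupancy-proportional site coefficients cᵢ ≥ 0 (fitted
   by non-negative least squares) and a baseline *f* (s⁻¹) from
   surface-diffusing O₂. The module also decomposes each prediction
   into per-site shares, forms cavity-to-cavity occupancy ratios from
   coefficient sums, bounds the binding probability against the
   6200 s⁻¹ permanent-contact rate, and screens protons within 6 Å of
   a site for severe line broadening.

3. **Trajectory analysis** — for a ligand position/orientation time
   series in the protein frame: voxelised occupancy densities with
   hotspot extraction (> 4× the mean occupied-voxel count), per-frame
   cavity assignment with binding/egress/transition events, and the
   rank-2 orientational autocorrelation C₂(τ) = ⟨P₂(u(t)·u(t+τ))⟩
   fitted by single- and bi-exponential decays to obtain rotational
   correlation times.

A synthetic-data module generates every input with known ground truth,
so the full pipeline is testable without spectrometer or MD output.

## Worked example

Generate a synthetic titration (five O₂ concentrations from 0.27 to
8.9 mM, twelve nuclei, realistic shift noise) and fit it:

```sh
oxycav simulate titration --seed 42 --out-dir demo
oxycav fit-isotherm demo/titration.tsv --bound-fraction 0.27
```

```
## fit
parameter	value	stderr
K_per_M	52.40197629	8.37419844
Kd_mM	19.08324973	3.049635366
ddmax_ppm[K85 N]	0.6631130215	0.1084943423
ddmax_ppm[Y88 N]	4.882249629	0.5769407903
...
```

The fitted association constant (52 ± 8 M⁻¹ here) agrees with the
generating value of 48 M⁻¹ within its standard error; `Kd_mM` is its
reciprocal, and the `--bound-fraction 0.27` flag appends the bound
population at atmospheric O₂ (≈1.4% for this replicate).

The PRE fit, from Python:

```python
from oxycav import synthdata, fit_pre, occupancy_ratio

geom = synthdata.gen_geometry(n_protons=50, seed=11)
pre = synthdata.gen_pre_field(table=geom.table, noise_sd=0.74, seed=1)
fit = fit_pre(pre.observations, geom.table)
print([round(float(c), 3) for c in fit.coefficients], round(fit.baseline, 3))
# [1.296, 1.101, 1.502, 0.113, 0.095] 1.089
print(round(100 * occupancy_ratio(fit, geom.sites, 3, 4), 1))
# 5.3
```

The five recovered coefficients match the generating values
(1.3, 1.1, 1.5, 0.11, 0.10; baseline 1.1) despite 0.74 s⁻¹ of
observation noise, and the cavity-3 : cavity-4 coefficient-sum ratio
puts the minor cavity's O₂ occupancy at ~5% of the major one's.

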